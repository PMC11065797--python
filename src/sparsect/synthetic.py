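"""Synthetic thorax phantoms and simulated reader annotations.

Stands in for patient CT slices and human observers: generates 2-D
HU-valued thorax phantoms (two lung fields, vessel-like structures,
optionally one nodule with its exact ground-truth mask) and draws
per-reader ordinal scores, detections, and noisy segmentations from a
configurable statistical reader model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

# HU conventions used by the phantom painter
HU_AIR = -1000.0
HU_LUNG = -800.0
HU_SOFT_TISSUE = 40.0
HU_VESSEL = 60.0
HU_NODULE = 20.0

#: smallest nodule rasterization considered meaningful, in pixels of diameter
MIN_NODULE_PX = 4.0

#: view levels shown to readers (512 excluded by design)
READER_STUDY_VIEWS = (16, 32, 64, 128, 256)

ARMS = ("sparse", "processed")


class SizingError(ValueError):
    """Raised when the image grid cannot hold a 1 cm nodule."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort."""

    n_subjects: int = 19
    diseased_fraction: float = 12.0 / 19.0
    image_size: int = 512
    pixel_spacing: float = 0.7  # mm per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.diseased_fraction <= 1.0:
            raise ValueError("diseased_fraction must lie in [0, 1]")
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass(frozen=True)
class PhantomSlice:
    """One synthetic CT slice with its ground truth."""

    subject_id: str
    image: np.ndarray  # HU values, (H, W)
    pixel_spacing: float  # mm / px
    diseased: bool
    nodule_mask: np.ndarray  # bool, same shape
    nodule_diameter: float  # cm (0.0 when healthy)

    def __post_init__(self) -> None:
        if self.image.shape != self.nodule_mask.shape:
            raise ValueError("image and nodule_mask shapes differ")
        if self.diseased != bool(self.nodule_mask.any()):
            raise ValueError("diseased flag inconsistent with nodule_mask")


@dataclass(frozen=True)
class ReaderProfile:
    """Statistical stand-in for one radiologist.

    Latent detectability and latent ordinal scores are linear in
    log2(view count); postprocessing adds a nonnegative boost whose
    strength fades as the view count approaches the level at which
    sparse and processed images become indistinguishable.
    """

    reader_id: str
    detection_slope: float = 1.2
    detection_intercept: float = -4.5
    processed_boost: float = 0.8
    segmentation_jitter: float = 1.5  # mm of translation noise on the mask
    false_mark_rate: float = 0.05
    # shared cut-points: 5 for the 6-point scales, 3 for the 4-point scale
    score_thresholds: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5, 4.5)
    artifact_thresholds: tuple[float, ...] = (1.5, 2.5, 3.5)
    score_noise: float = 0.6
    reader_shift: float = 0.0  # additive per-reader score offset

    def __post_init__(self) -> None:
        if self.detection_slope < 0:
            raise ValueError("detection probability must be nondecreasing in views")
        if self.processed_boost < 0:
            raise ValueError("processed_boost must be >= 0")
        for cuts in (self.score_thresholds, self.artifact_thresholds):
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError("score thresholds must be strictly increasing")

    def effect(self, view_count: int) -> float:
        """Postprocessing effect on latent scales, fading to 0 at 256 views."""
        return self.processed_boost * max(0.0, (8.0 - np.log2(view_count)) / 4.0)

    def detection_probability(self, view_count: int, processed: bool) -> float:
        z = self.detection_intercept + self.detection_slope * np.log2(view_count)
        if processed:
            z += self.effect(view_count)
        return float(1.0 / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class AnnotationRecord:
    """One reader x one image x one condition."""

    reader_id: str
    subject_id: str
    view_count: int
    arm: str  # "sparse" | "processed"
    quality: int  # 1..6
    confidence: int  # 1..6
    artifact: int  # 1..4
    segmentation: np.ndarray  # bool mask, possibly empty

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if not 1 <= self.quality <= 6:
            raise ValueError("quality out of range 1..6")
        if not 1 <= self.confidence <= 6:
            raise ValueError("confidence out of range 1..6")
        if not 1 <= self.artifact <= 4:
            raise ValueError("artifact out of range 1..4")


def _stable_hash(text: str) -> int:
    """Process-independent 32-bit hash (str.__hash__ is salted per run)."""
    return int.from_bytes(hashlib.blake2s(text.encode()).digest()[:4], "little")


def _subject_rng(config: CohortConfig, subject_id: str, seed: int | None = None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(entropy=base, spawn_key=(_stable_hash(subject_id),))
    return np.random.default_rng(ss)


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _soft_disk(shape: tuple[int, int], cy: float, cx: float, radius: float, edge: float) -> np.ndarray:
    """Disk with a Gaussian-smoothed rim; values in [0, 1]."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return np.clip(0.5 * (1.0 + np.tanh((radius - d) / max(edge, 1e-6))), 0.0, 1.0)


def _paint_vessels(
    image: np.ndarray, lung: np.ndarray, rng: np.random.Generator, n_vessels: int
) -> None:
    """Draw bright curvilinear structures (polyline strokes) inside a lung."""
    h, w = image.shape
    ys, xs = np.nonzero(lung)
    if ys.size == 0:
        return
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_vessels):
        i = rng.integers(ys.size)
        y, x = float(ys[i]), float(xs[i])
        angle = rng.uniform(0, 2 * np.pi)
        thickness = rng.uniform(0.006, 0.016) * h
        n_seg = rng.integers(3, 7)
        seg_len = rng.uniform(0.04, 0.10) * h
        for _ in range(n_seg):
            y2 = y + seg_len * np.sin(angle)
            x2 = x + seg_len * np.cos(angle)
            # distance from each pixel to the segment
            dy, dx = y2 - y, x2 - x
            norm2 = dy * dy + dx * dx + 1e-12
            t = np.clip(((yy - y) * dy + (xx - x) * dx) / norm2, 0.0, 1.0)
            dist = np.sqrt((yy - (y + t * dy)) ** 2 + (xx - (x + t * dx)) ** 2)
            stroke = np.clip(0.5 * (1.0 + np.tanh((thickness - dist) / 0.7)), 0, 1)
            stroke *= lung
            image[:] = np.maximum(image, HU_LUNG + stroke * (HU_VESSEL - HU_LUNG))
            y, x = y2, x2
            angle += rng.uniform(-0.6, 0.6)
            thickness *= rng.uniform(0.75, 0.95)


def generate_phantom(
    subject_id: str,
    diseased: bool,
    config: CohortConfig,
    seed: int | None = None,
) -> PhantomSlice:
    """Generate one thorax phantom slice, deterministic for a fixed seed.

    The slice holds an elliptical soft-tissue thorax (~0-40 HU) on an air
    background, two low-density lung fields with vessel-like strokes and,
    when ``diseased``, exactly one soft-tissue nodule of 1-2 cm equivalent
    diameter whose exact rasterized mask is returned.

    Raises
    ------
    SizingError
        If a 1 cm nodule cannot be represented on the grid (too few pixels
        per cm, or no lung region large enough to contain it).
    """
    rng = _subject_rng(config, subject_id, seed)
    n = config.image_size
    shape = (n, n)
    image = np.full(shape, HU_AIR, dtype=np.float64)

    # thorax ellipse, mildly randomized
    cy, cx = n * 0.52, n * 0.5
    ry = n * rng.uniform(0.30, 0.34)
    rx = n * rng.uniform(0.42, 0.46)
    body = _ellipse_mask(shape, cy, cx, ry, rx)
    image[body] = HU_SOFT_TISSUE

    # two lung fields
    lungs = []
    for side in (-1.0, 1.0):
        lcx = cx + side * n * rng.uniform(0.19, 0.22)
        lcy = cy - n * rng.uniform(0.0, 0.02)
        lry = ry * rng.uniform(0.72, 0.80)
        lrx = rx * rng.uniform(0.36, 0.42)
        lung = _ellipse_mask(shape, lcy, lcx, lry, lrx) & body
        image[lung] = HU_LUNG
        lungs.append(lung)

    for lung in lungs:
        _paint_vessels(image, lung, rng, n_vessels=int(rng.integers(5, 9)))

    nodule_mask = np.zeros(shape, dtype=bool)
    nodule_diameter = 0.0
    if diseased:
        px_per_cm = 10.0 / config.pixel_spacing
        if 1.0 * px_per_cm < MIN_NODULE_PX:
            raise SizingError(
                f"1 cm spans only {px_per_cm:.1f} px at {config.pixel_spacing} mm/px; "
                f"need >= {MIN_NODULE_PX} px to rasterize a nodule"
            )
        placed = False
        # try progressively smaller nodules if the lung is tight
        for _ in range(200):
            diameter_cm = rng.uniform(1.05, 1.95)
            radius_px = 0.5 * diameter_cm * px_per_cm
            lung = lungs[int(rng.integers(2))]
            eroded = _erode_margin(lung, radius_px + 2.0)
            ys, xs = np.nonzero(eroded)
            if ys.size == 0:
                continue
            i = rng.integers(ys.size)
            ncy, ncx = float(ys[i]), float(xs[i])
            yy, xx = np.mgrid[0:n, 0:n]
            nodule_mask = (yy - ncy) ** 2 + (xx - ncx) ** 2 <= radius_px**2
            area = int(nodule_mask.sum())
            eq_diam_cm = 2.0 * np.sqrt(area / np.pi) / px_per_cm
            if 1.0 <= eq_diam_cm <= 2.0:
                soft = _soft_disk(shape, ncy, ncx, radius_px, edge=1.5)
                image = np.maximum(image, HU_LUNG + soft * (HU_NODULE - HU_LUNG))
                nodule_diameter = eq_diam_cm
                placed = True
                break
            nodule_mask = np.zeros(shape, dtype=bool)
        if not placed:
            raise SizingError(
                f"no lung region can contain a 1-2 cm nodule at "
                f"{config.pixel_spacing} mm/px on a {n} px grid"
            )

    image = np.clip(image, -1024.0, 3000.0)
    return PhantomSlice(
        subject_id=subject_id,
        image=image,
        pixel_spacing=config.pixel_spacing,
        diseased=diseased,
        nodule_mask=nodule_mask,
        nodule_diameter=nodule_diameter,
    )


def _erode_margin(mask: np.ndarray, margin_px: float) -> np.ndarray:
    """Pixels of ``mask`` at least ``margin_px`` away from its boundary."""
    from scipy import ndimage

    dist = ndimage.distance_transform_edt(mask)
    return dist >= margin_px


def generate_cohort(config: CohortConfig) -> list[PhantomSlice]:
    """One slice per subject; diseased count = round(n * diseased_fraction)."""
    n_diseased = int(round(config.n_subjects * config.diseased_fraction))
    slices = []
    for i in range(config.n_subjects):
        subject_id = f"S{i:03d}"
        slices.append(
            generate_phantom(subject_id, diseased=i < n_diseased, config=config)
        )
    return slices


def _jitter_mask(
    mask: np.ndarray, jitter_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Translate a mask by a random integer offset drawn at scale jitter_px."""
    if jitter_px <= 0:
        return mask.copy()
    dy, dx = np.round(rng.normal(0.0, jitter_px, size=2)).astype(int)
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    ys = ys + dy
    xs = xs + dx
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    out[ys[keep], xs[keep]] = True
    return out


def _displaced_mark(
    truth_mask: np.ndarray, rng: np.random.Generator, radius_px: float
) -> np.ndarray:
    """A nonempty disk mark guaranteed to have zero overlap with the truth."""
    h, w = truth_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(100):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        if disk.any() and not (disk & truth_mask).any():
            return disk
    return np.zeros_like(truth_mask)  # give up: empty mark (still a miss)


def _latent_to_score(latent: float, cuts: Sequence[float]) -> int:
    return int(np.searchsorted(np.asarray(cuts), latent) + 1)


def simulate_annotations(
    cohort: Sequence[PhantomSlice],
    view_series_per_subject: dict[str, "object"] | None,
    readers: Sequence[ReaderProfile],
    seed: int,
    view_counts: Sequence[int] = READER_STUDY_VIEWS,
) -> list[AnnotationRecord]:
    """Simulate the full annotation grid: reader x subject x view x arm.

    Ordinal quality/confidence scores increase in log2(views) and with the
    processed arm; artifact severity decreases. Detections follow each
    reader's logistic model; detected nodules are segmented as jittered
    copies of the ground truth, misses yield empty masks or (rarely)
    displaced marks with zero overlap, and healthy images receive a false
    mark with probability ``false_mark_rate``.

    ``view_series_per_subject`` is accepted for interface completeness (the
    images shown to human readers); the statistical reader model needs only
    the ground truth in ``cohort``.
    """
    if len(readers) == 0:
        raise ValueError("reader list is empty")
    if view_series_per_subject is not None:
        missing = [s.subject_id for s in cohort if s.subject_id not in view_series_per_subject]
        if missing:
            raise ValueError(f"missing reconstructions for subjects: {missing}")

    records: list[AnnotationRecord] = []
    for r_idx, profile in enumerate(readers):
        for s_idx, slc in enumerate(cohort):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(r_idx, s_idx))
            rng = np.random.default_rng(ss)
            for v in view_counts:
                for arm in ARMS:
                    processed = arm == "processed"
                    eff = profile.effect(v) if processed else 0.0
                    lv = np.log2(v)
                    base = lv - 3.0 + profile.reader_shift
                    q = _latent_to_score(
                        base + eff + rng.normal(0, profile.score_noise),
                        profile.score_thresholds,
                    )
                    c = _latent_to_score(
                        base - 0.2 + eff + rng.normal(0, profile.score_noise),
                        profile.score_thresholds,
                    )
                    a_lat = 9.0 - lv - eff + rng.normal(0, profile.score_noise)
                    a = _latent_to_score(a_lat, profile.artifact_thresholds)
                    q = int(np.clip(q, 1, 6))
                    c = int(np.clip(c, 1, 6))
                    a = int(np.clip(a, 1, 4))

                    jitter_px = profile.segmentation_jitter / slc.pixel_spacing
                    mark = np.zeros_like(slc.nodule_mask)
                    if slc.diseased:
                        p_det = profile.detection_probability(v, processed)
                        if rng.uniform() < p_det:
                            mark = _jitter_mask(slc.nodule_mask, jitter_px, rng)
                            if not (mark & slc.nodule_mask).any():
                                mark = slc.nodule_mask.copy()  # jitter overshoot guard
                        elif rng.uniform() < 0.15:
                            radius = max(2.0, 0.5 * np.sqrt(slc.nodule_mask.sum() / np.pi))
                            mark = _displaced_mark(slc.nodule_mask, rng, radius)
                    else:
                        if rng.uniform() < profile.false_mark_rate:
                            radius = max(2.0, 0.01 * slc.image.shape[0])
                            mark = _displaced_mark(slc.nodule_mask, rng, radius)

                    records.append(
                        AnnotationRecord(
                            reader_id=profile.reader_id,
                            subject_id=slc.subject_id,
                            view_count=int(v),
                            arm=arm,
                            quality=q,
                            confidence=c,
                            artifact=a,
                            segmentation=mark,
                        )
                    )
    return records


def default_readers(n_readers: int = 3, processed_boost: float = 0.8) -> list[ReaderProfile]:
    """Three-radiologist default panel with small per-reader shifts."""
    shifts = [0.0, -0.15, 0.15, -0.3, 0.3]
    return [
        ReaderProfile(
            reader_id=f"R{i + 1}",
            processed_boost=processed_boost,
            reader_shift=shifts[i % len(shifts)],
        )
        for i in range(n_readers)
    ]
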