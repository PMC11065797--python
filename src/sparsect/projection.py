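"""Parallel-beam forward projection and filtered backprojection.

Wraps scikit-image's Radon transform and ramp-filtered backprojection
behind the acquisition-geometry contracts of the study: 2,048 evenly
spaced views over [0, 180) degrees, uniform-stride angular subsampling
anchored at angle 0, and reconstruction back onto the source grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

#: view counts used by the study: six sparse levels plus the full-view reference
STUDY_VIEW_COUNTS = (16, 32, 64, 128, 256, 512, 2048)
FULL_VIEW_COUNT = 2048


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry.

    ``n_detectors`` is derived from the image diagonal when left at None,
    which avoids projection truncation.
    """

    n_views_full: int = FULL_VIEW_COUNT
    angular_range: tuple[float, float] = (0.0, 180.0)  # degrees, half-open
    n_detectors: int | None = None
    beam: str = "parallel"
    filter_name: str = "ramp"

    def __post_init__(self) -> None:
        if self.n_views_full < 1:
            raise ValueError("n_views_full must be >= 1")
        if self.beam != "parallel":
            raise ValueError("only parallel-beam geometry is supported")
        lo, hi = self.angular_range
        if not hi > lo:
            raise ValueError("angular_range must be a nonempty interval")

    def angles_deg(self, n_views: int | None = None) -> np.ndarray:
        """Evenly spaced projection angles in degrees over the half-open range."""
        n = self.n_views_full if n_views is None else n_views
        lo, hi = self.angular_range
        return np.linspace(lo, hi, n, endpoint=False)


@dataclass(frozen=True)
class Sinogram:
    """Angle-ordered line-integral data, one row per view."""

    data: np.ndarray  # (n_views, n_detectors)
    angles: np.ndarray  # radians, strictly increasing
    geometry: Geometry
    image_size: int  # side of the square source image

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2-D")
        if self.data.shape[0] != len(self.angles):
            raise ValueError("rows(data) must equal len(angles)")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ViewSeries:
    """Reconstructions of one slice at several view counts."""

    subject_id: str
    reconstructions: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.reconstructions.values()}
        if len(shapes) > 1:
            raise ValueError("all reconstructions must share one shape")

    @property
    def view_counts(self) -> tuple[int, ...]:
        return tuple(sorted(self.reconstructions))

    @property
    def full_view(self) -> np.ndarray:
        """The densest reconstruction (the 2,048-view reference in study geometry)."""
        return self.reconstructions[max(self.reconstructions)]


def forward_project(image: np.ndarray, geometry: Geometry) -> Sinogram:
    """Parallel-beam Radon transform of a square image at all full views.

    Row k of the result holds the line integrals at ``angles[k]``; the
    operation is linear in the image and preserves total mass per view
    (sum over detectors ~ sum over pixels).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be a square 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    theta = geometry.angles_deg()
    # skimage returns (n_detectors, n_views); transpose to view-major rows
    sino = radon(image, theta=theta, circle=False).T
    if geometry.n_detectors is not None and sino.shape[1] != geometry.n_detectors:
        raise ValueError(
            f"geometry.n_detectors={geometry.n_detectors} does not match "
            f"projector output ({sino.shape[1]})"
        )
    diag = math.ceil(math.hypot(*image.shape))
    if sino.shape[1] < diag:
        raise AssertionError("detector row shorter than the image diagonal")
    return Sinogram(
        data=sino,
        angles=np.deg2rad(theta),
        geometry=geometry,
        image_size=image.shape[0],
    )


def subsample_views(sinogram: Sinogram, n_views: int) -> Sinogram:
    """Keep every (n_full/n_views)-th row starting at the first angle."""
    n_full = sinogram.n_views
    if n_views < 1 or n_full % n_views != 0:
        raise ValueError(
            f"n_views={n_views} must divide the full view count {n_full} "
            "to keep the angular spacing uniform"
        )
    stride = n_full // n_views
    return Sinogram(
        data=sinogram.data[::stride],
        angles=sinogram.angles[::stride],
        geometry=sinogram.geometry,
        image_size=sinogram.image_size,
    )


def fbp_reconstruct(sinogram: Sinogram) -> np.ndarray:
    """Ramp-filtered backprojection onto the source grid.

    Uses linear interpolation during backprojection; output shape equals
    the source image shape regardless of the number of views.
    """
    if sinogram.n_views == 0:
        raise ValueError("cannot reconstruct from an empty sinogram")
    theta = np.rad2deg(sinogram.angles)
    recon = iradon(
        sinogram.data.T,
        theta=theta,
        filter_name=sinogram.geometry.filter_name,
        interpolation="linear",
        circle=False,
        output_size=sinogram.image_size,
    )
    return recon


def make_view_series(
    image: np.ndarray,
    geometry: Geometry,
    view_counts: tuple[int, ...] = STUDY_VIEW_COUNTS,
    subject_id: str = "",
) -> ViewSeries:
    """Forward-project once, then reconstruct at every requested view count.

    The full-view (2,048) reference is always included.
    """
    counts = set(int(v) for v in view_counts)
    counts.add(geometry.n_views_full)
    full = forward_project(image, geometry)
    recons: dict[int, np.ndarray] = {}
    for v in sorted(counts):
        recons[v] = fbp_reconstruct(subsample_views(full, v))
    return ViewSeries(subject_id=subject_id, reconstructions=recons)
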