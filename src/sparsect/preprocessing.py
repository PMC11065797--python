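"""Windowing, residual labels, residual correction, and subject-level splits.

Sign convention (fixed once, package-wide): the training label is the pure
artifact ``residual = sparse - full`` on windowed/normalized images, so the
corrected image is ``sparse - prediction``. The equivalent formulation with
``full - sparse`` labels differs only by sign.

Residual pairs are quantized to a 2^-24 fixed-point lattice: differences of
lattice values are exactly representable in IEEE doubles, which makes the
reconstruction identity ``sparse - residual_label == full`` hold bit-exactly
(raw doubles can be off by 1 ulp). The quantization error (< 6e-8) is far
below reconstruction noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: fixed-point resolution of residual pairs (fraction bits)
RESIDUAL_QUANT_BITS = 24


def _quantize(image: np.ndarray) -> np.ndarray:
    scale = float(2**RESIDUAL_QUANT_BITS)
    return np.round(np.asarray(image, dtype=np.float64) * scale) / scale


@dataclass(frozen=True)
class WindowConfig:
    """Lung CT display window: clip interval [level - w/2, level + w/2]."""

    width: float = 1700.0  # HU
    level: float = -600.0  # HU

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


@dataclass(frozen=True)
class ResidualPair:
    """One training sample: normalized sparse input and pure-artifact label."""

    sparse: np.ndarray  # [0, 1]
    residual_label: np.ndarray  # sparse - full, in [-1, 1]
    view_count: int
    subject_id: str

    def __post_init__(self) -> None:
        if self.sparse.shape != self.residual_label.shape:
            raise ValueError("sparse and residual_label shapes differ")

    @property
    def full(self) -> np.ndarray:
        """The normalized full-view image implied by the pair (exact identity)."""
        return self.sparse - self.residual_label


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint subject-id partitions decided per subject, never per image."""

    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        parts = [self.train, self.validation, self.test]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("split partitions must be pairwise disjoint")

    @property
    def all_subjects(self) -> frozenset[str]:
        return self.train | self.validation | self.test


def apply_window(image_hu: np.ndarray, window: WindowConfig = WindowConfig()) -> np.ndarray:
    """Clip to the CT window and normalize to [0, 1].

    out = (clip(x, lo, hi) - lo) / width, so lo -> 0, level -> 0.5, hi -> 1.
    """
    image_hu = np.asarray(image_hu, dtype=np.float64)
    if not np.all(np.isfinite(image_hu)):
        raise ValueError("image contains non-finite values")
    return (np.clip(image_hu, window.lo, window.hi) - window.lo) / window.width


def make_residual_pair(
    full_norm: np.ndarray,
    sparse_norm: np.ndarray,
    view_count: int,
    subject_id: str,
) -> ResidualPair:
    """Form the pure-artifact label ``sparse - full`` from windowed images.

    Inputs are snapped to the 2^-24 lattice so that
    ``pair.sparse - pair.residual_label`` reconstructs the (quantized)
    full-view image bit-exactly.
    """
    full_norm = np.asarray(full_norm, dtype=np.float64)
    sparse_norm = np.asarray(sparse_norm, dtype=np.float64)
    if full_norm.shape != sparse_norm.shape:
        raise ValueError("full and sparse images must share a shape")
    full_q = _quantize(full_norm)
    sparse_q = _quantize(sparse_norm)
    return ResidualPair(
        sparse=sparse_q,
        residual_label=sparse_q - full_q,
        view_count=int(view_count),
        subject_id=subject_id,
    )


def apply_residual_correction(
    sparse_norm: np.ndarray,
    predicted_residual: np.ndarray,
    clip: bool = True,
) -> np.ndarray:
    """Subtract the predicted artifact from the sparse input.

    With a perfect prediction (the true ``sparse - full`` label) the output
    is the full-view image exactly. ``clip`` bounds the result to [0, 1]
    before metric computation; pass ``clip=False`` for the raw difference.
    """
    sparse_norm = np.asarray(sparse_norm, dtype=np.float64)
    predicted_residual = np.asarray(predicted_residual, dtype=np.float64)
    if sparse_norm.shape != predicted_residual.shape:
        raise ValueError("shape mismatch between input and prediction")
    out = sparse_norm - predicted_residual
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def split_cohort(
    subject_ids: Sequence[str],
    fractions: tuple[float, float, float],
    seed: int,
) -> DatasetSplit:
    """Random subject-level train/validation/test split, deterministic in seed.

    Partition sizes are the rounded fractions (largest-remainder), so e.g.
    22 subjects at (12/22, 2/22, 8/22) give sizes (12, 2, 8) exactly.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject_ids must be unique")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    # largest remainder rounding to distribute the leftover subjects
    order = np.argsort([s - r for s, r in zip(sizes, raw)])
    for k in range(n - sum(sizes)):
        sizes[order[k % 3]] += 1
    n_nonzero = sum(1 for f in fractions if f > 0)
    if n < n_nonzero:
        raise ValueError("fewer subjects than nonzero partitions")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    train = frozenset(shuffled[: sizes[0]])
    validation = frozenset(shuffled[sizes[0] : sizes[0] + sizes[1]])
    test = frozenset(shuffled[sizes[0] + sizes[1] :])
    return DatasetSplit(train=train, validation=validation, test=test)
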