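"""MSE and SSIM image-quality metrics with mean / 95%-CI aggregation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity


@dataclass(frozen=True)
class IQRecord:
    subject_id: str
    view_count: int
    arm: str  # "sparse" | "processed"
    mse: float
    ssim: float

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")
        if self.ssim > 1.0 + 1e-12:
            raise ValueError("ssim cannot exceed 1")


@dataclass(frozen=True)
class IQSummary:
    mean: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("confidence interval must bracket the mean")


def mse(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Mean of squared pixel differences."""
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((a - b) ** 2))


def ssim(image_a: np.ndarray, image_b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity with Gaussian 11-pixel windows.

    Standard constants K1=0.01, K2=0.03, sigma=1.5, population covariance —
    the reference formulation for images normalized to ``data_range``.
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def summarize(values: Sequence[float], confidence: float = 0.95) -> IQSummary:
    """Mean with a two-sided Student-t confidence interval of the mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if np.all(v == v[0]):  # exactly constant: degenerate zero-width interval
        c = float(v[0])
        return IQSummary(mean=c, ci_low=c, ci_high=c, n=int(v.size))
    m = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    if sem == 0.0:
        return IQSummary(mean=m, ci_low=m, ci_high=m, n=int(v.size))
    tq = float(stats.t.ppf(0.5 + confidence / 2.0, df=v.size - 1))
    return IQSummary(mean=m, ci_low=m - tq * sem, ci_high=m + tq * sem, n=int(v.size))
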