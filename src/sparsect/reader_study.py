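"""Observer-study analytics.

Dice overlap with the zero rule, image-level detection classification,
diagnostic summary metrics, pooled score means, and the clustered
Wilcoxon signed-rank test (Rosner-Glynn-Lee construction) used to compare
the processed and sparse arms per view level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sparsect.synthetic import AnnotationRecord, PhantomSlice

__all__ = [
    "AnnotationRecord",
    "DetectionOutcome",
    "DiagnosticSummary",
    "PairedClusteredSample",
    "dice",
    "classify_detection",
    "diagnostic_metrics",
    "clustered_wilcoxon",
    "summarize_scores",
    "paired_sample",
]


@dataclass(frozen=True)
class DetectionOutcome:
    reader_id: str
    subject_id: str
    view_count: int
    arm: str
    label: str  # TP | FP | FN | TN
    dsc: float | None  # defined only for TP

    def __post_init__(self) -> None:
        if self.label not in ("TP", "FP", "FN", "TN"):
            raise ValueError("label must be one of TP/FP/FN/TN")
        if (self.label == "TP") != (self.dsc is not None):
            raise ValueError("dsc is defined exactly for TP outcomes")


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    npv: float | None
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PairedClusteredSample:
    """Paired (processed, sparse) values with a cluster key per pair."""

    processed: np.ndarray
    sparse: np.ndarray
    clusters: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.processed) == len(self.sparse) == len(self.clusters)):
            raise ValueError("processed, sparse, and clusters must align")
        if any(c is None or c == "" for c in self.clusters):
            raise ValueError("cluster keys must be non-null")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); zero if either mask is empty
    or the masks do not overlap."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        return 0.0
    inter = int((a & b).sum())
    if inter == 0:
        return 0.0
    return 2.0 * inter / (na + nb)


def classify_detection(record: AnnotationRecord, truth: PhantomSlice) -> DetectionOutcome:
    """Image-level detection label.

    Diseased subject: a mark overlapping the ground truth is TP (with its
    Dice value); an empty mark, or a displaced mark with zero overlap, is
    FN. Healthy subject: any mark is FP, an empty mark is TN.
    """
    if record.subject_id != truth.subject_id:
        raise ValueError(
            f"record subject {record.subject_id!r} does not match truth {truth.subject_id!r}"
        )
    marked = bool(record.segmentation.any())
    if truth.diseased:
        if marked and (record.segmentation & truth.nodule_mask).any():
            return DetectionOutcome(
                record.reader_id,
                record.subject_id,
                record.view_count,
                record.arm,
                "TP",
                dice(record.segmentation, truth.nodule_mask),
            )
        return DetectionOutcome(
            record.reader_id, record.subject_id, record.view_count, record.arm, "FN", None
        )
    if marked:
        return DetectionOutcome(
            record.reader_id, record.subject_id, record.view_count, record.arm, "FP", None
        )
    return DetectionOutcome(
        record.reader_id, record.subject_id, record.view_count, record.arm, "TN", None
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostic_metrics(outcomes: Sequence[DetectionOutcome]) -> DiagnosticSummary:
    """Sensitivity, specificity, F1, NPV from a list of outcomes.

    Undefined ratios (zero denominators) are reported as None, never 0.
    """
    if len(outcomes) == 0:
        raise ValueError("empty outcome list")
    tp = sum(1 for o in outcomes if o.label == "TP")
    fp = sum(1 for o in outcomes if o.label == "FP")
    fn = sum(1 for o in outcomes if o.label == "FN")
    tn = sum(1 for o in outcomes if o.label == "TN")
    return DiagnosticSummary(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        npv=_ratio(tn, tn + fn),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def clustered_wilcoxon(
    sample: PairedClusteredSample,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Clustered Wilcoxon signed-rank test on paired differences.

    Rosner-Glynn-Lee construction: signed midranks of the nonzero
    differences are summed within clusters; the statistic is
    Z = sum(S_c) / sqrt(sum(S_c^2)), which is asymptotically standard
    normal under the null of sign-exchangeable clusters. Zero differences
    are dropped before ranking (classical convention). With singleton
    clusters the test reduces exactly to the classical signed-rank test's
    normal approximation (no continuity correction, midrank tie handling).

    Returns (Z, p). All-zero differences give (0.0, 1.0) — the degenerate
    no-evidence convention. A single cluster of nonzero differences is an
    error: the variance estimate needs at least two clusters.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater, less, or two-sided")
    d = np.asarray(sample.processed, dtype=np.float64) - np.asarray(
        sample.sparse, dtype=np.float64
    )
    clusters = np.asarray(sample.clusters)
    nonzero = d != 0
    if not nonzero.any():
        return 0.0, 1.0
    d = d[nonzero]
    clusters = clusters[nonzero]
    if len(set(clusters.tolist())) < 2:
        raise ValueError("need >= 2 clusters with nonzero differences")
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    signed = np.sign(d) * ranks
    cluster_sums = pd.Series(signed).groupby(pd.Series(clusters)).sum().to_numpy()
    total = float(cluster_sums.sum())
    var = float((cluster_sums**2).sum())
    if var == 0.0:
        return 0.0, 1.0
    z = total / np.sqrt(var)
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


def paired_sample(
    records: Sequence[AnnotationRecord],
    value: str | Callable[[AnnotationRecord], float],
    view_count: int,
    cluster_by: str = "subject",
) -> PairedClusteredSample:
    """Pair processed vs sparse records of one view level.

    Pairs are formed per (reader, subject); the cluster key is the subject
    (default — the three readers rate the same subjects) or the reader.
    """
    if cluster_by not in ("subject", "reader"):
        raise ValueError("cluster_by must be 'subject' or 'reader'")
    getter = (lambda r: getattr(r, value)) if isinstance(value, str) else value
    by_key: dict[tuple[str, str], dict[str, float]] = {}
    for r in records:
        if r.view_count != view_count:
            continue
        by_key.setdefault((r.reader_id, r.subject_id), {})[r.arm] = float(getter(r))
    processed, sparse, clusters = [], [], []
    for (reader_id, subject_id), arms in sorted(by_key.items()):
        if set(arms) != {"sparse", "processed"}:
            raise ValueError(
                f"incomplete pair for reader={reader_id}, subject={subject_id}, view={view_count}"
            )
        processed.append(arms["processed"])
        sparse.append(arms["sparse"])
        clusters.append(subject_id if cluster_by == "subject" else reader_id)
    return PairedClusteredSample(
        processed=np.asarray(processed),
        sparse=np.asarray(sparse),
        clusters=tuple(clusters),
    )


def summarize_scores(
    records: Sequence[AnnotationRecord],
    truth_by_subject: dict[str, PhantomSlice] | None = None,
    dsc_mode: str = "include_zeros",
) -> pd.DataFrame:
    """Pooled per-(view, arm) means over readers x subjects.

    Columns: quality, confidence, artifact, n and — when ground truth is
    supplied — dsc. ``dsc_mode='include_zeros'`` averages Dice over all
    diseased-subject records (misses count as 0, the zero rule);
    ``'tp_only'`` averages over true-positive records only.
    """
    if dsc_mode not in ("include_zeros", "tp_only"):
        raise ValueError("dsc_mode must be 'include_zeros' or 'tp_only'")
    rows = []
    for r in records:
        row = {
            "view_count": r.view_count,
            "arm": r.arm,
            "quality": r.quality,
            "confidence": r.confidence,
            "artifact": r.artifact,
        }
        if truth_by_subject is not None:
            truth = truth_by_subject[r.subject_id]
            if truth.diseased:
                d = dice(r.segmentation, truth.nodule_mask)
                if dsc_mode == "include_zeros" or d > 0:
                    row["dsc"] = d
        rows.append(row)
    frame = pd.DataFrame(rows)
    agg = frame.groupby(["view_count", "arm"]).agg(
        quality=("quality", "mean"),
        confidence=("confidence", "mean"),
        artifact=("artifact", "mean"),
        n=("quality", "size"),
    )
    if truth_by_subject is not None and "dsc" in frame:
        agg["dsc"] = frame.groupby(["view_count", "arm"])["dsc"].mean()
    return agg
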