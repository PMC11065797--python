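import numpy as np
import pytest
from scipy import stats

from sparsect.reader_study import (
    DetectionOutcome,
    PairedClusteredSample,
    classify_detection,
    clustered_wilcoxon,
    diagnostic_metrics,
    dice,
    paired_sample,
    summarize_scores,
)
from sparsect.synthetic import (
    AnnotationRecord,
    CohortConfig,
    default_readers,
    generate_cohort,
    simulate_annotations,
)


def _mask(shape, pixels):
    m = np.zeros(shape, dtype=bool)
    for p in pixels:
        m[p] = True
    return m


class TestDice:
    def test_identical_nonempty(self):
        m = _mask((8, 8), [(1, 1), (1, 2)])
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty_zero_rule(self):
        a = _mask((8, 8), [(0, 0)])
        b = _mask((8, 8), [(5, 5)])
        assert dice(a, b) == 0.0

    def test_empty_mask_zero_rule(self):
        a = np.zeros((8, 8), dtype=bool)
        b = _mask((8, 8), [(1, 1)])
        assert dice(a, b) == 0.0
        assert dice(b, a) == 0.0
        assert dice(a, a) == 0.0

    def test_pixel_counting_example(self):
        # |A| = 100, |B| = 50, overlap 40 -> 2*40/150
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a.ravel()[:100] = True
        b.ravel()[60:110] = True
        assert int(a.sum()) == 100 and int(b.sum()) == 50 and int((a & b).sum()) == 40
        assert dice(a, b) == pytest.approx(2 * 40 / 150)

    def test_brute_force_oracle(self, rng):
        for _ in range(100):
            a = rng.uniform(size=(12, 12)) > 0.6
            b = rng.uniform(size=(12, 12)) > 0.6
            na = sum(bool(x) for x in a.ravel())
            nb = sum(bool(x) for x in b.ravel())
            inter = sum(bool(x and y) for x, y in zip(a.ravel(), b.ravel()))
            expected = 0.0 if (na == 0 or nb == 0 or inter == 0) else 2 * inter / (na + nb)
            assert dice(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(20):
            a = rng.uniform(size=(10, 10)) > 0.5
            b = rng.uniform(size=(10, 10)) > 0.5
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_one_iff_identical_nonempty(self, rng):
        a = rng.uniform(size=(10, 10)) > 0.5
        b = a.copy()
        b[0, 0] = not b[0, 0]
        assert dice(a, b) < 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


def _record(subject, mask, view=64, arm="sparse", reader="R1", q=4, c=4, a=2):
    return AnnotationRecord(
        reader_id=reader,
        subject_id=subject,
        view_count=view,
        arm=arm,
        quality=q,
        confidence=c,
        artifact=a,
        segmentation=mask,
    )


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(
        CohortConfig(n_subjects=4, diseased_fraction=0.5, image_size=64, pixel_spacing=2.0, seed=13)
    )


class TestClassifyDetection:

    def test_healthy_empty_is_tn(self, cohort):
        healthy = next(s for s in cohort if not s.diseased)
        out = classify_detection(_record(healthy.subject_id, np.zeros((64, 64), bool)), healthy)
        assert out.label == "TN" and out.dsc is None

    def test_healthy_marked_is_fp(self, cohort):
        healthy = next(s for s in cohort if not s.diseased)
        out = classify_detection(_record(healthy.subject_id, _mask((64, 64), [(10, 10)])), healthy)
        assert out.label == "FP"

    def test_diseased_displaced_mark_is_fn(self, cohort):
        diseased = next(s for s in cohort if s.diseased)
        displaced = ~diseased.nodule_mask & _mask((64, 64), [(0, 0), (0, 1)])
        assert displaced.any() and not (displaced & diseased.nodule_mask).any()
        out = classify_detection(_record(diseased.subject_id, displaced), diseased)
        assert out.label == "FN" and out.dsc is None

    def test_diseased_empty_is_fn(self, cohort):
        diseased = next(s for s in cohort if s.diseased)
        out = classify_detection(_record(diseased.subject_id, np.zeros((64, 64), bool)), diseased)
        assert out.label == "FN"

    def test_diseased_overlap_is_tp_with_dsc(self, cohort):
        diseased = next(s for s in cohort if s.diseased)
        out = classify_detection(_record(diseased.subject_id, diseased.nodule_mask.copy()), diseased)
        assert out.label == "TP"
        assert out.dsc == 1.0

    def test_subject_mismatch(self, cohort):
        with pytest.raises(ValueError, match="does not match"):
            classify_detection(_record("nope", np.zeros((64, 64), bool)), cohort[0])

    def test_exhaustive_and_exclusive_on_simulation(self, cohort):
        records = simulate_annotations(cohort, None, default_readers(2), seed=5)
        truth = {s.subject_id: s for s in cohort}
        for r in records:
            out = classify_detection(r, truth[r.subject_id])
            if truth[r.subject_id].diseased:
                assert out.label in ("TP", "FN")
            else:
                assert out.label in ("FP", "TN")


class TestDiagnosticMetrics:
    def test_table_counts_example(self):
        # 36 diseased + 21 healthy records (n = 57): TP=34, FN=2, FP=2, TN=19
        outcomes = (
            [DetectionOutcome("R", f"d{i}", 64, "processed", "TP", 0.9) for i in range(34)]
            + [DetectionOutcome("R", f"f{i}", 64, "processed", "FN", None) for i in range(2)]
            + [DetectionOutcome("R", f"p{i}", 64, "processed", "FP", None) for i in range(2)]
            + [DetectionOutcome("R", f"t{i}", 64, "processed", "TN", None) for i in range(19)]
        )
        d = diagnostic_metrics(outcomes)
        assert d.n == 57
        assert round(d.sensitivity, 2) == 0.94
        assert round(d.specificity, 2) == 0.90
        assert d.f1 == pytest.approx(2 * 34 / (2 * 34 + 2 + 2))
        assert d.npv == pytest.approx(19 / 21)

    def test_all_tp_specificity_undefined(self):
        outcomes = [DetectionOutcome("R", "s", 64, "sparse", "TP", 1.0)] * 3
        d = diagnostic_metrics(outcomes)
        assert d.sensitivity == 1.0
        assert d.specificity is None
        assert d.npv is None

    def test_brute_force_recount(self, rng):
        labels = ["TP", "FP", "FN", "TN"]
        for _ in range(100):
            chosen = rng.choice(labels, size=rng.integers(1, 40))
            outcomes = [
                DetectionOutcome("R", f"s{i}", 64, "sparse", lab, 0.5 if lab == "TP" else None)
                for i, lab in enumerate(chosen)
            ]
            d = diagnostic_metrics(outcomes)
            tp = sum(1 for o in outcomes if o.label == "TP")
            fp = sum(1 for o in outcomes if o.label == "FP")
            fn = sum(1 for o in outcomes if o.label == "FN")
            tn = sum(1 for o in outcomes if o.label == "TN")
            assert (d.tp, d.fp, d.fn, d.tn) == (tp, fp, fn, tn)
            if tp + fn:
                assert d.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert d.specificity == pytest.approx(tn / (tn + fp))
            if 2 * tp + fp + fn:
                assert d.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
            if tn + fn:
                assert d.npv == pytest.approx(tn / (tn + fn))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics([])


class TestClusteredWilcoxon:
    def test_all_zero_differences(self):
        s = PairedClusteredSample(np.ones(6), np.ones(6), tuple("abcdef"))
        z, p = clustered_wilcoxon(s)
        assert (z, p) == (0.0, 1.0)

    def test_single_cluster_rejected(self):
        s = PairedClusteredSample(np.array([2.0, 3.0]), np.array([1.0, 1.0]), ("a", "a"))
        with pytest.raises(ValueError, match="clusters"):
            clustered_wilcoxon(s)

    @pytest.mark.parametrize("seed", range(10))
    def test_singleton_clusters_reduce_to_classical(self, seed):
        # integer scores force ties; midrank handling must match scipy's
        # normal approximation without continuity correction
        r = np.random.default_rng(seed)
        n = 25
        processed = r.integers(1, 7, size=n).astype(float)
        sparse = r.integers(1, 7, size=n).astype(float)
        if np.all(processed == sparse):
            processed[0] += 1
        s = PairedClusteredSample(processed, sparse, tuple(f"c{i}" for i in range(n)))
        z, p = clustered_wilcoxon(s, alternative="greater")
        ref = stats.wilcoxon(
            processed, sparse, alternative="greater", correction=False, method="approx"
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_permutation_oracle(self):
        # cluster-level sign-flip permutation p vs analytic p at study size
        r = np.random.default_rng(3)
        n_clusters, per_cluster = 19, 3
        cluster_effects = r.normal(0.4, 0.5, size=n_clusters)
        diffs = np.repeat(cluster_effects, per_cluster) + r.normal(0, 1, size=n_clusters * per_cluster)
        clusters = tuple(f"c{i}" for i in np.repeat(np.arange(n_clusters), per_cluster))
        s = PairedClusteredSample(diffs, np.zeros_like(diffs), clusters)
        z, p_analytic = clustered_wilcoxon(s, alternative="greater")

        ranks = stats.rankdata(np.abs(diffs))
        signed = np.sign(diffs) * ranks
        ids = np.repeat(np.arange(n_clusters), per_cluster)
        cluster_sums = np.array([signed[ids == i].sum() for i in range(n_clusters)])
        observed = cluster_sums.sum()
        flips = r.choice([-1.0, 1.0], size=(4000, n_clusters))
        perm = (flips * cluster_sums).sum(axis=1)
        p_perm = float(np.mean(perm >= observed - 1e-12))
        assert abs(p_perm - p_analytic) < 0.02

    def test_power_increases_with_effect(self):
        rejections = {}
        for effect in (0.0, 0.8):
            count = 0
            for rep in range(200):
                r = np.random.default_rng(1000 * rep + int(effect * 10))
                cluster_fx = r.normal(0, 0.3, size=19)
                d = effect + np.repeat(cluster_fx, 3) + r.normal(0, 1, size=57)
                s = PairedClusteredSample(
                    d, np.zeros_like(d), tuple(f"c{i}" for i in np.repeat(np.arange(19), 3))
                )
                _, p = clustered_wilcoxon(s)
                count += p < 0.05
            rejections[effect] = count / 200
        assert rejections[0.8] > rejections[0.0]
        assert rejections[0.8] > 0.5

    def test_alternatives(self):
        r = np.random.default_rng(0)
        d = r.normal(1.0, 1.0, size=20)
        s = PairedClusteredSample(d, np.zeros_like(d), tuple(f"c{i}" for i in range(20)))
        _, p_g = clustered_wilcoxon(s, alternative="greater")
        _, p_l = clustered_wilcoxon(s, alternative="less")
        _, p_t = clustered_wilcoxon(s, alternative="two-sided")
        assert p_g < 0.05 < p_l
        assert p_t == pytest.approx(2 * p_g, abs=1e-12)
        with pytest.raises(ValueError):
            clustered_wilcoxon(s, alternative="weird")


class TestPairedSample:
    def test_incomplete_pair_rejected(self):
        records = [_record("s1", np.zeros((4, 4), bool), arm="sparse")]
        with pytest.raises(ValueError, match="incomplete"):
            paired_sample(records, "quality", 64)

    def test_cluster_key_subject_vs_reader(self):
        records = []
        for reader in ("R1", "R2"):
            for subject in ("s1", "s2"):
                for arm in ("sparse", "processed"):
                    records.append(_record(subject, np.zeros((4, 4), bool), arm=arm, reader=reader))
        by_subject = paired_sample(records, "quality", 64, cluster_by="subject")
        by_reader = paired_sample(records, "quality", 64, cluster_by="reader")
        assert set(by_subject.clusters) == {"s1", "s2"}
        assert set(by_reader.clusters) == {"R1", "R2"}


class TestSummarizeScores:
    def test_constant_scores(self):
        records = [
            _record(f"s{i}", np.zeros((4, 4), bool), arm=arm, q=4)
            for i in range(5)
            for arm in ("sparse", "processed")
        ]
        out = summarize_scores(records)
        assert (out["quality"] == 4.0).all()

    def test_pooled_n_is_57_in_paper_design(self):
        cohort = generate_cohort(
            CohortConfig(n_subjects=19, diseased_fraction=12 / 19, image_size=64, pixel_spacing=2.0, seed=2)
        )
        records = simulate_annotations(cohort, None, default_readers(3), seed=1)
        out = summarize_scores(records, truth_by_subject={s.subject_id: s for s in cohort})
        assert (out["n"] == 57).all()
        assert "dsc" in out.columns

    def test_uniform_scores_mean(self):
        records = [
            _record(f"s{i}", np.zeros((4, 4), bool), arm="sparse", q=q)
            for i, q in enumerate([1, 2, 3, 4, 5, 6])
        ]
        out = summarize_scores(records)
        assert out.loc[(64, "sparse"), "quality"] == pytest.approx(3.5)

    def test_dsc_modes(self):
        cohort = generate_cohort(
            CohortConfig(n_subjects=2, diseased_fraction=1.0, image_size=64, pixel_spacing=2.0, seed=4)
        )
        truth = {s.subject_id: s for s in cohort}
        records = [
            _record(cohort[0].subject_id, cohort[0].nodule_mask.copy(), arm="sparse"),
            _record(cohort[1].subject_id, np.zeros((64, 64), bool), arm="sparse"),
        ]
        with_zeros = summarize_scores(records, truth, dsc_mode="include_zeros")
        tp_only = summarize_scores(records, truth, dsc_mode="tp_only")
        assert with_zeros.loc[(64, "sparse"), "dsc"] == pytest.approx(0.5)
        assert tp_only.loc[(64, "sparse"), "dsc"] == pytest.approx(1.0)


def test_end_to_end_significance_at_low_views():
    """With the default effectful reader panel, processed quality and
    confidence are flagged significant at 64 and fewer views."""
    cohort = generate_cohort(
        CohortConfig(n_subjects=19, diseased_fraction=12 / 19, image_size=64, pixel_spacing=2.0, seed=8)
    )
    records = simulate_annotations(cohort, None, default_readers(3, processed_boost=0.8), seed=8)
    for view in (16, 32, 64):
        for metric in ("quality", "confidence"):
            _, p = clustered_wilcoxon(paired_sample(records, metric, view), alternative="greater")
            assert p < 0.05, f"{metric} at {view} views: p={p}"
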