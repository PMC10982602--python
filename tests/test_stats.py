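"""Contingency metrics, kappa, ROC/AUC, Youden cutoff, DeLong CI, LOOCV."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from ivbm import (
    ContingencyTable,
    cohens_kappa,
    contingency_metrics,
    delong_auc_ci,
    loocv_evaluate,
    roc_curve,
    youden_cutoff,
)
from ivbm.stats import evaluate_index, pairwise_roi_tests


# ---------------------------------------------------------------------------
# contingency metrics with Wald intervals

# Rater-decision counts (tp, fn, fp, tn) for the MSA-vs-others dichotomy and
# the point estimates they reproduce.
RATER_TABLES = [
    ((16, 2, 7, 109), 0.889, 0.940, 0.933),  # trained rater
    ((17, 1, 23, 93), 0.944, 0.802, 0.821),  # untrained rater
]


@pytest.mark.parametrize("counts, sens, spec, acc", RATER_TABLES)
def test_rater_contingency_metrics(counts, sens, spec, acc):
    tp, fn, fp, tn = counts
    m = contingency_metrics(ContingencyTable(tp, fn, fp, tn))
    assert round(m["sensitivity"].value, 3) == sens
    assert round(m["specificity"].value, 3) == spec
    assert round(m["accuracy"].value, 3) == acc


def test_wald_lower_bound_of_sensitivity():
    """16/18 with a 95% Wald interval has lower bound 0.744."""
    m = contingency_metrics(ContingencyTable(16, 2, 7, 109))
    assert round(m["sensitivity"].lower, 3) == 0.744
    assert m["sensitivity"].upper == 1.0  # clipped


def test_symmetric_table_gives_half_everywhere():
    m = contingency_metrics(ContingencyTable(25, 25, 25, 25))
    for name in ("sensitivity", "specificity", "accuracy"):
        assert m[name].value == 0.5


def test_zero_denominator_flagged_undefined():
    m = contingency_metrics(ContingencyTable(0, 0, 3, 7))
    assert m["sensitivity"] is None
    assert m["specificity"] is not None


@given(
    st.integers(min_value=0, max_value=50), st.integers(min_value=0, max_value=50),
    st.integers(min_value=0, max_value=50), st.integers(min_value=1, max_value=50),
)
def test_wald_intervals_clipped_and_contain_estimate(tp, fn, fp, tn):
    m = contingency_metrics(ContingencyTable(tp, fn, fp, tn))
    for est in m.values():
        if est is None:
            continue
        assert 0.0 <= est.lower <= est.value <= est.upper <= 1.0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 5)


# ---------------------------------------------------------------------------
# Cohen's kappa


def test_kappa_identical_vectors():
    assert cohens_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"]) == 1.0


def test_kappa_chance_agreement_is_zero():
    # 2x2 with independent margins: agreement exactly at chance level
    a = ["x"] * 50 + ["y"] * 50
    b = (["x"] * 25 + ["y"] * 25) * 2
    assert cohens_kappa(a, b) == pytest.approx(0.0, abs=1e-12)


def test_kappa_matches_independent_implementations(rng):
    """Random 3-class vectors agree with the defining-formula oracle and sklearn."""
    for _ in range(20):
        a = rng.choice(["MSA", "PSP", "PD"], size=30)
        b = rng.choice(["MSA", "PSP", "PD"], size=30)
        # brute-force confusion-matrix computation of (p_o - p_e) / (1 - p_e)
        cats = sorted(set(a) | set(b))
        conf = np.zeros((len(cats), len(cats)))
        for x, y in zip(a, b):
            conf[cats.index(x), cats.index(y)] += 1
        conf /= conf.sum()
        p_o = np.trace(conf)
        p_e = float(conf.sum(axis=1) @ conf.sum(axis=0))
        oracle = (p_o - p_e) / (1 - p_e)
        k = cohens_kappa(a, b)
        assert k == pytest.approx(oracle, abs=1e-8)
        assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-8)


def test_kappa_length_mismatch_and_degenerate():
    with pytest.raises(ValueError, match="length"):
        cohens_kappa([1, 2], [1, 2, 3])
    # both raters constant and identical: perfect agreement by convention
    assert cohens_kappa(["a"] * 5, ["a"] * 5) == 1.0


# ---------------------------------------------------------------------------
# ROC and AUC


def test_perfectly_separated_scores_auc_one():
    scores = [0.1, 0.2, 0.3, 1.1, 1.2, 1.3]
    truth = [False, False, False, True, True, True]
    roc = roc_curve(scores, truth, "greater")
    assert roc.auc == 1.0


def test_constant_scores_auc_half():
    roc = roc_curve([1.0] * 10, [True] * 5 + [False] * 5, "greater")
    assert roc.auc == 0.5


def test_auc_equals_pairwise_concordance_oracle(rng):
    """Midrank AUC equals the O(n^2) tie-aware concordance count."""
    for _ in range(20):
        scores = rng.choice(np.round(rng.normal(size=8), 1), size=20)
        truth = np.zeros(20, dtype=bool)
        truth[rng.choice(20, size=8, replace=False)] = True
        roc = roc_curve(scores, truth, "greater")
        pos, neg = scores[truth], scores[~truth]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert roc.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)


def test_direction_less_reverses_orientation(rng):
    scores = rng.normal(size=30)
    truth = scores < -0.2  # disease has low scores
    roc = roc_curve(scores, truth, "less")
    assert roc.auc == 1.0
    # reported thresholds live on the original scale
    cutoff, j = youden_cutoff(roc)
    assert j == 1.0
    preds = scores <= cutoff
    assert (preds == truth).all()


def test_single_class_truth_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_curve([1.0, 2.0], [True, True])


def test_roc_curve_endpoints():
    roc = roc_curve([0.3, 0.7, 0.5], [True, False, True], "greater")
    # -inf threshold calls everyone diseased; +inf no one
    assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
    assert roc.sensitivity[-1] == 0.0 and roc.specificity[-1] == 1.0


# ---------------------------------------------------------------------------
# Youden cutoff


def test_youden_perfect_separation():
    scores = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
    truth = scores > 5
    roc = roc_curve(scores, truth, "greater")
    cutoff, j = youden_cutoff(roc)
    assert j == 1.0
    assert cutoff == 6.0  # midpoint between the separated samples


def test_youden_j_from_sensitivity_specificity_pair():
    """J = sens + spec - 1; e.g. 0.889 + 0.897 - 1 = 0.786."""
    assert 0.889 + 0.897 - 1 == pytest.approx(0.786, abs=1e-12)
    scores = [0.1, 0.4, 0.35, 0.8]
    truth = [False, True, False, True]
    roc = roc_curve(scores, truth, "greater")
    _, j = youden_cutoff(roc)
    scan = max(
        s + p - 1.0 for s, p in zip(roc.sensitivity, roc.specificity)
    )
    assert j == pytest.approx(scan, abs=1e-12)


def test_youden_all_scores_equal_j_zero():
    roc = roc_curve([2.0] * 8, [True] * 4 + [False] * 4, "greater")
    _, j = youden_cutoff(roc)
    assert j == 0.0


def test_youden_matches_exhaustive_scan(rng):
    for _ in range(20):
        scores = rng.normal(size=25)
        truth = rng.random(25) < 0.4
        if truth.all() or not truth.any():
            continue
        roc = roc_curve(scores, truth, "greater")
        cutoff, j = youden_cutoff(roc)
        brute = max(
            (scores[truth] >= t).mean() + (scores[~truth] < t).mean() - 1.0
            for t in np.concatenate((roc.thresholds[np.isfinite(roc.thresholds)], [-np.inf]))
        )
        assert j == pytest.approx(brute, abs=1e-12)
        # the returned cutoff actually achieves the maximal J
        achieved = (scores[truth] >= cutoff).mean() + (scores[~truth] < cutoff).mean() - 1.0
        assert achieved == pytest.approx(j, abs=1e-12)


# ---------------------------------------------------------------------------
# DeLong confidence interval


def test_delong_degenerate_perfect_separation():
    scores = np.concatenate((np.zeros(20), np.ones(20)))
    truth = scores > 0.5
    auc, (lo, hi), degenerate = delong_auc_ci(scores, truth)
    assert auc == 1.0 and hi == 1.0 and degenerate


def test_delong_interval_width_shrinks_with_n(rng):
    widths = []
    for n in (20, 80, 320):
        scores = np.concatenate((rng.normal(0, 1, n), rng.normal(1.5, 1, n)))
        truth = np.arange(2 * n) >= n
        _, (lo, hi), _ = delong_auc_ci(scores, truth)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_delong_label_swap_reflects_interval(rng):
    scores = rng.normal(size=60)
    truth = rng.random(60) < 0.5
    auc, (lo, hi), _ = delong_auc_ci(scores, truth)
    auc2, (lo2, hi2), _ = delong_auc_ci(scores, ~truth)
    assert auc2 == pytest.approx(1.0 - auc, abs=1e-12)
    assert lo2 == pytest.approx(1.0 - hi, abs=1e-12)
    assert hi2 == pytest.approx(1.0 - lo, abs=1e-12)


def test_delong_matches_bootstrap_oracle():
    """DeLong endpoints agree with a 2000-rep bootstrap percentile interval."""
    rng = np.random.default_rng(77)
    n = 50
    scores = np.concatenate((rng.normal(0, 1, n), rng.normal(1.0, 1, n)))
    truth = np.arange(2 * n) >= n
    _, (lo, hi), _ = delong_auc_ci(scores, truth)

    from scipy.stats import rankdata

    boot = np.empty(2000)
    for b in range(2000):
        ip = rng.integers(0, n, n)
        iq = rng.integers(0, n, n)
        pos, neg = scores[n:][ip], scores[:n][iq]
        allv = np.concatenate((pos, neg))
        r = rankdata(allv)
        boot[b] = (r[:n].sum() - n * (n + 1) / 2) / (n * n)
    blo, bhi = np.percentile(boot, [2.5, 97.5])
    assert lo == pytest.approx(blo, abs=0.02)
    assert hi == pytest.approx(bhi, abs=0.02)


def test_delong_requires_two_per_class():
    with pytest.raises(ValueError):
        delong_auc_ci([1.0, 2.0, 3.0], [True, False, False])


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


def test_loocv_perfect_separation():
    scores = np.array([0.0, 0.5, 1.0, 5.0, 5.5, 6.0])
    truth = scores > 3
    cv = loocv_evaluate(scores, truth, "greater")
    assert cv.accuracy == 1.0 and cv.kappa == 1.0
    assert cv.n_excluded_folds == 0


def test_loocv_deterministic():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=30)
    truth = rng.random(30) < 0.4
    cv1 = loocv_evaluate(scores, truth, "greater")
    cv2 = loocv_evaluate(scores, truth, "greater")
    assert cv1.accuracy == cv2.accuracy and cv1.kappa == cv2.kappa
    np.testing.assert_array_equal(cv1.predictions, cv2.predictions)


def test_loocv_permuted_labels_kappa_near_zero():
    """With labels independent of scores, mean held-out kappa is ~0."""
    rng = np.random.default_rng(99)
    scores = rng.normal(size=100)
    base_truth = np.zeros(100, dtype=bool)
    base_truth[:30] = True
    kappas = []
    for _ in range(200):
        truth = rng.permutation(base_truth)
        cv = loocv_evaluate(scores, truth, "greater")
        kappas.append(cv.kappa)
    assert abs(np.mean(kappas)) < 0.1


def test_loocv_fold_losing_a_class_excluded():
    # a single positive: its fold has no positives left to train on
    scores = np.array([5.0, 0.1, 0.2, 0.3, 0.4])
    truth = np.array([True, False, False, False, False])
    cv = loocv_evaluate(scores, truth, "greater")
    assert cv.n_excluded_folds == 1
    assert cv.predictions.size == 4


def test_loocv_fixed_cutoff():
    scores = np.array([-3.0, -2.0, 0.0, 0.1, 0.2, 1.0])
    truth = np.array([True, True, False, False, False, False])
    cv = loocv_evaluate(scores, truth, "less", fixed_cutoff=-1.43)
    assert cv.accuracy == 1.0
    assert np.all(cv.per_fold_cutoffs == -1.43)


def test_loocv_requires_three_subjects_and_two_classes():
    with pytest.raises(ValueError):
        loocv_evaluate([1.0, 2.0], [True, False])
    with pytest.raises(ValueError):
        loocv_evaluate([1.0, 2.0, 3.0], [True, True, True])


# ---------------------------------------------------------------------------
# combined report and ROI group comparisons


def test_evaluate_index_report_keys(rng):
    scores = np.concatenate((rng.normal(0, 1, 30), rng.normal(2, 1, 10)))
    truth = np.arange(40) >= 30
    rep = evaluate_index(scores, truth, "greater")
    for key in ("auc", "auc_ci", "optimal_cutoff", "youden_j",
                "loocv_accuracy", "loocv_kappa"):
        assert key in rep
    assert 0 <= rep["auc"] <= 1
    assert rep["auc_ci"][0] <= rep["auc"] <= rep["auc_ci"][1]


def test_pairwise_roi_tests_bonferroni(rng):
    values = np.concatenate((rng.normal(0, 1, 30), rng.normal(3, 1, 30),
                             rng.normal(0, 1, 30)))
    groups = ["PD"] * 30 + ["PSP"] * 30 + ["MSA"] * 30
    out = pairwise_roi_tests(values, groups)
    assert len(out) == 3  # three pairwise contrasts
    by_pair = {(d["group_a"], d["group_b"]): d for d in out}
    assert by_pair[("PD", "PSP")]["p_bonferroni"] < 0.001
    for d in out:
        assert d["p_bonferroni"] >= d["p_raw"]
        assert d["p_bonferroni"] <= 1.0
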