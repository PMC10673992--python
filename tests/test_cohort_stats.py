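"""Cohort statistics: rank correlation, group tests, ROC/Youden, ICC."""

import itertools

import numpy as np
import pytest

from ossiratio.cohort_stats import (
    CohortRecord,
    Group,
    cohort_from_frame,
    cohort_to_frame,
    group_compare,
    icc_two_raters,
    roc_max_youden,
    simulate_cohort,
    spearman_vs_degree,
    youden_index,
)


def rec(group, r2, scan_id="s"):
    return CohortRecord(scan_id=scan_id, group=Group(group), r2=r2, r4=1.0, r5=r2)


# ---------------------------------------------------------------- Spearman


def test_spearman_perfect_monotone_is_one():
    # ratio ranks tie exactly like the degree midranks -> rho = 1
    records = [rec("C", 0.6), rec("C", 0.6), rec("B", 0.8),
               rec("B", 0.8), rec("A", 0.9), rec("A", 0.9)]
    rho, p = spearman_vs_degree(records, "r2")
    assert rho == pytest.approx(1.0)
    assert p < 0.05


def _midranks(values):
    """Independent rank oracle: average rank over ties, by enumeration."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = (values < v).sum()
        equal = (values == v).sum()
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def test_spearman_matches_brute_force_rank_correlation():
    r2s = [0.62, 0.71, 0.71, 0.80, 0.88, 0.95]
    groups = ["C", "C", "B", "B", "A", "A"]
    records = [rec(g, r) for g, r in zip(groups, r2s)]
    rho, _ = spearman_vs_degree(records, "r2")
    rx = _midranks(r2s)
    ry = _midranks([{"C": 1, "B": 2, "A": 3}[g] for g in groups])
    expected = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(expected, abs=1e-12)


def test_spearman_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        spearman_vs_degree([rec("A", 0.9)] * 5, "r2")  # one group only
    records = [rec("A", 0.8), rec("B", 0.8), rec("C", 0.8)]
    with pytest.raises(ValueError, match="zero variance"):
        spearman_vs_degree(records, "r2")


# ---------------------------------------------------------------- groups


def test_group_compare_fully_separated_toy_groups():
    records = ([rec("C", 1.0)] * 3 + [rec("B", 2.0)] * 3 + [rec("A", 3.0)] * 3)
    res = group_compare(records, "r2")
    assert res.medians == {"A": 3.0, "B": 2.0, "C": 1.0}
    # exact Mann-Whitney, n=3 vs 3, full separation: p = 2/20
    assert all(p == pytest.approx(0.1) for p in res.pairwise_raw.values())


def test_group_compare_identical_groups_p_one():
    records = [rec("A", 0.8), rec("A", 0.8), rec("B", 0.8), rec("B", 0.8)]
    res = group_compare(records, "r2")
    assert res.pairwise_raw[("A", "B")] == pytest.approx(1.0)
    assert res.kruskal_p == pytest.approx(1.0)


def test_group_compare_null_simulation_rarely_rejects():
    rng = np.random.default_rng(42)
    rejections = 0
    for _ in range(100):
        vals = np.exp(rng.normal(-0.2, 0.1, 24))
        records = [rec(g, v) for g, v in zip("ABC" * 8, vals)]
        if group_compare(records, "r2").kruskal_p <= 0.05:
            rejections += 1
    assert rejections <= 10


def test_group_compare_insufficient_sizes_raise():
    with pytest.raises(ValueError):
        group_compare([rec("A", 0.9), rec("B", 0.8)], "r2")


# ---------------------------------------------------------------- ROC


def test_roc_perfect_separation():
    scores = [0.9, 0.88, 0.86, 0.7, 0.65]
    labels = [True, True, True, False, False]
    res = roc_max_youden(scores, labels)
    assert res.auc == 1.0
    assert res.youden == pytest.approx(1.0)
    assert res.sensitivity == 1.0 and res.specificity == 1.0
    assert res.best_cutoff == 0.86  # smallest cutoff attaining max J


def test_youden_index_identity():
    assert youden_index(0.796, 0.841) == pytest.approx(0.637, abs=1e-12)


def _auc_pair_counting(scores, labels):
    """Brute-force AUC: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_auc_equals_pair_counting_with_ties(seed):
    rng = np.random.default_rng(seed)
    scores = rng.choice([0.6, 0.7, 0.7, 0.8, 0.9], size=9).tolist()
    labels = (rng.random(9) < 0.5).tolist()
    if not (any(labels) and not all(labels)):
        labels[0], labels[-1] = True, False
    res = roc_max_youden(scores, labels)
    assert res.auc == pytest.approx(_auc_pair_counting(scores, labels), abs=1e-12)


def test_auc_negation_symmetry():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=20)
    labels = rng.random(20) < 0.4
    a = roc_max_youden(scores, labels).auc
    b = roc_max_youden(-scores, labels).auc
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auc_matches_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(11)
    scores = np.round(rng.normal(size=50), 1)  # force ties
    labels = rng.random(50) < 0.45
    res = roc_max_youden(scores, labels)
    assert res.auc == pytest.approx(
        sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
    )
    assert res.ci_low <= res.auc <= res.ci_high


def test_roc_recovers_classification_cutoff_on_separable_cohort():
    scores = [0.95, 0.9, 0.84, 0.80, 0.74, 0.70]
    labels = [s >= 0.84 for s in scores]
    res = roc_max_youden(scores, labels)
    assert res.best_cutoff == 0.84
    assert res.youden == pytest.approx(1.0)


def test_roc_single_class_raises():
    with pytest.raises(ValueError):
        roc_max_youden([0.1, 0.2], [True, True])


# ---------------------------------------------------------------- ICC


def test_icc_identical_raters_is_one():
    table = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
    assert icc_two_raters(table) == pytest.approx(1.0)


def test_icc_penalizes_systematic_offset():
    base = np.array([1.0, 1.1, 0.9, 1.05, 0.95])
    table = np.column_stack([base, base + 5.0])
    assert icc_two_raters(table) < 0.2


def _icc21_oracle(table):
    """ICC(2,1) from the two-way ANOVA mean squares, written out by hand."""
    n, k = table.shape
    grand = table.mean()
    msr = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = (
        table - table.mean(axis=1, keepdims=True)
        - table.mean(axis=0, keepdims=True) + grand
    )
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_matches_mean_square_formula():
    table = np.array([[9.0, 10.0], [6.5, 6.0], [8.0, 7.5], [7.0, 7.5], [6.0, 6.5]])
    assert icc_two_raters(table) == pytest.approx(_icc21_oracle(table), abs=1e-9)


def test_icc_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        icc_two_raters(np.array([[1.0, 1.0], [2.0, 2.0]]))  # n < 3
    with pytest.raises(ValueError, match="between-subject"):
        icc_two_raters(np.array([[1.0, 1.0]] * 4))


# ---------------------------------------------------------------- cohort sim


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_simulated_cohort_auc_in_sanity_corridor(seed):
    """AUC of R2 for healed-vs-rest stays in a plausible band across seeds."""
    records = simulate_cohort(seed=seed)
    scores = np.array([r.r2 for r in records])
    labels = np.array([Group(r.group) is Group.A for r in records])
    res = roc_max_youden(scores, labels)
    assert 0.75 <= res.auc <= 0.95


def test_simulated_cohort_group_structure():
    records = simulate_cohort(seed=0)
    assert len(records) == 112
    res = group_compare(records, "r2")
    assert res.medians["A"] > res.medians["B"] > res.medians["C"]
    assert res.kruskal_p < 0.01
    rho, p = spearman_vs_degree(records, "r2")
    assert rho > 0.4 and p < 0.001


def test_cohort_frame_roundtrip():
    records = simulate_cohort(sizes={"A": 4, "B": 3, "C": 3}, seed=1)
    df = cohort_to_frame(records)
    back = cohort_from_frame(df)
    assert back == records
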