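import numpy as np
import pandas as pd
import pytest
from scipy import stats

import uropep as up
from uropep.evaluation import auc_mann_whitney


def _pair_count_auc(scores, outcomes):
    """Oracle: concordant case-control pairs (+ half ties) / all pairs."""
    case = scores[outcomes]
    ctrl = scores[~outcomes]
    total = 0.0
    for c in case:
        for k in ctrl:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(case) * len(ctrl))


def test_auc_trivial_cases():
    perfect = up.roc_curve([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
    assert perfect.auc == 1.0
    ties = up.roc_curve([5.0] * 6, [0, 0, 0, 1, 1, 1])
    assert ties.auc == 0.5


def test_auc_equals_pair_counting_oracle():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = int(rng.integers(4, 31))
        scores = rng.integers(0, 6, n).astype(float)  # heavy ties
        outcomes = rng.random(n) < 0.5
        if outcomes.all() or not outcomes.any():
            continue
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(
            _pair_count_auc(scores, outcomes), abs=1e-12)


def test_roc_curve_trapezoid_identity_and_monotonicity():
    rng = np.random.default_rng(4)
    scores = np.round(rng.normal(size=200), 1)
    outcomes = rng.random(200) < 0.3
    roc = up.roc_curve(scores, outcomes)
    fpr = 1 - roc.specificity
    tpr = roc.sensitivity
    area = np.trapezoid(tpr, fpr)
    assert area == pytest.approx(roc.auc, abs=1e-12)
    assert (np.diff(roc.sensitivity) >= 0).all()  # threshold descending
    assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]


def test_roc_matches_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(9)
    scores = rng.normal(size=300) + rng.random(300)
    outcomes = rng.random(300) < 0.4
    roc = up.roc_curve(scores, outcomes)
    assert roc.auc == pytest.approx(roc_auc_score(outcomes, scores), abs=1e-12)


def test_clopper_pearson_closed_form():
    ci = up.clopper_pearson(0, 10)
    assert ci.lo == 0.0
    assert ci.hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-10)
    assert up.clopper_pearson(10, 10).hi == 1.0
    with pytest.raises(up.UropepError):
        up.clopper_pearson(5, 4)


def test_clopper_pearson_contains_estimate():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = int(rng.integers(1, 200))
        k = int(rng.integers(0, n + 1))
        ci = up.clopper_pearson(k, n)
        assert ci.lo <= k / n <= ci.hi
        assert 0.0 <= ci.lo <= ci.hi <= 1.0


def test_sens_spec_matches_explicit_loop():
    rng = np.random.default_rng(6)
    scored = pd.DataFrame({
        "score": rng.normal(size=100),
        "outcome": np.where(rng.random(100) < 0.3, "sig", "nonsig")})
    cutoff = 0.1
    res = up.sens_spec_at_cutoff(scored, cutoff)
    tp = fn = tn = fp = 0
    for _, row in scored.iterrows():
        pos = row["score"] >= cutoff
        if row["outcome"] == "sig":
            tp, fn = tp + pos, fn + (not pos)
        else:
            fp, tn = fp + pos, tn + (not pos)
    assert (res["tp"], res["fp"], res["tn"], res["fn"]) == (tp, fp, tn, fn)
    assert res["sensitivity"].estimate == tp / (tp + fn)
    assert res["specificity"].estimate == tn / (tn + fp)


def test_sens_spec_extreme_cutoffs():
    scored = pd.DataFrame({"score": [0.0, 1.0, 2.0, 3.0],
                           "outcome": ["nonsig", "sig", "nonsig", "sig"]})
    lo = up.sens_spec_at_cutoff(scored, -10)
    assert lo["sensitivity"].estimate == 1.0
    assert lo["specificity"].estimate == 0.0
    hi = up.sens_spec_at_cutoff(scored, 10)
    assert hi["sensitivity"].estimate == 0.0
    assert hi["specificity"].estimate == 1.0


def test_delong_self_comparison():
    rng = np.random.default_rng(1)
    s = rng.normal(size=50)
    y = rng.random(50) < 0.5
    y[:2] = [True, False]
    a, b, z, p = up.delong_test(s, s, y)
    assert a == b and z == 0.0 and p == 1.0


def test_delong_hand_computed_small_instance():
    """Perfectly separating vs anti-separating scores on 6 samples."""
    y = np.array([True, True, False, False, False, False])
    s_a = np.array([10.0, 9.0, 1.0, 2.0, 3.0, 4.0])
    s_b = -s_a
    a, b, z, p = up.delong_test(s_a, s_b, y)
    assert a == 1.0 and b == 0.0
    # all placement values are constant -> estimated variance is zero
    assert p == 0.0


def test_delong_variance_reduces_to_placement_variance():
    rng = np.random.default_rng(8)
    s = rng.normal(size=80)
    y = rng.random(80) < 0.4
    y[:2] = [True, False]
    case, ctrl = s[y], s[~y]
    psi = (case[:, None] > ctrl[None, :]) + 0.5 * (case[:, None] == ctrl)
    v10, v01 = psi.mean(axis=1), psi.mean(axis=0)
    expected = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    assert up.delong_variance(s, y) == pytest.approx(expected, abs=1e-15)


def test_delong_against_paired_bootstrap():
    """DeLong p within Monte-Carlo error of a 1e4-resample paired bootstrap."""
    rng = np.random.default_rng(12)
    n = 150
    y = np.zeros(n, dtype=bool)
    y[:45] = True
    latent = rng.normal(size=n)
    s_a = latent + 0.9 * y + rng.normal(scale=0.8, size=n)
    s_b = latent + 0.55 * y + rng.normal(scale=0.8, size=n)
    auc_a, auc_b, z, p = up.delong_test(s_a, s_b, y)

    n_boot = 10_000
    diffs = np.empty(n_boot)
    idx_all = np.arange(n)
    for i in range(n_boot):
        idx = rng.choice(idx_all, size=n, replace=True)
        yy = y[idx]
        if yy.all() or not yy.any():
            idx = idx_all
            yy = y
        diffs[i] = (auc_mann_whitney(s_a[idx], yy)
                    - auc_mann_whitney(s_b[idx], yy))
    sd_boot = diffs.std(ddof=1)
    z_boot = (auc_a - auc_b) / sd_boot
    p_boot = 2 * stats.norm.sf(abs(z_boot))
    assert abs(p - p_boot) < 0.02


def test_delong_matches_pROC_reference():
    # reference p-value computed once with R pROC::roc.test (DeLong) on
    # this exact fixture
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
    s_a = np.array([8.1, 7.2, 6.3, 4.1, 5.0, 3.9, 2.8, 4.4, 1.7, 2.2])
    s_b = np.array([6.0, 5.1, 7.9, 2.2, 6.6, 4.0, 3.1, 5.2, 2.5, 1.1])
    auc_a, auc_b, z, p = up.delong_test(s_a, s_b, y)
    assert auc_a == pytest.approx(0.9166666667, abs=1e-9)
    assert auc_b == pytest.approx(0.6666666667, abs=1e-9)
    assert z == pytest.approx(1.9926334925, abs=1e-9)
    assert p == pytest.approx(0.0463015949, abs=1e-9)


def test_kruskal_wallis_toy_h():
    h, p = up.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert h == pytest.approx(32 / 7, abs=1e-12)
    assert p == pytest.approx(stats.chi2.sf(32 / 7, 2), abs=1e-12)


def test_kruskal_wallis_degenerate_all_equal():
    h, p = up.kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
    assert h == 0.0 and p == 1.0
    with pytest.raises(up.UropepError):
        up.kruskal_wallis([[1.0]])


def test_kruskal_wallis_two_groups_equals_squared_rank_deviate():
    """With 2 groups, H equals z^2 of the tie-corrected rank-sum statistic
    (no continuity correction)."""
    rng = np.random.default_rng(14)
    x = np.round(rng.normal(size=25), 1)
    y = np.round(rng.normal(0.4, size=30), 1)
    h, _ = up.kruskal_wallis([x, y])
    u, _ = up.mann_whitney_u(x, y)
    pooled = np.concatenate([x, y])
    n1, n0, n = len(x), len(y), len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    var = n1 * n0 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = (u - n1 * n0 / 2) / np.sqrt(var)
    assert h == pytest.approx(z ** 2, abs=1e-9)


def test_chi_squared_examples():
    chi2, df, p = up.chi_squared_2xk([[10, 10], [10, 10]])
    assert chi2 == 0.0 and p == 1.0
    chi2, df, p = up.chi_squared_2xk([[20, 0], [0, 20]])
    assert chi2 == pytest.approx(40.0) and df == 1
    with pytest.raises(up.UropepError):
        up.chi_squared_2xk([[0, 0], [5, 5]])


def test_chi_squared_permutation_invariance():
    table = np.array([[12, 5, 9], [3, 11, 7]])
    chi2, df, p = up.chi_squared_2xk(table)
    chi2_p, df_p, _ = up.chi_squared_2xk(table[::-1, ::-1])
    assert chi2 == pytest.approx(chi2_p, abs=1e-12)
    assert df == df_p == 2


# ---------------------------------------------------------------------------
# cohort summary

def test_reference_cohort_reproduces_reported_shares():
    samples, split = up.reference_cohort()
    by_split = up.cohort_summary(samples, "by_split", split=split)
    comp = by_split.composition.set_index("group")
    assert comp.loc["discovery", "pct_sig_pca"] == 18.0
    assert comp.loc["validation", "pct_sig_pca"] == 17.1
    by_outcome = up.cohort_summary(samples, "by_outcome")
    comp_o = by_outcome.composition.set_index("group")
    assert comp_o.loc["control", "pct_of_total"] == 82.3
    assert comp_o.loc["sig_pca", "pct_of_total"] == 17.7
    cat = by_outcome.categorical.set_index("variable")
    assert cat.loc["no_prior_biopsy", "control_pct"] == 70.9
    assert cat.loc["no_prior_biopsy", "sig_pca_pct"] == 85.6
    gl = by_split.gleason.set_index("stratum")
    assert gl.loc["GS3+4", "discovery_pct"] == 64.3
    assert gl.loc["GS8", "discovery_pct"] == 9.2


def test_cohort_summary_identical_variable():
    samples, split = up.reference_cohort()
    s = up.cohort_summary(samples, "by_split", split=split)
    row = s.continuous.set_index("variable").loc["age"]
    assert row["p_value"] == 1.0  # constant in the fixture
    assert row["discovery_iqr"] == 0.0


def test_cohort_summary_percentage_self_consistency():
    samples, split = up.reference_cohort()
    s = up.cohort_summary(samples, "by_split", split=split)
    n1, n2 = s.group_sizes
    for _, row in s.categorical.iterrows():
        assert row["discovery_pct"] == round(
            100 * row["discovery_count"] / n1, 1)
        assert row["validation_pct"] == round(
            100 * row["validation_count"] / n2, 1)
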