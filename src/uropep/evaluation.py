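"""Validation statistics: ROC/AUC, exact binomial CIs, DeLong, KW, chi2.

AUC is tie-aware (Mann–Whitney U / (n1·n0)); its variance and the paired
AUC comparison follow DeLong's placement-value estimator.  Sensitivity and
specificity carry exact Clopper–Pearson binomial intervals.  The cohort
summary reproduces the usual baseline-characteristics table: medians + IQR
with Mann–Whitney p for continuous variables, counts + percentages with
chi-squared p for categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import mann_whitney_u, wilcoxon_rank_sum  # shared rank core
from .model import SampleTable, SplitAssignment, UropepError

__all__ = [
    "ROCResult", "BinomialCI", "CohortSummary", "roc_curve",
    "clopper_pearson", "sens_spec_at_cutoff", "delong_test", "delong_variance",
    "kruskal_wallis", "mann_whitney_u", "wilcoxon_rank_sum",
    "chi_squared_2xk", "cohort_summary",
]


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCResult:
    thresholds: np.ndarray          # descending; predict positive at >= t
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_variance: float             # DeLong estimator
    auc_ci: tuple[float, float]     # normal-approximation, clipped to [0, 1]

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def _check_two_classes(outcomes: np.ndarray) -> np.ndarray:
    outcomes = np.asarray(outcomes, dtype=bool)
    if outcomes.all() or not outcomes.any():
        raise UropepError("both outcome classes must be present")
    return outcomes


def _placements(scores: np.ndarray, outcomes: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 per case, V01 per control)."""
    case = scores[outcomes][:, None]
    ctrl = scores[~outcomes][None, :]
    psi = (case > ctrl) + 0.5 * (case == ctrl)
    return psi.mean(axis=1), psi.mean(axis=0)


def auc_mann_whitney(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Tie-aware AUC = U / (n1 · n0) via midranks."""
    outcomes = _check_two_classes(outcomes)
    ranks = stats.rankdata(scores)
    n1 = int(outcomes.sum())
    n0 = outcomes.size - n1
    u = ranks[outcomes].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def delong_variance(scores, outcomes) -> float:
    """Variance of a single AUC estimate (DeLong)."""
    outcomes = _check_two_classes(np.asarray(outcomes))
    scores = np.asarray(scores, dtype=float)
    v10, v01 = _placements(scores, outcomes)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_curve(scores, outcomes, level: float = 0.95) -> ROCResult:
    """ROC over all distinct score thresholds with DeLong AUC interval."""
    scores = np.asarray(scores, dtype=float)
    outcomes = _check_two_classes(outcomes)
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[uniq[0] + 1.0], uniq])
    n1 = int(outcomes.sum())
    n0 = outcomes.size - n1
    case_sorted = np.sort(scores[outcomes])
    ctrl_sorted = np.sort(scores[~outcomes])
    # counts >= t via searchsorted on the sorted group scores
    sens = 1.0 - np.searchsorted(case_sorted, thresholds, side="left") / n1
    spec = np.searchsorted(ctrl_sorted, thresholds, side="left") / n0
    auc = auc_mann_whitney(scores, outcomes)
    var = delong_variance(scores, outcomes)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc, auc_variance=var, auc_ci=ci)


def delong_test(scores_a, scores_b, outcomes
                ) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two AUCs; returns (auc_a, auc_b, z, p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise UropepError("paired score vectors must have equal length")
    outcomes = _check_two_classes(outcomes)
    va10, va01 = _placements(scores_a, outcomes)
    vb10, vb01 = _placements(scores_b, outcomes)
    auc_a = float(va10.mean())
    auc_b = float(vb10.mean())
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ (s10 / m + s01 / n) @ contrast)
    diff = auc_a - auc_b
    if var <= 0:
        # degenerate: identical placement differences everywhere
        return auc_a, auc_b, 0.0, (1.0 if diff == 0 else 0.0)
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


# ---------------------------------------------------------------------------
# exact binomial intervals

@dataclass
class BinomialCI:
    successes: int
    trials: int
    level: float
    lo: float
    hi: float

    @property
    def estimate(self) -> float:
        return self.successes / self.trials


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact (beta-quantile) binomial confidence interval."""
    if not (0 <= k <= n) or n < 1:
        raise UropepError(f"invalid binomial counts k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialCI(successes=k, trials=n, level=level, lo=lo, hi=hi)


def sens_spec_at_cutoff(scored: pd.DataFrame, cutoff: float,
                        level: float = 0.95) -> dict:
    """Sensitivity/specificity with exact CIs at score >= cutoff positive.

    ``scored`` is a ScoredCohort table with ``score`` and ``outcome``.
    """
    outcomes = _check_two_classes(
        (scored["outcome"] == "sig").to_numpy())
    pos = scored["score"].to_numpy() >= cutoff
    tp = int((pos & outcomes).sum())
    fn = int((~pos & outcomes).sum())
    tn = int((~pos & ~outcomes).sum())
    fp = int((pos & ~outcomes).sum())
    return {
        "sensitivity": clopper_pearson(tp, tp + fn, level),
        "specificity": clopper_pearson(tn, tn + fp, level),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


# ---------------------------------------------------------------------------
# group tests

def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-squared p (k−1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise UropepError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # tie correction degenerates: all values equal
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def chi_squared_2xk(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared on a contingency table of counts."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise UropepError("contingency table must hold non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UropepError("contingency table has an all-zero margin")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# baseline-characteristics summary

CONTINUOUS_VARS = ["age", "psa", "prostate_volume_ml", "prior_biopsy_count",
                   "urinary_creatinine"]
CATEGORICAL_VARS = [("dre_positive", True), ("no_prior_biopsy", True),
                    ("fivear_inhibitor", True)]
CASE_STRATA = ["GS3+4", "GS4+3", "GS8", "GS>=9"]
CONTROL_STRATA = ["GS6", "benign"]


@dataclass
class CohortSummary:
    grouping: str
    group_names: tuple[str, str]
    group_sizes: tuple[int, int]
    composition: pd.DataFrame     # outcome counts/shares per group
    continuous: pd.DataFrame
    categorical: pd.DataFrame
    gleason: pd.DataFrame         # strata shares within each group's cases

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"composition": self.composition, "continuous": self.continuous,
                "categorical": self.categorical, "gleason": self.gleason}


def _pct(k, n) -> float:
    return round(100.0 * k / n, 1) if n else float("nan")


def cohort_summary(samples: SampleTable, grouping: str = "by_outcome",
                   split: SplitAssignment | None = None,
                   yates: bool = False) -> CohortSummary:
    """Baseline-characteristics comparison of two sample groups.

    ``by_outcome`` compares controls vs significant-PCa cases;
    ``by_split`` compares the discovery vs validation subsets (requires
    ``split``).  Missing prostate-volume rows are excluded pairwise with
    the per-group n reported.
    """
    df = samples.df
    if grouping == "by_outcome":
        names = ("control", "sig_pca")
        masks = ((df["outcome"] == "nonsig").to_numpy(),
                 (df["outcome"] == "sig").to_numpy())
    elif grouping == "by_split":
        if split is None:
            raise UropepError("by_split grouping needs a SplitAssignment")
        names = ("discovery", "validation")
        disc = set(split.discovery_ids)
        val = set(split.validation_ids)
        masks = (df["sample_id"].isin(disc).to_numpy(),
                 df["sample_id"].isin(val).to_numpy())
    else:
        raise UropepError(f"unknown grouping {grouping!r}")
    g1, g2 = masks
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 == 0 or n2 == 0:
        raise UropepError("both groups must be non-empty")

    work = df.copy()
    work["no_prior_biopsy"] = work["prior_biopsy_count"] == 0

    comp_rows = []
    for name, mask, n in zip(names, masks, (n1, n2)):
        k = int((work.loc[mask, "outcome"] == "sig").sum())
        comp_rows.append({
            "group": name, "n": n,
            "pct_of_total": _pct(n, len(work)),
            "n_sig_pca": k, "pct_sig_pca": _pct(k, n),
            "n_control": n - k, "pct_control": _pct(n - k, n),
        })
    composition = pd.DataFrame(comp_rows)

    cont_rows = []
    for var in CONTINUOUS_VARS:
        v1 = work.loc[g1, var].dropna()
        v2 = work.loc[g2, var].dropna()
        if v1.empty or v2.empty:
            continue
        q1a, q3a = np.percentile(v1, [25, 75])
        q1b, q3b = np.percentile(v2, [25, 75])
        _, p = mann_whitney_u(v1.to_numpy(), v2.to_numpy())
        cont_rows.append({
            "variable": var,
            f"{names[0]}_n": int(v1.size),
            f"{names[0]}_median": float(np.median(v1)),
            f"{names[0]}_iqr": float(q3a - q1a),
            f"{names[1]}_n": int(v2.size),
            f"{names[1]}_median": float(np.median(v2)),
            f"{names[1]}_iqr": float(q3b - q1b),
            "p_value": p, "test": "mann_whitney",
        })
    continuous = pd.DataFrame(cont_rows)

    cat_rows = []
    for var, level in CATEGORICAL_VARS:
        k1 = int((work.loc[g1, var] == level).sum())
        k2 = int((work.loc[g2, var] == level).sum())
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        try:
            _, _, p = chi_squared_2xk(table, yates=yates)
        except UropepError:
            p = float("nan")  # degenerate margin (level absent everywhere)
        cat_rows.append({
            "variable": var, "level": str(level),
            f"{names[0]}_count": k1, f"{names[0]}_pct": _pct(k1, n1),
            f"{names[1]}_count": k2, f"{names[1]}_pct": _pct(k2, n2),
            "p_value": p, "test": "chi_squared",
        })
    categorical = pd.DataFrame(cat_rows)

    gl_rows = []
    case1 = work.loc[g1 & (work["outcome"] == "sig").to_numpy()]
    case2 = work.loc[g2 & (work["outcome"] == "sig").to_numpy()]
    for stratum in CASE_STRATA:
        k1 = int((case1["gleason_stratum"] == stratum).sum())
        k2 = int((case2["gleason_stratum"] == stratum).sum())
        gl_rows.append({
            "stratum": stratum,
            f"{names[0]}_count": k1, f"{names[0]}_pct": _pct(k1, len(case1)),
            f"{names[1]}_count": k2, f"{names[1]}_pct": _pct(k2, len(case2)),
        })
    gleason = pd.DataFrame(gl_rows)

    return CohortSummary(grouping=grouping, group_names=names,
                         group_sizes=(n1, n2), composition=composition,
                         continuous=continuous, categorical=categorical,
                         gleason=gleason)
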