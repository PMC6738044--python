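"""Clinical utility: logistic comparison, nomogram, decision-curve analysis.

Predictors of significant PCa (biomarker score, PSA, age, DRE, prior
biopsies, prostate volume) are compared by maximum-likelihood logistic
regression with per-predictor odds ratios and Wald p-values; the significant
ones combine into a nomogram through the regression equation.  Clinical
benefit is quantified by decision-curve analysis: net benefit
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) over biopsy-decision thresholds p_t,
against the treat-all and treat-none strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .evaluation import delong_test, roc_curve
from .model import SampleTable, UropepError

LOG = logging.getLogger("uropep.clinical")


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with per-predictor inference."""

    predictors: list[str]
    coefficients: pd.Series       # includes "intercept"
    odds_ratios: pd.Series        # per unit of each predictor
    wald_p: pd.Series
    converged: bool
    separation_flag: bool
    n_used: int

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(data), self.coefficients["intercept"])
        for name in self.predictors:
            lp = lp + self.coefficients[name] * data[name].to_numpy(dtype=float)
        return lp

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))

    def coefficient_table(self) -> pd.DataFrame:
        rows = [{"term": "intercept",
                 "coefficient": self.coefficients["intercept"],
                 "odds_ratio": float("nan"), "wald_p": float("nan")}]
        for name in self.predictors:
            rows.append({"term": name,
                         "coefficient": self.coefficients[name],
                         "odds_ratio": self.odds_ratios[name],
                         "wald_p": self.wald_p[name]})
        return pd.DataFrame(rows)


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    collinear = []
    kept: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, kept + [j]]
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(j)
        else:
            collinear.append(names[j])
    raise UropepError(f"collinear predictors: {collinear}")


def fit_logistic(data: pd.DataFrame, predictors: list[str],
                 outcome: str = "outcome") -> LogisticFit:
    """Fit outcome ~ predictors by maximum likelihood (complete cases).

    Rows with missing predictor values are dropped (the used n is reported).
    Perfect separation is flagged and coefficients are still reported from a
    quasi-Newton fit; rank deficiency raises naming the collinear predictors.
    """
    work = data[predictors + [outcome]].dropna()
    n_used = len(work)
    if n_used < len(data):
        LOG.info("fit_logistic: %d of %d rows complete-case",
                 n_used, len(data))
    y = work[outcome]
    if y.dtype == object:
        y = (y == "sig").astype(int)
    y = y.to_numpy(dtype=float)
    if y.min() == y.max():
        raise UropepError("outcome is degenerate (single class)")
    x = work[predictors].to_numpy(dtype=float)
    design = sm.add_constant(x, has_constant="add")
    _check_rank(design, ["intercept"] + predictors)

    import warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=100, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            res = sm.Logit(y, design).fit(method="bfgs", maxiter=500, disp=0)
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        separation = True
    fitted = res.predict(design)
    if not separation and (np.abs(res.params).max() > 50
                           or fitted.min() < 1e-10 or fitted.max() > 1 - 1e-10):
        separation = True
    if separation:
        LOG.warning("fit_logistic: perfect or quasi-perfect separation; "
                    "coefficients are unstable")
    names = ["intercept"] + predictors
    coefs = pd.Series(res.params, index=names)
    pvals = pd.Series(res.pvalues, index=names)
    return LogisticFit(
        predictors=list(predictors), coefficients=coefs,
        odds_ratios=np.exp(coefs[predictors]), wald_p=pvals[predictors],
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separation, n_used=n_used)


# ---------------------------------------------------------------------------
# nomogram

@dataclass
class Nomogram:
    """Combined risk equation: inverse-logit of a fitted linear predictor."""

    fit: LogisticFit

    def risk(self, data: pd.DataFrame) -> np.ndarray:
        return self.fit.predict_proba(data)

    def coefficient_table(self) -> pd.DataFrame:
        return self.fit.coefficient_table()


def build_nomogram(fit: LogisticFit) -> Nomogram:
    """Wrap a converged logistic fit as a combined risk function."""
    if not fit.converged:
        raise UropepError("cannot build a nomogram from an unconverged fit")
    return Nomogram(fit=fit)


# ---------------------------------------------------------------------------
# decision-curve analysis

def decision_curve(probabilities: dict[str, np.ndarray], outcomes,
                   thresholds=None) -> pd.DataFrame:
    """Net benefit of each model over a grid of decision thresholds.

    ``probabilities`` maps model name to per-sample risk in [0, 1]; a sample
    is "treated" (sent to biopsy) when its risk >= p_t.  The returned
    long-format table includes the treat_all and treat_none references.
    """
    outcomes = np.asarray(outcomes, dtype=bool)
    n = outcomes.size
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.501, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds <= 0).any() or (thresholds >= 1).any():
        raise UropepError("threshold grid must lie strictly inside (0, 1)")
    for name, p in probabilities.items():
        p = np.asarray(p, dtype=float)
        if p.shape != outcomes.shape:
            raise UropepError(f"model {name!r}: length mismatch with outcomes")
        if (p < 0).any() or (p > 1).any():
            raise UropepError(f"model {name!r}: probabilities outside [0, 1]")
    prevalence = outcomes.mean()
    rows = []
    for pt in thresholds:
        odds = pt / (1 - pt)
        for name, p in probabilities.items():
            treat = np.asarray(p) >= pt
            tp = (treat & outcomes).sum()
            fp = (treat & ~outcomes).sum()
            rows.append({"model": name, "threshold": pt,
                         "net_benefit": tp / n - fp / n * odds})
        rows.append({"model": "treat_all", "threshold": pt,
                     "net_benefit": prevalence - (1 - prevalence) * odds})
        rows.append({"model": "treat_none", "threshold": pt,
                     "net_benefit": 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# joint model comparison

def compare_models(models: dict[str, np.ndarray], samples: SampleTable,
                   sample_ids, probabilities: dict[str, np.ndarray] | None = None,
                   thresholds=None, psa_model: str = "psa",
                   level: float = 0.95) -> dict:
    """Head-to-head comparison of risk models on one sample set.

    ``models`` maps model name to per-sample scores (any monotone risk
    scale).  Pairs are compared with the paired DeLong test.  For any pair
    involving the PSA model, samples on 5-alpha-reductase inhibitors are
    excluded (5-ARI therapy lowers PSA) and the reduced n is reported.
    Returns {"aucs": DataFrame, "pairs": DataFrame, "dca": DataFrame|None}.
    """
    ann = samples.subset(sample_ids).df
    outcomes = (ann["outcome"] == "sig").to_numpy()
    fivear = ann["fivear_inhibitor"].to_numpy(dtype=bool)
    names = list(models)
    arrays = {}
    for name in names:
        arr = np.asarray(models[name], dtype=float)
        if arr.shape != outcomes.shape:
            raise UropepError(f"model {name!r}: length mismatch with cohort")
        arrays[name] = arr

    auc_rows = []
    for name in names:
        keep = ~fivear if name == psa_model else np.ones_like(fivear)
        keep = keep.astype(bool)
        r = roc_curve(arrays[name][keep], outcomes[keep], level=level)
        auc_rows.append({"model": name, "n": int(keep.sum()), "auc": r.auc,
                         "auc_lo": r.auc_ci[0], "auc_hi": r.auc_ci[1]})
    pair_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            keep = (~fivear if psa_model in (a, b)
                    else np.ones_like(fivear)).astype(bool)
            auc_a, auc_b, z, p = delong_test(
                arrays[a][keep], arrays[b][keep], outcomes[keep])
            pair_rows.append({"model_a": a, "model_b": b, "n": int(keep.sum()),
                              "auc_a": auc_a, "auc_b": auc_b,
                              "delta_auc": auc_a - auc_b, "z": z, "p": p})
    dca = None
    if probabilities is not None:
        dca = decision_curve(probabilities, outcomes, thresholds)
    return {"aucs": pd.DataFrame(auc_rows), "pairs": pd.DataFrame(pair_rows),
            "dca": dca}
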