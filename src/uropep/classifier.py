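"""SVM panel classifier: training, cutoff selection, scoring, persistence.

The panel peptides span the feature space — one dimension per biomarker.
Features are the per-peptide log intensities with censored non-detects set
to the peptide's discovery-set minimum detected log value minus a fixed
offset, standardised with discovery-set constants.  The decision function
is evaluated from the stored support coefficients, so a model reloaded from
its JSON bundle reproduces scores bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .discovery import BiomarkerPanel
from .model import PeptideMatrix, SampleTable, SplitAssignment, UropepError

LOG = logging.getLogger("uropep.classifier")

MODEL_FORMAT_VERSION = 1


@dataclass
class SVMPanelModel:
    """Trained SVM over the panel peptides plus its feature pipeline.

    Holds everything needed to score new samples deterministically: panel
    order, per-peptide censoring floors, standardisation constants, kernel
    spec, support coefficients, the discovery-set cutoff and the Platt-type
    probability calibration (monotone when ``platt_slope >= 0``).
    """

    peptide_ids: list[str]
    directions: list[str]
    kernel: str                      # "rbf" | "linear"
    gamma: float
    c: float
    floors: np.ndarray               # per-peptide censoring floor (log AU)
    means: np.ndarray                # standardisation constants (discovery)
    sds: np.ndarray
    support_vectors: np.ndarray      # standardised feature space
    dual_coef: np.ndarray
    intercept: float
    cutoff: float
    platt_intercept: float
    platt_slope: float

    # -- feature pipeline ----------------------------------------------------

    def features(self, matrix: PeptideMatrix, sample_ids) -> np.ndarray:
        if matrix.scale != "log":
            raise UropepError("scoring expects the log-scale matrix")
        cols = matrix.column_index(self.peptide_ids)  # raises listing missing
        rows = matrix.row_index(sample_ids)
        vals = matrix.values[np.ix_(rows, cols)]
        vals = np.where(np.isfinite(vals), vals, self.floors)
        return (vals - self.means) / self.sds

    def _kernel_matrix(self, x: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return x @ self.support_vectors.T
        if self.kernel == "rbf":
            sq = ((x[:, None, :] - self.support_vectors[None, :, :]) ** 2
                  ).sum(axis=2)
            return np.exp(-self.gamma * sq)
        raise UropepError(f"unsupported kernel {self.kernel!r}")

    def decision_scores(self, matrix: PeptideMatrix, sample_ids) -> np.ndarray:
        """Signed decision-function values (positive leans significant PCa)."""
        x = self.features(matrix, sample_ids)
        return self._kernel_matrix(x) @ self.dual_coef + self.intercept

    def probabilities(self, scores: np.ndarray) -> np.ndarray:
        """Monotone Platt map from decision score to risk in (0, 1)."""
        from scipy.special import expit
        return expit(self.platt_intercept + self.platt_slope * scores)

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "peptide_ids": self.peptide_ids,
            "directions": self.directions,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "c": self.c,
            "floors": self.floors.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "platt_intercept": self.platt_intercept,
            "platt_slope": self.platt_slope,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "SVMPanelModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.pop("format_version") != MODEL_FORMAT_VERSION:
            raise UropepError("unsupported model bundle version")
        for key in ("floors", "means", "sds", "support_vectors", "dual_coef"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def train_svm(matrix: PeptideMatrix, samples: SampleTable,
              split: SplitAssignment, panel: BiomarkerPanel | None = None,
              peptide_ids=None, directions=None, kernel: str = "rbf",
              c: float = 1.0, gamma: float | None = None,
              censor_offset: float = 1.0, cutoff_criterion: str = "youden",
              target_sensitivity: float = 0.90,
              grid_search: bool = False) -> SVMPanelModel:
    """Train the panel SVM on the discovery samples only.

    Censoring floors, standardisation constants, the decision cutoff and the
    probability calibration are all computed from the discovery set; the
    validation samples never influence the model.  Deterministic given
    identical inputs and configuration.

    ``grid_search=True`` is an extension beyond the frozen defaults: it
    tunes (C, gamma) by stratified cross-validation *within the discovery
    set* (validation samples still never participate).
    """
    if panel is not None:
        peptide_ids = panel.peptide_ids
        directions = [panel.directions[p] for p in peptide_ids]
    if not peptide_ids:
        raise UropepError("cannot train on an empty biomarker panel")
    if directions is None:
        directions = ["up_in_sig"] * len(peptide_ids)
    y = samples.outcome_bool(split.discovery_ids).astype(int)
    if y.all() or not y.any():
        raise UropepError("discovery set must contain both outcome classes")

    cols = matrix.column_index(peptide_ids)
    rows = matrix.row_index(split.discovery_ids)
    raw = matrix.values[np.ix_(rows, cols)]
    detected = np.isfinite(raw)
    if not detected.any(axis=0).all():
        missing = [p for p, d in zip(peptide_ids, detected.any(axis=0)) if not d]
        raise UropepError(
            f"panel peptides never detected in discovery: {missing}")
    mins = np.where(detected, raw, np.inf).min(axis=0)
    floors = mins - censor_offset
    floored = np.where(detected, raw, floors)
    means = floored.mean(axis=0)
    sds = floored.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    x = (floored - means) / sds

    gamma_val = float(gamma) if gamma is not None else 1.0 / len(peptide_ids)
    if grid_search:
        from sklearn.model_selection import GridSearchCV, StratifiedKFold
        grid = {"C": [0.1, 1.0, 10.0],
                "gamma": [gamma_val / 10, gamma_val, gamma_val * 10]}
        search = GridSearchCV(SVC(kernel=kernel), grid, scoring="roc_auc",
                              cv=StratifiedKFold(5, shuffle=False))
        search.fit(x, y)
        c = float(search.best_params_["C"])
        gamma_val = float(search.best_params_["gamma"])
        LOG.info("train_svm grid search: C=%g gamma=%g", c, gamma_val)
    svc = SVC(C=c, kernel=kernel, gamma=gamma_val)
    svc.fit(x, y)
    # orientation: sklearn's decision_function is positive for class 1 (case)
    dual = svc.dual_coef_[0].copy()
    model = SVMPanelModel(
        peptide_ids=list(peptide_ids), directions=list(directions),
        kernel=kernel, gamma=gamma_val, c=c, floors=floors, means=means,
        sds=sds, support_vectors=svc.support_vectors_.copy(), dual_coef=dual,
        intercept=float(svc.intercept_[0]), cutoff=0.0,
        platt_intercept=0.0, platt_slope=1.0)

    disc_scores = model.decision_scores(matrix, split.discovery_ids)
    model.cutoff = select_cutoff(disc_scores, y.astype(bool),
                                 criterion=cutoff_criterion,
                                 target_sensitivity=target_sensitivity)
    # Platt-type calibration on discovery scores; the light L2 penalty keeps
    # the fit defined under perfect separation
    platt = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
    platt.fit(disc_scores[:, None], y)
    model.platt_intercept = float(platt.intercept_[0])
    model.platt_slope = float(platt.coef_[0, 0])
    LOG.info("train_svm: %d features, %d SVs, cutoff=%.6f",
             len(peptide_ids), len(dual), model.cutoff)
    return model


def select_cutoff(scores: np.ndarray, outcomes: np.ndarray,
                  criterion: str = "youden",
                  target_sensitivity: float = 0.90) -> float:
    """Choose the decision cutoff on the discovery scores.

    ``youden`` maximises sensitivity + specificity − 1 over the midpoints of
    adjacent distinct scores (ties resolved toward the lower cutoff,
    favouring sensitivity); ``target_sensitivity`` returns the largest
    candidate cutoff whose sensitivity is >= the target.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if outcomes.all() or not outcomes.any():
        raise UropepError("need both outcome classes to set a cutoff")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n_case = outcomes.sum()
    n_ctrl = (~outcomes).sum()
    sens = np.array([(scores[outcomes] >= c).sum() / n_case
                     for c in candidates])
    spec = np.array([(scores[~outcomes] < c).sum() / n_ctrl
                     for c in candidates])
    if criterion == "youden":
        j = sens + spec - 1.0
        return float(candidates[np.argmax(j)])  # argmax: first = lowest cutoff
    if criterion == "target_sensitivity":
        ok = sens >= target_sensitivity
        if not ok.any():
            raise UropepError(
                f"no cutoff reaches sensitivity {target_sensitivity}")
        return float(candidates[ok][-1])
    raise UropepError(f"unknown cutoff criterion {criterion!r}")


def score_samples(model: SVMPanelModel, matrix: PeptideMatrix,
                  samples: SampleTable, sample_ids) -> pd.DataFrame:
    """Score a sample set; returns the per-sample ScoredCohort table.

    Columns: sample_id, score, probability, predicted_label (score >= cutoff
    means predicted significant PCa), outcome, gleason_stratum.
    """
    scores = model.decision_scores(matrix, sample_ids)
    ann = samples.subset(sample_ids).df
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "score": scores,
        "probability": model.probabilities(scores),
        "predicted_label": np.where(scores >= model.cutoff, "sig", "nonsig"),
        "outcome": ann["outcome"].to_numpy(),
        "gleason_stratum": ann["gleason_stratum"].to_numpy(),
    })
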