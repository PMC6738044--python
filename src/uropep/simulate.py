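"""Synthetic CE–MS-like cohorts with ground truth.

Emulates the statistical structure the pipeline assumes: log-normal detected
intensities, per-peptide Bernoulli detection, ~29 disease-invariant
internal-standard peptides, a subset of peptides with planted case–control
shifts on the natural-log scale, and clinical covariates whose group
differences run in the directions seen in biopsy cohorts (older cases,
higher PSA, fewer prior biopsies among cases).

One global seed is split into named sub-streams (``SeedSequence.spawn``)
so adding a generator never perturbs the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (GLEASON_STRATA, PeptideMatrix, SampleTable,
                    SplitAssignment, UropepError, outcome_from_stratum)

LOG = logging.getLogger("uropep.simulate")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``effect_sizes`` is the per-marker shift of mean log-intensity in cases
    (natural-log AU); a scalar means the same magnitude for every marker with
    signs drawn so roughly 70 % of markers are up-regulated in cases (the
    direction balance typical of urinary collagen-fragment panels).
    """

    n_cases: int = 146
    n_controls: int = 677
    n_peptides: int = 5000
    n_internal_standards: int = 29
    n_true_markers: int = 19
    effect_sizes: float | np.ndarray = 1.5
    base_log_mean: float = 7.0
    base_log_sd: float = 1.0
    detection_prob_range: tuple[float, float] = (0.2, 0.99)
    #: detection probability of the planted markers (both groups)
    marker_detection_prob: float = 0.95
    #: optional additive change of marker detection probability in cases
    detection_effect: float = 0.0
    standard_detection_prob: float = 0.999
    #: AUC of the simulated external risk-calculator column; None disables it
    external_risk_auc: float | None = 0.69
    prostate_volume_missing_rate: float = 0.124
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_markers + self.n_internal_standards > self.n_peptides:
            raise UropepError(
                "n_true_markers + n_internal_standards exceeds n_peptides")
        lo, hi = self.detection_prob_range
        if not (0 < lo <= hi <= 1):
            raise UropepError("detection_prob_range must lie in (0, 1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise UropepError("need at least one case and one control")


@dataclass
class GroundTruth:
    """Simulation truth: planted markers, standards, latent group."""

    marker_effects: dict[str, float]      # peptide_id -> signed log-AU shift
    internal_standard_ids: list[str]
    case_sample_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.marker_effects) & set(self.internal_standard_ids)
        if overlap:
            raise UropepError(f"markers overlap internal standards: {overlap}")


# covariate marginals loosely matched to a biopsy-referral cohort:
# (control, case) pairs
_AGE = ((63.0, 8.5), (68.0, 7.6))          # normal: median, sd
_PSA = ((5.1, 0.47), (6.1, 0.47))          # lognormal: median, log-sd
_VOLUME = ((37.4, 0.45), (28.0, 0.47))     # lognormal
_CREATININE = ((7.9, 0.43), (7.8, 0.43))   # lognormal, mmol/L
_DRE_POS = (0.139, 0.342)
_NO_PRIOR_BIOPSY = (0.709, 0.856)
_FIVEAR = (0.032, 0.014)
# gleason stratum mix: controls over (benign, GS6), cases over GS>=7 strata
_CONTROL_GS6 = 0.194
_CASE_STRATA_P = (0.651, 0.199, 0.096, 0.054)   # GS3+4, GS4+3, GS8, GS>=9


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[PeptideMatrix, SampleTable, GroundTruth]:
    """Draw one synthetic cohort (peak-list matrix, annotation, truth).

    Detected intensities are log-normal: log-intensity ~
    N(base_log_mean + group·effect, base_log_sd) for planted markers and
    N(base_log_mean, base_log_sd) otherwise; each cell is independently
    censored to 0 with 1 − detection probability.  Internal standards have
    zero group effect and near-certain detection.
    """
    cfg = config
    LOG.info("simulate_cohort: seed=%d, %d cases / %d controls, %d peptides",
             cfg.seed, cfg.n_cases, cfg.n_controls, cfg.n_peptides)
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_layout, rng_int, rng_det, rng_cov, rng_strat, rng_ext = (
        np.random.default_rng(s) for s in streams)

    n = cfg.n_cases + cfg.n_controls
    m = cfg.n_peptides
    sample_ids = [f"S{i:04d}" for i in range(n)]
    is_case = np.zeros(n, dtype=bool)
    is_case[: cfg.n_cases] = True

    # peptide layout: standards and markers placed at random columns
    cols = rng_layout.permutation(m)
    std_cols = np.sort(cols[: cfg.n_internal_standards])
    mk_cols = np.sort(cols[cfg.n_internal_standards:
                           cfg.n_internal_standards + cfg.n_true_markers])
    peptide_ids = [f"P{j:05d}" for j in range(m)]

    effects = np.zeros(m)
    eff = np.asarray(cfg.effect_sizes, dtype=float)
    if eff.ndim == 0:
        signs = np.where(rng_layout.random(cfg.n_true_markers) < 0.7, 1.0, -1.0)
        eff = float(eff) * signs
    elif len(eff) != cfg.n_true_markers:
        raise UropepError("effect_sizes length must equal n_true_markers")
    effects[mk_cols] = eff

    # latent log-intensities, group shift only on marker columns for cases
    log_int = rng_int.normal(cfg.base_log_mean, cfg.base_log_sd, size=(n, m))
    log_int[is_case] += effects

    # detection probabilities
    lo, hi = cfg.detection_prob_range
    det_p = rng_det.uniform(lo, hi, size=m)
    det_p[std_cols] = cfg.standard_detection_prob
    det_p[mk_cols] = cfg.marker_detection_prob
    det_mat = np.broadcast_to(det_p, (n, m)).copy()
    if cfg.detection_effect:
        det_mat[np.ix_(is_case, mk_cols)] = np.clip(
            cfg.marker_detection_prob + cfg.detection_effect, 1e-6, 1.0)
    detected = rng_det.random((n, m)) < det_mat

    values = np.where(detected, np.exp(log_int), 0.0)

    features = pd.DataFrame({
        "peptide_id": peptide_ids,
        "mass_kda": np.round(rng_layout.uniform(0.8, 12.0, size=m), 4),
        "migration_min": np.round(rng_layout.uniform(18.0, 45.0, size=m), 3),
        "is_internal_standard": np.isin(np.arange(m), std_cols),
    })
    matrix = PeptideMatrix(sample_ids=sample_ids, features=features,
                           values=values, scale="raw")

    samples = _simulate_samples(sample_ids, is_case, cfg, rng_cov, rng_strat,
                                rng_ext)
    truth = GroundTruth(
        marker_effects={peptide_ids[j]: effects[j] for j in mk_cols},
        internal_standard_ids=[peptide_ids[j] for j in std_cols],
        case_sample_ids=[s for s, c in zip(sample_ids, is_case) if c],
    )
    return matrix, samples, truth


def _simulate_samples(sample_ids, is_case, cfg, rng, rng_strat, rng_ext
                      ) -> SampleTable:
    n = len(sample_ids)
    g = is_case.astype(int)

    age = rng.normal([_AGE[i][0] for i in g], [_AGE[i][1] for i in g])
    age = np.clip(np.round(age), 40, 90)
    psa = _truncated_lognormal(rng, g, _PSA, upper=15.0)
    volume = _truncated_lognormal(rng, g, _VOLUME, upper=None)
    creat = _truncated_lognormal(rng, g, _CREATININE, upper=None)
    dre = rng.random(n) < np.take(_DRE_POS, g)
    no_prior = rng.random(n) < np.take(_NO_PRIOR_BIOPSY, g)
    # among re-biopsied patients the count is small: 1 + geometric tail
    n_prior = np.where(no_prior, 0, rng.geometric(0.8, size=n))
    fivear = rng.random(n) < np.take(_FIVEAR, g)
    volume[rng.random(n) < cfg.prostate_volume_missing_rate] = np.nan

    strata = np.empty(n, dtype=object)
    ncase = int(is_case.sum())
    strata[is_case] = rng_strat.choice(
        ["GS3+4", "GS4+3", "GS8", "GS>=9"], size=ncase, p=_CASE_STRATA_P)
    strata[~is_case] = rng_strat.choice(
        ["GS6", "benign"], size=n - ncase, p=[_CONTROL_GS6, 1 - _CONTROL_GS6])

    if cfg.external_risk_auc is not None:
        # binormal latent with the configured AUC, mapped through a logistic
        delta = np.sqrt(2.0) * _norm_ppf(cfg.external_risk_auc)
        latent = rng_ext.normal(-1.5 + delta * g, 1.0)
        external = expit(latent)
    else:
        external = np.full(n, np.nan)

    return SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "gleason_stratum": strata,
        "age": age,
        "psa": psa,
        "dre_positive": dre,
        "prior_biopsy_count": n_prior.astype(int),
        "prostate_volume_ml": volume,
        "fivear_inhibitor": fivear,
        "urinary_creatinine": creat,
        "external_risk": external,
    }))


def _truncated_lognormal(rng, g, params, upper) -> np.ndarray:
    med = np.array([params[i][0] for i in g])
    sd = np.array([params[i][1] for i in g])
    out = med * np.exp(rng.normal(0.0, sd))
    if upper is not None:
        bad = out >= upper
        while bad.any():  # rejection sampling against the inclusion limit
            out[bad] = med[bad] * np.exp(rng.normal(0.0, sd[bad]))
            bad = out >= upper
    out = np.round(out, 3)
    if upper is not None:
        out = np.minimum(out, upper - 1e-3)  # rounding must not cross the limit
    return out


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm
    return float(norm.ppf(q))


def simulate_study_scale(seed: int
                         ) -> tuple[PeptideMatrix, SampleTable, GroundTruth]:
    """Convenience preset at full study scale.

    823 samples (146 significant-PCa cases, 677 controls), 5000 peptides,
    29 internal standards, 19 planted markers at |effect| = 1.5 log-AU with
    detection probability 0.95; a stratified 2/3–1/3 split of this cohort
    yields approximately 98/445 discovery and 48/232 validation samples.
    """
    return simulate_cohort(SimulationConfig(seed=seed))


# ---------------------------------------------------------------------------
# reference cohort composition (deterministic bookkeeping fixture)

def reference_cohort() -> tuple[SampleTable, SplitAssignment]:
    """Deterministic cohort with the reference composition of the study design.

    823 samples: discovery 543 (98 significant-PCa cases, 445 controls) and
    validation 280 (48 cases, 232 controls).  Gleason strata within cases:
    discovery 63/20/9/6 and validation 32/9/5/2 across GS 3+4 / 4+3 / 8 / >=9;
    GS 6 controls number 99 (discovery) and 32 (validation), the remainder
    benign.  480 of the 677 controls (70.9 %) and 125 of the 146 cases
    (85.6 %) have no prior biopsy.  Covariates beyond these counts are
    constants — the fixture exists for count bookkeeping, not statistics.
    """
    rows: list[dict] = []

    def add(n, subset, stratum):
        start = len(rows)
        for k in range(n):
            rows.append({"sample_id": f"R{start + k:04d}", "subset": subset,
                         "gleason_stratum": stratum})

    add(63, "discovery", "GS3+4"); add(20, "discovery", "GS4+3")
    add(9, "discovery", "GS8");    add(6, "discovery", "GS>=9")
    add(32, "validation", "GS3+4"); add(9, "validation", "GS4+3")
    add(5, "validation", "GS8");    add(2, "validation", "GS>=9")
    add(99, "discovery", "GS6");   add(346, "discovery", "benign")
    add(32, "validation", "GS6");  add(200, "validation", "benign")

    df = pd.DataFrame(rows)
    df["outcome"] = df["gleason_stratum"].map(outcome_from_stratum)

    # prior-biopsy flags: fill per outcome group to hit the group margins
    df["prior_biopsy_count"] = 0
    for outcome, n_prior in (("nonsig", 197), ("sig", 21)):
        idx = df.index[df["outcome"] == outcome][:n_prior]
        df.loc[idx, "prior_biopsy_count"] = 1

    df["age"] = 64.0
    df["psa"] = 5.0
    df["dre_positive"] = False
    df["prostate_volume_ml"] = 35.0
    df["fivear_inhibitor"] = False
    df["urinary_creatinine"] = 7.8
    df["external_risk"] = np.nan

    split = SplitAssignment(
        discovery_ids=list(df.loc[df["subset"] == "discovery", "sample_id"]),
        validation_ids=list(df.loc[df["subset"] == "validation", "sample_id"]),
        seed=0)
    return SampleTable(df.drop(columns="subset")), split
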