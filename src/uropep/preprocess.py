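"""Normalisation, log transform, detection frequencies, cohort split.

Intensities are scaled per sample against the internal-standard peptides
(disease-invariant collagen fragments): each standard's reference level is
its median detected intensity across samples, and a sample's multiplicative
factor is the median of (reference / observed) over the standards detected
in that sample — robust to individual standard dropout.  After
normalisation, detected intensities are natural-log transformed; non-detects
stay at the censoring floor (stored as ``-inf`` on the log scale) so that
every rank-based statistic treats them as tied below all detected values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (OUTCOME_SIG, PeptideMatrix, SampleTable, SplitAssignment,
                    UropepError, ValidationError)

LOG = logging.getLogger("uropep.preprocess")


@dataclass
class NormalisationModel:
    """Per-standard reference levels and per-sample scale factors."""

    standard_ids: list[str]
    reference: np.ndarray       # AU, one per standard
    sample_ids: list[str]
    factors: np.ndarray         # dimensionless, one per sample, > 0

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("scale factors must be strictly positive")


def fit_normalisation(matrix: PeptideMatrix,
                      reference: np.ndarray | None = None
                      ) -> NormalisationModel:
    """Fit per-sample scale factors from the internal standards.

    Each standard's reference level is its median detected intensity across
    samples (or the ``reference`` levels of a previously fitted model, for
    re-fitting an already scaled matrix); a sample's factor is the median of
    (reference / observed) over its detected standards.
    """
    if matrix.scale != "raw":
        raise ValidationError(f"expected raw-scale matrix, got {matrix.scale}")
    std_ids = matrix.internal_standard_ids
    if not std_ids:
        raise UropepError("matrix carries no internal-standard peptides")
    cols = matrix.column_index(std_ids)
    std = matrix.values[:, cols]                      # samples x standards
    detected = std > 0
    undetected_everywhere = ~detected.any(axis=0)
    if undetected_everywhere.any():
        raise UropepError(
            "internal standards never detected: "
            f"{[std_ids[j] for j in np.flatnonzero(undetected_everywhere)]}")
    if reference is None:
        reference = np.array([np.median(std[detected[:, j], j])
                              for j in range(len(std_ids))])
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (len(std_ids),):
            raise ValidationError("reference levels do not match standards")
    with np.errstate(divide="ignore"):
        ratio = np.where(detected, reference / std, np.nan)
    none_detected = ~detected.any(axis=1)
    if none_detected.any():
        raise UropepError(
            "samples with zero detected internal standards: "
            f"{[matrix.sample_ids[i] for i in np.flatnonzero(none_detected)]}")
    factors = np.nanmedian(ratio, axis=1)
    return NormalisationModel(standard_ids=std_ids, reference=reference,
                              sample_ids=list(matrix.sample_ids),
                              factors=factors)


def apply_normalisation(matrix: PeptideMatrix,
                        model: NormalisationModel) -> PeptideMatrix:
    """Multiply each sample's nonzero intensities by its factor."""
    if matrix.scale != "raw":
        raise ValidationError(f"expected raw-scale matrix, got {matrix.scale}")
    if list(matrix.sample_ids) != model.sample_ids:
        raise ValidationError("normalisation model fitted on different samples")
    scaled = matrix.values * model.factors[:, None]   # zeros stay zero
    return matrix.with_values(scaled, "normalised")


def log_transform(matrix: PeptideMatrix) -> PeptideMatrix:
    """Natural log of detected intensities; non-detects become ``-inf``."""
    if matrix.scale != "normalised":
        raise ValidationError(
            f"expected normalised-scale matrix, got {matrix.scale}")
    with np.errstate(divide="ignore"):
        logged = np.where(matrix.values > 0, np.log(matrix.values), -np.inf)
    return matrix.with_values(logged, "log")


def detection_frequencies(matrix: PeptideMatrix, samples: SampleTable,
                          sample_ids=None) -> pd.DataFrame:
    """Per-peptide detection frequency in each outcome group.

    Returns a DataFrame indexed by peptide_id with columns ``case_freq`` and
    ``control_freq`` (fraction of group samples with a detected intensity).
    """
    if sample_ids is None:
        sample_ids = matrix.sample_ids
    sub = matrix.subset_samples(sample_ids)
    is_case = samples.outcome_bool(sample_ids)
    if is_case.all() or not is_case.any():
        raise UropepError("both outcome groups must be non-empty")
    det = sub.detected()
    return pd.DataFrame({
        "case_freq": det[is_case].mean(axis=0),
        "control_freq": det[~is_case].mean(axis=0),
    }, index=pd.Index(matrix.peptide_ids, name="peptide_id"))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def stratified_split(samples: SampleTable, discovery_fraction: float = 2 / 3,
                     seed: int = 0) -> SplitAssignment:
    """Random per-outcome-class split into discovery and validation.

    Per class, round(fraction · n_class) samples (half away from zero) are
    drawn without replacement into discovery; deterministic given seed.
    """
    LOG.info("stratified_split: seed=%d fraction=%.4f", seed, discovery_fraction)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    discovery: list[str] = []
    validation: list[str] = []
    df = samples.df
    for outcome in (OUTCOME_SIG, "nonsig"):
        ids = df.loc[df["outcome"] == outcome, "sample_id"].to_numpy()
        if len(ids) == 0:
            raise UropepError(f"outcome class {outcome!r} is empty")
        n_disc = _round_half_away(discovery_fraction * len(ids))
        if n_disc >= len(ids):
            raise UropepError(
                f"class {outcome!r} too small for a non-empty validation set")
        if n_disc < 1:
            raise UropepError(
                f"class {outcome!r} too small for a non-empty discovery set")
        chosen = rng.choice(ids, size=n_disc, replace=False)
        chosen_set = set(chosen)
        discovery.extend(chosen)
        validation.extend(s for s in ids if s not in chosen_set)
    return SplitAssignment(discovery_ids=discovery, validation_ids=validation,
                           seed=seed)
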