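"""Shared domain types for the urinary-peptide pipeline.

A CE–MS peak list characterises each deconvoluted peptide by its molecular
mass (kDa), normalised migration time (min) and signal intensity (arbitrary
units, AU).  Intensity 0 encodes "not detected" on the raw and normalised
scales; on the natural-log scale non-detects are stored as ``-inf`` so the
censoring floor ranks below every detected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# errors

class UropepError(Exception):
    """Base class for all package errors."""


class FormatError(UropepError):
    """Structurally malformed input file (duplicate ids, bad header...)."""


class ParseError(UropepError):
    """A cell could not be parsed; message names the row and column."""


class ValidationError(UropepError):
    """Parsed but invalid values (negative intensity, outcome mismatch...)."""


# ---------------------------------------------------------------------------
# Gleason coding

GLEASON_STRATA = ("benign", "GS6", "GS3+4", "GS4+3", "GS8", "GS>=9")
#: strata defining significant prostate cancer (Gleason score >= 7)
SIG_STRATA = frozenset({"GS3+4", "GS4+3", "GS8", "GS>=9"})

OUTCOME_SIG = "sig"
OUTCOME_NONSIG = "nonsig"

#: maximum PSA (ng/ml) for cohort inclusion
PSA_INCLUSION_LIMIT = 15.0

FEATURE_COLUMNS = ["peptide_id", "mass_kda", "migration_min", "is_internal_standard"]

SAMPLE_COLUMNS = [
    "sample_id", "gleason_stratum", "outcome", "age", "psa", "dre_positive",
    "prior_biopsy_count", "prostate_volume_ml", "fivear_inhibitor",
    "urinary_creatinine", "external_risk",
]


def outcome_from_stratum(stratum: str) -> str:
    return OUTCOME_SIG if stratum in SIG_STRATA else OUTCOME_NONSIG


# ---------------------------------------------------------------------------
# peptide matrix

SCALE_ORDER = ("raw", "normalised", "log")


@dataclass
class PeptideMatrix:
    """Samples × peptides intensity matrix with peptide metadata.

    ``values`` rows follow ``sample_ids``; columns follow ``features``
    (a DataFrame with columns ``peptide_id``, ``mass_kda``, ``migration_min``,
    ``is_internal_standard``).  ``scale`` moves only raw → normalised → log.
    """

    sample_ids: list[str]
    features: pd.DataFrame
    values: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in SCALE_ORDER:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if list(self.features.columns[:4]) != FEATURE_COLUMNS:
            raise FormatError(
                f"feature table must carry columns {FEATURE_COLUMNS}, "
                f"got {list(self.features.columns)}")
        ids = self.features["peptide_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate peptide_id: {sorted(set(dup))}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise ValidationError(
                f"intensity shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.features)} peptides")
        if (self.features["mass_kda"] <= 0).any():
            raise ValidationError("mass_kda must be positive")
        if (self.features["migration_min"] <= 0).any():
            raise ValidationError("migration_min must be positive")
        if self.scale in ("raw", "normalised"):
            if np.isnan(self.values).any() or (self.values < 0).any():
                raise ValidationError(
                    f"negative or NaN intensity on {self.scale} scale")

    # -- convenience views ---------------------------------------------------

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.features["peptide_id"])

    @property
    def internal_standard_ids(self) -> list[str]:
        mask = self.features["is_internal_standard"].astype(bool)
        return list(self.features.loc[mask, "peptide_id"])

    def detected(self) -> np.ndarray:
        """Boolean samples × peptides mask of detected cells."""
        if self.scale == "log":
            return np.isfinite(self.values)
        return self.values > 0

    def column_index(self, peptide_ids) -> np.ndarray:
        """Column positions of the given peptides; raises on missing ids."""
        lookup = {p: i for i, p in enumerate(self.peptide_ids)}
        missing = [p for p in peptide_ids if p not in lookup]
        if missing:
            raise ValidationError(f"peptides absent from matrix: {missing}")
        return np.array([lookup[p] for p in peptide_ids], dtype=int)

    def row_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids) -> "PeptideMatrix":
        rows = self.row_index(sample_ids)
        return replace(self, sample_ids=list(sample_ids),
                       values=self.values[rows])

    def with_values(self, values: np.ndarray, scale: str) -> "PeptideMatrix":
        i, j = SCALE_ORDER.index(self.scale), SCALE_ORDER.index(scale)
        if j != i + 1:
            raise ValidationError(
                f"illegal scale transition {self.scale} -> {scale}")
        return replace(self, values=values, scale=scale)


# ---------------------------------------------------------------------------
# sample annotation

class SampleTable:
    """Per-sample clinical annotation wrapped around a DataFrame.

    The binary outcome (significant prostate cancer, Gleason >= 7, vs
    control) is derived from ``gleason_stratum`` and validated against any
    explicit ``outcome`` column.  Samples with PSA >= 15 ng/ml violate the
    cohort inclusion rule and are rejected at construction.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        required = {"sample_id", "gleason_stratum", "age", "psa",
                    "dre_positive", "prior_biopsy_count", "fivear_inhibitor",
                    "urinary_creatinine"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in sample table")
        bad_stratum = set(df["gleason_stratum"]) - set(GLEASON_STRATA)
        if bad_stratum:
            raise ValidationError(
                f"unknown gleason_stratum values: {sorted(bad_stratum)}")
        derived = df["gleason_stratum"].map(outcome_from_stratum)
        if "outcome" in df.columns:
            clash = df.loc[df["outcome"] != derived, "sample_id"]
            if len(clash):
                raise ValidationError(
                    "outcome contradicts gleason_stratum for samples: "
                    f"{list(clash)}")
        df["outcome"] = derived
        over = df.loc[df["psa"] >= PSA_INCLUSION_LIMIT, "sample_id"]
        if len(over):
            raise ValidationError(
                f"samples violate the PSA < {PSA_INCLUSION_LIMIT} ng/ml "
                f"inclusion criterion: {list(over)}")
        if (df["prior_biopsy_count"] < 0).any():
            raise ValidationError("prior_biopsy_count must be >= 0")
        if "prostate_volume_ml" not in df.columns:
            df["prostate_volume_ml"] = np.nan
        if "external_risk" not in df.columns:
            df["external_risk"] = np.nan
        vol = df["prostate_volume_ml"]
        if (vol.dropna() <= 0).any():
            raise ValidationError("prostate_volume_ml must be positive")
        risk = df["external_risk"].dropna()
        if ((risk < 0) | (risk > 1)).any():
            raise ValidationError("external_risk must lie in [0, 1]")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def outcome_bool(self, sample_ids=None) -> np.ndarray:
        """True for significant-PCa samples, in the given sample order."""
        sub = self.subset(sample_ids).df if sample_ids is not None else self.df
        return (sub["outcome"] == OUTCOME_SIG).to_numpy()

    def subset(self, sample_ids) -> "SampleTable":
        sub = self.df.set_index("sample_id", drop=False).loc[list(sample_ids)]
        return SampleTable(sub.reset_index(drop=True))


@dataclass
class SplitAssignment:
    """Stratified discovery/validation partition of a cohort."""

    discovery_ids: list[str]
    validation_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.discovery_ids) & set(self.validation_ids):
            raise ValidationError("discovery and validation sets overlap")
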