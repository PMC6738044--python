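"""Pipeline configuration and logging.

Every cross-module tunable lives in one :class:`PipelineConfig`, loadable
from a single YAML file; CLI flags override individual fields.  All delimited
I/O in the package is UTF-8, tab-separated, ``.`` decimal — this is enforced,
not configurable.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

LOG = logging.getLogger("uropep")


@dataclass
class PipelineConfig:
    """All tunables of the discovery/validation pipeline.

    Defaults mirror the study conditions: a stratified 2/3–1/3 split, a 70 %
    detection-frequency threshold, five stability runs each excluding 30 % of
    the discovery samples, and Benjamini–Hochberg significance at 0.05.
    """

    # stratified split
    split_fraction: float = 2.0 / 3.0
    # discovery stage
    freq_threshold: float = 0.70
    n_stability_runs: int = 5
    exclude_fraction: float = 0.30
    alpha: float = 0.05
    #: interpret "significant (p < alpha)" on BH-adjusted p (True) or raw p
    use_adjusted_p: bool = True
    #: BH family: "filtered" restricts correction to frequency-passing
    #: peptides, "all" corrects across every profiled peptide
    bh_family: str = "filtered"
    # classifier
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    #: None -> 1 / n_panel (one dimension per biomarker)
    svm_gamma: float | None = None
    #: extension: tune (C, gamma) by CV within the discovery set
    svm_grid_search: bool = False
    #: non-detects enter the SVM as (per-peptide discovery min detected
    #: log value) - censor_offset, in natural-log AU units
    censor_offset: float = 1.0
    cutoff_criterion: str = "youden"
    target_sensitivity: float = 0.90
    # evaluation
    chi2_yates: bool = False
    ci_level: float = 0.95
    # decision-curve analysis threshold grid
    dca_grid_start: float = 0.01
    dca_grid_stop: float = 0.50
    dca_grid_step: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML; absent keys keep their defaults."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given (non-None) fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)


def setup_logging(verbosity: int = 0, logfile: str | Path | None = None) -> None:
    """Configure the package logger with timestamped lines.

    verbosity 0 = WARNING, 1 = INFO, 2+ = DEBUG.  Every stochastic operation
    in the package logs the seed it consumes at INFO level.
    """
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbosity, 2)]
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile, encoding="utf-8"))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    LOG.setLevel(level)
    for h in handlers:
        h.setFormatter(fmt)
        LOG.addHandler(h)
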