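"""Biomarker discovery: frequency filter, rank tests, BH, stability runs.

Each peptide is compared between significant-PCa cases and controls with a
two-sided Wilcoxon rank-sum test (censored non-detects tied below every
detected value), restricted to peptides detected in at least 70 % of one
group, corrected by Benjamini–Hochberg, and the whole analysis is repeated
on five random 70 % subsamples of the discovery set ("stability runs").
Only peptides significant in all runs form the biomarker panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import PeptideMatrix, SampleTable, SplitAssignment, UropepError
from .preprocess import _round_half_away, detection_frequencies

LOG = logging.getLogger("uropep.discovery")

#: exact-enumeration Wilcoxon is used up to this combined sample size
EXACT_THRESHOLD = 12

DIRECTION_UP = "up_in_sig"
DIRECTION_DOWN = "down_in_sig"


# ---------------------------------------------------------------------------
# rank-sum tests

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney / Wilcoxon rank-sum test; returns (U, p).

    U is the statistic of the first sample (midranks under ties).  The exact
    null distribution is enumerated when the combined sample size is at most
    ``EXACT_THRESHOLD`` and there are no ties; otherwise the normal
    approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UropepError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    if np.ptp(combined) == 0 or u_x == x.size * y.size / 2:
        return u_x, 1.0  # all identical, or U at its null mean (symmetry)
    method = ("exact" if combined.size <= EXACT_THRESHOLD and not has_ties
              else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return u_x, p


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p-value (see :func:`mann_whitney_u`)."""
    return mann_whitney_u(x, y)[1]


def rank_sum_bulk(values: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values (normal approximation).

    Vectorised tie- and continuity-corrected test across thousands of
    peptides; columns with all observations identical get p = 1.
    ``-inf`` censored values participate as tied minima.
    """
    n1 = int(is_case.sum())
    n0 = int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise UropepError("both groups must be non-empty")
    n = n1 + n0
    ranks = stats.rankdata(values, axis=0)
    u1 = ranks[is_case].sum(axis=0) - n1 * (n1 + 1) / 2
    tie_term = _tie_term(values)
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    num = u1 - n1 * n0 / 2.0
    num = num - 0.5 * np.sign(num)  # continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / np.sqrt(var)
    p = np.where(var > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return np.minimum(p, 1.0)


def _tie_term(values: np.ndarray) -> np.ndarray:
    """Per-column sum of (t^3 - t) over tie groups of size t."""
    n, m = values.shape
    s = np.sort(values, axis=0)
    new_run = np.vstack([np.ones((1, m), dtype=bool), s[1:] != s[:-1]])
    run_id = np.cumsum(new_run, axis=0) - 1            # per-column run index
    flat = (run_id + np.arange(m) * n).T.ravel()       # unique id per (col, run)
    counts = np.bincount(flat, minlength=n * m).astype(float)
    contrib = counts ** 3 - counts
    cols = np.arange(n * m) // n
    return np.bincount(cols, weights=contrib, minlength=m)


# ---------------------------------------------------------------------------
# multiple testing

def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise UropepError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(stepped[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


def frequency_filter(freq: pd.DataFrame, threshold: float = 0.70) -> pd.Index:
    """Peptides detected in >= threshold of cases OR controls (inclusive)."""
    keep = (freq["case_freq"] >= threshold) | (freq["control_freq"] >= threshold)
    return freq.index[keep]


# ---------------------------------------------------------------------------
# stability analysis

def _run_analysis(matrix: PeptideMatrix, samples: SampleTable, sample_ids,
                  freq_threshold: float, bh_family: str) -> pd.DataFrame:
    """Frequency filter + rank tests + BH on one sample subset."""
    freq = detection_frequencies(matrix, samples, sample_ids)
    passed = frequency_filter(freq, freq_threshold)
    sub = matrix.subset_samples(sample_ids)
    is_case = samples.outcome_bool(sample_ids)
    if is_case.all() or not is_case.any():
        raise UropepError("subsample degenerated to a single outcome class")
    raw_p = rank_sum_bulk(sub.values, is_case)
    out = freq.copy()
    out["passed_filter"] = out.index.isin(passed)
    out["raw_p"] = raw_p
    adj = np.full(len(out), np.nan)
    if bh_family == "all":
        adj = benjamini_hochberg(raw_p)
    elif bh_family == "filtered":
        mask = out["passed_filter"].to_numpy()
        if mask.any():
            adj[mask] = benjamini_hochberg(raw_p[mask])
    else:
        raise UropepError(f"unknown bh_family {bh_family!r}")
    out["adjusted_p"] = adj
    return out


def stability_runs(matrix: PeptideMatrix, samples: SampleTable,
                   split: SplitAssignment, n_runs: int = 5,
                   exclude_fraction: float = 0.30, freq_threshold: float = 0.70,
                   bh_family: str = "filtered", seed: int = 0
                   ) -> list[pd.DataFrame]:
    """Repeat the discovery statistics on random stratified subsamples.

    Each run retains (1 − exclude_fraction) of the discovery samples per
    outcome class (round half away from zero) and re-applies the frequency
    filter, rank tests and BH correction within the retained subsample.
    Deterministic given seed; run k uses the k-th spawned sub-stream, so
    shortening the run list never changes earlier runs.
    """
    LOG.info("stability_runs: seed=%d runs=%d exclude=%.2f", seed, n_runs,
             exclude_fraction)
    disc = samples.subset(split.discovery_ids).df
    by_class = {o: disc.loc[disc["outcome"] == o, "sample_id"].to_numpy()
                for o in ("sig", "nonsig")}
    if min(len(v) for v in by_class.values()) == 0:
        raise UropepError("discovery set must contain both outcome classes")
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    results = []
    for run, stream in enumerate(streams):
        if exclude_fraction == 0:
            retained = list(split.discovery_ids)
        else:
            rng = np.random.default_rng(stream)
            retained = []
            for ids in by_class.values():
                n_keep = _round_half_away((1 - exclude_fraction) * len(ids))
                if n_keep < 1:
                    raise UropepError("subsample degenerates to one class")
                retained.extend(rng.choice(ids, size=n_keep, replace=False))
        results.append(_run_analysis(matrix, samples, retained,
                                     freq_threshold, bh_family))
    return results


@dataclass
class BiomarkerPanel:
    """Selected peptides with directions and full audit trail.

    ``members`` rows: peptide_id, mass_kda, migration_min, direction,
    case_freq, control_freq, raw_p, adjusted_p, plus one ``run_k_p`` column
    per stability run.  ``full_results`` retains the statistics for every
    peptide tested on the complete discovery set.
    """

    members: pd.DataFrame
    full_results: pd.DataFrame
    run_results: list[pd.DataFrame]
    alpha: float
    n_runs: int
    exclude_fraction: float
    freq_threshold: float
    seed: int

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.members["peptide_id"])

    @property
    def directions(self) -> dict[str, str]:
        return dict(zip(self.members["peptide_id"], self.members["direction"]))

    def __len__(self) -> int:
        return len(self.members)


def _directions(matrix: PeptideMatrix, samples: SampleTable, sample_ids,
                peptide_ids) -> pd.Series:
    """Sign of case-minus-control median log intensity (ties -> up)."""
    sub = matrix.subset_samples(sample_ids)
    cols = matrix.column_index(peptide_ids)
    vals = sub.values[:, cols]
    # censored floor for the median: just below the smallest detected value
    finite = vals[np.isfinite(vals)]
    floor = (finite.min() - 1.0) if finite.size else 0.0
    vals = np.where(np.isfinite(vals), vals, floor)
    is_case = samples.outcome_bool(sample_ids)
    diff = np.median(vals[is_case], axis=0) - np.median(vals[~is_case], axis=0)
    return pd.Series(np.where(diff >= 0, DIRECTION_UP, DIRECTION_DOWN),
                     index=pd.Index(peptide_ids, name="peptide_id"))


def discover_panel(matrix: PeptideMatrix, samples: SampleTable,
                   split: SplitAssignment, n_runs: int = 5,
                   exclude_fraction: float = 0.30, alpha: float = 0.05,
                   freq_threshold: float = 0.70, use_adjusted_p: bool = True,
                   bh_family: str = "filtered", seed: int = 0
                   ) -> BiomarkerPanel:
    """Select the biomarker panel from the discovery set.

    A peptide enters the panel when it passes the frequency filter on the
    full discovery set and is significant (BH-adjusted p < alpha by default;
    raw p when ``use_adjusted_p=False``) in every stability run.  Regulation
    directions come from the full discovery set.  An empty panel is returned
    with a warning, not an error.
    """
    if matrix.scale != "log":
        raise UropepError("discovery expects the log-scale matrix")
    full = _run_analysis(matrix, samples, split.discovery_ids,
                         freq_threshold, bh_family)
    runs = stability_runs(matrix, samples, split, n_runs=n_runs,
                          exclude_fraction=exclude_fraction,
                          freq_threshold=freq_threshold,
                          bh_family=bh_family, seed=seed)
    p_col = "adjusted_p" if use_adjusted_p else "raw_p"
    member_mask = full["passed_filter"].copy()
    for res in runs:
        sig = res["passed_filter"] & (res[p_col] < alpha)
        member_mask &= sig.reindex(member_mask.index, fill_value=False)
    member_ids = list(full.index[member_mask])

    meta = matrix.features.set_index("peptide_id")
    members = pd.DataFrame({"peptide_id": member_ids})
    members["mass_kda"] = meta.loc[member_ids, "mass_kda"].to_numpy()
    members["migration_min"] = meta.loc[member_ids, "migration_min"].to_numpy()
    if member_ids:
        members["direction"] = _directions(
            matrix, samples, split.discovery_ids, member_ids).to_numpy()
    else:
        members["direction"] = pd.Series(dtype=object)
    for col in ("case_freq", "control_freq", "raw_p", "adjusted_p"):
        members[col] = full.loc[member_ids, col].to_numpy()
    for k, res in enumerate(runs, start=1):
        members[f"run_{k}_p"] = res[p_col].reindex(member_ids).to_numpy()
    members = members.sort_values(
        ["adjusted_p", "peptide_id"]).reset_index(drop=True)

    if not member_ids:
        LOG.warning("discover_panel selected an empty panel "
                    "(downstream training will refuse)")
    else:
        LOG.info("discover_panel: %d peptides selected", len(member_ids))
    return BiomarkerPanel(members=members, full_results=full,
                          run_results=runs, alpha=alpha, n_runs=n_runs,
                          exclude_fraction=exclude_fraction,
                          freq_threshold=freq_threshold, seed=seed)
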