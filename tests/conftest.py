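import numpy as np
import pytest

import uropep as up


@pytest.fixture(scope="session")
def small_pipeline():
    """One small simulated cohort carried through preprocessing + discovery.

    40 cases / 160 controls, 300 peptides, 19 planted markers at 1.5 log-AU:
    large enough for the discovery stage to behave, small enough to share
    across tests.
    """
    cfg = up.SimulationConfig(n_cases=40, n_controls=160, n_peptides=300,
                              seed=11)
    matrix, samples, truth = up.simulate_cohort(cfg)
    norm_model = up.fit_normalisation(matrix)
    norm = up.apply_normalisation(matrix, norm_model)
    logm = up.log_transform(norm)
    split = up.stratified_split(samples, seed=11)
    panel = up.discover_panel(logm, samples, split, seed=11)
    return {"config": cfg, "matrix": matrix, "samples": samples,
            "truth": truth, "norm_model": norm_model, "norm": norm,
            "log": logm, "split": split, "panel": panel}


@pytest.fixture(scope="session")
def trained(small_pipeline):
    p = small_pipeline
    model = up.train_svm(p["log"], p["samples"], p["split"], panel=p["panel"])
    scored_val = up.score_samples(model, p["log"], p["samples"],
                                  p["split"].validation_ids)
    return {"model": model, "scored_val": scored_val, **p}


def rank_sum_permutation_p(x, y):
    """Exhaustive-enumeration two-sided rank-sum p (oracle, no ties).

    Enumerates every assignment of the pooled ranks to the first group and
    doubles the smaller tail of the exact U distribution, capped at 1.
    """
    from itertools import combinations
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [sum(c) - n1 * (n1 + 1) / 2
          for c in combinations(ranks, n1)]
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))
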