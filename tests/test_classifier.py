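import numpy as np
import pandas as pd
import pytest

import uropep as up
from uropep.classifier import select_cutoff
from uropep.model import PeptideMatrix, SampleTable, SplitAssignment


def _toy_problem(case_vals, ctrl_vals):
    """1-D problem: one panel peptide, values given per class, log scale."""
    n_case, n_ctrl = len(case_vals), len(ctrl_vals)
    ids = [f"S{i}" for i in range(n_case + n_ctrl)]
    features = pd.DataFrame({
        "peptide_id": ["PX", "PSTD"], "mass_kda": [1.5, 2.0],
        "migration_min": [25.0, 30.0],
        "is_internal_standard": [False, True]})
    values = np.column_stack([
        np.concatenate([case_vals, ctrl_vals]).astype(float),
        np.zeros(n_case + n_ctrl)])
    matrix = PeptideMatrix(sample_ids=ids, features=features, values=values,
                           scale="raw").with_values(values, "normalised"
                           ).with_values(values, "log")
    samples = SampleTable(pd.DataFrame({
        "sample_id": ids,
        "gleason_stratum": ["GS4+3"] * n_case + ["benign"] * n_ctrl,
        "age": 65.0, "psa": 5.0, "dre_positive": False,
        "prior_biopsy_count": 0, "fivear_inhibitor": False,
        "urinary_creatinine": 8.0}))
    split = SplitAssignment(discovery_ids=ids, validation_ids=[], seed=0)
    return matrix, samples, split


def test_separable_toy_classified_correctly():
    matrix, samples, split = _toy_problem([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
    model = up.train_svm(matrix, samples, split, peptide_ids=["PX"],
                         kernel="linear")
    scored = up.score_samples(model, matrix, samples, split.discovery_ids)
    assert (scored["predicted_label"] == scored["outcome"]).all()


def test_training_deterministic(trained):
    p = trained
    again = up.train_svm(p["log"], p["samples"], p["split"], panel=p["panel"])
    s1 = p["model"].decision_scores(p["log"], p["split"].validation_ids)
    s2 = again.decision_scores(p["log"], p["split"].validation_ids)
    np.testing.assert_allclose(s1, s2, atol=1e-9)
    assert again.cutoff == p["model"].cutoff


def test_decision_scores_match_sklearn(trained):
    """Our kernel evaluation reproduces sklearn's decision_function."""
    from sklearn.svm import SVC
    p = trained
    model = p["model"]
    x = model.features(p["log"], p["split"].discovery_ids)
    y = p["samples"].outcome_bool(p["split"].discovery_ids).astype(int)
    svc = SVC(C=model.c, kernel=model.kernel, gamma=model.gamma)
    svc.fit(x, y)
    ours = model.decision_scores(p["log"], p["split"].discovery_ids)
    np.testing.assert_allclose(ours, svc.decision_function(x), atol=1e-9)


def test_model_save_load_bit_exact(tmp_path, trained):
    model = trained["model"]
    path = tmp_path / "model.json"
    model.save(path)
    loaded = up.SVMPanelModel.load(path)
    s1 = model.decision_scores(trained["log"], trained["split"].validation_ids)
    s2 = loaded.decision_scores(trained["log"],
                                trained["split"].validation_ids)
    np.testing.assert_array_equal(s1, s2)
    assert loaded.cutoff == model.cutoff
    assert loaded.peptide_ids == model.peptide_ids


def test_missing_panel_column_lists_ids(trained):
    p = trained
    logm = p["log"]
    keep = [c for c in logm.peptide_ids if c != p["panel"].peptide_ids[0]]
    cols = logm.column_index(keep)
    sub = PeptideMatrix(sample_ids=logm.sample_ids,
                        features=logm.features.iloc[cols].reset_index(drop=True),
                        values=logm.values[:, cols], scale="log")
    with pytest.raises(up.UropepError,
                       match=p["panel"].peptide_ids[0]):
        p["model"].decision_scores(sub, logm.sample_ids)


def test_all_undetected_sample_scores_at_floor(trained):
    p = trained
    model = p["model"]
    logm = p["log"]
    values = logm.values.copy()
    cols = logm.column_index(model.peptide_ids)
    values[0, cols] = -np.inf  # erase the panel in one sample
    blank = PeptideMatrix(sample_ids=logm.sample_ids, features=logm.features,
                          values=values, scale="log")
    score_blank = model.decision_scores(blank, [logm.sample_ids[0]])[0]
    # reference: feature vector sitting exactly on the censoring floor
    x_floor = ((model.floors - model.means) / model.sds)[None, :]
    expected = model._kernel_matrix(x_floor) @ model.dual_coef + model.intercept
    assert score_blank == pytest.approx(expected[0], abs=1e-12)


def test_linear_kernel_monotone_in_up_regulated_feature():
    matrix, samples, split = _toy_problem([4.0, 5.0, 6.0, 7.0],
                                          [1.0, 2.0, 2.5, 3.0])
    model = up.train_svm(matrix, samples, split, peptide_ids=["PX"],
                         directions=["up_in_sig"], kernel="linear")
    # weight of an up-in-cases feature is positive: score rises with intensity
    w = model.dual_coef @ model.support_vectors
    assert w[0] > 0
    base = model.features(matrix, [split.discovery_ids[0]]).copy()
    bumped = base + np.array([[1.0]])
    s0 = model._kernel_matrix(base) @ model.dual_coef + model.intercept
    s1 = model._kernel_matrix(bumped) @ model.dual_coef + model.intercept
    assert s1[0] > s0[0]


def test_linear_kernel_sign_symmetry():
    """Flipping a standardised feature's sign flips its learned weight."""
    matrix, samples, split = _toy_problem([4.0, 5.0, 6.0, 7.0],
                                          [1.0, 2.0, 2.5, 3.0])
    model = up.train_svm(matrix, samples, split, peptide_ids=["PX"],
                         kernel="linear")
    flipped_vals = matrix.values.copy()
    flipped_vals[:, 0] = -flipped_vals[:, 0] + 8.0  # affine flip on log scale
    flipped = PeptideMatrix(sample_ids=matrix.sample_ids,
                            features=matrix.features, values=flipped_vals,
                            scale="log")
    model_f = up.train_svm(flipped, samples, split, peptide_ids=["PX"],
                           kernel="linear")
    w = (model.dual_coef @ model.support_vectors)[0]
    w_f = (model_f.dual_coef @ model_f.support_vectors)[0]
    assert np.sign(w) == -np.sign(w_f)
    assert abs(abs(w) - abs(w_f)) < 1e-9


def test_select_cutoff_matches_exhaustive_scan():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=60)
    outcomes = rng.random(60) < 0.4
    outcomes[0], outcomes[1] = True, False  # both classes guaranteed
    cutoff = select_cutoff(scores, outcomes, criterion="youden")

    def youden(c):
        sens = (scores[outcomes] >= c).mean()
        spec = (scores[~outcomes] < c).mean()
        return sens + spec - 1

    grid = np.concatenate([scores - 1e-9, scores + 1e-9])
    assert youden(cutoff) == pytest.approx(max(youden(c) for c in grid),
                                           abs=1e-12)


def test_select_cutoff_perfect_separation_midpoint():
    scores = np.array([1.0, 2.0, 5.0, 6.0])
    outcomes = np.array([False, False, True, True])
    cutoff = select_cutoff(scores, outcomes)
    sens = (scores[outcomes] >= cutoff).mean()
    spec = (scores[~outcomes] < cutoff).mean()
    assert sens == 1.0 and spec == 1.0
    assert 2.0 < cutoff < 5.0


def test_target_sensitivity_cutoff():
    scores = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    outcomes = np.array([False, False, True, True, True])
    c = select_cutoff(scores, outcomes, criterion="target_sensitivity",
                      target_sensitivity=1.0)
    assert c <= scores[outcomes].min()
    with pytest.raises(up.UropepError):
        select_cutoff(np.array([0.0, 1.0]), np.array([True, False]),
                      criterion="target_sensitivity", target_sensitivity=2.0)


def test_grid_search_stays_inside_discovery(small_pipeline):
    """The optional (C, gamma) search tunes by discovery-set CV only and
    still yields a deterministic, working model."""
    p = small_pipeline
    m1 = up.train_svm(p["log"], p["samples"], p["split"], panel=p["panel"],
                      grid_search=True)
    m2 = up.train_svm(p["log"], p["samples"], p["split"], panel=p["panel"],
                      grid_search=True)
    assert m1.to_dict() == m2.to_dict()
    scores = m1.decision_scores(p["log"], p["split"].discovery_ids)
    y = p["samples"].outcome_bool(p["split"].discovery_ids)
    assert up.auc_mann_whitney(scores, y) > 0.9


def test_calibration_monotone(trained):
    model = trained["model"]
    s = np.linspace(-3, 3, 50)
    probs = model.probabilities(s)
    assert (np.diff(probs) >= 0).all()
    assert ((probs > 0) & (probs < 1)).all()


def test_no_information_leak_from_validation(trained):
    """Permuting validation outcomes leaves model and panel bit-identical."""
    p = trained
    df = p["samples"].df.copy()
    rng = np.random.default_rng(1)
    val_mask = df["sample_id"].isin(p["split"].validation_ids)
    perm = rng.permutation(df.loc[val_mask, "gleason_stratum"].to_numpy())
    df.loc[val_mask, "gleason_stratum"] = perm
    df = df.drop(columns="outcome")
    permuted = SampleTable(df)

    panel2 = up.discover_panel(p["log"], permuted, p["split"], seed=11)
    pd.testing.assert_frame_equal(panel2.members, p["panel"].members)
    model2 = up.train_svm(p["log"], permuted, p["split"], panel=panel2)
    assert model2.to_dict() == p["model"].to_dict()
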