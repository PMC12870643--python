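"""Methylation risk scores: splitting, selection, pruning, scoring, eval."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methewas.mrs import (
    MrsError,
    MrsModel,
    compute_mrs,
    evaluate_mrs,
    evaluate_mrs_auc,
    prune_comethylated,
    select_sites,
    split_cohort,
    threshold_ladder,
    threshold_sweep,
)


# -- split --------------------------------------------------------------


def test_split_is_75_25_disjoint_exhaustive():
    ids = [f"s{i}" for i in range(100)]
    pheno = np.array([1] * 30 + [0] * 70)
    disc, valid = split_cohort(ids, pheno, seed=0)
    assert len(disc) == 75 and len(valid) == 25
    assert set(disc) | set(valid) == set(ids)
    assert not set(disc) & set(valid)


def test_split_reproducible_under_seed():
    ids = [f"s{i}" for i in range(60)]
    pheno = np.tile([0, 1], 30)
    assert split_cohort(ids, pheno, seed=5) == split_cohort(ids, pheno, seed=5)
    assert split_cohort(ids, pheno, seed=5) != split_cohort(ids, pheno, seed=6)


def test_stratified_split_preserves_case_fraction():
    ids = [f"s{i}" for i in range(200)]
    pheno = np.array([1] * 40 + [0] * 160)
    disc, valid = split_cohort(ids, pheno, seed=1, stratify_by_phenotype=True)
    lookup = dict(zip(ids, pheno))
    n_case_disc = sum(lookup[i] for i in disc)
    assert abs(n_case_disc - 0.75 * 40) <= 1
    assert len(disc) == 150


def test_split_single_class_validation_rejected():
    ids = [f"s{i}" for i in range(8)]
    pheno = np.array([1, 1, 0, 0, 0, 0, 0, 0])
    with pytest.raises(MrsError, match="fewer than 2"):
        split_cohort(ids, pheno, seed=3)


# -- ladder and selection ------------------------------------------------


def test_threshold_ladder_spec():
    ladder = threshold_ladder()
    assert len(ladder) == 9
    assert ladder[0] == 0.005
    assert ladder[-1] == 5e-11
    for a, b in zip(ladder, ladder[1:]):
        assert a / b == pytest.approx(10.0)


def test_select_sites_threshold_boundaries():
    tab = pd.DataFrame(
        {"coefficient": [0.01, -0.02, 0.03], "p": [0.004, 0.006, 0.001]},
        index=["a", "b", "c"],
    )
    sel = select_sites(tab, 0.005)
    assert list(sel.index) == ["c", "a"]  # ascending p; 0.006 excluded
    assert len(select_sites(tab, 0.9999)) == 3


def test_select_sites_matches_brute_force():
    rng = np.random.default_rng(2)
    tab = pd.DataFrame(
        {"coefficient": rng.normal(size=20), "p": rng.random(20)},
        index=[f"cg{i}" for i in range(20)],
    )
    sel = select_sites(tab, 0.4)
    expected = sorted(
        [i for i in tab.index if tab.loc[i, "p"] < 0.4], key=lambda i: (tab.loc[i, "p"], i)
    )
    assert list(sel.index) == expected
    assert (sel["weight"] == tab.loc[sel.index, "coefficient"]).all()


# -- pruning -------------------------------------------------------------


def make_beta(X, prefix="cg"):
    return pd.DataFrame(
        X, index=[f"{prefix}{i}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(X.shape[1])],
    )


def test_prune_hand_example_keeps_first_and_third():
    rng = np.random.default_rng(3)
    n = 400
    z = rng.normal(size=n)
    x1 = z + rng.normal(0, 1.2, n)          # corr(x1, x2) ~ 0.5
    x2 = z + rng.normal(0, 1.2, n)
    x3 = rng.normal(size=n)                  # independent
    beta = make_beta(np.vstack([x1, x2, x3]))
    r12 = np.corrcoef(x1, x2)[0, 1]
    assert r12 > 0.3
    kept = prune_comethylated(beta, ["cg0", "cg1", "cg2"], r_cutoff=0.3)
    assert kept == ["cg0", "cg2"]


def test_prune_keeps_all_when_below_cutoff():
    rng = np.random.default_rng(4)
    beta = make_beta(rng.normal(size=(5, 500)))
    cands = [f"cg{i}" for i in range(5)]
    assert prune_comethylated(beta, cands, r_cutoff=0.3) == cands


def test_prune_duplicated_probe_keeps_lower_p_copy():
    rng = np.random.default_rng(5)
    x = rng.normal(size=50)
    beta = make_beta(np.vstack([x, x]))
    assert prune_comethylated(beta, ["cg0", "cg1"]) == ["cg0"]


def greedy_oracle(corr, r_cutoff=0.3):
    """Independent re-implementation on a precomputed correlation matrix."""
    kept = []
    for i in range(corr.shape[0]):
        if all(abs(corr[i, j]) <= r_cutoff for j in kept):
            kept.append(i)
    return kept


def test_prune_matches_independent_oracle_on_random_instances():
    rng = np.random.default_rng(6)
    for _ in range(100):
        k = int(rng.integers(2, 13))
        n = 60
        # random correlation structure via random loadings on shared factors
        L = rng.normal(size=(k, 3))
        X = L @ rng.normal(size=(3, n)) + rng.normal(0, 1, (k, n))
        beta = make_beta(X)
        cands = [f"cg{i}" for i in range(k)]
        kept = prune_comethylated(beta, cands, r_cutoff=0.3)
        corr = np.corrcoef(X)
        expected = [cands[i] for i in greedy_oracle(corr)]
        assert kept == expected


def test_pruned_set_has_no_pair_above_cutoff():
    rng = np.random.default_rng(7)
    L = rng.normal(size=(30, 2))
    X = L @ rng.normal(size=(2, 100)) + rng.normal(0, 0.5, (30, 100))
    beta = make_beta(X)
    kept = prune_comethylated(beta, [f"cg{i}" for i in range(30)], r_cutoff=0.3)
    sub = beta.loc[kept].to_numpy()
    corr = np.corrcoef(sub)
    off = np.abs(corr[np.triu_indices(len(kept), 1)])
    assert (off <= 0.3 + 1e-12).all()


def test_prune_missing_probe_rejected():
    beta = make_beta(np.zeros((2, 10)))
    with pytest.raises(MrsError, match="missing"):
        prune_comethylated(beta, ["cg0", "nope"])


# -- scoring -------------------------------------------------------------


def model_of(weights: dict, thr=0.005):
    return MrsModel(thr, pd.DataFrame({"weight": pd.Series(weights)}), 0.3)


def test_score_single_site_arithmetic():
    beta = make_beta(np.array([[0.5]]))
    scores = compute_mrs(beta, model_of({"cg0": -0.0123}))
    assert scores.iloc[0] == pytest.approx(-0.00615)


def test_score_matches_hand_computed_sums():
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 1, (5, 4))
    beta = make_beta(X)
    w = {"cg0": 0.1, "cg1": -0.2, "cg2": 0.05, "cg3": 0.0123, "cg4": -0.5}
    scores = compute_mrs(beta, model_of(w))
    for j, sid in enumerate(beta.columns):
        expected = sum(w[f"cg{i}"] * X[i, j] for i in range(5))
        assert abs(scores[sid] - expected) < 1e-12


@settings(derandomize=True, max_examples=30)
@given(scale=st.floats(-5, 5, allow_nan=False))
def test_score_linearity_in_weights(scale):
    rng = np.random.default_rng(9)
    X = rng.uniform(0, 1, (3, 6))
    beta = make_beta(X)
    w = {"cg0": 0.2, "cg1": -0.1, "cg2": 0.05}
    base = compute_mrs(beta, model_of(w))
    if scale == 0:
        return  # zero weights are rejected by the model contract
    scaled = compute_mrs(beta, model_of({k: v * scale for k, v in w.items()}))
    np.testing.assert_allclose(scaled, base * scale, atol=1e-12)


def test_score_refuses_missing_probes():
    beta = make_beta(np.zeros((1, 3)))
    with pytest.raises(MrsError, match="missing"):
        compute_mrs(beta, model_of({"cg0": 0.1, "gone": 0.2}))


def test_model_file_round_trip(tmp_path):
    model = model_of({"cg0": -0.012, "cg1": 0.3}, thr=5e-8)
    path = tmp_path / "model.tsv"
    model.write(path)
    back = MrsModel.read(path)
    assert back.p_threshold == model.p_threshold
    pd.testing.assert_frame_equal(back.sites, model.sites)


# -- evaluation ----------------------------------------------------------


def test_perfect_scores_give_r2_one():
    y = np.array([0, 1] * 20)
    ev = evaluate_mrs(y.astype(float), y, n_bootstrap=200, seed=0)
    assert ev.r2 == pytest.approx(1.0)
    assert ev.lb95 == pytest.approx(1.0) and ev.ub95 == pytest.approx(1.0)


def test_unrelated_scores_give_near_zero_r2():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, 10_000)
    s = rng.normal(size=10_000)
    ev = evaluate_mrs(s, y, n_bootstrap=100, seed=1)
    assert ev.r2 < 0.001


def test_constant_scores_warn_and_return_zero():
    with pytest.warns(UserWarning, match="constant"):
        ev = evaluate_mrs(np.ones(50), np.tile([0, 1], 25))
    assert ev.r2 == 0.0


def test_single_class_evaluation_rejected():
    with pytest.raises(MrsError, match="single class"):
        evaluate_mrs(np.arange(10.0), np.ones(10))


def test_auc_enumeration_example():
    assert evaluate_mrs_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)


def test_auc_perfect_separation():
    assert evaluate_mrs_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)


def test_auc_ties_counted_half():
    assert evaluate_mrs_auc([1.0, 1.0], [0, 1]) == pytest.approx(0.5)


def test_auc_matches_mann_whitney_identity():
    rng = np.random.default_rng(11)
    s = rng.normal(size=200)
    y = rng.integers(0, 2, 200)
    cases, controls = s[y == 1], s[y == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    expected = wins / (len(cases) * len(controls))
    assert evaluate_mrs_auc(s, y) == pytest.approx(expected)


# -- sweep ---------------------------------------------------------------


def test_sweep_shapes_and_monotonicity(signal_dataset):
    ds = signal_dataset
    from methewas.ewas import run_ewas

    ids = list(ds.beta.columns)
    disc, valid = ids[:150], ids[150:]
    res = run_ewas(ds.beta[disc], ds.samples.loc[disc], ["age", "sex"], apply_bacon=False)
    sweep = threshold_sweep(
        res, ds.beta[disc], ds.beta[valid],
        ds.samples.loc[valid, "phenotype"].to_numpy(),
        n_bootstrap=100, seed=0,
    )
    assert len(sweep) == 9
    assert (sweep["n_independent"] <= sweep["n_sites"]).all()
    empty = sweep[sweep["n_sites"] == 0]
    assert empty["lm_R_square"].isna().all()


def test_sweep_prunes_planted_comethylation_blocks(signal_dataset):
    """High-correlation blocks must shrink the independent site count."""
    ds = signal_dataset
    pt = ds.truth.probe_truth
    block_ids = pt.index[pt["block_id"] >= 0].tolist()
    fake = pd.DataFrame(
        {"coefficient": 0.01, "p": 1e-4}, index=block_ids
    )
    sweep = threshold_sweep(
        fake, ds.beta, ds.beta, ds.samples["phenotype"].to_numpy(),
        ladder=[0.005], n_bootstrap=50, seed=0,
    )
    assert sweep.loc[0, "n_independent"] < sweep.loc[0, "n_sites"]
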