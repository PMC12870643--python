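"""Per-CpG regression, inflation diagnostics, PC covariates, variants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methewas.ewas import (
    EwasError,
    compute_lambda,
    compute_methylation_pcs,
    compute_technical_pcs,
    ews_threshold,
    never_smoker_ewas,
    run_ewas,
    sensitivity_ewas,
    significant_sites,
)


def make_cohort(n=40, m=12, seed=0, n_cov=3):
    rng = np.random.default_rng(seed)
    sids = [f"s{i}" for i in range(n)]
    beta = pd.DataFrame(
        rng.uniform(0.2, 0.8, (m, n)), index=[f"cg{i}" for i in range(m)], columns=sids
    )
    samples = pd.DataFrame({"phenotype": rng.integers(0, 2, n)}, index=sids)
    while samples["phenotype"].nunique() < 2 or samples["phenotype"].value_counts().min() < 2:
        samples["phenotype"] = rng.integers(0, 2, n)
    for j in range(n_cov):
        samples[f"x{j}"] = rng.normal(size=n)
    return beta, samples


def normal_equations_oracle(y, X):
    """From-scratch OLS: coefficient and SE of the second design column."""
    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ b
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    return b[1], se


def test_coefficients_match_normal_equations_oracle():
    beta, samples = make_cohort(n=50, m=20, seed=1, n_cov=5)
    covs = [f"x{j}" for j in range(5)]
    res = run_ewas(beta, samples, covs, apply_bacon=False)
    X = np.column_stack(
        [np.ones(50), samples["phenotype"], samples[covs].to_numpy()]
    )
    for pid in beta.index:
        coef, se = normal_equations_oracle(beta.loc[pid].to_numpy(), X)
        assert abs(res.table.loc[pid, "coefficient"] - coef) < 1e-8
        assert abs(res.table.loc[pid, "se"] - se) < 1e-8


def test_pvalues_match_t_distribution():
    beta, samples = make_cohort(n=30, m=5, seed=2, n_cov=2)
    res = run_ewas(beta, samples, ["x0", "x1"], apply_bacon=False)
    dof = 30 - 4
    expect = 2 * stats.t.sf(np.abs(res.table["t"]), dof)
    np.testing.assert_allclose(res.table["p"], expect, rtol=1e-12)


def test_single_class_phenotype_rejected():
    beta, samples = make_cohort()
    samples["phenotype"] = 1
    with pytest.raises(EwasError, match="single class"):
        run_ewas(beta, samples, [])


def test_collinear_covariates_named():
    beta, samples = make_cohort()
    samples["dup"] = samples["x0"] * 2.0
    with pytest.raises(EwasError, match="dup"):
        run_ewas(beta, samples, ["x0", "dup"])


def test_missing_covariate_rows_dropped_and_counted():
    beta, samples = make_cohort(n=40)
    samples.loc[samples.index[:5], "x0"] = np.nan
    res = run_ewas(beta, samples, ["x0"], apply_bacon=False)
    assert res.dropped_missing == 5
    assert res.n_samples == 35


def test_orthogonal_covariate_barely_moves_coefficients():
    beta, samples = make_cohort(n=60, m=15, seed=3, n_cov=1)
    # orthogonalize x0 against phenotype and every probe's methylation
    pheno = samples["phenotype"].to_numpy().astype(float)
    basis = np.column_stack([np.ones(60), pheno, beta.to_numpy().T])
    q, _ = np.linalg.qr(basis)
    x = np.random.default_rng(4).normal(size=60)
    samples["x0"] = x - q @ (q.T @ x)
    res0 = run_ewas(beta, samples, [], apply_bacon=False)
    res1 = run_ewas(beta, samples, ["x0"], apply_bacon=False)
    diff = (res0.table["coefficient"] - res1.table["coefficient"]).abs()
    assert diff.max() < 1e-6


# -- lambda -------------------------------------------------------------


def test_lambda_is_one_for_constant_half_pvalues():
    assert compute_lambda(np.full(101, 0.5)) == pytest.approx(1.0)


def test_lambda_scale_equivariance():
    rng = np.random.default_rng(5)
    chi = stats.chi2.rvs(1, size=200_000, random_state=rng)
    p_inflated = stats.chi2.sf(2 * chi, 1)
    assert compute_lambda(p_inflated) == pytest.approx(2.0, rel=0.02)


def test_lambda_near_one_for_uniform_pvalues():
    rng = np.random.default_rng(6)
    assert compute_lambda(rng.random(100_000)) == pytest.approx(1.0, abs=0.02)


def test_lambda_rejects_zero_pvalues():
    with pytest.raises(EwasError, match="smallest representable"):
        compute_lambda([0.5, 0.0])


# -- principal-component covariates -------------------------------------


def test_technical_pc1_separates_pure_scanner_shifts():
    n_probes, n_per = 50, 10
    shift = np.zeros((n_probes, 2 * n_per))
    shift[:, n_per:] = 1.0  # scanner B mean shift, no noise
    controls = pd.DataFrame(
        5.0 + shift,
        index=[f"c{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(2 * n_per)],
    )
    pcs = compute_technical_pcs(controls, k=1)
    a, b = pcs.iloc[:n_per, 0], pcs.iloc[n_per:, 0]
    assert max(a.max(), b.max()) < min(b.min(), a.min()) or a.max() < b.min()


def test_technical_pcs_deterministic_sign_convention():
    rng = np.random.default_rng(7)
    controls = pd.DataFrame(
        rng.normal(10, 1, (30, 20)),
        index=[f"c{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(20)],
    )
    a = compute_technical_pcs(controls, k=3)
    b = compute_technical_pcs(controls.copy(), k=3)
    pd.testing.assert_frame_equal(a, b)


def test_constant_control_matrix_rejected():
    controls = pd.DataFrame(np.full((10, 8), 3.0))
    with pytest.raises(EwasError, match="zero variance"):
        compute_technical_pcs(controls, k=2)


def test_technical_pcs_k_too_large_rejected():
    controls = pd.DataFrame(np.random.default_rng(8).normal(size=(5, 4)))
    with pytest.raises(EwasError, match="too large"):
        compute_technical_pcs(controls, k=4)


def test_methylation_pc1_separates_planted_clusters():
    rng = np.random.default_rng(9)
    m, n = 200, 40
    beta = rng.uniform(0.3, 0.7, (m, n))
    beta[:10, n // 2 :] += 0.25  # 5% of probes differ between clusters
    df = pd.DataFrame(beta, index=[f"cg{i}" for i in range(m)],
                      columns=[f"s{j}" for j in range(n)])
    pcs = compute_methylation_pcs(df, k=1, n_top_var=50)
    left, right = pcs.iloc[: n // 2, 0], pcs.iloc[n // 2 :, 0]
    assert left.max() < right.min() or right.max() < left.min()


def test_methylation_pcs_k_zero_gives_empty_block():
    beta, _ = make_cohort()
    assert compute_methylation_pcs(beta, k=0).shape == (beta.shape[1], 0)


# -- significance and variants -------------------------------------------


def test_significant_sites_equals_brute_force_filter():
    beta, samples = make_cohort(n=50, m=30, seed=10)
    res = run_ewas(beta, samples, [], apply_bacon=False)
    alpha = 0.3
    hits = significant_sites(res, alpha=alpha)
    expected = sorted(
        [p for p in res.table.index if res.table.loc[p, "p"] < alpha],
        key=lambda p: res.table.loc[p, "p"],
    )
    assert list(hits.index) == expected
    assert len(significant_sites(res, alpha=1.0)) == 30


def test_default_ews_threshold_matches_850k_bonferroni():
    assert ews_threshold(850_000) == pytest.approx(5.88e-08, rel=0.002)


def test_sensitivity_matches_primary_without_confounders():
    from methewas import SimulationConfig, generate_dataset

    cfg = SimulationConfig(
        n_samples=800, n_probes=200, n_cases=240, n_causal=20,
        causal_effect_range=(0.02, 0.05), n_smoking_probes=0, n_bmi_probes=0,
        confounding_strength=0.0, markers_per_type=5,
        covariate_missing_rate=0.0, seed=19,
    )
    ds = generate_dataset(cfg)
    res_p = run_ewas(ds.beta, ds.samples, ["age", "sex"], apply_bacon=False)
    res_s = sensitivity_ewas(
        ds.beta, ds.samples, covariates=["age", "sex"], min_cases=10, apply_bacon=False
    )
    r = np.corrcoef(res_p.table["coefficient"], res_s.table["coefficient"])[0, 1]
    assert r > 0.99


def test_never_smoker_scan_restricts_samples(signal_dataset):
    ds = signal_dataset
    res = never_smoker_ewas(
        ds.beta, ds.samples, covariates=["age"], min_cases=2, apply_bacon=False
    )
    n_never = int((ds.samples["smoking"] == 0).sum())
    assert res.n_samples <= n_never
    with pytest.raises(EwasError, match="never-smoker"):
        never_smoker_ewas(ds.beta, ds.samples, covariates=[], min_cases=10_000)
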