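"""Per-CpG covariate-adjusted association testing.

Beta values (methylation fractions) are regressed probe-by-probe on a
binary phenotype plus covariates by ordinary least squares; the
phenotype coefficient is the case-control methylation difference on the
beta scale. The regression is solved once for all probes through the
shared design matrix (the per-probe fits differ only in the response),
which keeps genome-scale runs fast while remaining numerically identical
to fitting each probe separately.

The module also provides genomic-inflation diagnostics (lambda),
empirical-null adjustment of the z-scores (see :mod:`methewas.bacon`),
principal-component covariate construction from control probes or from
the methylation matrix itself, and the sensitivity (smoking + BMI
covariates) and never-smoker restricted variants of the main scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bacon import BaconFit, bacon_adjust, bacon_fit

logger = logging.getLogger(__name__)

#: Epigenome-wide significance threshold for a full EPIC-array scan
#: (0.05 Bonferroni-corrected for ~850k probes).
EWS_ALPHA = 5.88e-08


class EwasError(ValueError):
    pass


def ews_threshold(n_probes: int, family_alpha: float = 0.05) -> float:
    """Bonferroni-style array-wide threshold 0.05 / n_probes."""
    if n_probes <= 0:
        raise EwasError("n_probes must be positive")
    return family_alpha / n_probes


@dataclass
class EwasResult:
    """Per-probe association statistics plus run-level diagnostics.

    ``table`` columns: coefficient, se, t, p, z, z_bacon, p_bacon
    (indexed by probe id). ``lambda_`` is the genomic inflation factor of
    the raw p-values.
    """

    table: pd.DataFrame
    lambda_: float
    n_samples: int
    n_cases: int
    covariates: list[str]
    bacon: BaconFit | None = None
    dropped_missing: int = 0
    extra: dict = field(default_factory=dict)

    def significant(self, alpha: float = EWS_ALPHA, use_adjusted: bool = False) -> pd.DataFrame:
        return significant_sites(self, alpha=alpha, use_adjusted=use_adjusted)


def _fix_pc_signs(scores: np.ndarray, loadings: np.ndarray):
    """Make the largest-magnitude loading of each component positive."""
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def _pca_scores(X: np.ndarray, k: int) -> np.ndarray:
    """First k PC scores of the rows of X (features centred)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise EwasError("matrix has zero variance; principal components undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12))
    if k > rank:
        raise EwasError(f"requested {k} components but matrix rank is {rank}")
    scores = U[:, :k] * S[:k]
    scores, _ = _fix_pc_signs(scores, Vt[:k].T.copy())
    return scores


def compute_technical_pcs(controls: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """PC scores per sample from a control-probe intensity matrix.

    ``controls`` is probes x samples; samples are the observations. The
    leading components capture scanner/batch structure when control
    intensities carry batch shifts. Sign convention: the
    largest-magnitude probe loading of each component is positive.
    """
    if k == 0:
        return pd.DataFrame(index=controls.columns)
    if k >= min(controls.shape):
        raise EwasError(f"k={k} too large for a {controls.shape} control matrix")
    scores = _pca_scores(controls.to_numpy(dtype=float).T, k)
    return pd.DataFrame(
        scores, index=controls.columns, columns=[f"tpc{i+1}" for i in range(k)]
    )


def compute_methylation_pcs(
    beta: pd.DataFrame, k: int, n_top_var: int = 20000
) -> pd.DataFrame:
    """PC scores per sample from the most variable methylation probes."""
    if k == 0:
        return pd.DataFrame(index=beta.columns)
    if k >= beta.shape[1]:
        raise EwasError(f"k={k} too large for {beta.shape[1]} samples")
    var = beta.var(axis=1)
    top = var.nlargest(min(n_top_var, len(var))).index
    scores = _pca_scores(beta.loc[top].to_numpy(dtype=float).T, k)
    return pd.DataFrame(
        scores, index=beta.columns, columns=[f"mpc{i+1}" for i in range(k)]
    )


def _build_design(samples: pd.DataFrame, covariates: list[str], phenotype_col: str):
    """Intercept + phenotype + covariates; categoricals dummy-coded."""
    cols = [pd.Series(1.0, index=samples.index, name="intercept")]
    pheno = samples[phenotype_col].astype(float)
    cols.append(pheno.rename("phenotype"))
    for c in covariates:
        if c not in samples.columns:
            raise EwasError(f"covariate '{c}' missing from sample table")
        col = samples[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            cols.extend(dummies[d] for d in dummies.columns)
        else:
            cols.append(col.astype(float))
    X = pd.concat(cols, axis=1)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    _, R = np.linalg.qr(A / norms)
    diag = np.abs(np.diag(R))
    bad = np.where(diag < 1e-8)[0]
    if bad.size:
        names = [X.columns[i] for i in bad]
        raise EwasError(
            f"collinear covariates: {names} are linearly dependent on the "
            "preceding design columns"
        )


def run_ewas(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    phenotype_col: str = "phenotype",
    apply_bacon: bool = True,
    bacon_seed: int = 0,
) -> EwasResult:
    """Regress every probe's beta values on phenotype + covariates.

    Rows (samples) with missing values in the phenotype or any selected
    covariate are dropped with a logged count. Requires at least two
    samples in each phenotype class.

    Returns an :class:`EwasResult` whose coefficient column is the
    case-control beta-value difference per probe, with raw t-based
    p-values, probit-scale z-scores, and (when ``apply_bacon``) empirical
    -null-adjusted z and p.
    """
    covariates = list(covariates or [])
    common = [s for s in beta.columns if s in samples.index]
    if len(common) < len(beta.columns):
        logger.info("dropping %d samples absent from sample table", len(beta.columns) - len(common))
    samp = samples.loc[common]
    needed = [phenotype_col] + [c for c in covariates if c in samp.columns]
    missing_cov = [c for c in covariates if c not in samp.columns]
    if missing_cov:
        raise EwasError(f"covariates missing from sample table: {missing_cov}")
    keep = samp[needed].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("complete-case filter dropped %d samples with missing covariates", dropped)
    samp = samp.loc[keep]
    if samp.shape[0] < 3:
        raise EwasError("too few complete-case samples")
    pheno = samp[phenotype_col]
    classes = pheno.value_counts()
    if len(classes) < 2:
        raise EwasError("phenotype has a single class; association is undefined")
    if classes.min() < 2:
        raise EwasError("need at least 2 samples per phenotype class")

    X = _build_design(samp, covariates, phenotype_col)
    _check_full_rank(X)
    Xm = X.to_numpy(dtype=float)
    Y = beta.loc[:, samp.index].to_numpy(dtype=float).T  # samples x probes
    n, p = Xm.shape
    if n <= p:
        raise EwasError(f"design has {p} columns but only {n} samples")

    XtX = Xm.T @ Xm
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (Xm.T @ Y)  # p x m coefficient matrix
    resid = Y - Xm @ B
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    coef = B[1]  # phenotype column
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    se = np.where(se == 0, np.nan, se)
    tstat = coef / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    # probit-scale z keeps the tail information of the t distribution
    z = np.sign(tstat) * stats.norm.isf(pval / 2.0)

    table = pd.DataFrame(
        {"coefficient": coef, "se": se, "t": tstat, "p": pval, "z": z},
        index=beta.index,
    )
    lam = compute_lambda(table["p"].to_numpy())

    fit = None
    if apply_bacon:
        fit = bacon_fit(table["z"].to_numpy(), seed=bacon_seed)
        z_adj, p_adj = bacon_adjust(table["z"].to_numpy(), fit)
        table["z_bacon"] = z_adj
        table["p_bacon"] = p_adj
    else:
        table["z_bacon"] = np.nan
        table["p_bacon"] = np.nan

    return EwasResult(
        table=table,
        lambda_=lam,
        n_samples=int(n),
        n_cases=int((pheno == 1).sum()),
        covariates=X.columns.tolist()[2:],
        bacon=fit,
        dropped_missing=dropped,
    )


def compute_lambda(pvalues) -> float:
    """Genomic inflation factor: median chi-square over the null median.

    The p-values are converted to 1-df chi-square quantiles; the ratio of
    their median to the theoretical null median (~0.4549) is 1 for a
    well-calibrated null scan.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise EwasError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise EwasError(
            "p-values must lie in (0, 1]; replace exact zeros with the "
            "smallest representable value upstream"
        )
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def significant_sites(
    result: EwasResult, alpha: float = EWS_ALPHA, use_adjusted: bool = False
) -> pd.DataFrame:
    """Probes with p < alpha, sorted ascending by the chosen p-value."""
    col = "p_bacon" if use_adjusted else "p"
    tab = result.table
    hits = tab[tab[col] < alpha]
    return hits.sort_values(col, kind="mergesort")


def sensitivity_ewas(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    extra_covariates: tuple[str, ...] = ("smoking", "bmi"),
    min_cases: int = 50,
    **kwargs,
) -> EwasResult:
    """Main scan with smoking and BMI added as covariates.

    Samples missing the extra covariates are dropped (complete-case); an
    error is raised when fewer than ``min_cases`` cases remain.
    """
    covs = list(covariates or []) + [c for c in extra_covariates if c not in (covariates or [])]
    pheno_col = kwargs.get("phenotype_col", "phenotype")
    complete = samples.dropna(subset=[c for c in extra_covariates if c in samples.columns])
    n_cases = int((complete[pheno_col] == 1).sum())
    if n_cases < min_cases:
        raise EwasError(
            f"only {n_cases} cases with complete smoking/BMI data (minimum {min_cases})"
        )
    return run_ewas(beta, samples, covariates=covs, **kwargs)


def never_smoker_ewas(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    smoking_col: str = "smoking",
    never_value: float = 0,
    min_cases: int = 50,
    **kwargs,
) -> EwasResult:
    """Main scan restricted to never-smokers (smoking category 0)."""
    sub = samples[samples[smoking_col] == never_value]
    pheno_col = kwargs.get("phenotype_col", "phenotype")
    n_cases = int((sub[pheno_col] == 1).sum())
    if n_cases < min_cases:
        raise EwasError(f"only {n_cases} never-smoker cases (minimum {min_cases})")
    keep = [s for s in beta.columns if s in sub.index]
    return run_ewas(beta[keep], sub, covariates=covariates, **kwargs)


def result_to_frame(result: EwasResult, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Summary-statistics table with fixed column names for TSV export.

    Columns: probe_id, chrom, pos, gene, coefficient, SE, z, p, z_bacon,
    p_bacon (chrom/pos/gene blank when no annotation is supplied).
    """
    tab = result.table
    out = pd.DataFrame(index=tab.index)
    if annotation is not None:
        ann = annotation.reindex(tab.index)
        out["chrom"] = ann["chrom"]
        out["pos"] = ann["pos"]
        out["gene"] = ann["gene"].fillna("")
    else:
        out["chrom"] = ""
        out["pos"] = ""
        out["gene"] = ""
    out["coefficient"] = tab["coefficient"]
    out["SE"] = tab["se"]
    out["z"] = tab["z"]
    out["p"] = tab["p"]
    out["z_bacon"] = tab["z_bacon"]
    out["p_bacon"] = tab["p_bacon"]
    out.index.name = "probe_id"
    return out
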