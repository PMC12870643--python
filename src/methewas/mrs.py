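"""Clumping-and-correlation methylation risk scores.

Analogous to pruning-and-thresholding polygenic scores: CpG sites are
selected from discovery summary statistics below each p-value threshold
of a nine-step ladder (0.005 down to 5e-11 by factors of ten),
co-methylated sites are greedily pruned so that no retained pair
correlates above ``r_cutoff`` (0.3) in the discovery beta values, and a
sample's score is the weighted sum of its beta values at the surviving
sites, with the discovery regression coefficients as weights.

Evaluation regresses the binary phenotype on the score (linear
probability model, matching common MRS reporting), with a nonparametric
bootstrap CI for R-squared, and computes the rank-based AUC for external
cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

DEFAULT_R_CUTOFF = 0.3
DISCOVERY_FRACTION = 0.75


class MrsError(ValueError):
    pass


@dataclass
class MrsModel:
    """Selected CpG sites with discovery weights at one p threshold."""

    p_threshold: float
    sites: pd.DataFrame  # index probe_id, column 'weight'
    r_cutoff: float = DEFAULT_R_CUTOFF
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise MrsError("p_threshold must lie in (0, 1)")
        self.sites.index.name = "probe_id"
        if self.sites.index.duplicated().any():
            raise MrsError("duplicate probes in MRS model")
        w = self.sites["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise MrsError("MRS weights must be finite")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# p_threshold={self.p_threshold!r}\n")
            fh.write(f"# r_cutoff={self.r_cutoff!r}\n")
            fh.write(f"# provenance={self.provenance}\n")
            self.sites.to_csv(fh, sep="\t", index_label="probe_id")

    @classmethod
    def read(cls, path) -> "MrsModel":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
            else:
                body.append(line)
        from io import StringIO

        sites = pd.read_csv(StringIO("".join(body)), sep="\t", index_col="probe_id")
        return cls(
            p_threshold=float(meta.get("p_threshold", "0.05")),
            sites=sites,
            r_cutoff=float(meta.get("r_cutoff", DEFAULT_R_CUTOFF)),
            provenance=meta.get("provenance", ""),
        )


@dataclass
class MrsEvaluation:
    """Score-phenotype association metrics (one ladder row)."""

    n_sites: int
    n_independent: int
    r2: float
    lb95: float
    ub95: float
    lm_beta: float
    lm_se: float
    lm_pval: float
    auc: float | None = None
    p_threshold: float | None = None
    extra: dict = field(default_factory=dict)


def split_cohort(
    sample_ids,
    phenotype=None,
    discovery_fraction: float = DISCOVERY_FRACTION,
    seed: int = 0,
    stratify_by_phenotype: bool = False,
):
    """Random discovery/validation partition (discovery = floor(f*n)).

    With ``stratify_by_phenotype`` the case fraction is preserved within
    each class to within one sample. Raises when either partition ends
    up with fewer than two cases or two controls (phenotype required for
    the check and for stratification).
    """
    ids = np.asarray(list(sample_ids))
    rng = np.random.default_rng(seed)
    if stratify_by_phenotype:
        if phenotype is None:
            raise MrsError("stratified split requires the phenotype")
        pheno = np.asarray(phenotype)
        disc_mask = np.zeros(len(ids), dtype=bool)
        for cls_val in np.unique(pheno):
            idx = np.where(pheno == cls_val)[0]
            perm = rng.permutation(idx)
            n_disc = int(np.floor(discovery_fraction * len(idx)))
            disc_mask[perm[:n_disc]] = True
        discovery = ids[disc_mask]
        validation = ids[~disc_mask]
    else:
        perm = rng.permutation(len(ids))
        n_disc = int(np.floor(discovery_fraction * len(ids)))
        discovery = ids[perm[:n_disc]]
        validation = ids[perm[n_disc:]]
    if phenotype is not None:
        lookup = dict(zip(ids, np.asarray(phenotype)))
        for name, part in (("discovery", discovery), ("validation", validation)):
            vals = np.array([lookup[i] for i in part])
            if (vals == 1).sum() < 2 or (vals == 0).sum() < 2:
                raise MrsError(f"{name} partition has fewer than 2 cases or 2 controls")
    return list(discovery), list(validation)


def threshold_ladder() -> list[float]:
    """The nine selection thresholds, 0.005 down to 5e-11 by tens."""
    return [5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8, 5e-9, 5e-10, 5e-11]


def select_sites(discovery_result, threshold: float, use_adjusted: bool = False) -> pd.DataFrame:
    """Probes below the threshold with their discovery coefficients.

    Returns a DataFrame (index probe_id, columns weight, p) sorted by
    ascending p, ties broken lexicographically by probe id. Empty
    selections are allowed.
    """
    tab = discovery_result.table if hasattr(discovery_result, "table") else discovery_result
    col = "p_bacon" if use_adjusted else "p"
    sel = tab[tab[col] < threshold]
    sel = sel.sort_index().sort_values(col, kind="mergesort")
    out = pd.DataFrame({"weight": sel["coefficient"], "p": sel[col]})
    if out.empty:
        warnings.warn(f"no probes pass p < {threshold}", stacklevel=2)
    return out


def prune_comethylated(
    beta_discovery: pd.DataFrame,
    candidates,
    r_cutoff: float = DEFAULT_R_CUTOFF,
    use_absolute: bool = True,
) -> list[str]:
    """Greedy co-methylation clumping over p-ordered candidates.

    Walk the candidates in the supplied (ascending-p) order; keep a
    probe iff its Pearson correlation across the discovery samples with
    every already-kept probe does not exceed ``r_cutoff`` (absolute
    correlation by default — negatively co-methylated pairs are just as
    redundant). The output preserves walk order, so no retained pair
    correlates above the cutoff.
    """
    candidates = list(candidates)
    missing = [p for p in candidates if p not in beta_discovery.index]
    if missing:
        raise MrsError(f"candidate probes missing from beta matrix: {missing[:5]}")
    if not candidates:
        return []
    X = beta_discovery.loc[candidates].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    # constant probes: define correlation with anything as 0
    safe = np.where(norms > 0, norms, 1.0)
    Z = Xc / safe[:, None]
    Z[norms == 0] = 0.0

    kept_idx: list[int] = []
    for i in range(len(candidates)):
        if kept_idx:
            r = Z[kept_idx] @ Z[i]
            if use_absolute:
                r = np.abs(r)
            if np.any(r > r_cutoff):
                continue
        kept_idx.append(i)
    return [candidates[i] for i in kept_idx]


def compute_mrs(beta: pd.DataFrame, model: MrsModel) -> pd.Series:
    """Per-sample weighted sum of beta values at the model's sites.

    Refuses (listing them) when any model probe is absent from the
    matrix — scores are never silently imputed.
    """
    probes = model.sites.index
    missing = [p for p in probes if p not in beta.index]
    if missing:
        raise MrsError(f"model probes missing from beta matrix: {missing[:5]}")
    w = model.sites["weight"].to_numpy(dtype=float)
    scores = w @ beta.loc[probes].to_numpy(dtype=float)
    return pd.Series(scores, index=beta.columns, name="mrs")


def _bootstrap_r2(scores: np.ndarray, pheno: np.ndarray, n_bootstrap: int, seed: int):
    """Percentile bootstrap of the squared score-phenotype correlation."""
    rng = np.random.default_rng(seed)
    n = scores.size
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    s = scores[idx]
    y = pheno[idx]
    s = s - s.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    num = (s * y).sum(axis=1)
    den = np.sqrt((s**2).sum(axis=1) * (y**2).sum(axis=1))
    r2 = np.zeros(n_bootstrap)
    ok = den > 0
    r2[ok] = (num[ok] / den[ok]) ** 2
    return float(np.quantile(r2, 0.025)), float(np.quantile(r2, 0.975))


def evaluate_mrs(
    scores,
    phenotype,
    n_bootstrap: int = 1000,
    seed: int = 0,
    n_sites: int | None = None,
    n_independent: int | None = None,
) -> MrsEvaluation:
    """Linear-model association between score and binary phenotype.

    Fits phenotype ~ score by OLS (linear probability model) and reports
    R-squared with a seeded nonparametric bootstrap 95% CI, plus the
    slope, its SE and two-sided p-value.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if s.size != y.size:
        raise MrsError("scores and phenotype lengths differ")
    if len(np.unique(y)) < 2:
        raise MrsError("phenotype has a single class")
    if np.std(s) == 0:
        warnings.warn("constant scores; association is undefined (r2 set to 0)", stacklevel=2)
        return MrsEvaluation(
            n_sites=n_sites or 0, n_independent=n_independent or 0,
            r2=0.0, lb95=0.0, ub95=0.0, lm_beta=0.0, lm_se=np.nan, lm_pval=1.0,
        )
    X = sm.add_constant(s)
    fit = sm.OLS(y, X).fit()
    lb, ub = _bootstrap_r2(s, y, n_bootstrap, seed)
    return MrsEvaluation(
        n_sites=n_sites if n_sites is not None else -1,
        n_independent=n_independent if n_independent is not None else -1,
        r2=float(fit.rsquared),
        lb95=lb,
        ub95=ub,
        lm_beta=float(fit.params[1]),
        lm_se=float(fit.bse[1]),
        lm_pval=float(fit.pvalues[1]),
    )


def evaluate_mrs_auc(scores, phenotype) -> float:
    """Probability a random case outscores a random control (ties half)."""
    y = np.asarray(phenotype, dtype=float)
    if len(np.unique(y)) < 2:
        raise MrsError("phenotype has a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def threshold_sweep(
    discovery_result,
    beta_discovery: pd.DataFrame,
    beta_validation: pd.DataFrame,
    phenotype_validation,
    ladder: list[float] | None = None,
    r_cutoff: float = DEFAULT_R_CUTOFF,
    use_absolute: bool = True,
    n_bootstrap: int = 1000,
    seed: int = 0,
    compute_auc: bool = False,
) -> pd.DataFrame:
    """One MRS per ladder threshold, evaluated in the validation samples.

    Returns a table shaped like standard MRS-prediction reports:
    p_threshold, n_sites (pre-pruning), n_independent (post-pruning),
    lm_R_square with bootstrap bounds, slope, SE and p-value.
    """
    ladder = ladder or threshold_ladder()
    rows = []
    for thr in ladder:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_sites(discovery_result, thr)
        n_sites = len(sel)
        if n_sites == 0:
            rows.append(
                MrsEvaluation(0, 0, np.nan, np.nan, np.nan, np.nan, np.nan,
                              np.nan, p_threshold=thr)
            )
            continue
        kept = prune_comethylated(beta_discovery, sel.index.tolist(), r_cutoff, use_absolute)
        model = MrsModel(
            p_threshold=thr,
            sites=sel.loc[kept, ["weight"]],
            r_cutoff=r_cutoff,
        )
        scores = compute_mrs(beta_validation, model)
        ev = evaluate_mrs(
            scores.to_numpy(), phenotype_validation, n_bootstrap=n_bootstrap,
            seed=seed, n_sites=n_sites, n_independent=len(kept),
        )
        ev.p_threshold = thr
        if compute_auc:
            ev.auc = evaluate_mrs_auc(scores.to_numpy(), phenotype_validation)
        rows.append(ev)
    return pd.DataFrame(
        {
            "p_threshold": [r.p_threshold for r in rows],
            "n_sites": [r.n_sites for r in rows],
            "n_independent": [r.n_independent for r in rows],
            "lm_R_square": [r.r2 for r in rows],
            "lb95_R2": [r.lb95 for r in rows],
            "ub95_R2": [r.ub95 for r in rows],
            "lm_beta": [r.lm_beta for r in rows],
            "lm_SE": [r.lm_se for r in rows],
            "lm_pval": [r.lm_pval for r in rows],
            **({"auc": [r.auc for r in rows]} if compute_auc else {}),
        }
    )
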