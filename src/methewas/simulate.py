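"""Synthetic EPIC-style blood methylation datasets with known truth.

The generator emulates the statistical structure a blood EWAS pipeline
has to cope with, so that every downstream stage is testable without any
restricted data:

* each sample's beta profile is a cell-fraction-weighted mixture of
  cell-type reference profiles (fractions Dirichlet-distributed around
  realistic whole-blood proportions, neutrophil-dominant);
* planted case-control effects on the beta scale (magnitudes of a few
  thousandths to a few hundredths, the range reported for blood EWAS of
  psychiatric phenotypes), mostly hypomethylating in cases;
* smoking-driven probes whose methylation tracks a three-level smoking
  category (never/former/current scored 0/1/2) that is itself correlated
  with case status at a configurable strength — the confounding
  structure sensitivity analyses exist for;
* BMI-, age-, sex- and scanner-batch-driven probes;
* blockwise co-methylation (shared per-sample factors within probe
  blocks) for the risk-score pruning step;
* detection p-values near zero except for random probe x sample
  failures drawn uniform on (0.05, 1];
* a control-probe intensity matrix carrying scanner mean shifts, so
  technical principal components genuinely capture batch.

All randomness flows from a single integer seed through named
sub-streams; identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import ProbeAnnotation
from .deconv import ReferencePanel
from . import io as mio

BLOOD_CELL_TYPES = ("CD8T", "CD4T", "NK", "B", "Mono", "Neu")
BLOOD_PROPORTIONS = (0.08, 0.16, 0.07, 0.05, 0.09, 0.55)


class SimulationConfigError(ValueError):
    """Invalid or infeasible simulation configuration; names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults describe a desk-scale cohort with the case prevalence,
    effect magnitudes, smoking distribution and covariate-missingness
    rate of a large veteran blood-methylation study, scaled to 500
    samples x 5000 probes.
    """

    n_samples: int = 500
    n_probes: int = 5000
    n_cases: int | None = None  # default: 6.2% prevalence
    n_causal: int = 10
    causal_effect_range: tuple[float, float] = (0.003, 0.023)
    causal_hypo_fraction: float = 0.75
    n_smoking_probes: int = 20
    smoking_effect_range: tuple[float, float] = (0.01, 0.03)
    smoking_hypo_fraction: float = 0.7
    n_bmi_probes: int = 20
    bmi_effect_sd: float = 0.003
    confounding_strength: float = 0.1
    n_blocks: int = 10
    block_size: int = 5
    block_rho: float = 0.6
    n_cell_types: int = 6
    markers_per_type: int = 20
    scanner_count: int = 4
    detection_fail_rate: float = 0.002
    noise_sd: float = 0.05
    n_control_probes: int = 200
    covariate_missing_rate: float = 0.048
    n_ancestry_pcs: int = 20
    smoking_scores: tuple[float, float, float] = (0.0, 1.0, 2.0)  # never/former/current
    seed: int = 0

    @property
    def effective_n_cases(self) -> int:
        if self.n_cases is not None:
            return self.n_cases
        return max(2, round(0.062 * self.n_samples))

    def validate(self) -> None:
        c = self

        def bad(fieldname, msg):
            raise SimulationConfigError(f"{fieldname}: {msg}")

        if c.n_samples < 4:
            bad("n_samples", "need at least 4 samples")
        if c.n_probes < 1:
            bad("n_probes", "need at least 1 probe")
        if not 0 < self.effective_n_cases < c.n_samples:
            bad("n_cases", "must satisfy 0 < n_cases < n_samples")
        n_planted = c.n_causal + c.n_smoking_probes + c.n_bmi_probes
        n_reserved = (
            n_planted
            + c.n_blocks * c.block_size
            + c.n_cell_types * c.markers_per_type
        )
        if n_reserved > c.n_probes:
            bad(
                "n_probes",
                f"{n_reserved} probes needed for planted effects, blocks and "
                f"markers but only {c.n_probes} available",
            )
        for name, rng_ in (("causal_effect_range", c.causal_effect_range),
                           ("smoking_effect_range", c.smoking_effect_range)):
            lo, hi = rng_
            if not (0 <= lo <= hi):
                bad(name, "must be 0 <= low <= high")
            if hi > 0.5:
                bad(name, "effects above 0.5 push beta means outside [0, 1]")
        if c.smoking_effect_range[1] * max(c.smoking_scores) > 0.5:
            bad("smoking_effect_range", "effect x max category score exceeds 0.5")
        if not -1 <= c.confounding_strength <= 1:
            bad("confounding_strength", "must lie in [-1, 1]")
        for name, val in (("block_rho", c.block_rho),
                          ("detection_fail_rate", c.detection_fail_rate),
                          ("covariate_missing_rate", c.covariate_missing_rate),
                          ("causal_hypo_fraction", c.causal_hypo_fraction),
                          ("smoking_hypo_fraction", c.smoking_hypo_fraction)):
            if not 0 <= val <= 1:
                bad(name, "must lie in [0, 1]")
        if c.noise_sd < 0:
            bad("noise_sd", "must be non-negative")
        if c.n_cell_types < 2:
            bad("n_cell_types", "need at least 2 cell types")
        if c.scanner_count < 1:
            bad("scanner_count", "need at least 1 scanner")

    @property
    def cell_type_names(self) -> list[str]:
        if self.n_cell_types == len(BLOOD_CELL_TYPES):
            return list(BLOOD_CELL_TYPES)
        return [f"CT{i+1}" for i in range(self.n_cell_types)]


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic dataset.

    ``probe_truth``: per probe — true_effect (case-control beta
    difference), smoking_loading (per category step), bmi_loading,
    age_loading, sex_loading, block_id (-1 = none), is_marker.
    ``sample_truth``: per sample — phenotype, smoking_category, scanner,
    bmi, age, sex and the true cell fractions (simplex rows).
    ``reference`` holds the full cell-type reference beta profiles the
    mixtures were built from, so replication cohorts can reuse them.
    """

    probe_truth: pd.DataFrame
    sample_truth: pd.DataFrame
    reference: pd.DataFrame  # probes x cell types
    marker_probes: list[str]
    config: SimulationConfig


@dataclass
class SyntheticDataset:
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    control_probes: pd.DataFrame
    samples: pd.DataFrame
    annotation: ProbeAnnotation
    reference_panel: ReferencePanel
    truth: SyntheticTruth


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(n)]


def _build_probe_structure(config: SimulationConfig, rng: np.random.Generator):
    """Reference profiles, marker designation and per-probe loadings."""
    m, k = config.n_probes, config.n_cell_types

    # bimodal baseline typical of methylation arrays
    u = rng.random(m)
    base = np.where(
        u < 0.45, rng.beta(2, 8, m), np.where(u < 0.9, rng.beta(8, 2, m), rng.beta(2, 2, m))
    )
    base = np.clip(base, 0.02, 0.98)
    R = np.tile(base, (k, 1)).T  # probes x cell types

    # cell-type-informative probes get per-type deviations
    informative = rng.random(m) < 0.3
    R[informative] += rng.normal(0, 0.04, (informative.sum(), k))

    # markers: strongly discriminating probes, one group per cell type,
    # drawn from the non-informative pool and excluded from planted effects
    pool = np.where(~informative)[0]
    pool = rng.permutation(pool)
    n_mark = config.markers_per_type * k
    marker_idx = pool[:n_mark]
    pool = pool[n_mark:]
    for t in range(k):
        idx = marker_idx[t * config.markers_per_type : (t + 1) * config.markers_per_type]
        R[idx] = 0.15 + rng.normal(0, 0.03, (len(idx), k))
        R[idx, t] = 0.85 + rng.normal(0, 0.03, len(idx))
    R = np.clip(R, 0.01, 0.99)

    # planted effect probes, disjoint from markers and from each other
    n_causal, n_smo, n_bmi = config.n_causal, config.n_smoking_probes, config.n_bmi_probes
    n_block = config.n_blocks * config.block_size
    need = n_causal + n_smo + n_bmi + n_block
    if need > len(pool):
        raise SimulationConfigError(
            "n_probes: not enough non-marker probes for planted effects and blocks"
        )
    causal_idx = pool[:n_causal]
    smoking_idx = pool[n_causal : n_causal + n_smo]
    bmi_idx = pool[n_causal + n_smo : n_causal + n_smo + n_bmi]
    block_idx = pool[n_causal + n_smo + n_bmi : need]

    true_effect = np.zeros(m)
    lo, hi = config.causal_effect_range
    mag = rng.uniform(lo, hi, n_causal)
    sign = np.where(rng.random(n_causal) < config.causal_hypo_fraction, -1.0, 1.0)
    true_effect[causal_idx] = mag * sign

    smoking_loading = np.zeros(m)
    lo, hi = config.smoking_effect_range
    mag = rng.uniform(lo, hi, n_smo)
    sign = np.where(rng.random(n_smo) < config.smoking_hypo_fraction, -1.0, 1.0)
    smoking_loading[smoking_idx] = mag * sign

    bmi_loading = np.zeros(m)
    bmi_loading[bmi_idx] = rng.normal(0, config.bmi_effect_sd, n_bmi)

    # mild age/sex structure on a fifth of probes (per SD of age; male shift)
    age_loading = np.where(rng.random(m) < 0.2, rng.normal(0, 0.002, m), 0.0)
    sex_loading = np.where(rng.random(m) < 0.2, rng.normal(0, 0.002, m), 0.0)

    block_id = np.full(m, -1)
    for b in range(config.n_blocks):
        block_id[block_idx[b * config.block_size : (b + 1) * config.block_size]] = b

    # scanner batch shifts: 5% of probes shift per scanner
    scanner_shift = np.zeros((config.scanner_count, m))
    batch_probes = rng.random(m) < 0.05
    scanner_shift[:, batch_probes] = rng.normal(
        0, 0.01, (config.scanner_count, int(batch_probes.sum()))
    )

    probe_truth = pd.DataFrame(
        {
            "true_effect": true_effect,
            "smoking_loading": smoking_loading,
            "bmi_loading": bmi_loading,
            "age_loading": age_loading,
            "sex_loading": sex_loading,
            "block_id": block_id,
            "is_marker": np.isin(np.arange(m), marker_idx),
        },
        index=_probe_ids(m),
    )
    return R, probe_truth, marker_idx, scanner_shift


def _simulate_samples(
    config: SimulationConfig,
    R: np.ndarray,
    probe_truth: pd.DataFrame,
    scanner_shift: np.ndarray,
    n_samples: int,
    n_cases: int,
    seed_seq: np.random.SeedSequence,
    attenuation: float = 1.0,
    sample_prefix: str = "S",
):
    """Draw a cohort against a fixed probe structure (shared by the main
    cohort and replication cohorts)."""
    rng_design, rng_frac, rng_noise, rng_det, rng_ctrl = (
        np.random.default_rng(s) for s in seed_seq.spawn(5)
    )
    n, m = n_samples, config.n_probes
    k = config.n_cell_types

    pheno = np.zeros(n)
    if n_cases > 0:
        pheno[rng_design.choice(n, n_cases, replace=False)] = 1.0
    sd_p = pheno.std()
    z_p = (pheno - pheno.mean()) / sd_p if sd_p > 0 else np.zeros(n)

    # smoking: latent correlated with case status, binned 25/50/25 into
    # never(25%) / former(50%) / current(25%)
    rho = config.confounding_strength
    latent = rho * z_p + np.sqrt(max(0.0, 1 - rho**2)) * rng_design.normal(size=n)
    q25, q75 = np.quantile(latent, [0.25, 0.75])
    smoking_cat = np.where(latent < q25, 0, np.where(latent < q75, 1, 2))
    smoking_score = np.asarray(config.smoking_scores)[smoking_cat]

    bmi = 29.2 + 4.5 * (0.17 * z_p + rng_design.normal(size=n))
    age = 67.8 - 6.7 * pheno + rng_design.normal(0, 9, n)
    sex = (rng_design.random(n) < (0.952 - 0.054 * pheno)).astype(float)
    scanner = rng_design.integers(config.scanner_count, size=n)
    pcs = rng_design.normal(size=(n, config.n_ancestry_pcs))

    if k == len(BLOOD_PROPORTIONS):
        props = np.asarray(BLOOD_PROPORTIONS)
    else:
        props = np.full(k, 1.0 / k)
    fractions = rng_frac.dirichlet(props * 60, size=n)

    beta = fractions @ R.T  # n x m
    beta += pheno[:, None] * (attenuation * probe_truth["true_effect"].to_numpy())[None, :]
    beta += smoking_score[:, None] * probe_truth["smoking_loading"].to_numpy()[None, :]
    beta += ((bmi - 29.2) / 4.5)[:, None] * probe_truth["bmi_loading"].to_numpy()[None, :]
    beta += ((age - 65.0) / 10.0)[:, None] * probe_truth["age_loading"].to_numpy()[None, :]
    beta += (sex - 0.9)[:, None] * probe_truth["sex_loading"].to_numpy()[None, :]
    beta += scanner_shift[scanner]

    # noise: shared per-sample factor within co-methylated blocks
    eps = rng_noise.normal(size=(n, m))
    block_id = probe_truth["block_id"].to_numpy()
    if config.n_blocks > 0 and config.block_rho > 0:
        u_block = rng_noise.normal(size=(n, config.n_blocks))
        in_block = block_id >= 0
        eps[:, in_block] = (
            np.sqrt(config.block_rho) * u_block[:, block_id[in_block]]
            + np.sqrt(1 - config.block_rho) * eps[:, in_block]
        )
    beta += config.noise_sd * eps
    beta = np.clip(beta, 0.0, 1.0)

    # detection p-values: near zero, random failures uniform on (0.05, 1]
    detp = rng_det.uniform(0, 1e-3, size=(n, m))
    fail = rng_det.random((n, m)) < config.detection_fail_rate
    detp[fail] = 1.0 - rng_det.uniform(0, 0.95, size=int(fail.sum()))

    # control probes: scanner mean shifts + noise on an intensity-like scale
    ctrl_base = rng_ctrl.normal(10, 1, config.n_control_probes)
    ctrl_scanner = rng_ctrl.normal(0, 0.5, (config.scanner_count, config.n_control_probes))
    controls = (
        ctrl_base[None, :]
        + ctrl_scanner[scanner]
        + rng_ctrl.normal(0, 0.1, (n, config.n_control_probes))
    )

    sids = _sample_ids(n, sample_prefix)
    pids = _probe_ids(m)

    smoking_obs = smoking_score.astype(float)
    bmi_obs = bmi.copy()
    if config.covariate_missing_rate > 0:
        miss = rng_design.random(n) < config.covariate_missing_rate
        smoking_obs[miss] = np.nan
        bmi_obs[miss] = np.nan

    samples = pd.DataFrame(
        {
            "phenotype": pheno.astype(int),
            "age": age,
            "sex": sex.astype(int),
            "smoking": smoking_obs,
            "bmi": bmi_obs,
            "scanner_id": [f"scanner_{s+1}" for s in scanner],
        },
        index=pd.Index(sids, name="sample_id"),
    )
    for j in range(config.n_ancestry_pcs):
        samples[f"pc{j+1}"] = pcs[:, j]

    sample_truth = pd.DataFrame(
        {
            "phenotype": pheno.astype(int),
            "smoking_category": smoking_cat,
            "scanner_id": [f"scanner_{s+1}" for s in scanner],
            "bmi": bmi,
            "age": age,
            "sex": sex.astype(int),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    for t, name in enumerate(config.cell_type_names):
        sample_truth[f"frac_{name}"] = fractions[:, t]

    pidx = pd.Index(pids, name="probe_id")
    beta_df = pd.DataFrame(beta.T, index=pidx, columns=sids)
    detp_df = pd.DataFrame(detp.T, index=pidx, columns=sids)
    ctrl_df = pd.DataFrame(
        controls.T,
        index=pd.Index([f"ctrl{i:05d}" for i in range(config.n_control_probes)], name="probe_id"),
        columns=sids,
    )
    return beta_df, detp_df, ctrl_df, samples, sample_truth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic dataset.

    Returns measurements (beta, detection p, control probes), the sample
    table with covariates, probe annotation, the cell-type reference
    panel at its marker probes, and the planted truth.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_probe, ss_samples, ss_manifest = root.spawn(3)

    rng_probe = np.random.default_rng(ss_probe)
    R, probe_truth, marker_idx, scanner_shift = _build_probe_structure(config, rng_probe)

    beta, detp, controls, samples, sample_truth = _simulate_samples(
        config, R, probe_truth, scanner_shift,
        config.n_samples, config.effective_n_cases, ss_samples,
    )

    pids = _probe_ids(config.n_probes)
    annotation = generate_manifest(
        config.n_probes,
        n_islands=max(config.n_probes // 50, 1),
        seed=int(ss_manifest.generate_state(1)[0] % (2**31)),
    )
    reference = pd.DataFrame(R, index=pids, columns=config.cell_type_names)
    panel = ReferencePanel(reference.iloc[np.sort(marker_idx)])
    truth = SyntheticTruth(
        probe_truth=probe_truth,
        sample_truth=sample_truth,
        reference=reference,
        marker_probes=reference.index[np.sort(marker_idx)].tolist(),
        config=config,
    )
    return SyntheticDataset(
        beta=beta,
        detection_p=detp,
        control_probes=controls,
        samples=samples,
        annotation=annotation,
        reference_panel=panel,
        truth=truth,
    )


def generate_replication_cohort(
    truth: SyntheticTruth,
    n_samples: int,
    n_cases: int,
    seed: int,
    attenuation: float = 1.0,
) -> SyntheticDataset:
    """Fresh samples against the same probe structure.

    The per-probe true effects and loadings are reused (optionally
    attenuated — 0 gives a cohort where the original signal is absent,
    emulating a failed external replication), while cell fractions,
    scanner assignment, noise and detection failures are drawn anew.
    """
    config = truth.config
    if list(truth.reference.index) != _probe_ids(config.n_probes):
        raise SimulationConfigError("truth probe set does not match its config")
    root = np.random.SeedSequence(seed)
    rng_scan = np.random.default_rng(root.spawn(1)[0])
    # a replication site has its own scanners
    m = config.n_probes
    scanner_shift = np.zeros((config.scanner_count, m))
    batch_probes = rng_scan.random(m) < 0.05
    scanner_shift[:, batch_probes] = rng_scan.normal(
        0, 0.01, (config.scanner_count, int(batch_probes.sum()))
    )
    cfg = replace(config, n_samples=n_samples, n_cases=n_cases)
    beta, detp, controls, samples, sample_truth = _simulate_samples(
        cfg, truth.reference.to_numpy(), truth.probe_truth, scanner_shift,
        n_samples, n_cases, root.spawn(2)[1], attenuation=attenuation,
        sample_prefix="R",
    )
    marker_idx = np.where(truth.probe_truth["is_marker"].to_numpy())[0]
    panel = ReferencePanel(truth.reference.iloc[marker_idx])
    new_probe_truth = truth.probe_truth.copy()
    new_probe_truth["true_effect"] *= attenuation
    annotation = generate_manifest(
        config.n_probes,
        n_islands=max(config.n_probes // 50, 1),
        seed=int(np.random.SeedSequence(config.seed).spawn(3)[2].generate_state(1)[0] % (2**31)),
    )
    return SyntheticDataset(
        beta=beta,
        detection_p=detp,
        control_probes=controls,
        samples=samples,
        annotation=annotation,
        reference_panel=panel,
        truth=SyntheticTruth(
            probe_truth=new_probe_truth,
            sample_truth=sample_truth,
            reference=truth.reference,
            marker_probes=truth.marker_probes,
            config=cfg,
        ),
    )


def generate_manifest(n_probes: int, n_islands: int, seed: int) -> ProbeAnnotation:
    """Synthetic probe annotation with CpG islands and gene symbols.

    Islands are placed on a spaced grid (so they never overlap and
    shore/shelf bands stay unambiguous); probes are distributed across
    island / shore / shelf / open-sea contexts. Positions are 1-based,
    islands half-open. Gene symbols come from a synthetic pool; a few
    probes carry two ';'-joined symbols.
    """
    if n_probes < 0 or n_islands < 0:
        raise SimulationConfigError("n_probes/n_islands: must be non-negative")
    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in range(1, 23)]

    islands: dict[str, list[tuple[int, int]]] = {}
    island_list = []
    for i in range(n_islands):
        chrom = chroms[i % 22]
        slot = i // 22
        start = 1_000_000 + slot * 100_000 + int(rng.integers(0, 50_000))
        length = int(rng.integers(300, 2000))
        islands.setdefault(chrom, []).append((start, start + length))
        island_list.append((chrom, start, start + length))

    pos = np.empty(n_probes, dtype=np.int64)
    chrom_col = np.empty(n_probes, dtype=object)
    cat = rng.random(n_probes)
    for j in range(n_probes):
        if n_islands > 0 and cat[j] < 0.45:
            chrom, s, e = island_list[int(rng.integers(n_islands))]
            if cat[j] < 0.15:  # inside
                p = int(rng.integers(s, e))
            elif cat[j] < 0.35:  # shore
                off = int(rng.integers(1, 2001))
                p = s - off if rng.random() < 0.5 else e - 1 + off
            else:  # shelf
                off = int(rng.integers(2001, 4001))
                p = s - off if rng.random() < 0.5 else e - 1 + off
            chrom_col[j] = chrom
            pos[j] = max(1, p)
        else:
            chrom_col[j] = chroms[int(rng.integers(22))]
            pos[j] = int(rng.integers(50_000_000, 200_000_000))

    n_genes = max(50, n_probes // 10)
    gene_pool = [f"GENE{i:05d}" for i in range(n_genes)]
    genes = []
    for j in range(n_probes):
        r = rng.random()
        if r < 0.05:
            a, b = rng.choice(n_genes, 2, replace=False)
            genes.append(f"{gene_pool[a]};{gene_pool[b]}")
        elif r < 0.65:
            genes.append(gene_pool[int(rng.integers(n_genes))])
        else:
            genes.append("")

    probes = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos, "gene": genes},
        index=pd.Index(_probe_ids(n_probes), name="probe_id"),
    )
    return ProbeAnnotation(probes, {c: np.asarray(v) for c, v in islands.items()})


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every component as TSV; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    mio.write_matrix(ds.beta, out / "beta.tsv")
    paths["beta"] = str(out / "beta.tsv")
    mio.write_matrix(ds.detection_p, out / "detection_p.tsv")
    paths["detection_p"] = str(out / "detection_p.tsv")
    mio.write_matrix(ds.control_probes, out / "control_probes.tsv")
    paths["control_probes"] = str(out / "control_probes.tsv")
    mio.write_sample_table(ds.samples, out / "samples.tsv")
    paths["samples"] = str(out / "samples.tsv")
    ds.annotation.write(out / "annotation.tsv")
    paths["annotation"] = str(out / "annotation.tsv")
    ds.reference_panel.write(out / "reference_panel.tsv")
    paths["reference_panel"] = str(out / "reference_panel.tsv")
    ds.truth.probe_truth.to_csv(out / "truth_probes.tsv", sep="\t", index_label="probe_id")
    paths["truth_probes"] = str(out / "truth_probes.tsv")
    mio.write_sample_table(ds.truth.sample_truth, out / "truth_samples.tsv")
    paths["truth_samples"] = str(out / "truth_samples.tsv")
    return paths
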