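# methewas

An end-to-end pipeline for array-based epigenome-wide association
studies (EWAS) of a binary phenotype in whole-blood DNA methylation,
together with a *clumping-and-correlation* methylation risk score (MRS).
It is aimed at researchers analysing Illumina-style beta-value matrices
(methylation fractions in [0, 1], probes × samples) who need the full
chain — quality control, cell-type deconvolution, covariate-adjusted
per-CpG regression, inflation diagnostics and empirical-null correction,
sensitivity analyses, annotation, risk scoring and enrichment — as
tested, reusable library code rather than a one-off script.

Because real cohort data of this kind is typically access-restricted,
the package ships a first-class synthetic-data generator that emulates
the statistical structure of blood methylation arrays (cell-composition
mixtures, smoking/BMI/batch-driven probes, co-methylated blocks,
detection failures) with fully known planted truth, so every stage is
testable end to end.

## What it computes

**Per-CpG association.** For each probe *j*, ordinary least squares on
the beta scale:

    beta_ij = b0 + b1 * case_i + covariates_i * g + e_ij

where `case_i` is 0/1 and covariates follow standard blood-EWAS
practice: age, sex, scanner id, estimated cell-type fractions, ancestry
PCs, and technical PCs computed from control-probe intensities. `b1` is
the case−control methylation difference; two-sided p-values come from
the t statistic.

**Calibration diagnostics.** The genomic inflation factor
λ = median(χ²_obs) / median(χ²_null) of the p-value vector, and an
empirical-null correction that models the genome-wide z-scores as a
three-component Gaussian mixture (dominant null N(μ₀, σ₀²) plus
negative- and positive-signal components), fit by Gibbs sampling.
Adjusted statistics are z' = (z − μ₀)/σ₀, removing systematic bias and
inflation.

**Cell deconvolution.** Houseman-style constrained projection: each
sample's marker-probe betas are projected onto sorted-cell reference
profiles under f ≥ 0, Σf ≤ 1.

**Methylation risk score.** On a 75/25 discovery/validation split:
select sites with discovery p below each threshold of the ladder
{5e-3, …, 5e-11}, greedily prune any site correlating |r| > 0.3 with an
already-kept site (keeping the lower-p member, as in LD clumping), and
score samples as the weighted sum Σ w_j β_ij with discovery coefficients
as weights. Evaluation reports the linear-model R² (with bootstrap 95%
CI), slope, SE, p, and the rank-based AUC for external cohorts.

## Worked example

```python
from methewas import *
from methewas.ewas import compute_technical_pcs, run_ewas, significant_sites
from methewas.mrs import split_cohort, threshold_sweep

cfg = SimulationConfig(
    n_samples=1000, n_probes=3000, n_cases=300,
    n_causal=8, causal_effect_range=(0.02, 0.04),
    n_smoking_probes=10, confounding_strength=0.2, seed=42,
)
ds = generate_dataset(cfg)

report = run_qc(ds.detection_p)              # probe then sample filters
beta = apply_qc(ds.beta, report)

fractions = estimate_fractions(beta, ds.reference_panel)
tech_pcs = compute_technical_pcs(ds.control_probes[beta.columns], k=5)
samples = ds.samples.loc[beta.columns].join(fractions).join(tech_pcs)

covariates = (["age", "sex", "scanner_id"] + list(fractions.columns)
              + [f"pc{i+1}" for i in range(10)] + list(tech_pcs.columns))
result = run_ewas(beta, samples, covariates, bacon_seed=42)
hits = significant_sites(result, alpha=ews_threshold(beta.shape[0]))

disc, valid = split_cohort(samples.index, samples["phenotype"].to_numpy(), seed=42)
disc_res = run_ewas(beta[disc], samples.loc[disc], covariates, bacon_seed=43)
sweep = threshold_sweep(disc_res, beta[disc], beta[valid],
                        samples.loc[valid, "phenotype"].to_numpy(), seed=42)
```

Output:

```
QC: 3000 probes x 1000 samples retained
lambda = 1.036; bacon bias = 0.002, inflation = 0.996
8 array-wide significant sites (threshold 1.67e-05)
{'hypo': 5, 'hyper': 3, 'zero': 0}
 p_threshold  n_sites  n_independent  lm_R_square      lm_pval
5.000000e-03       24             24     0.236400 3.071647e-16
5.000000e-04        9              9     0.304879 2.365189e-21
...
5.000000e-11        3              3     0.293865 1.691374e-20
```

The scan is well calibrated (λ = 1.036, empirical-null bias ≈ 0,
inflation ≈ 1) and recovers the planted signal: 8 sites pass the
Bonferroni threshold 0.05/3000, and the risk score built from the
discovery split explains a substantial share of validation-set
phenotype variance at every ladder threshold (the planted effects here
are deliberately strong; real blood-methylation signals for psychiatric
phenotypes give R² nearer 0.02).

The same flow is scriptable from the shell:

```bash
methewas simulate --config sim.yaml --out data/
methewas qc --beta data/beta.tsv --detp data/detection_p.tsv --out qc/
methewas pipeline run --config pipeline.yaml --out run/
```

See `examples/pipeline.yaml` for a complete configuration.

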