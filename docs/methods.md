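# Methods

This note documents the statistical models, the numerical choices, and
the design decisions behind `methewas`, in the order the pipeline runs
them.

## Quality control

Inputs are a probes × samples detection p-value matrix (pOOBAH-style,
consumed as data — the package does not compute detection p-values,
which require raw out-of-band intensities) and an optional probe
blocklist standing in for cross-hybridisation / poor-mapping masks.

Two single-pass filters with strict inequalities:

* a probe is excluded when detp > 0.05 in **more than** 10% of samples;
* a sample is excluded when **less than** 96% of probes pass
  (detp < 0.05), with pass-rates computed on the probes that survived
  the probe filter.

Probe QC precedes sample QC and the pair is applied once; the suite
verifies the pair is idempotent and that the retained submatrix
violates neither rule under brute-force recount. Thresholds are
parameters with the defaults above.

## Cell-type deconvolution

Houseman-style constrained projection. For each sample with marker
betas y and reference profile matrix P (markers × cell types):

    minimise ||P f − y||²  subject to  f ≥ 0,  Σ f ≤ 1.

The sum constraint is an inequality (the reference panel never spans
all of whole blood exactly); an off-by-default flag renormalises to the
simplex. The solver is deterministic: non-negative least squares first,
then an SLSQP quadratic program only when the NNLS solution violates
the sum constraint; solutions satisfy the constraints to 1e-8.
Rank-deficient panels produce a warning and a flagged pseudo-solution.
The default synthetic panel uses six blood cell types (CD8T, CD4T, NK,
B, Mono, Neu) with designated marker probes; marker discovery is out of
scope — the panel is data.

## Per-CpG regression

Beta values are regressed directly (no M-value transform — effect sizes
stay on the interpretable methylation-fraction scale). The design
matrix is shared across probes, so the scan is solved once via the
normal equations for all probes simultaneously; this is numerically
identical to per-probe OLS and is tested against an independent
normal-equations solver to 1e-8. Complete-case analysis per run: rows
missing any selected covariate are dropped with a logged count.
Categorical covariates (scanner id) are dummy-coded; collinear designs
are rejected naming the dependent column. Two-sided p-values from the t
distribution; z-scores are obtained by probit-transforming the t-based
p-values (preserving tail accuracy at moderate sample sizes).

Covariates follow blood-EWAS practice: age, sex, scanner, estimated
cell fractions, ancestry PCs (consumed from the sample table; a
methylation-PC alternative is provided), and technical PCs computed
from the control-probe matrix. PCA uses exact SVD with a deterministic
sign convention (largest-magnitude loading positive).

The array-wide ("epigenome-wide significant", EWS) threshold is
0.05/n_probes; the constant 5.88e-08 — the conventional value for a
~850k-probe array — is the default where a fixed threshold is wanted,
and both forms are selectable.

### Inflation diagnostics and empirical null

λ = median(χ²(p))/0.4549 on the raw p-vector. Exact-zero p-values are
rejected with advice to substitute the smallest representable value
upstream.

The empirical-null correction models z-scores as a three-component
Gaussian mixture: a dominant null N(μ₀, σ₀²) and two signal components
truncated to the negative/positive half-lines. Estimation is by Gibbs
sampling with conjugate priors:

* weights ~ Dirichlet(90, 2, 2) — the null dominates a priori;
* means: μ₀ ~ N(0, 1); signal means ~ N(∓4, 4) truncated at 0, placing
  signal in the tails so it does not absorb the null's shoulders;
* variances ~ inverse-gamma(2, 1).

1500 iterations, 500 burn-in, posterior means as point estimates, all
seeded. Adjusted z = (z − μ₀)/σ₀ with two-sided normal p. On 50,000
scores with true bias 0.1, inflation 1.2 and 1% signal at |z| ≈ 4, the
sampler recovers both parameters within ±0.05 and restores λ ≈ 1; on
pure-null input it returns bias ≈ 0, inflation ≈ 1. Inputs below 1000
scores trigger a warning (the empirical null is weakly identified).

### Sensitivity and never-smoker variants

The sensitivity scan adds smoking (ordinal 0/1/2 = never/former/
current) and BMI to the covariates, on the complete-case subset; the
never-smoker scan restricts to smoking category 0. Both refuse to run
below a configurable minimum case count (default 50). Smoking-driven,
case-correlated probes reach array-wide significance in the primary
scan and lose it under the sensitivity covariates, while genuinely
causal probes retain it — the package's acceptance suite checks exactly
this signature.

## Annotation

Positions are 1-based; CpG islands are half-open intervals on the same
coordinates (BED input is converted on read). Shore = within 2 kb of an
island edge, shelf = the next 2 kb, open sea beyond — the widths are
the field's convention and are parameters. Gene mapping splits
';'-joined symbols, deduplicates, and keeps first-occurrence order.
Direction summaries count hypo- (coefficient < 0) and hyper-methylated
sites, with zero coefficients reported separately.

## Methylation risk score

* **Split:** discovery = floor(0.75 n) samples, seeded; optional
  phenotype stratification (off by default). Partitions with fewer than
  2 cases or controls on either side are refused.
* **Ladder:** {5e-3 … 5e-11}, factors of ten, nine thresholds.
* **Selection:** discovery p < threshold; candidates ordered by
  ascending p, ties broken lexicographically by probe id.
* **Pruning:** greedy walk in that order; a candidate is kept iff its
  absolute Pearson correlation (across discovery samples, raw betas)
  with every kept site is ≤ 0.3. Keeping the lower-p member of a
  correlated pair mirrors LD clumping; absolute correlation is the
  default because negative co-methylation is equally redundant (a flag
  restores signed r > 0.3). Constant probes correlate 0 by convention.
  The greedy rule is tested against an independent re-implementation
  on random instances.
* **Score:** Σ w_j β_ij with discovery coefficients as weights, no
  standardisation by default. Missing model probes are a refusal, never
  imputed, so a model trained on cohort A applies to cohort B only when
  B carries every site.
* **Evaluation:** OLS of the binary phenotype on the score (linear
  probability model, the common MRS reporting convention; a logistic
  route backs the AUC pathway). R² confidence bounds by seeded
  nonparametric bootstrap (1000 resamples, percentile method). AUC is
  the Mann–Whitney probability that a random case outscores a random
  control, ties counted half.

## Gene-set over-representation

One-sided hypergeometric tail per set against an explicit background
universe (default: all genes in the probe annotation — never an
implicit genome-wide constant), sets intersected with the background
first, Bonferroni over the number of sets tested. A relaxed selection
threshold (default 5e-05) expands the query gene list beyond the
array-wide hits. Gene sets are GMT files supplied by the user; no
collections are bundled.

## Synthetic data

The generator emulates what the pipeline must withstand, with defaults
describing a realistic blood-methylation cohort scaled to desk size
(500 samples × 5000 probes):

* **Mixtures:** per-probe baseline betas are bimodal; 30% of probes
  carry cell-type-specific deviations; each sample's profile is a
  Dirichlet-distributed (concentration 60, neutrophil-dominant
  proportions) mixture of the reference profiles. Marker probes are
  strongly discriminating (0.85 vs 0.15) and excluded from planted
  effects.
* **Case prevalence:** 6.2% by default, matching large biobank
  psychiatric phenotypes; configurable.
* **Planted case effects:** |δ| uniform on [0.003, 0.023] — the
  magnitude range reported for blood EWAS of psychiatric phenotypes —
  with 75% of effects hypomethylating in cases.
* **Smoking:** a latent score correlated with case status at the
  configured confounding strength is binned 25/50/25 into
  never/former/current (scored 0/1/2); smoking-driven probes shift per
  category step. Default confounding 0.1 (mild, as observed in real
  cohorts); the acceptance scenario uses 0.3.
* **Other structure:** BMI-, age- and sex-driven probes; scanner batch
  shifts on 5% of probes plus a control-probe matrix whose leading PCs
  genuinely capture scanner; co-methylated blocks via shared per-sample
  factors giving within-block correlation ≈ block_rho; detection
  failures at rate 0.002 drawn uniform on (0.05, 1]; smoking/BMI
  missing at 4.8%.
* **Noise:** Gaussian on the beta scale (sd 0.05) with final clamping
  to [0, 1] — the regression itself operates on betas, so the noise
  model matches the analysis scale.
* **Seeding:** one integer seed; named sub-streams per component;
  identical seeds give bit-identical datasets. Replication cohorts
  reuse the probe structure (optionally attenuating the true effects —
  attenuation 0 emulates a failed external replication) with fresh
  samples, noise and scanners.

What the generator does **not** emulate: probe-specific
heteroscedasticity and beta-distributed (rather than clamped-Gaussian)
measurement noise, realistic genomic autocorrelation beyond the
explicit blocks, genotype-driven methylation, age×phenotype
interactions, and any linkage to a real array manifest. Passing tests
therefore demonstrate the correctness and calibration of the
*machinery* under the assumed structure, not performance on any real
cohort.

## Problem sizes and defaults used in validation

The packaged checks run at sizes chosen to make the statistical
properties sharp while staying desk-scale: null calibration at
500 × 5000; empirical-null recovery on 50,000 z-scores; deconvolution
on 200 samples × 600 markers × 6 types at noise sd 0.02; confounding
attenuation at n = 2000 with 10 causal (δ ∈ [0.02, 0.03]) and 20
smoking-driven (loading ∈ [0.04, 0.06]) probes at confounding 0.3; MRS
calibration on 100 replicates of a 600-sample balanced cohort whose ten
planted ±0.0045 effects put the latent score–phenotype R² near 0.02,
with a 6000-sample signal-free replication cohort for the chance-level
AUC check.

## Known limitations

* The linear probability model for score evaluation is the reporting
  convention, not the best classifier; its R² is small-signal-friendly
  but heteroscedastic.
* The empirical-null sampler assumes signal lives in the tails; dense
  moderate signal (many probes at |z| ≈ 2) will be partially absorbed
  into the null component and under-corrected.
* Constrained projection assumes the reference panel's cell types span
  the sample; unmodelled cell types bias fractions toward the nearest
  modelled profile.
* QC operates purely on detection p-values; intensity-based filters
  (bead counts, control-probe failures) are out of scope.
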