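# Methods

## The analysis model

The pipeline targets a two-group exposure design measured on a
methylation array: a binary prenatal exposure X (e.g. maternal smoking),
per-CpG methylation beta values M_j ∈ [0, 1] in cord blood, and a
continuous outcome BW (birthweight, grams).

**EWAS.** For each retained probe j,

    M_j = α + βa_j · X + γ'C + ε,

where C collects sex, gestational age (weeks), maternal age (years),
pre-pregnancy BMI (kg/m²), education (0 = low/middle, 1 = university),
plate (treatment-coded dummies, first plate as reference) and the six
estimated leukocyte proportions.  Fitting is ordinary least squares,
vectorised across probes (one shared hat matrix, per-probe residual
variance), with two-sided Student-t inference on n − k degrees of
freedom.  An empirical-Bayes moderated variance (limma-style) would
shrink per-probe variances toward a common prior; at n ≈ 250 the
difference in p-values is negligible and ordinary t-tests are used
throughout — this is a known limitation at much smaller n.
Multiplicity: Benjamini–Hochberg step-up q-values over all tested
probes; the Bonferroni flag defaults to the community's fixed
genome-wide threshold p < 1e-7 (appropriate for ~465k-probe arrays),
with the exact 0.05/m bound reported alongside.  The unadjusted
exposed-minus-unexposed mean difference is reported next to the adjusted
coefficient because both are conventionally tabulated.

**Mediation.** For a candidate mediator CpG the three nested models

    (a)    M  = βa·X + γ'C
    (c)    BW = βc·X + δ'C
    (full) BW = βc'·X + βb·M + θ'C

are fitted by OLS **on the identical complete-case sample set**.  In
that setting βa·βb = βc − βc′ is an algebraic identity (product of
coefficients = difference of coefficients), and the code asserts it to
relative tolerance 1e-8 on every run — a violated identity always means
the models silently saw different rows, which is treated as an error
rather than a warning.  The proportion mediated is reported as
(βc − βc′)/βc ≡ (βa·βb)/((βa·βb) + βc′).  Inference on the indirect
effect is the classical Sobel test with a standard-normal reference,
SE = √(βa²SEb² + βb²SEa²); the test is known to be conservative, which
the suite checks as non-anticonservatism rather than exact size.
Baron–Kenny conditions (i)–(v) are reported as booleans alongside the
estimates rather than gating them.  Interaction diagnostics augment the
full model with one centred product term at a time (exposure×M, then
each covariate×M).

**Meta-analysis.** Fixed-effects inverse-variance pooling:
weights w_i = 1/SE_i², pooled SE = 1/√Σw_i, two-sided normal z-test.
When a cohort is available only as a printed (effect, two-sided p) pair,
its SE is recovered as |effect|/Φ⁻¹(1 − p/2); this recovery round-trips
exactly with the pooling z-test, and reproduces published
discovery-plus-replication tables to printed rounding.  Heterogeneity
(Cochran's Q) is available but optional; no random-effects model is
provided.  The confirmation rule for a replicated mediated effect is
two-sided p < 0.05 in both the replication meta and the joint meta.

## Quality control conventions

* A probe measurement is "called" when detection p **< 0.05** (strict
  inequality, so p = 0.05 exactly fails).
* Sample filter first: keep samples with call rate **≥ 99%** across
  probes.  Probe filter second, on the retained samples: keep non-control
  autosomal probes with call rate ≥ 99% across samples.  The alternative
  order (probe fractions over all samples) can be had by calling
  `filter_probes` before `filter_samples_by_detection`; the composed
  `apply_qc` fixes sample-first because sample exclusion is logically
  prior to probe summarisation.
* Missing covariates get single imputation — mean for continuous
  covariates, median for binary education — computed over the full sheet,
  with `<covariate>_imputed` provenance columns.  Which statistic applies
  to which covariate is configurable since conventions differ.
* Declared-sex-versus-intensity cluster checks require raw X-chromosome
  intensities and are out of scope; the sample sheet's sex column is
  taken at face value.

## Cell-type deconvolution

Per sample, proportions over the six reference types solve

    min ‖S_d w − m_d‖²  subject to  w ≥ 0,

where S_d is the signature matrix restricted to the k most
type-discriminating probes (largest between-type variance of the
reference rows; ties broken by probe order; k = 100 by default) and m_d
the sample's betas on those probes.  Nonnegativity is the only
constraint — no sum-to-one equality — matching the original
constrained-projection formulation; estimated proportions therefore sum
close to, but not exactly, 1, which keeps all six types usable together
as regression covariates without exact collinearity with the intercept.
(A `renormalize` flag rescales to unit sum for reporting.)  The solver is
deterministic active-set NNLS; a rank-deficient signature on the selected
probes raises an error naming the collinear cell types.  Note that a
*true* proportion matrix that sums to exactly 1 per sample (e.g. the
generator's truth record) must have one column dropped before being used
as covariates.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not the measurement chemistry (no IDATs, fluorescence intensities or
probe-type effects — these are explicit non-goals):

* **Cell-composition confounding.** Per-sample proportions are drawn from
  group-specific Dirichlet distributions; by default the exposed group is
  shifted toward granulocytes and away from T cells, so unadjusted and
  cell-adjusted EWAS results genuinely differ — the phenomenon that makes
  reference-based correction worth doing.
* **Baseline methylation** is `signature @ proportions`; exposed samples
  receive planted beta-scale shifts at designated CpGs (default lead
  effect −0.105, the magnitude of a strong smoking-associated CpG).
* **Noise** is additive Gaussian on the beta scale, clipped to [0, 1] —
  simpler than a logit-normal model and adequate at this scale; a
  clipping-rate record in the truth object guards against distortion
  (< 1% clipped at defaults, asserted in tests).  The default residual SD
  of 0.1 was chosen to match the per-probe standard errors implied by
  published EWAS/mediation tables at n ≈ 255 (SE of the CpG→outcome slope
  ≈ 280 g, SE of the exposure coefficient ≈ 0.014); with much smaller
  residual variance the mediator carries too little information for
  mediation SEs to resemble real cohorts.
* **Outcome.** `BW = intercept + βc'_true·X + Σ_j b_j·M_j(observed) +
  covariate effects + N(0, 420 g)`, with the intercept anchored so the
  unexposed mean is 3685 g.  Defaults: direct effect −143.3 g, lead
  mediator slope 1190 g per unit beta — together a total exposure effect
  of ≈ −268 g, about 47% mediated.  Covariate effects default to
  +130 g/gestational week, +120 g for males, +15 g per BMI unit; the
  outcome residual SD of 420 g reproduces a model-c R² near 0.3.
* **Covariate distributions** follow the motivating cohort's descriptive
  table: sex ≈ 53% male; gestational age 39.8 ± 1.2 vs 39.7 ± 1.3 weeks;
  maternal age 31.1 ± 3.6 vs 29.7 ± 4.7 years; BMI 23.9 ± 3.3 vs
  24.9 ± 5.1; university education 44% vs 19%; cigarettes/day for exposed
  mothers a discretised lognormal clipped to 1–30 with median 10.
  Replication-cohort covariate distributions are not published in detail;
  the same defaults are reused with different sizes and seeds, which is
  an acknowledged arbitrary choice.
* **Detection p-values** are Uniform(0, 0.01) with a configurable
  entry-level failure rate (p ~ Uniform(0.05, 1)) plus optional
  whole-sample failures (2% of that sample's probes fail, enough to break
  the 99% call-rate rule), so both QC filters are exercised.
* **Missingness** hits gestational age, BMI and education at
  `missing_covariate_rate` (default 2%, the order of magnitude seen in
  practice); the outcome is generated from the pre-masking values.
* **Determinism.** All randomness flows from one seed through
  `numpy.random.SeedSequence.spawn` into six named streams (proportions,
  probe noise, covariates, outcome, detection, missingness), so identical
  configs give bit-identical cohorts and adding a stream never perturbs
  the others.

What passing tests on this generator do **not** show: robustness to
probe-type chemistry and normalisation artefacts, non-Gaussian beta
distributions (bimodality at imprinted/polymorphic sites), batch
structure beyond plate labels, measurement error correlated across
probes, or reference panels mismatched to cord blood (the well-known
adult-reference limitation).  Conclusions about real cohorts still
require the usual sensitivity analyses.

## Numerical choices

* BH-FDR is a vectorised step-up (`running minimum of m·p_(j)/j from the
  largest rank`), capped at 1, stable under ties; verified to 1e-12
  against both a brute-force definitional oracle and
  `statsmodels.multipletests`.
* Zero-residual probe fits produce SE ≈ 0 and a p-value clamped to the
  smallest positive float rather than 0, so downstream −log10 transforms
  never overflow; all reported p-values live in (0, 1].
* Design matrices are checked for full column rank before fitting; a
  deficiency error lists the aliased columns (greedy rank scan), both in
  the EWAS design and in the mediation models.
* `se_from_p` refuses p outside (0, 1) and zero effects rather than
  returning infinities.
* Tie-break for discriminating-probe selection is input probe order
  (stable argsort on negated variance).
* Flat files are written with `%.17g` floats and read with pandas'
  round-trip parser, so write∘read is the identity for finite values.

## Pipeline and sizes

`run_pipeline` executes simulate (or load) → QC → deconvolution →
descriptives + EWAS (optionally with a no-cell-correction sensitivity
pass) → mediation → (optionally) replication cohorts and fixed-effects
meta, writing every intermediate table plus a manifest (seed, counts,
thresholds, SHA-256 of every output) sufficient to re-run
bit-identically.  Default problem sizes are desk-scale by design —
hundreds to thousands of probes and a few hundred samples — which is
ample for the statistical properties being demonstrated, since every
estimator here is probe-wise; genome-scale matrices change only runtime,
not behaviour.  The published genome-wide hit counts (35 FDR / 23
Bonferroni CpGs) depend on the unavailable cohort data and are therefore
not reproduction targets.
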