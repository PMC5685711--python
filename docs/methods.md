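# Methods

This document records the statistical model behind the synthetic cohorts,
the numerical choices made in the analysis machinery, and the limits of
both. The README covers usage; this covers *why the numbers are what they
are*.

## 1. Synthetic cohort model

All generators draw from `numpy.random.default_rng` with spawned substreams
`default_rng([seed, stream])` (stream 0: counts/expression noise, 1:
baseline abundances, 2: CA-125, 3: subtype assignment), so adding or
removing one output never reshuffles another and every byte of output is a
pure function of the seed.

### 1.1 Sequencing counts

Counts are negative binomial via the gamma–Poisson mixture: marker *i* in
sample *j* has mean μ_ij and variance μ_ij + α·μ_ij² with dispersion
α = `nb_dispersion` (default **0.3**, a typical miRNA-seq value; α < 1e-8
falls back to pure Poisson). Per-marker baseline abundances are log-normal
around `mean_count` (default **200** reads, log-SD 1), so libraries span a
realistic dynamic range. Group effects are multiplicative on the mean:
μ_ij = exp(base_i + δ_i,g(j)) with δ the planted natural-log shift.

**All-or-none markers** are structural zeros in every healthy sample and
ordinary NB draws (log-shift `allornone_shift`, default **1.5**) in cancer
samples — the pattern the sequencing screen's second selection rule looks
for. The count cohorts contain only healthy/early/advanced groups; benign
sera enter at the qRT-PCR stages only.

### 1.2 qRT-PCR expression

Expression is reported on the 2^ΔCt scale (ΔCt = Ct_reference −
Ct_target). Values are log-normal: exp(base_i + δ_i,g(j) + subtype shift +
ε), ε ~ N(0, `noise_sd`²) with default **noise_sd = 1.0** on the natural-log
scale. Baselines sit near 2⁻⁸ of the normalizer (log-SD 1.5), matching the
usual situation where miRNAs are orders of magnitude rarer than the
reference.

Under this model a single marker with log-shift δ has binormal
AUC = Φ(δ / (σ√2)); `experiments.binormal_shift` inverts this, which is how
effect sizes are calibrated (e.g. δ = √2·σ·Φ⁻¹(0.75) ≈ 0.954 for a
single-marker AUC of 0.75). The pipeline default `effect_size = 0.9`
(+0.3 in advanced disease) gives per-marker AUCs near 0.74/0.80 — strong
markers, but individually imperfect, so panels genuinely help.

All-or-none markers are *not* floored in expression: on the qRT-PCR scale
they behave as ordinary strongly shifted markers (undetermined-Ct handling
lives in `delta_ct_normalize`, which imputes NaN Ct at the instrument
maximum of 40 cycles).

### 1.3 CA-125 and subtypes

CA-125 (U/mL) is log-normal per diagnostic group: healthy ln 15 (σ 0.55),
benign ln 22 (σ 0.80), early-stage ln 35 (σ 1.00), advanced ln 250
(σ 1.10). The early-stage centre sits at the 35 U/mL clinical cut-off,
reproducing the marker's well-known weakness in stage I disease; benign
tumors overlap the healthy range enough to make early-vs-benign the hard
contrast, as in practice.

Cancer samples receive a histological subtype drawn with probabilities
112/155 serous, 11/155 mucinous, 13/155 endometrioid, 19/155 clear-cell — a
serous-dominated epithelial cohort. `subtype_effects` can plant
subtype-specific marker shifts for the one-vs-rest classifiers to find.

### 1.4 Default cohort sizes

63 healthy, 43 benign, 65 early-stage and 90 advanced sera (155 cancers),
40 miRNAs in the expression panels; the sequencing discovery cohorts are
scaled to 10% of those sizes (a handful of sera per group) and the
qRT-PCR trial cohort to `trial_fraction` (default 25%).

## 2. Numerical and algorithmic choices

**TMM normalization.** Factors are defined on the *absolute* scale: an
entry-wise doubled library gets a pre-centering factor twice as large, and
multiplying one library by c multiplies its factor by c exactly
(scale-equivariance). Trimming is rank-based — the top and bottom 30% of
M-values (log-ratios vs the reference sample) and 5% of A-values (average
log-abundances) are removed, with trim indices floor(n·trim)+1 … n −
floor(n·trim) — and zero-count markers are excluded pairwise. The default
trimmed mean is **unweighted**, which is what makes scale-equivariance
exact; `weighted=True` enables the delta-method inverse-variance weights
and reproduces edgeR's `calcNormFactors` after converting conventions
(f_abs = f_edgeR × library size, then re-centering to geometric mean 1),
which the test suite verifies to 1e-9 against frozen edgeR output. The
reference sample is the one whose 75th-percentile count fraction is closest
to the mean, as in edgeR.

**Mann–Whitney U.** U counts case–control pairs with a > b plus half the
ties (computed from midranks), so U/(n₁n₀) equals the rank AUC exactly.
p-values: scipy's exact distribution for untied samples with n₁·n₀ ≤ 400; a
full enumeration over all C(n, n₁) group assignments when ties are present
and C(n, n₁) ≤ 200,000 (vectorized over a cached combination matrix);
otherwise the tie-corrected normal approximation with continuity
correction, which agrees with the exact p to within 0.01 by n = 30 per
group.

**Logistic regression.** IRLS/Newton, tolerance 1e-10, at most 50
iterations, linear predictor clipped at ±30 for overflow safety. Complete
or quasi-complete separation (non-convergence or |β| > 30) triggers a
ridge refit (λ = 1e-4 on slopes only) and sets a `separation` flag that is
carried into the exported equation as a warning block. Markers enter
models as log2(2^ΔCt); CA-125 enters as log10(U/mL). Coefficients are
serialized with full `repr` precision so equations round-trip bit-exactly.

**Cross-validation.** Repeated stratified two-fold CV: each repetition
splits every class in half (from `default_rng([seed, rep])`, so subset
evaluations share splits and rankings are paired comparisons), fits on the
training half only, and records AUC on both halves; reported values are
means over repetitions. The `swap_halves` option averages both half/half
directions per repetition (classic two-fold). A model with k predictors
requires ≥ 2(k+1) samples per class (a warning instead of an error in the
subtype setting, where cohorts are unavoidably small).

**Best-subset search.** All 2^k − 1 non-empty subsets of the pool (255 for
8 markers, 511 with CA-125) are fitted; subsets pass if *both* mean CV
AUCs exceed the floor (default 0.7), are ranked by mean test AUC, then mean
train AUC, then smaller size, then lexicographically (so results are
independent of pool order), and the top 10 are reported. The winner is
refit on the full cohort to produce the final probability equation.

**ROC.** The empirical curve sweeps distinct thresholds (prepending the
(0,0) corner), predicting positive when score ≥ threshold; its trapezoidal
area equals the rank AUC to machine precision, ties included. Confidence
intervals: DeLong's placement-value variance by default, percentile
bootstrap (2000 resamples) as the alternative; a zero-variance (perfectly
separated) sample yields a degenerate interval with an explicit flag.
Youden-optimal cutoffs are midpoints between adjacent distinct scores,
breaking J ties toward higher specificity; a closest-to-(0,1) policy is
available.

## 3. Experiment scales

The self-check experiments (`mirnapanel.experiments`, reused by
`scripts/acceptance.py` and the test suite) run at: 1000 random instances
for the AUC-route equivalence sweep; 200 CV repetitions on a 60 vs 60
no-signal cohort for null calibration (compared against the closed-form
null SD of the rank AUC at the half-cohort sizes, √((n₁+n₀+1)/(12n₁n₀)));
and 20 generator seeds × 100 CV repetitions for planted-marker recovery (3
of 8 markers at single-marker AUC 0.75, development-sized cohort), where
the winning panel must contain all three planted markers.

## 4. Limitations

- The generators are deliberately simple: no between-sample technical
  batch effects, no marker–marker correlation beyond shared group shifts,
  no hemolysis contamination, and NB dispersion is constant across
  markers. Real serum data are messier in all four ways.
- Resubstitution ROC summaries (AUC/sensitivity/specificity of the final
  model on the cohort it was refit on) are optimistic by construction; the
  cross-validated mean test AUC is the honest performance number, and the
  two are reported side by side.
- The qRT-PCR validation screen is a raw-α Mann–Whitney rule (with an
  optional Benjamini–Hochberg correction); retention by unquantified
  "trend" criteria is not modelled.
- Subtype classifiers run on very few positives (as few as 8); they are
  flagged as exploratory in output and their model selection should not be
  over-read.
- DeLong intervals are asymptotic; measured null coverage at n = 200/200
  is ≈ 0.94–0.95, slightly anti-conservative at small samples (the
  bootstrap alternative behaves similarly).
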