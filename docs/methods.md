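# Methods

`mepx` implements an analysis pipeline for paired-pulse TMS motor-evoked
potentials (MEPs) built around two dimensionless, ratio-to-baseline
excitability metrics, and evaluates them as diagnostic features for major
depressive disorder (MDD) versus healthy controls (HC). Because the kind of
dataset it targets is not publicly deposited, the pipeline ships with a
first-class synthetic cohort generator, and every stage is specified and
tested against that generator.

## The excitability metrics

For a MEP peak-to-peak amplitude `X` (μV) and the session's baseline set of
`m` single-pulse amplitudes `T_1..T_m`:

    rho   = X·m / Σ T_i          (X over the arithmetic mean of the baseline)
    delta = (X/m)·Σ 1/T_i        (X over the harmonic mean of the baseline)

Both are dimensionless, invariant under rescaling of a session's amplitudes
(so they remove between-session and between-subject gain differences such as
electrode placement or resting motor threshold), and satisfy `delta >= rho`
by the AM–HM inequality, with equality iff the baseline is constant. Two
conservation laws follow directly from the definitions and are asserted to
1e-12: within a session, the mean of `rho` over the baseline singles is 1,
and the mean of `1/delta` over the baseline singles is 1. A single pulse is
a member of its own baseline by convention; a leave-one-out variant exists
but is off by default. For a paired pulse at interstimulus interval (ISI)
`t`, values above/below 1 quantify intracortical facilitation/inhibition.

The baseline is formed *after* outlier removal, preserving the processing
order in which cleaning precedes metric computation; a session whose singles
are all removed is a hard error rather than a silent fallback.

## Synthetic cohort generator

The generator emulates the ICF/ICI protocol: per session, 24 single pulses
and 8 paired pulses at each ISI in {4, 5, 8, 10, 15, 20} ms (72 pulses),
randomly intermixed; 26 MDD and 17 HC subjects, one session each.
Amplitudes are phenomenological Gamma draws — no EMG waveform, artifact
window or threshold staircase is simulated, and stimulation intensities
(80%/120% RMT) are metadata only:

    X ~ Gamma(shape α, scale θ_eff),
    θ_eff = θ_base · s_subject · f_group · f_ISI(paired pulses only)

Defaults, chosen as plausible for APB-muscle MEPs at 120% RMT and *not*
estimated from any real dataset:

| parameter | default | why |
|---|---|---|
| α (shape) | 2.0 | right-skewed amplitude histogram, CV ≈ 0.7 |
| θ_base | 150 μV | mean single-pulse MEP ≈ 300 μV |
| s_subject | log-normal, σ = 0.5 | strong between-subject gain heterogeneity |
| f_group (MDD) | 1.15 | mild overall amplitude elevation in MDD |
| f_ISI (HC) | 0.55, 0.60, 0.90, 1.25, 1.35, 1.15 | short-ISI inhibition, 10–15 ms facilitation |
| f_ISI (MDD) | 0.80, 0.85, 1.10, 1.55, 1.70, 1.45 | reduced inhibition, enhanced facilitation |

The MDD profile encodes the GABAergic-disinhibition picture (weaker
short-interval inhibition, stronger facilitation), which places the reliable
diagnostic signal in the paired/single *ratios* — exactly what `delta`/`rho`
measure — while the subject-level gain noise obscures raw amplitudes. This
is the mechanism by which the generator reproduces the qualitative finding
that ratio features outperform raw MEPs. What passing tests on this cohort
do **not** show: that real MDD/HC cohorts separate this way, that the chosen
effect sizes are physiological, or that row-level cross-validation
generalises across subjects (see Limitations).

## Preprocessing

Outliers are removed by the Tukey IQR rule on amplitudes: keep values in
`[Q1 − k·IQR, Q3 + k·IQR]`, `k = 1.5`, quartiles by linear interpolation
(type-7) — the convention matters because it determines how many rows are
removed. Fences are computed globally over all amplitudes by default (the
minimal reading of "IQR criteria on MEP amplitudes"); per-subject and
per-ISI scopes are available because the rule's scope is genuinely
ambiguous. Cleaning is single-pass; refiltering after removal could remove
more and is deliberately not done. After cleaning, each sample carries
(amplitude, ISI with 0 encoding single pulses, delta, rho, group).

## Distributional checks

Amplitudes are averaged within subject (to respect repeated measures),
stratified by ISI × group, and each cell is fitted with a two-parameter
Gamma (location fixed at 0) by maximum likelihood, then tested with a
one-sample KS test against the fitted CDF. The default p-value treats the
fitted parameters as known; with parameters estimated from the same sample
this is conservative (null rejection well below the nominal 5%, verified by
simulation), which replicates the customary procedure. A parametric
bootstrap p-value is available as the corrected mode.

## PCA + mixed-effects logistic model

MEP amplitude, delta and rho are strongly collinear, so they are z-scored,
and only the first principal component PC1 enters the diagnostic model. The
eigenvector sign is fixed by a non-negative loading on amplitude, making the
slope's sign interpretable (higher excitability → log-odds of MDD). PCA is
computed on sample-level rows first; PC1 is then averaged within
subject × ISI, and on that aggregated table we fit

    logit P(y_ij = MDD) = β0 + β1·PC1_ij + b0_j + b1_j·PC1_ij

with ISI level `j` (7 levels) as the grouping factor and independent
(diagonal) random intercept and slope. Estimation is maximum likelihood
with a Laplace approximation to the marginal likelihood — the same
approximation lme4's `glmer` uses at `nAGQ = 1`, against which the fitter is
validated to ~2e-4 on a fixture. Numerical contract: random-effect standard
deviations are optimized on `[0, 10]` with L-BFGS-B; dimensions with sd
below 1e-6 are dropped from the Laplace integral (the likelihood is
continuous through that limit), sd below 1e-4 is reported as a boundary
(zero-variance) fit — a legitimate ML solution, flagged rather than raised.
Wald standard errors come from the numerical curvature in the fixed effects
at the variance estimates; AIC/BIC count 4 parameters. Single-class
outcomes and suspected complete separation (|β| at the 25 bound) return
flagged non-converged results. On the default synthetic cohort the variance
estimates typically hit the boundary, which is the expected behaviour when
the ISI-level effects are homogeneous.

Note the grouping factor is ISI, not subject: subject-level dependence in
the aggregated table is not modelled. This mirrors the modelling choice the
pipeline replicates and is a known caveat, not an oversight.

## Classification experiment

Three xgboost gradient-boosted tree classifiers (logistic loss, 250
estimators, learning rate 0.1, max depth 8, single-threaded for
determinism) are trained on identical 10-fold stratified CV splits (split
identity asserted by hashing the fold assignment) over three nested feature
sets: {amplitude, ISI}, {delta, rho, ISI}, and all four. Rows — individual
stimulations — are the CV unit, stratified on diagnosis only, replicating
the evaluated design; a subject-grouped CV mode is provided because
row-level splitting lets a subject appear in both train and test, which
inflates any feature that fingerprints subjects. MDD is the positive class;
labels use a 0.5 probability threshold, AUCs use the raw scores. Eight
metrics per fold (accuracy, balanced accuracy, Cohen's kappa, MCC, F1,
recall, ROC-AUC, PR-AUC; MCC and kappa take the 0 convention on degenerate
denominators) are fold-averaged, and two-sided paired t-tests across the 10
fold values compare consecutive feature sets; identical metric vectors are
reported as p = 1 with a zero-variance flag.

## Attribution

SHAP values for the all-features model are computed per fold on the
held-out rows only, then pooled; because delta and rho are collinear their
columns are additionally summed into a combined column. The implementation
is exact path-dependent TreeSHAP executed in double precision over the
parsed tree ensemble, so the local-accuracy identity (base value + sum of
contributions = model margin) holds to ~1e-13 per row; it is cross-checked
against xgboost's built-in single-precision contributions. Gini importance
is the total loss reduction attributed to each feature's splits, normalised
per model and averaged across folds; importances of features outside a
model's set are reported as missing, unused features get exactly zero.

## Reproducibility

A `RunConfig` (cohort parameters incl. seed, IQR settings, CV fold count
and seed, positive class) fully determines a run; the pipeline writes the
stimulation table, feature table, cleaning report, distribution report,
GLMM summary, comparison report, per-fold metric table, Gini table and a
manifest, and re-running the same config reproduces every artifact
byte-for-byte (asserted in tests).

## Problem sizes used in the test suite

Unit tests run on a reduced cohort (8 MDD + 6 HC, 3-fold CV); the
end-to-end scientific checks use the full default cohort (43 subjects, 3096
pulses, 10-fold CV), 1e5-draw Monte Carlo for estimator recovery, 1000
simulations for KS calibration, and 200 replicates for GLMM coverage and
type-I error. These sizes give comfortable Monte Carlo margins for every
asserted band.

## Known limitations

- Effect sizes, not being estimable from published numbers, are design
  choices; absolute performance figures on synthetic data are therefore
  illustrative, only the qualitative structure (ordering of feature sets,
  boundary variances, attribution signs) is meaningful.
- Row-level CV overstates generalisation to new subjects; use the
  subject-grouped mode for an honest out-of-subject estimate.
- The naive KS p-value is conservative; use the bootstrap mode when the
  calibration matters.
- Amplitudes are independent draws within a session; serial correlation,
  drift, and hysteresis of real TMS sessions are not emulated.
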