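# Methods

This note records the models, conventions and design choices behind
`aminofrail`, in the order the pipeline runs them.

## Synthetic cohort generator

The generator emulates a targeted UPLC/MS serum panel of 37 amino acids and
derivatives measured in three groups of older adults: robust controls
(n = 40), physical frailty & sarcopenia (PF&S, n = 94) and pre-frail/frail
type-2 diabetes (F-T2DM, n = 66).

**Concentration model.** Log-concentrations are multivariate normal:
analyte *i* in class *c* has mean `log_mean[c][i]` and standard deviation
`log_sd[i]`, with an exchangeable correlation ρ between analytes on the log
scale. Concentrations are the exponentials, hence positive and right-skewed
with mutually correlated analytes — the ill-conditioning PLS is meant to
handle. Defaults: `log_sd = 0.35` (a ~35 % biological coefficient of
variation, typical for serum amino acids) and ρ = 0.3. Baseline medians are
literature-plausible control values (e.g. alanine 350 µmol/L, glutamine
600 µmol/L, 3-methylhistidine 5 µmol/L).

**Class effects.** Signature analytes are shifted additively on the log
scale relative to controls, in two tiers:

| tier | analytes | shift (log-units) |
|---|---|---|
| F-T2DM primary | 3-methylhistidine, alanine, arginine, ethanolamine, glutamic acid | +0.50 |
| F-T2DM secondary | β-aminobutyric acid, isoleucine, methionine, 1-methylhistidine, sarcosine | +0.25 |
| PF&S primary | aminoadipic acid, aspartic acid, cystine, taurine, tryptophan | +0.30 |
| PF&S secondary | asparagine, citrulline | +0.15 |

The tiering is deliberate: the primary analytes are the headline
discriminators and must dominate the canonical-variate weights, while the
weaker PF&S shifts keep PF&S and controls substantially overlapping. This
calibration reproduces the qualitative regime the analysis is built to
expose — near-perfect two-class separation of PF&S vs F-T2DM (~99 %
DCV accuracy), a degraded three-class model (~88 %, controls the weakest
class at ~70 %), and a PF&S SIMCA model that rejects F-T2DM far better
than it rejects controls. It was fixed once and is not a tuning surface.

**Censoring.** Values below an analyte's lower limit of quantitation
(LLOQ, 0.5 µmol/L; 1 µmol/L for cystine, which is calibrated on a
higher-range standard curve) are stored as a censoring flag carrying the
bound, never as an imputed number. Six analytes (anserine, carnosine,
cystathionine, γ-aminobutyric acid, phosphoethanolamine, phosphoserine)
are flagged fully censored: serum levels sit entirely below this assay's
LLOQ, so every sample is censored regardless of the draw.

**Reproducibility.** One master seed; per-class streams are spawned from it
with `numpy.random.SeedSequence`, so tables are byte-identical across runs.

**What the generator does not model.** Age/sex/BMI confounding, batch and
instrument drift, analyte-specific correlation structure (the exchangeable
ρ is a simplification), non-lognormal tails, and the measurement process
itself. Passing tests therefore demonstrate correctness of the *analysis*
under a plausible data-generating mechanism, not clinical performance on
real serum data.

## Preprocessing

Pipeline order is fixed: LLOQ filter → censored-value substitution →
autoscaling.

- **LLOQ filter:** an analyte is dropped iff its censored fraction across
  all samples exceeds `max_censored_fraction` (default 0.5). On the replica
  panel exactly the six fully censored analytes drop, leaving 31.
  The filter is applied once, outside the cross-validation loops: panel
  composition is treated as an assay property, not a fitted parameter.
- **Substitution:** default LLOQ/2 (the targeted-metabolomics convention);
  `lloq` and `drop_sample` are available.
- **Scaling:** autoscaling (mean-center, unit variance) with the *sample*
  (n − 1) standard deviation. Scaling parameters are estimated on training
  rows only and applied unchanged to test rows; the cross-validation engine
  re-fits them inside every fold, so no test information leaks into the
  model. Mean-centering-only is available via `scale=False` on the model
  classes.

## PLS–DA

- **Dummy coding:** `[1 0 0]`/`[0 1 0]`/`[0 0 1]` for
  controls/PF&S/F-T2DM; a single 0/1 column for two classes (first class
  in `class_order` = 1).
- **Algorithm:** NIPALS with response deflation (PLS2 for multiclass). Each
  weight vector is computed directly as the dominant left singular vector
  of the current cross-covariance E′F — the exact fixpoint of the NIPALS
  inner power iteration, which can stall when two covariance directions are
  nearly degenerate. Weight signs are fixed deterministically (largest-
  magnitude entry positive). The response intercept is the training column
  mean; X is expected centered (autoscaled upstream).
  Components are nested: truncating a fitted decomposition equals a fresh
  fit at the smaller complexity, which the inner CV loop exploits to score
  all candidate complexities from one fit per fold.
- **Identities maintained:** `T = X R` to 1e-8 on training data; score
  orthogonality to 1e-8; at full rank the predictions coincide with
  ordinary least squares.
- **LDA on predictions:** pooled within-class covariance, priors
  proportional to training class frequencies (`priors="equal"` available).
  Multiclass dummy predictions vary only in a (k − 1)-dimensional plane, so
  the discriminant is fitted in the rank-revealing subspace of the training
  predictions; a covariance that is singular *within* that subspace (e.g.
  perfectly separated training classes) is ridge-regularized with a
  warning. Ties in the discriminant scores resolve to the earliest class in
  `class_order` (deterministic, documented).
- **Canonical variates:** k − 1 LDA directions; `cv_weights` pulls them
  back to the analytes through R q, unit-norm with largest-magnitude entry
  positive (plot convention); `cv_weights_raw` keeps the sign consistent
  with the score projection, so an analyte elevated in a class points to
  that class's side — the form used when reading discriminators off the
  weights, mirroring how scores and weights plots are read jointly.

## Double cross-validation

Stratified outer loop (default 7 folds) for honest test predictions;
stratified inner loop (default 5 folds) on each outer-training set selects
the number of latent variables (1..`max_lv`, default 15) minimizing the
pooled inner misclassification error, ties to the fewest (parsimony). The
procedure repeats `n_repetitions` times (default 50) with reshuffled folds.
Figures of merit — overall accuracy and per-class correct-classification
rates — are reported as mean ± sd over repetitions on the percent scale;
the sd uses n − 1. Complexity is summarized as mean ± sd over all outer
folds and repetitions. The fold counts are package defaults (they are not
dictated by the method) and configurable.

A class must keep at least two members in every training fold; otherwise
the engine raises an error advising fewer folds.

**Permutation testing.** Class labels are permuted B times (default 999
for a final analysis; the shipped acceptance script uses 199 with 3 DCV
repetitions per draw to keep the run to minutes — a documented problem-size
choice, which floors the attainable p at 1/200) and the full DCV is rerun
per draw. p = (1 + #{null ≥ observed}) / (1 + B), computed for the accuracy
and each per-class rate.

## SIMCA

One PCA per class, fitted on that class's rows after per-class autoscaling
(classical SIMCA; global scaling available via `scale=False`). For a sample
with scaled residual decomposition into scores t and residual e:

- T² = Σₐ tₐ²/λₐ (Mahalanobis distance from the center of the score
  space, λₐ = training score variances, n − 1 convention);
- Q = ‖e‖² (squared orthogonal residual norm — the "orthogonal distance"
  is ambiguous between the norm and its square; the square is used, and
  after percentile normalization the two are monotone equivalent, so the
  acceptance decisions differ only through the normalizer);
- d = √((T²/T²₉₅)² + (Q/Q₉₅)²), the percentiles computed on the training
  statistics with linear interpolation. Acceptance is strict: d < 2.
  If a normalizer vanishes (data exactly in the PCA span), a vanishing
  statistic reduces to 0 and a non-vanishing one to ∞.

Per-class component counts are selected by the same nested-CV machinery,
maximizing balanced (sensitivity + specificity)/2 on inner folds — the
selection criterion is a package choice, as class modeling does not define
a canonical one. Sensitivity = % of own-class rows accepted; specificity
vs another class = % of that class's rows rejected; overall specificity
pools all non-member rows (and equals the size-weighted mean of the
pairwise specificities, an identity the tests assert).

## Numerical conventions and degenerate inputs

- Percentages on the 0–100 scale, one decimal in displays; full precision
  in serialized outputs.
- `n_components` above the effective PCA rank, constant columns (named in
  the error), unknown labels, dimension mismatches, and infeasible fold
  counts all raise typed errors.
- A response with no covariance against the predictors yields a
  zero-component model predicting the class means.
- Training misclassification is *not* guaranteed monotone in the number of
  latent variables (the LDA readout can fluctuate by a sample or two); the
  guaranteed nesting property, asserted in the tests, is that the training
  response residual sum of squares is non-increasing.

## Problem sizes used by the shipped scripts

The acceptance script runs 50-repetition DCVs for both PLS-DA models,
199-permutation tests with 3 repetitions per null draw, 20-repetition
SIMCA DCVs per class (max 12 components), and 20 seeded cohorts for the
signature-recovery rate; the full run takes ~6 minutes on one core. The
test suite uses smaller fold/repetition counts chosen to exercise the same
code paths in seconds.

## Known limitations

- The exchangeable-correlation log-normal cohort is a deliberately simple
  stand-in; effect tiers were calibrated to the qualitative separability
  pattern described above, not to any participant-level data.
- SIMCA component selection by balanced sensitivity/specificity tends to
  pick generous complexities on strongly separated synthetic classes.
- The permutation p-value resolution is limited by the draw count; claims
  below 1/(B + 1) are not possible.
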