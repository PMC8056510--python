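# Methods

## Pipeline overview

The package implements a hybrid association/classification pipeline for
two-group (case-control) phenotypes over direct-to-consumer genotype data:

1. **Ingest** — 23andme (4-column) and AncestryDNA (5-column) raw files are
   parsed to a common profile structure; AncestryDNA allele pairs are merged
   into a single genotype string. The SNP reference panel (rsid, REF, ALT)
   comes from a VCF, read through cyvcf2.
2. **Quality control** — reference entries with a missing REF or ALT are
   dropped without imputation; duplicate rsids keep the first occurrence;
   SNP columns whose per-sample missing fraction exceeds a bound (default
   0.2) are removed from the coded matrix.
3. **Coding** — every person × SNP genotype becomes 0/1/2 (count of observed
   alleles differing from REF) or missing.
4. **Pre-selection** — per-SNP, per-group mutation-type percentages feed an
   optional absolute-difference prefilter and the slope-controlled linear
   threshold; any qualifying mutation type admits the SNP.
5. **Dataset** — selected codes form the feature matrix; a seeded
   class-ratio-preserving split and optional train-fitted scaling follow.
6. **Models** — grid-searched random forest / XGBoost, five neural kinds on
   a NumPy engine, and a stacked ensemble of frozen bases with a trainable
   dense head.
7. **Evaluation** — accuracy, confusion matrix, per-class one-vs-rest
   ROC/AUC (trapezoidal integration over the threshold sweep).

## Conventions and degenerate inputs

- Genotype strings that cannot be compared to a single-base reference — the
  `--` no-call, AncestryDNA `0` placeholder alleles, indel codes I/D, or any
  character outside {A,C,G,T} — are stored and coded as missing.
- Haploid calls code to {0, 2}: "full mutation" is read as *every observed
  allele differs from the reference*.
- An allele matching neither REF nor ALT still counts as mutated; the
  coding rule is defined against the reference allele only, and the ALT
  column is carried for bookkeeping. No strand flipping is attempted.
- Chromosome labels are kept verbatim (a `chr` prefix is stripped on read);
  all joins across files are by rsid, never by coordinates.
- Multi-allelic VCF rows keep the first ALT allele and log a warning.
- Group percentages are computed over non-missing observations only; a
  group with zero observations at a SNP yields (0, 0, 0) and such SNPs are
  excluded from selection outright — treating them as 0% would spuriously
  maximise between-group differences.
- Percentages per group sum to 100 within 1e-6 whenever at least one
  observation exists (asserted in tests).

## The linear threshold

For one mutation type with between-group extrema `max%` and `min%`:

```
Threshold      = slope · max% + intercept
LowerThreshold = (1 − Threshold/100) · max%
selected      ⇔ min% ≤ LowerThreshold
```

The intercept defaults to 100, which keeps `Threshold` on the percent scale
and collapses the rule to `min% ≤ (−slope/100)·(max%)²`. Consequences:

- **Monotonicity.** For fixed intercept, the selected set at a more
  negative slope is a superset of the set at a less negative slope; panel
  sizes are non-increasing in slope (property-tested and asserted on a
  seeded cohort).
- **Structural region.** Any SNP with a mutation-type percentage above
  `100/|slope|` in *both* groups satisfies the rule regardless of group
  difference (at slope −1.5 that is ≈67%). The rule is therefore a
  gap-*or*-prevalence screen, not a pure association test.
- **Noise floor.** Against a null SNP with identical group probabilities,
  sampling noise alone triggers the rule at a non-trivial rate: at ~95
  observations per group the false-positive rate is ≈6% for a balanced
  composition (Monte-Carlo estimate; the balanced vector is the minimum
  over the composition simplex). This is intrinsic to the bare rule at
  this sample size.
- **Prefilter.** The absolute-difference prefilter (discard unless some
  type's |group difference| exceeds a predefined cutoff) suppresses that
  noise floor. The cutoff is a required, logged config field defaulting to
  0 (disabled). For the planted-recovery checks it is set to 25 percentage
  points, derived from the study conditions rather than tuned: the 3σ
  between-group noise ceiling at n≈95/group is ≈21 points, the planted
  effect is ≥40 points, and 25 separates the two regimes. With it, planted
  sensitivity is 1.0 and the background rate ≤0.001 across seeds.
- The selection predicate follows the equation form (`min ≤ lower ⇒
  selected`); an `invert_threshold` switch flips it for sensitivity
  analysis. Panels are ordered by descending maximum absolute difference,
  ties broken by rsid, for determinism.

## Dataset construction

- Missing codes at selected SNPs are filled with 0 (no mutation) and the
  imputed-cell count is logged; no other imputation is performed anywhere.
- The split permutes samples under a seed and allocates the training budget
  across the two classes by largest-remainder rounding, preserving the
  class ratio within one sample per class. The default training size is
  `round(n · 540/806)`, a two-thirds hold-out design.
- Scaling (min-max or standardisation) is fitted on the training split only
  and applied to both splits; constant columns map to 0. Leaving the
  choice of scaler to the user reflects that either convention is common
  for 0/1/2 codes.

## Models

- **Tree models.** Random forest (scikit-learn) and XGBoost are searched
  exhaustively over their full printed hyperparameter lists — RF: criterion
  {gini, entropy}, min_samples_split {0.01, 0.015, 0.02, 0.025}, max_depth
  {None, 4, 5}, min_samples_leaf {0.0025, 0.005, 0.01, 0.015}, max_features
  {sqrt, 0.3, 0.4, 0.5}, n_estimators {500, 1000, 3000}; XGB:
  min_child_weight {1, 5, 10}, gamma {0.5, 1, 1.5, 2, 5}, subsample and
  colsample_bytree {0.6, 0.8, 1.0}, max_depth {3, 4, 5}, boosters {gbtree,
  gblinear, dart}, objectives {hinge, logistic, logitraw} — with a single
  stratified validation split and refit on the whole training split. The
  full grids are large; reduced grids are used in the test suite and the
  defaults are asserted list-for-list rather than executed.
- **Neural kinds.** A compact NumPy engine provides dense, dropout, 1-D
  convolution + global average pooling, LSTM, GRU and bidirectional LSTM
  layers with softmax cross-entropy and SGD/RMSprop/Adam. All gradients
  (including backpropagation through time) are exact and unit-tested
  against central finite differences. Architectures are deliberately
  small and configurable: ANN uses two hidden layers with widths scaled to
  the input (capped at 64); the recurrent kinds use one cell layer of 16
  hidden units over the panel-ordered sequence of one-channel steps; the
  1DCNN uses 8 kernel-3 filters, global averaging, and a 16-unit dense
  head. The output layer always has 2 units with normalised class scores.
  Default learning rates are 0.01 (Adam, RMSprop) and 0.05 (SGD). No early
  stopping; dropout at the swept rate is the only regulariser.
- **Sweep.** The hyperparameter sweep enumerates the full Cartesian product
  of the axes (activation {sigmoid, relu, softmax}, dropout {0.2, 0.3,
  0.5}, optimizer {adam, sgd, rmsprop}, batch size {1, 10, 15, 20},
  validation split {0.2, 0.3, 0.4}, epochs {10, 20, 50, 100}), ranks by
  validation accuracy (ties by enumeration order) and journals finished
  combinations to a JSON-lines file so interrupted sweeps resume without
  retraining; journal-restored entries carry their score but not a fitted
  estimator.
- **Stacked ensemble.** Bases with validation accuracy strictly above the
  threshold (default 0.92) are frozen; their concatenated two-unit score
  vectors feed a dense head (ReLU hidden layer, 2-unit softmax output)
  trained for 10 epochs by default. Zero qualifying bases raise an error
  naming the threshold; an explicit `fallback_top_k` admits the best k
  candidates with a logged warning instead, which the scaled-down
  end-to-end check uses. Base parameters are asserted bit-identical before
  and after head training.
- Raw scores from objectives that are not probabilities (hinge, logitraw)
  are squashed through a sigmoid and renormalised so every model satisfies
  the two-column simplex contract.

## The synthetic cohort generator

The generator emulates a crowd-sourced DTC case-control cohort and is the
test bed for every stage. Design choices:

- Genotypes are drawn directly from per-SNP mutation-type probability
  vectors `(p_no, p_partial, p_full)` rather than from allele frequencies
  under Hardy–Weinberg, because the selection statistics operate on
  mutation-type percentages; a drawn type is rendered against the SNP's
  REF/ALT as ref/ref, ref/alt or alt/alt.
- The default cohort shape is 404 + 402 samples; tests scale down to
  100 + 100. Default missingness is 5% absent records plus 2% no-calls.
- **Informative SNPs** (default 20) use group-specific vectors, by default
  (0.1, 0.1, 0.8) vs (0.6, 0.3, 0.1) — a 70-point PFM gap.
- **Background SNPs** share one vector per SNP across both groups, drawn
  from Dirichlet(200, 200, 200): tightly concentrated at the balanced
  composition (sd ≈1.9 points, well under the ≈5-point binomial noise at
  the default group size), so background SNPs are a clean noise-only null
  that sits away from the threshold's structural selection region. A
  background with a dominant mutation type (as real reference-matched
  cohorts often have) would be selected structurally at moderate slopes —
  by design of the rule, not by error; users probing that regime can pass
  their own `background_alpha`.
- All randomness derives from a single seed; identical seeds yield
  byte-identical files. 10⁵ SNPs × a few hundred samples generate in
  minutes on one CPU (vectorised draws; file writing dominates).

What passing tests on this generator do **not** show: robustness to linkage
disequilibrium, population structure, genotyping-platform batch effects,
strand inconsistencies between files, or realistic minor-allele-frequency
spectra — none of which the generator models.

## Problem sizes used in the checks

The behavioural checks run at desk scale by choice: recovery and
monotonicity use 200-sample, ~1000-SNP cohorts; the end-to-end run uses
100 + 100 samples × 300 SNPs with a reduced RF grid (2 configurations,
100 trees), one 30-epoch ANN and one 30-epoch LSTM, and the top-2 fallback
for ensemble membership (base validation accuracies on the strong-effect
cohort typically reach 1.0, so the 0.92 threshold is also met). The whole
suite runs in a few seconds.

## Known limitations

- The recurrent kinds scale linearly in panel size per step and are
  impractical beyond a few hundred selected SNPs in this pure-NumPy form.
- `binary:hinge`/`binary:logitraw` scores are rank-preserving after the
  sigmoid squash but are not calibrated probabilities.
- ftdna-illumina exports are encrypted and are detected and skipped, never
  decrypted.
- The intercept of the linear threshold is exposed but essentially always
  100; other values move `Threshold` off the percent scale and are
  supported for sensitivity analysis only.
- No multiple-testing correction is applied in pre-selection; the screen is
  a filter, not an inference procedure.
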