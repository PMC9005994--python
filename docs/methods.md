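# Methods

## Problem and segment model

RNA 5-methylcytosine (m5C) prediction is cast as binary classification of
41-nt windows centred on a candidate cytosine (λ = 20 flanking nucleotides
per side).  The window length follows the convention of the m5C predictor
literature, where ±20 nt flanks consistently outperform shorter contexts.
Windows are validated strictly: the center must be C, the alphabet must be
{A,C,G,U} after uppercasing and T→U mapping, and candidates whose full
window would run past a sequence end are *skipped*, never padded — all
encoders assume fixed length, and padded composition statistics would be
biased.  Records violating these rules are collected in a per-record
rejection report rather than aborting a run.  Coordinates are reported
1-based inclusive throughout.

## Feature encodings

Seven families are concatenated in a fixed order with stable column names
(`ENAC_win{j}_{nt}`, `CKSNAP_k{k}_{XY}`, `ANF_p{i}`, `NCP_p{i}_b{b}`,
`BIN_p{i}_{nt}`, `SCPDNC_{k}`, `W2V_{d}`), 808 columns in total for a 41-nt
window.  Stable names are load-bearing: rankings and trained-model column
contracts are exchanged as plain text and re-joined by name.

- **ENAC** (148): per-window A/C/G/U frequencies for every length-5 window
  slid 5′→3′; each window block sums to 1.
- **CKSNAP** (96): for each gap k = 0..5, the 16 pair frequencies
  N<sub>X*Y</sub>/(L−k−1) in lexicographic A,C,G,U order; each k-block sums
  to 1.
- **ANF** (41): the running prefix frequency of each position's own
  nucleotide, d_i = (1/i)·Σ_{j≤i} 1[S_j = S_i]; values in (0, 1].
- **NCP** (123): the 3-bit chemical code A=(1,1,1), C=(0,1,0), U=(1,0,0),
  G=(0,0,1).  The U/G triples are adopted verbatim from the predictor
  convention even though a (purine, amino, strong-H-bond) class reading
  would swap two bits; the code is a bijection either way, so downstream
  models are unaffected by the labelling.
- **BIN** (164): per-position one-hot in A,C,G,U order.
- **SCPseDNC** (136): 16 normalized dinucleotide frequencies plus λ·Λ
  correlation factors θ (λ = 20 tiers × Λ = 6 indices, tier-major order).
  The tier-m factor averages J = P_ς(R_iR_{i+1})·P_ς(R_{i+m}R_{i+m+1}) over
  i = 1..L−m−2, the bound consistent with both the first- and last-tier
  displayed forms of the standard definition.  The shared denominator
  1 + w·Σθ (w = 0.9) makes the 136 components sum to exactly 1.
  The six physicochemical indices (Roll, Rise, Shift, Twist, Slide, Tilt)
  are the standard RNA helical step parameters, shipped as a packaged TSV
  (reverse-complement symmetric) and z-standardized per index across the 16
  dinucleotides at load time, as the correlation formula presumes.
  Published uses of this encoding do not print their index values, so other
  implementations may differ in the raw table — dimensions, ordering and
  normalization are unaffected.
- **Word embedding** (100): segments are sentences of overlapping 3-mer
  tokens (stride 1, the dominant convention for nucleotide embeddings;
  configurable).  A CBOW model with negative sampling is trained by
  mini-batch SGD in numpy: window 5, 20 epochs, 5 negatives drawn from the
  unigram^0.75 distribution, learning rate 0.025 decaying linearly to 1e-4,
  batch 512, minimum token count 1, word-level tokens (no subword n-grams).
  The trainer is single-threaded and seeded, so feature matrices are
  byte-reproducible — a property chosen over training throughput.  A
  segment's feature vector is the mean of its token vectors;
  out-of-vocabulary tokens contribute zero vectors but still count in the
  denominator.  The embedding is part of the fitted pipeline: it should be
  trained on training-split segments only when a held-out evaluation
  follows, and it is bundled inside the model artifact so prediction uses
  the exact training-time tokens.

## Feature selection

- **SHAP ranking**: a boosted-tree ensemble (depth 6, learning rate 0.1,
  500 trees, fixed seed) is fit on the full training matrix once, and each
  feature is scored by the mean absolute Shapley attribution over training
  rows.  Attributions are computed exactly by the tree-path-dependent
  TreeSHAP algorithm built into XGBoost (`pred_contribs`); per row they sum
  (with the base value) to the raw margin prediction, which the test suite
  asserts, and on depth-1 ensembles they match the exponential-sum Shapley
  definition evaluated by brute force over all feature subsets.  The
  ranking model is deliberately independent of the later per-dataset
  hyperparameter search, since ranking precedes tuning in the pipeline; a
  single full-training fit (rather than averaging over CV folds) keeps the
  ranking deterministic and cheap.
- **F-score**: ((x̄⁺−x̄)² + (x̄⁻−x̄)²) / (s²⁺ + s²⁻) with n−1 sample
  variances.  Zero denominator with positive numerator ⇒ +inf (ranked
  first); 0/0 ⇒ 0.  Affine-invariant, as a ratio of second moments.
- **mRMR**: features are discretized by equal-frequency quintile binning
  (duplicate quantile edges collapse, so 0/1 indicators keep their natural
  levels); mutual information is estimated in nats from the joint
  histogram.  The first pick maximizes I(f, label); each later pick
  maximizes I(f, label) − mean_{s∈selected} I(f, s).  Because the spec of a
  ranking is a full permutation, features beyond the greedy selection
  budget (default 50) are appended ordered by their final-step criterion.
  The estimator choice (binning + plug-in MI) is ours; the selection
  criterion itself takes no estimator stance for continuous features.
- **Incremental selection (IFS)**: for each n in a grid (default: step 4 to
  300, then step 20 to 808; fully configurable), the top-n prefix is scored
  by mean stratified 5-fold CV AUROC with a fixed modest classifier
  (depth 4, 200 trees, learning rate 0.1); best n wins, smallest n on exact
  ties.  The fold seed is shared with the modeling grid search so curves
  are comparable across stages.

All three rankers are deterministic given data and seed; ties everywhere
break by original column index via stable sorts.

## Modeling

Stratified k-fold CV (default k = 5, shuffled, seeded) guarantees both
classes in every fold even for small balanced sets — a refinement of plain
random subset splitting that matters at a few hundred rows.  Grid search is
exhaustive with mean CV AUROC as the selection metric and grid-order
tie-breaking; the full boosted-tree grid is 8 depths × 5 learning rates ×
7 tree counts = 280 combinations.  Baselines: random forest (grid over
tree count and depth) and an RBF SVM behind a standardization step with
sigmoid-calibrated probabilities (internal CV calibration).  Final models
freeze their feature-name contract; prediction refuses inputs missing any
contract column and reorders the rest.  One top-level run seed derives all
stage seeds through SHA-256 (`derive_seed`), keeping stages decorrelated
but jointly reproducible.

## Evaluation

Scalars Sen, Spe, Pre, Acc, F1, MCC and FOR = FN/(FN+TN) from confusion
counts under the decision rule score ≥ threshold (ties predict positive —
documented because it changes counts at exact-threshold scores).
Zero-denominator conventions: Pre = 0 with no positive predictions,
FOR = 0 with no negative predictions, MCC = 0 when any denominator factor
vanishes.  AUROC equals the Mann–Whitney pair statistic (ties ½); AUPRC is
step-wise average precision, not trapezoidal, the standard for PR curves.
`threshold_for_fpr` returns the smallest threshold whose empirical FPR on
the supplied scores is within budget; operating points should be chosen on
training scores to avoid test leakage.

## Synthetic benchmark

The generator emulates the shape of published m5C benchmarks — balanced
41-nt segment sets with a centred C — with an i.i.d. background (uniform by
default) and a planted positional signal: at each biased position
(defaults: 5, 11, 17, 27, 33, 39, spaced ≥ 6 nt so no length-5 composition
window spans two of them) the positive class samples from
(1−effect)·background + effect·δ(designated nucleotide).  Defaults are
500+500 segments and effect 0.5, the regime in which all three rankers are
expected to recover the planted set and selection measurably beats the full
feature set.  Effect 0 makes the classes exactly exchangeable (null
benchmark); effect 1 fixes the designated nucleotides in positives.  The
planted signal is positional rather than motif-based on purpose: the
one-hot indicator of the designated nucleotide at each biased position is
then a known minimal relevant column set (`relevant_feature_names`),
giving ranking tests an exact ground truth.  The generator does **not**
emulate motif context, inter-position dependence, or species-specific base
composition — passing tests demonstrate pipeline correctness and
sensitivity, not performance on real methylomes.  Reproducing published
per-species figures requires the external benchmark corpora and the full
280-combination grid search; that workflow is supported (encode/tune/train
on downloaded FASTA) but intentionally not bundled.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the benchmark at 500+500
segments with a 12-point IFS grid and reduced tuning grids (e.g. 2×2×2),
sizes chosen to exercise every stage end-to-end on a single CPU in minutes;
all grids and sizes scale up by configuration only.  Oracle-equivalence
tests compare vectorized encoders against naive loop re-derivations at
1e-12; TreeSHAP identities are asserted at 1e-6 on small-margin models
(attributions are float32, so the identity degrades with margin magnitude
and tree count); normalization identities at 1e-9 or better.  Degenerate
inputs (single-class labels, empty grids, non-finite features, constant
columns) raise informative errors or receive the documented conventions
rather than propagating NaN.
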