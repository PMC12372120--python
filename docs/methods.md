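# Methods

## Problem and model

The package targets multi-class tabular classification under severe class
imbalance with boundary overlap — the regime of cardiotocography (CTG)
fetal-health screening, where the clinically critical classes (suspect,
pathological) are a small minority of records and sit near the majority
class in feature space. Two mechanisms address it jointly:

1. **MAAL**, a cost-sensitive cross-entropy whose class weights are driven
   by the model's *current* mistakes rather than by static class
   frequencies. Per epoch, with `e_i` misclassified samples of true class
   `i`, the error shares are `r_i = e_i / Σ_j e_j` (defined as 0 when no
   errors occurred), the weights `w_i = clip(exp(r_i), 1, 5)`, and the loss
   is the batch mean of `−w_y log p_y`. With uniform weights this is
   exactly plain cross-entropy, which the tests assert to 1e-9.
2. **A main–auxiliary correction cascade**: a second, lighter network is
   trained only on the samples the primary model got wrong, and a routing
   rule combines the two at prediction time.

## Networks and optimization

Primary: `fc(p→64) → ReLU → dropout 0.3 → fc(64→64) → 4-head
self-attention (d_model 64, d_k=d_v=16) → dropout 0.3 → classifier(64→C)`.
Secondary: `fc(64→32) → ReLU → dropout 0.5 → 4-head attention (d_model 32,
d_k=d_v=8) → dropout 0.5 → classifier(32→C)`; it consumes the primary's
64-d pre-classifier embedding of each banked sample (a `raw_features` mode
with an input projection is available). Attention projections carry no bias
terms, and there are no residual connections or layer normalization — the
architecture adds nothing beyond the stated blocks. On a single 64-d (or
32-d) token the attention softmax is degenerate and the block reduces to a
linear composition of the head projections; a `feature_tokens` layout that
reshapes the hidden vector into 4 tokens is available behind configuration.
The secondary network's attention geometry (d_k=d_v=8) preserves the
4-head layout at its 32-d width.

Everything is trained in float64 NumPy through a small reverse-mode
autodiff module (verified against central differences to ~1e-9) with AdamW
(decoupled weight decay): lr 1e-3, batch 32, weight decay 1e-5, fresh
seeded shuffle per epoch. Parameters initialize from a seeded uniform
fan-in scheme; every random draw in a run fans out from one seed via a
`numpy` seed sequence, and two runs with the same seed are byte-identical.

Default schedule: 600 primary epochs, 1000 secondary epochs, MAAL warm-up
delay 60, early-stopping patience 50. Scaled-down runs (tests, the
acceptance script, examples) shrink the schedule proportionally —
120/200 epochs with delay 20 — keeping the warm-up at roughly its 10%
share of the budget; truncating the epochs while keeping the absolute
60-epoch delay would let early stopping end training before the adaptive
weights ever act, which changes the design rather than the scale.

### Early-stopping monitor

Early stopping monitors a stratified 15% validation carve-out of the
training split (the secondary model likewise, when it has ≥20 samples;
otherwise its own training loss). The monitored quantity is the
**class-balanced (macro) validation cross-entropy** — the unweighted mean
over classes of each class's mean CE. On 78:14:8 data, a plain sample-mean
monitor is dominated by the majority class and systematically selects
majority-biased checkpoints, which would discard exactly the minority
improvements the adaptive loss produces; the macro monitor weighs each
class's generalization equally and is applied identically to every
training arm, so paired comparisons remain fair. A `paper_mode` flag
instead monitors the test set, mirroring the reference evaluation protocol; it is
labeled unsound for deployment claims wherever it surfaces.

MAAL's epoch error counts come from end-of-epoch predictions on the fit
portion (training minus the validation carve-out), keeping validation data
out of the loss-weight feedback loop.

## Error bank and leakage isolation

Original file row ids are assigned at load time and propagate unchanged
through feature selection, splitting and scaling. At every best-checkpoint
event the current model's mistakes over the full training split are
unioned into the bank (set semantics; re-recording is idempotent and
accumulation is monotone — samples are never removed once banked), with
per-checkpoint provenance `(checkpoint, predicted, true)`. Test-side
errors come from the final model only. The leakage check requires (a)
disjoint train/test error-id sets and (b) no bitwise-identical
standardized feature row on both sides; materialization of secondary data
refuses to run until it passes. Fuzzed tests plant id overlaps and
duplicated rows in 100 trials each and require 100% detection.

## Routing

`oracle` routing re-predicts exactly the primary's wrong test samples.
It requires true labels, so it is an evaluation device: it measures how
much a correction stage *can* add, and by construction its accuracy weakly
dominates the primary's (asserted end-to-end over 20 seeds). `confidence`
routing (default threshold 0.5 on the primary's max softmax) is the
label-free deployable alternative. Neither is claimed to be "the"
reference protocol beyond what its definition states.

## Preprocessing

- **mRMR** (difference criterion): greedy forward selection maximizing
  `MI(feature; label) − mean MI(feature; selected)`, with mutual
  information measured on equal-frequency discretized columns (default 10
  bins); ties break toward the lower feature index, and constant features
  have MI 0. Default k=8.
- **Stratified split** (default 77/23, seed 42): per-class training counts
  by largest-remainder rounding, membership by seeded within-class
  shuffle.
- **Standardization**: `(x − μ)/σ` with population (ddof=0) σ, fitted on
  the training partition only; zero-variance features are an error.

## Evaluation

Per-class precision/recall/F1 from one-vs-rest confusion counts
(zero-denominator cases defined as 0 with a warning), support-weighted
aggregates, one-vs-rest AUC (rank-based with half credit for ties; absent
classes reported missing and excluded from the weighted mean), and
percentile bootstrap CIs: B=1000 seeded with-replacement resamples,
interval = 2.5th/97.5th percentiles (a symmetric 95% interval; resamples
on which a metric is undefined are redrawn with a capped retry count).
Cluster quality of the 64-d test embeddings uses the textbook silhouette
and Davies–Bouldin indices; both are checked against naive O(n²)
references. Embeddings are exported as TSV for external projection (e.g.
t-SNE, perplexity 30, 1000 iterations); the projection itself is out of
scope.

## Synthetic data

Each class is an isotropic Gaussian; class centers are regular-simplex
vertices with pairwise distance 3, and all spreads scale with `overlap`,
so raising `overlap` blurs boundaries without moving the geometry. Counts
follow largest-remainder allocation of the class proportions; rows are
seed-shuffled with ids 0..n−1. The CTG-like preset fixes n=2126, counts
1655:295:176, 8 features, `overlap=1.0` — calibrated against the ideal
observer, not against trained models: at this setting the Bayes classifier
reaches ≈0.93–0.94 accuracy with suspect/pathology recall ≈0.82/0.72,
matching the difficulty profile of the real benchmark (baseline MLPs in
the low 90s with pronounced minority errors) while leaving the headroom
the adaptive loss and the correction stage exist to exploit.

What the generator does *not* emulate: real CTG marginals are skewed,
discrete and correlated rather than isotropic Gaussian; real class
structure is not a single mode per class; and real minority samples are
not exchangeable draws. Passing tests on this data therefore demonstrate
the *mechanisms* (weight schedule, leakage isolation, cascade dominance,
metric correctness) and directional effects, not clinical performance
levels; headline accuracies from the real benchmark are not reproduced
here and are not asserted anywhere in the test suite.

## Numerical choices and degenerate inputs

Probabilities are floored at 1e-12 before logs. Zero-total-error epochs
leave MAAL weights unchanged (0/0 defined as no-op rather than reset).
Single-member classes are rejected at split time; single-class secondary
training sets train with a loud warning (MAAL degenerates to weighted CE).
SMOTE lowers k with a warning when a class has ≤ k members and gives
synthetic rows fresh negative ids; neighbor ties resolve by row-id order.
Mean reduction over batches throughout; no gradient clipping.

## Known limitations

- Oracle routing's gains are an upper bound; the confidence router's gains
  depend on calibration, which is not explicitly modeled.
- The literal weight rule bounds weights by e, so classes can differ by at
  most a factor ≈2.7 in loss emphasis — far less than the 20:1 prior
  imbalance; MAAL nudges boundaries, it does not rebalance them.
- The per-epoch error shares are noisy for very small classes; no
  smoothing or momentum is applied because none is part of the stated
  rule.
- Training is single-threaded NumPy; it is sized for thousands of samples
  and tens of features, not for large-scale use.
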