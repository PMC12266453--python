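# Methods

`ubisite` predicts whether a lysine (K) residue in a protein is a
ubiquitination site. The method consumes per-residue embeddings from a
protein language model, compresses them with a conditional variational
autoencoder (cVAE) whose bottleneck is shaped by the site labels, cleans
the notoriously noisy negative class with neighborhood editors, trains a
residual classifier on the latent codes, and explains predictions with
integrated gradients. This note records the model, its assumptions, the
parameters that matter, and the choices made where the design was open.

## Sites, windows and redundancy

Every lysine in a sequence is a candidate site; positions are 1-based.
Ambiguity codes (X, U, B, Z, J, O) are tolerated in sequences but never
counted as lysines. Window extraction around a site takes `n` residues
either side and truncates at the termini rather than padding — padding
characters would pollute a language-model's context, truncation only
shortens it. The lysine's position inside the window shifts accordingly
and the embedding row is taken at the shifted position.

Training sets built from site databases are homology-redundant. The
redundancy filter performs greedy representative selection, longest
sequence first with lexicographic id tie-break, discarding a record when
its identity to a kept representative exceeds the threshold (default
0.30). Identity is estimated by 5-mer containment: shared 5-mers divided
by the 5-mer count of the shorter sequence. This is a deliberate,
self-contained stand-in for alignment-based clustering tools, which
cannot natively cluster at 30% identity; containment over-estimates
identity for repetitive sequences, which errs on the side of removing
redundancy. The estimate, k, and the greedy order are all documented
knobs (`kmer_identity`, `redundancy_filter`).

## Encoders

An encoder maps an amino-acid string to a `(length, dim)` matrix — one
vector per residue, deterministically. The deployed-scale regime uses a
2560-dimensional language-model embedding taken from the final
per-residue representation before the output head; adapters for real
models must document which layer they expose. The package ships no model
weights. The `MockEncoder` satisfies the contract with a seeded hash of
(residue letter, position): deterministic, context-free, any
dimensionality. Because it is keyed on position *within the presented
sequence*, window truncation shifts its rows exactly as it shifts a real
encoder's coordinates, so the window/full-sequence equivalence for
interior sites is testable without weights.

Embedding tables persist as a TSV site list plus a raw little-endian
float32 matrix with a magic string and explicit shape; writes are
byte-reproducible. Model checkpoints use a purpose-built binary container
of named float64 arrays, sorted by name with no timestamps, so a rerun
with the same seed produces byte-identical checkpoints and save→load is
lossless (reloaded models predict bit-identically).

## The conditional VAE

Per-site features `x ∈ R^d` are encoded to a Gaussian latent code
(mean `μ`, log-variance `log σ²`, dimension `z ≪ d`). During training the
code is sampled by reparameterization, `z = μ + ε·exp(½ log σ²)` with
`ε ~ N(0, I)`; a decoder reconstructs `x` from `z` and a classification
head maps `z` to a single logit. The loss is

    L = α·L_rec + β·L_kld + γ·L_cls

with `L_rec` the mean squared reconstruction error over all `N·d`
entries, `L_kld = -(1/2N) Σ_n Σ_j (1 + log σ²_j - μ_j² - σ²_j)` the KL
divergence from the standard-normal prior, and `L_cls` binary
cross-entropy computed in the numerically stable logits form (softplus
identities; probabilities are never formed or clipped). With class
weighting on, the positive-class term is multiplied by the
negative:positive count ratio of the training set. `log σ²` is clamped to
[-10, 10] before exponentiation.

Inference is deterministic: encoding returns `μ` and the classification
head consumes `μ`; sampling happens only in training. A prediction tool
must give the same answer twice, and the latent mean is the posterior's
best point summary.

Optimisation is Adam with decoupled weight decay; decay applies to
weight matrices only (not biases or batch-norm parameters). Hidden
layers are residual blocks: two fully-connected layers (in→out, out→out),
each followed by batch normalization and Leaky ReLU (slope 0.01), with an
identity skip when in==out and a single affine skip otherwise. One root
seed drives parameter initialisation (He normal), `ε` draws, and batch
shuffling. When training from an embedding table, minibatches keep
same-protein sites together (their embeddings came from one encoder
pass) while the protein-group order is reshuffled every epoch — fixed
batch membership across epochs measurably hurts held-out performance.

**Scale regimes.** `CvaeConfig`'s class defaults record the
deployed-scale configuration: 2560 → 100 dimensions, learning rate 1e-4,
weight decay 8e-3, α = β = γ = 1 (β = 0.3 is the documented alternative
weighting). The pipeline wrappers (`train_variant`, `denoise_pipeline`)
default to a desk-scale recipe — width 64, latent 8–32, learning rate
1e-3, β = 0.3, 60–150 epochs — sized for the synthetic study conditions
(hundreds to thousands of samples, 64 features). Two desk-scale findings
shaped these defaults: (1) with few samples, long or strongly
label-coupled training memorises the training labels (training AUROC
reaches 1.0 while held-out performance collapses), so schedules are
deliberately short; (2) in the denoising pipeline the same memorisation
is qualitatively harmful, not just wasteful — see below.

## Downstream heads and the four variants

`dnn_linear` is an affine+batchnorm+LeakyReLU stack ending in a
single-logit layer; `res_dnn` replaces the stack with `num_blocks`
residual blocks whose widths cycle through `layer_dims`. Both train with
stable-logits binary cross-entropy and optional minority-class
weighting. The four deployable variants — DNNLinear, ResDNN, and each
behind a cVAE front end — share one predictor surface
(`predict_proba`, `predict_logits`, `input_gradient`) and one checkpoint
layout, so evaluation and attribution treat them uniformly.

## Denoising

Negative labels in site data are unverified; some are unobserved true
sites. The two-stage pipeline targets them:

1. **NCR on raw features** — remove majority-class samples whose k-NN
   vote classifies them as minority, plus majority neighbours implicated
   in misclassifying a minority sample. The minority class is never
   removed.
2. **ENN on latent codes** — fit the cVAE on the stage-1 survivors,
   encode them to latent means, and remove any sample (either class)
   whose k-NN vote there disagrees with its label, in one simultaneous
   pass against the unedited set.

Distances are Euclidean on per-feature standardized coordinates, with
ties broken toward the lowest index, so reports are exactly reproducible.
Vote ties keep the sample: a tie is not evidence of mislabeling.

Defaults: k = 7 for both stages. With a ~1:6 imbalance in
high-dimensional features, 3-neighbour votes proved too noisy — across
generator seeds they intermittently either missed planted flips or
removed >10% of the clean minority, while k = 7 passed the same sweep
with margin. The stage-2 cVAE default (β = 0.3, γ = 1, 150 epochs,
lr 1e-3) balances two failure modes observed directly on the generator:
a latent space trained too long around the observed labels places
mislabeled points on their observed-label side, hiding them from the
editor; one trained with too little label signal (γ → 0) produces a
diffuse latent whose votes remove clean minority wholesale.

## Evaluation

Predicted positive means score ≥ threshold, boundary inclusive — fixed
so that the deployment threshold (DT = 0.4) is unambiguous. Metrics are
the standard precision, recall, F1, accuracy and Matthews correlation;
any 0/0 cell reports 0 and is flagged `degenerate` rather than raising,
because threshold sweeps hit empty cells routinely. ROC points are taken
at every unique score with ties grouped; the trapezoidal area equals the
Mann–Whitney probability estimate. The precision–recall area uses the
step-wise average-precision convention. The fixed-FPR evaluator returns
the smallest threshold whose achieved false-positive rate is at most the
target, with the achieved rate reported; an unreachable target returns a
threshold above the maximum score, flagged. Threshold-free metrics are
invariant to the thresholding strategy by construction.

The DeLong test for two correlated AUROCs uses midrank structural
components and a two-sided normal p-value; zero estimated variance with
zero difference (identical scores) reports p = 1, flagged degenerate.
Stratified k-fold splitting and the hyperparameter search objective
(mean validation MCC) wrap scikit-learn's splitter and a seeded random
search over the architecture/regularisation space; failed trials are
logged and skipped.

## Attribution

Integrated gradients on the logit (pre-sigmoid) output: sigmoid
gradients saturate for confident predictions, logit gradients do not.
The path integral from a zero baseline (the stated convention) is
approximated with a midpoint Riemann sum, default 64 steps, 256 for
audits; the completeness gap `|Σ_i IG_i − (F(x) − F(0))|` is reported
per site.

A numerical caveat documented here because it is easy to misread as a
bug: for Leaky-ReLU networks the integrand's derivative is a step
function, so the quadrature error is O(1/n_steps) with a constant set by
the network's slope variation along the path (its activation-kink
jumps), not the O(1/n²) a smooth model would give. Gradients were
verified exact against finite differences, and the gap falls to ~4e-6 at
131k steps. Consequently the sub-1e-3 completeness audit uses a compact,
strongly weight-decayed residual head (width 4, decay 10), which trains
to a near-linear function with mild kinks; attributing a large trained
model to the same absolute tolerance requires proportionally more steps,
which `n_steps` exposes.

Feature ranking reports mean |attribution| per feature (ties to the
lower index) with a sign-consistency fraction — the share of sites on
which the feature pushes in its dominant direction. Cross-method rank
agreement is Spearman correlation with average-rank ties and the
two-sided t-approximation p-value.

## Synthetic data: what it emulates and what it does not

The generator draws negatives from N(0, I) and positives from
N(δ·u, I), with u a unit vector on the first m coordinates, so the
optimal (Bayes) AUROC is exactly Φ(δ/√2) — every recovery experiment has
a known ceiling. Label noise relabels a chosen fraction of true
positives as negatives and returns the flip mask, so denoising is scored
against ground truth. Defaults mirror the real regime at desk scale:
dim 64 standing in for 2560, a 1:6 positive:negative imbalance matching
the ~182k:1.1M site counts of the curated databases, δ = 3, 15% flips.
One root seed drives every draw in a fixed order.

What passing these tests shows: the losses, editors, metrics, and
attribution are implemented correctly, and the pipeline recovers known
structure under the stated statistical shape. What it does not show:
performance on real language-model embeddings, whose geometry is
anisotropic, clustered and sequence-correlated — nothing here simulates
that, deliberately. Claims about real-data accuracy require real data.

## Problem sizes

Tests and the acceptance script run the method at n = 600–2,000 samples
and 2–64 features with the schedules above; each training run takes
seconds on one CPU. These sizes were chosen so the statistical questions
(recovery of a known AUROC, removal of planted noise) are answerable
with stable margins at interactive runtimes.

## Known limitations

- The numpy network core is CPU-only and eager; it is sized for the
  desk-scale models here, not for 2560-dimensional production training.
- The k-mer containment identity is not an alignment; at very short
  lengths (< k) it reports 0.
- The hyperparameter search is a seeded random search; no adaptive
  (model-based) engine is shipped.
- ENN's both-classes editing in latent space is a documented choice; the
  editors expose `classes_to_edit` for the majority-only alternative.
- The completeness audit tolerance applies to compact heads as described
  above.
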