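# Methods

`claimpt` models longitudinal administrative claims — per patient a
date-ordered sequence of visits, each carrying a visit type (inpatient `IP`,
outpatient `OP`, pharmacy `RX`) and sets of diagnosis/procedure/medication
codes — with a two-stage pipeline: unsupervised pre-training of a
transformer encoder on a large unlabeled corpus, followed by supervised
fine-tuning of a small linear head (plus, optionally, the encoder body) on a
small labeled cohort. This note records the model, the choices that were
genuinely open, the synthetic data the package is validated on, and what the
tests do and do not establish.

## Encoder

**Visit embedding.** Each medical code is a row of a single embedding table
over the concatenated DIAG/PROC/DRUG index space (one out-of-vocabulary slot
per channel). A visit stacks the rows of its codes, one visit-type row, and
one date-bucket row, and takes the element-wise maximum. Max-pooling is the
only reading of "pool the within-visit features" that returns one d-vector
per visit and is exactly invariant to code order; the tests assert that
invariance bitwise.

**Date encoding.** Claims sequences are unevenly spaced, so the temporal
signal is the *gap* to the previous visit, bucketed into
{0, 1–7, 8–30, 31–90, 91–365, >365} days (first visit → bucket 0) and
embedded. No other positional encoding is used: order information enters
through the causal mask during pre-training and through the date buckets.

**Demographic token.** Gender (M/F/U) and age at first visit (annual buckets
0–18 plus 19+; the target population is pediatric) are one-hot concatenated
(width 23) and linearly projected to d. This token is prepended to the visit
sequence and its output state is the patient representation `pe`.

**Transformer.** Post-norm blocks: multi-head scaled dot-product attention
(forbidden positions get −10⁹ pre-softmax, so their weight is exactly 0
after normalisation), residual + layer norm, a position-wise feed-forward
layer, residual + layer norm. Defaults follow the published training setup:
width d = 100, 1 layer, 4 heads, feed-forward width 100. Two mask modes
share all weights: CAUSAL (position i attends to ≤ i; used for the
autoregressive objective) and BIDIRECTIONAL (used wherever a whole-sequence
summary is needed — category prediction, fine-tuning, probes). The source
formulation is ambiguous here: its autoregressive objective conditions on
the past only, while `pe` sits at position 0, which a causal mask would
blind. Sharing one body across both masks is the resolution implemented.
Sequences are truncated to the most recent 128 visits.

## Pre-training objectives

**Next-visit prediction (NVP).** Under the causal mask, the hidden state of
visit i scores the whole code vocabulary through a linear layer and a
softmax. A visit holds several codes but the likelihood is written as a
single softmax, so the target is uniform over the codes of visit i+1: the
per-position loss is the mean of −log softmax over those codes, averaged
over all positions with a successor. A multi-label sigmoid variant was
rejected to keep the stated softmax form.

**Categorial prediction (CP).** Each visit's bidirectional hidden state
predicts the set of grouper categories (CCS-style for DIAG/PROC, drug-class
for DRUG) of its own codes through independent sigmoids; the loss is binary
cross-entropy averaged over categories and visits. This injects the grouper
ontology and counteracts rare-code sparsity.

**Training loop.** Total loss = NVP + λ·CP (λ = 1; no weighting is given in
the source). RMSprop (lr 0.001, decay 0.9, eps 1e-8), minibatch 100
patients, up to 1000 epochs, 80/20 patient-level train/validation split,
dropout 0.1 on both sub-layer outputs, L2 penalty 1e-5 (excluding the head
of a disabled objective so it stays bit-identical to its initialisation),
early stopping on validation total loss with patience 10, best-validation
parameters returned. Minibatches group patients of similar sequence length
(within the epoch's shuffled order) to keep attention padding small; this
changes batch composition but is deterministic under the run seed. On the
default synthetic corpus validation NVP bottoms out after roughly 5 epochs
and then overfits, which is exactly what early stopping handles.

## Fine-tuning and probes

The added head is a d×2 linear layer + softmax on `pe` — 202 parameters at
d = 100. Protocol per the published setup: 20 epochs, 70/30 train/test
split, 5 repeats with repeat-specific splits, mean AUC reported. Four modes:

* `FULL_FINETUNE` — head and body both update;
* `PROBE_START` — body frozen, head on `pe`;
* `PROBE_POOL` — body frozen, head on the element-wise max (or mean, by
  flag) of the visit hidden states;
* `FROM_SCRATCH` — body re-initialised, trained end-to-end on the cohort
  alone (the no-pre-training control).

Unstated hyperparameters were fixed as follows: batch 64; body lr 3e-4
(below the pre-training 1e-3, the usual fine-tuning practice), head lr
1e-2. With a randomly initialised head, 20 epochs on a few hundred patients
is not enough for joint RMSprop training to converge, so fine-tuning warms
up by fitting the head to convergence (L2-regularised logistic regression)
on the frozen initial representations before the joint epochs — the
standard "linear probe, then unfreeze" schedule. Probe modes use that same
converged logistic fit; a head trained on frozen representations is the
only coherent reading of a zero-shot variant that still outputs scores.
`FROM_SCRATCH` goes through the identical schedule, so arm differences are
attributable to initialisation, not protocol.

Checkpoints store the vocabulary and grouper with content hashes;
fine-tuning and scoring refuse a vocabulary whose fingerprint differs from
the checkpoint's.

## Synthetic data

No public claims corpus at the required scale exists (real pediatric
Medicaid extracts are restricted), so the package ships a generator that
reproduces the statistical structure the model must exploit, calibrated to
the published corpus statistics: 10.4 visits/patient (1 + Poisson), 2.8
codes/visit (1 + Poisson), 49.8% male, age at first visit uniform 0–18,
log-normal inter-visit gaps (median 30 days, σ = 1 log-day — the source
states only that gaps are uneven).

Structure: each patient follows a first-order Markov chain over 4 latent
health states (self-transition 0.7). States condition the visit-type
distribution (sicker states are more inpatient-heavy) and the per-channel
code distributions: a global Zipf(1) long tail mixed (weight 0.7) with a
state-specific preferred subset, drawn without replacement within a visit.
Categories are contiguous blocks of the frequency-ranked code list, so every
code has exactly one category. The downstream label is
Bernoulli(sigmoid(6·(f − ¼))) where f is the fraction of visits spent in
the designated high-risk state; at the default scale this gives a
Bayes-optimal AUC ≈ 0.81 and places the from-scratch arm mid-range, leaving
headroom to measure a transfer gain. `label_effect = 0` yields exactly
chance-level labels (the null used in tests). Default corpus: 5,000
patients, 500 codes (300/120/80 per channel), 25 categories — sized so the
full pipeline runs in CPU minutes.

Transfer pairs share the code space and grouper; corpus B's state-
conditional code distributions are a linear mixture of corpus A's tables
(weight = overlap) and independently drawn tables, so overlap 1 emulates a
held-out slice of the same institution and overlap 0 a foreign one. The
generator exposes its parameter tables, letting tests compute
state↔code mutual information and total-variation distances exactly.

**What the simulator does not model:** real ICD/CPT/NDC code semantics,
comorbidity structure, insurance churn, coding drift over time, costs, and
visit-level label mechanisms. Passing tests show the pipeline recovers the
*kind* of structure it assumes (latent-state co-occurrence, temporal
correlation, ontology consistency); they do not certify performance on real
claims.

## Numerical choices

The network and training loops run on a small reverse-mode autodiff core
over numpy float32 (`claimpt._tensor`), with fused softmax/cross-entropy,
sigmoid-BCE and layer-norm primitives for stability and speed; gradients of
every primitive are checked against central differences in float64. Visit
pooling uses a flat segment-max over real code rows rather than a padded
4-D block (code counts are long-tailed; padding would dominate memory).
Attention mask value −10⁹; layer-norm ε 1e-5; max-pool gradient splits
evenly across ties. AUC is the Mann–Whitney form (ties = ½) via
scikit-learn; baselines are L2 logistic regressions on code or category
count vectors. All randomness flows from per-component seeds derived by
hashing a master seed with the component name, so adding a component never
shifts another's stream; repeated runs are bit-identical up to wall-clock
columns.

## Known limitations

* `pe` receives no direct pre-training gradient (position 0 is outside both
  objectives), so the first-token probe is the weakest arm; pooled visit
  states probe consistently higher — consistent with the published
  observation that the pooled zero-shot variant wins — and on unlucky small
  cohort draws the pooled probe can edge out full fine-tuning.
* Expenditure variables, attention-based interpretation, multi-class or
  visit-level heads, and bootstrap confidence intervals are out of scope.
* Single-threaded CPU implementation; corpus sizes in the millions of
  patients would need a GPU backend.
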