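# claimpt

Pre-train/fine-tune transformer modelling of longitudinal medical claims,
with a calibrated synthetic claims simulator.

## The problem

Administrative claims databases hold millions of patient histories, but any
*population-specific* prediction task — suicide-risk screening, asthma
exacerbation, and the like — survives cohort selection with only a few
hundred labeled patients, far too few to train a sequence model from
scratch. `claimpt` implements the two-stage answer: learn a general patient
representation from the whole unlabeled corpus, then adapt it to each small
cohort with a minimal task head.

A patient is a date-ordered sequence of visits v₁…v_T, each a set of
medical codes (diagnoses, procedures, drugs) plus a visit type (IP/OP/RX)
and service date. The encoder embeds every visit as

    e_t = maxpool([E_diag; E_proc; E_drug; E_util; E_date]),

prepends a demographic token, and applies a transformer layer

    pe, ê_1, …, ê_T = TransLayer([E_demo; e_1, …, e_T]),

where `pe`, the hidden state of the demographic token, is the patient
representation. Pre-training optimises two objectives jointly:

* **NVP** (next-visit prediction): under a causal mask, ê_i scores the full
  code vocabulary with a softmax; the target is the set of codes of visit
  i+1 (mean cross-entropy, L = −Σᵢ log P(v_{i+1} | v₁…v_i));
* **CP** (categorial prediction): each visit's category set under a
  code→category grouper (CCS-style for diagnoses/procedures, drug classes
  for medications) is predicted from ê_i with per-category sigmoids,
  injecting ontology knowledge against rare-code sparsity.

Fine-tuning adds a d×2 linear head on `pe`, P(y | v₁…v_T) = softmax(pe·W_pe),
and ships four regimes: full fine-tuning, two frozen-body probes ("start" =
head on pe, "pool" = head on max-pooled visit states), and a from-scratch
control. Evaluation follows the small-cohort protocol: 70/30 splits, 20
epochs, 5 repeats, mean AUC.

Real pediatric Medicaid corpora are access-restricted, so the package
includes `claimpt.synthetic_claims`: a latent-health-state Markov simulator
whose corpora match the published marginals (≈10.4 visits/patient, ≈2.8
codes/visit, 49.8% male, uneven log-normal visit gaps, long-tailed codes,
deterministic code→category map, labels driven by the latent state). All
experiments in the test suite run on it end-to-end on one CPU. The neural
network runs on a small numpy reverse-mode autodiff core bundled with the
package (`claimpt._tensor`) — no deep-learning framework required.

## Worked example

```python
from claimpt.data_model import build_vocabulary, cohort_from_labels
from claimpt.encoder import Checkpoint
from claimpt.finetune import FULL_FINETUNE, FROM_SCRATCH, FinetuneConfig, finetune
from claimpt.pretrain import PretrainConfig, pretrain
from claimpt.synthetic_claims import SimulationConfig, simulate_population

records, grouper, truth = simulate_population(SimulationConfig(n_patients=5000, seed=11))
vocab = build_vocabulary(records, min_count=1)
params, trace = pretrain(records, PretrainConfig(max_epochs=30, seed=3), vocab, grouper)
ckpt = Checkpoint(params=params, vocab=vocab, grouper=grouper)

cohort = cohort_from_labels(records, n_cases=160, control_ratio=2.0, seed=5)  # 480 patients
for mode in (FULL_FINETUNE, FROM_SCRATCH):
    res = finetune(cohort, ckpt, FinetuneConfig(mode=mode, seed=5))
    print(mode, round(res.mean_auc, 3))
```

Output:

```
FULL_FINETUNE 0.712
FROM_SCRATCH 0.615
```

The pre-trained model beats the identically trained from-scratch control by
~0.10 AUC on a 480-patient cohort — the core transfer effect. (The
Bayes-optimal AUC of this synthetic task is ≈0.81; a bag-of-codes logistic
baseline lands near 0.69.) The same pipeline is scriptable from the shell:

```bash
claimpt simulate --seed 11 --out corpus/
claimpt pretrain --claims corpus/claims.jsonl --grouper corpus/grouper.tsv --epochs 30 --out run/
claimpt finetune --cohort cohort.jsonl --ckpt run/ckpt --mode full --out ft/
claimpt embed --ckpt run/ckpt --what codes --out codes.tsv   # t-SNE-ready export
```

`claimpt ablate` (input channels or objectives) and `claimpt transfer`
(matched vs shifted corpus pairs) reproduce the experiment designs; every
run writes a manifest with config, input hashes and the seed fan-out.

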