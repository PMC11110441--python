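# biochemlm

Generative design of active compounds with desired potency from target
protein sequences, using a dual-component "biochemical" language model.

## The problem

Given only a target's amino-acid sequence and a desired potency level, can a
model propose compounds that are active against that target at that potency?
`biochemlm` implements a conditional machine-translation approach to this
question, aimed at computational chemists who want to study
sequence-conditioned molecule generation end to end at desk scale:

1. **Protein language model component** — a frozen, inference-only sequence
   embedder produces one fixed-size vector per target (mean-pooled along the
   sequence). The package ships a deterministic k-mer-profile embedder so
   everything runs without downloads; a ProtT5 adapter can be plugged in
   where the ProtTrans weights are available.
2. **Conditional transformer component** — a three-encoder-layer /
   three-decoder-layer transformer reads the pair

   *(protein sequence embedding, potency embedding)* → *(compound)*

   and autoregressively decodes a SMILES string by multinomial sampling.
   Potency values pKi = −log10 Ki are discretized into 852 conditioning
   tokens of width 0.01 pKi units over the range [4.00, 12.52]; each token
   has its own learned embedding. An unconditional variant
   *(protein embedding)* → *(compound)* serves as the control for the effect
   of potency conditioning.

Around the model, the package implements the full protocol:

- **Curation** (`biochemlm.curation`): activity tables are filtered to direct
  binding assays ("D") at the top confidence level (9) with numeric Ki and a
  target sequence of ≤ 4000 residues; replicate Ki values are aggregated by
  geometric mean when they agree within one order of magnitude, otherwise
  the compound is excluded; compounds are grouped into target-based activity
  classes with canonical SMILES identity.
- **Structurally disjoint splitting** (`biochemlm.series`): analogue series
  are found by matched-molecular-pair-style fragmentation under
  retrosynthetic cut rules (up to five substitution sites; the core must
  carry at least twice the heavy atoms of all substituents combined), then
  randomly halved into fine-tuning/test sides with disjoint core structures;
  the side with fewer compounds fine-tunes.
- **Training** (`biochemlm.training`): teacher-forced cross-entropy with
  Adam, micro-batch 1 with gradient accumulation, per-epoch checkpoints, and
  selection of the minimum-loss checkpoint; pre-training on pooled
  target–compound triples, then full fine-tuning per activity class.
- **Evaluation** (`biochemlm.evaluation`): up to 100 valid candidates are
  sampled per test instance at the instance's experimental potency; reports
  cover exact reproduction of held-out compounds (the most stringent
  criterion), 1-nearest-neighbor Tanimoto similarity on 2048-bit Morgan
  fingerprints (radius 3), Welch t-tests across potency distributions, and
  synthetic-accessibility score distributions.
- **Synthetic fixtures** (`biochemlm.fixtures`): a seeded toy world of
  scaffold+substituent compounds with an additive potency rule,
  pKi = base(target) + Σ contribution(substituent) + noise, so that every
  stage — including whether conditioning helps — is testable against known
  ground truth.

## Worked example

```python
from biochemlm import (ToyWorldConfig, generate_world, group_series,
                       split_series, learnability_probe)

world = generate_world(ToyWorldConfig(seed=0))
print(len(world.triples))           # 180 target-compound-pKi triples, 3 targets

focal = world.triples[0].target_id
pki = world.pki_lookup(focal)
series = group_series(list(pki), pki=pki)
print(len(series))                  # 6 analogue series of 10 members each

split = split_series(series, seed=0)
print(len(split.finetune_compounds), len(split.test_compounds))   # 30 30

report = learnability_probe(seed=0)  # trains + samples; a few minutes
print(report.summary()["reproduced"])
# {'conditional': 6, 'unconditional': 5, 'no_finetune_control': 0}
```

The last line is the package's core result in miniature: after pre-training
on the other targets and fine-tuning on one half of the focal class, the
fine-tuned models exactly reproduce held-out test compounds they have never
seen (6 of 30 for the potency-conditioned model here), while the
pre-trained model without fine-tuning reproduces none. At this desk scale
the conditional-vs-unconditional count margin is noisy from seed to seed;
see `docs/methods.md` for what desk-scale statistics can and cannot show.

A command-line interface mirrors the pipeline stages:

```bash
biochemlm make-fixtures --seed 3 --out world/
biochemlm curate --activities world/activities.tsv --sequences world/targets.fasta --out classes/
biochemlm split --class classes/T000.tsv --seed 17 --out splits/
biochemlm pretrain --classes classes/T001.tsv --classes classes/T002.tsv \
    --sequences world/targets.fasta --out pre.npz
biochemlm finetune --checkpoint pre.npz --class splits/finetune.tsv \
    --sequences world/targets.fasta --out ft.npz
biochemlm sample --model ft.npz --split splits/ --sequences world/targets.fasta \
    --target T000 --n 100 --seed 3 --out candidates.smi
biochemlm evaluate --candidates candidates.smi --split splits/ --target T000 --out report.json
```

## Scope

The package targets desk-scale experimentation: the default test profile
uses a 128-dimensional model on synthetic worlds. The full-scale profile
(1024-dimensional hidden states matching the ProtT5 embedding width,
learning rate 1e-5, effective batch 64, ≥ 50 epochs) is configuration — see
`docs/methods.md` for what does and does not transfer from desk-scale runs.
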