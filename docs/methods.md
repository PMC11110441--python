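# Methods

This note documents the model, the surrounding protocol, the synthetic data
used for testing, and the numerical and design choices the implementation
makes where the design was genuinely open.

## Model

The generator is a conditional encoder–decoder transformer over multimodal
input. The encoder consumes a length-2 sequence of d_model vectors: the
pooled protein-sequence embedding and the embedding of a potency
conditioning token (length-1 without conditioning, the control variant).
Concatenation along the sequence axis — rather than vector concatenation —
keeps each component at the full model width, so the embedder dimension
must equal d_model; the constructor enforces this. Three encoder layers
(multi-head self-attention + position-wise feed-forward, post-layer-norm
residuals) produce the memory; three decoder layers (causally masked
self-attention, cross-attention to the memory, feed-forward) decode SMILES
tokens autoregressively. Sampling is multinomial at temperature 1.0 from
the decoder softmax, one token at a time until the end token or a length
cap.

Choices that the architecture description leaves open, fixed here:

- n_heads = 8 and d_feedforward = 4 x d_model (standard transformer
  defaults; the desk profile uses 2 heads at d_model 128),
  dropout 0.1 on sublayer outputs and input embeddings.
- Decoder positions use fixed sinusoidal encodings; the (at most two)
  encoder positions use learned vectors.
- The potency table is a separate 852-row embedding table, not a slice of
  the SMILES token table (they are different vocabularies); no weight tying
  anywhere. Rows are initialised sinusoidally over the bin index (and stay
  trainable): bins are ordinal, and with random rows the sparse handful of
  examples per 0.01 bin leaves neighbouring bins unrelated — at desk scale
  the model then provably ignores the potency token.
- Output-projection weights are initialised 10x smaller than the other
  linear layers so an untrained model starts near the uniform distribution
  over tokens (the expected initial cross-entropy is then log |vocab|).
- Generation maximum length defaults to 150 tokens, comfortably above the
  longest canonical SMILES in Ki-annotated sets.

The transformer and its gradients are implemented in NumPy on a small
reverse-mode autodiff engine inside the package (`autodiff.py`), with fused
linear and multi-head-attention tape nodes whose hand-derived backward
passes are verified against central differences in the test suite. Training
defaults to float64; each gradient-accumulation group is evaluated as one
padded batched forward pass whose gradient equals accumulating
micro-batch-1 gradients to machine precision (asserted in the tests).
Generation casts weights to float32 and uses batched incremental decoding
with per-layer key/value caches (mathematically the same network; the test
suite checks the two paths agree to inference precision).

## Tokenization

- Protein sequences: one token per residue, 21-symbol vocabulary (20
  natural amino acids plus `X`). Nonstandard residues (B, Z, U, O, J, ...)
  map to `X`.
- SMILES: greedy left-to-right tokenization; bracket expressions (`[nH]`,
  `[O-]`), two-character halogens (`Cl`, `Br`) and `%nn` ring labels are
  single tokens. The vocabulary is corpus-derived from the training data
  (pre-training plus fine-tuning compounds) with `<pad>/<start>/<end>/<unk>`
  specials; unseen tokens at inference map to `<unk>`. All 852 potency
  tokens are registered regardless of which bins occur in the corpus.
- Potency: pKi values are clamped to [4.00, 12.52] (with a warning — the
  range is the globally observed one, so out-of-range means new data, not an
  error) and binned at width 0.01: index = floor((pKi − 4.00)/0.01 + 1e−9),
  the top bin closed so 12.52 → 851. The 1e−9 guard avoids
  binary-representation artifacts at bin edges. Bins are half-open so every
  in-range value has a unique bin and the count is exactly 852.

## Curation

Rows must be direct binding interactions (relationship `"D"`), assay
confidence 9, with a numeric positive Ki (nM) and a target sequence of 1 to
4000 residues; rows without a sequence are dropped with a warning rather
than failing the run. pKi = −log10(Ki·1e−9), kept at 4 decimals internally.
Replicates of one compound against one target aggregate to the geometric
mean of Ki — equivalently the arithmetic mean of per-measurement pKi (the
log identity is asserted in tests) — provided max(Ki)/min(Ki) ≤ 10; "same
order of magnitude" is not defined numerically anywhere, and a factor-10
spread (pKi range ≤ 1.0) is the natural operationalisation. Disagreeing
compounds are excluded. Canonicalisation happens once at ingestion through
a single RDKit canonicaliser; compound identity everywhere downstream is
canonical-string equality. Distinct canonical strings (stereoisomers, salt
forms) are distinct compounds.

## Analogue series and the disjoint split

Fragmentation cuts 1–5 acyclic single bonds drawn from a configurable
retrosynthetic rule list; the default covers amide C–N, ester C(=O)–O,
amine N–C(sp3), ether O–C(sp3), aromatic C–sp3 C and sulfonamide S–N
environments. This is a deliberate, documented simplification of the full
published retrosynthetic rule collections; the rule list is a parameter.
A cut combination is valid when exactly one fragment (the core) touches
every cut and each remaining fragment touches exactly one. Attachment
points are numbered wildcards `[*:1]`–`[*:5]`, renumbered canonically (by
the canonical atom ranking of the map-stripped core) so the same core from
different molecules compares equal; heavy-atom counts exclude the
wildcards. The core-size filter requires heavy(core) ≥ 2 × Σ
heavy(substituents) and is applied per fragmentation. Compounds sharing an
identical canonical core form a series; a compound eligible for several
cores joins the largest resulting series (ties: lexicographically smallest
core string); series of size 1 are disregarded.

The split shuffles series with a seeded generator, assigns half to each
side (odd counts: the extra series to the test side), then labels the side
with the smaller total compound count as fine-tuning. Core sets are
disjoint by construction; the reassembly identity (core + substituents
rebuilds the parent exactly) is asserted over the full fixture corpus.

## Training

Adam, micro-batch 1 with gradient accumulation (the accumulated gradient of
per-sequence losses scaled by 1/N is exactly the gradient of the batch-mean
loss; the equivalence to a true batch-64 update is asserted at 1e−5
relative tolerance). Per-epoch checkpoints; the returned model is the
argmin-loss epoch, earliest epoch on ties. The selection loss is the
training loss — no validation split is prescribed anywhere — and a
validation-based selection can be layered on by the caller; this is a known
deviation risk for overfit-prone corpora. Example order is shuffled per
epoch from the run seed; identical (data, plan, seed) reproduce identical
loss trajectories bitwise. Fine-tuning updates all weights with the same
procedure; epoch count defaults to the pre-training value.

Profiles:

- full-scale: d_model 1024, learning rate 1e−5, effective batch 64,
  ≥ 50 epochs (configuration only at desk scale).
- desk (the probe profile): d_model 128, 2 heads, feed-forward width 256,
  no dropout, float32 arithmetic; pre-training 140 epochs at learning rate
  7e−4 with accumulation 8, fine-tuning 30 epochs at 2e−4; 40 valid
  candidates sampled per test instance (cap 160 attempts). Rates sit below
  the post-layer-norm stability edge (1.5e−3 diverges on the toy corpora);
  the long pre-training run is what makes the model actually use the
  potency token — bin sensitivity keeps growing well after the loss has
  mostly flattened.

## Protein embeddings

Backends satisfy a small protocol (name, dimension, determinism, embed).
The built-in backend counts overlapping 3-mers circularly (the window wraps
around the end), hashes them with CRC-32 into an 8000-slot profile,
projects with a fixed Gaussian matrix drawn from the backend seed, and
L2-normalises. Circular counting makes repetition exact: a sequence
repeated k times scales every circular 3-mer count by k, so the normalised
vector is identical — the discrete analogue of mean pooling's length
invariance. The embedder only needs to separate targets deterministically,
which suffices because the generator receives one pooled vector per target;
it does not model biology. The ProtT5 adapter (mean pooling of the last
hidden state) is inference-only, as is every backend: no embedder state is
ever trained. Embeddings are cached keyed by (backend, sequence hash).

## Synthetic world and the learnability probe

The toy world assembles compounds as aromatic scaffold + substituent pair
via attachment-point chemistry: ten two-site scaffolds of 12-16 heavy atoms
and a pool of 36 substituents of 1-4 heavy atoms, attached through sp3
carbons so the default fragmentation rules recover every planted series
exactly (substituent pairs are capped at 6 combined heavy atoms, keeping
each fragmentation inside the core-size filter). Each class draws its
members from a class-level pool of twelve substituent pairs shared across
its scaffolds — substituents recur across real analogue series in the same
way — so the association between a pair and its potency is visible on
several scaffolds at once. Substituent sets are disjoint across targets,
so activity classes never share compounds and a model that has not been
fine-tuned on a class has never seen its substituent chemistry.

Potency follows an additive structure-activity rule,
pKi = base(target) + sum contribution(substituent) + N(0, 0.1), with
contribution = 0.35 x heavy atoms + a small seeded jitter: substituent bulk
drives potency, a rule shared by every class, so the semantics of the
potency token are learnable during pre-training and only class-specific
details must come from fine-tuning. Values land on a 0.1-pKi reporting
grid — coarser than the 0.01 tokenization bins, as a corpus of realistic
reporting precision covers bins densely at small size. Defaults: 3 targets
x 6 series x 10 members (180 triples; the focal class splits 30/30).
Worlds are pure functions of (config, seed).

What the world does *not* emulate: real SAR landscapes, activity cliffs,
class-size imbalance, heteroscedastic measurement error, or chemistry
outside the small pools. A passing probe demonstrates that the
implementation can learn and exploit potency conditioning when signal
exists — not that the approach works on real assay data at scale.

The probe holds out the first target as the focal activity class, splits it
by analogue series, pre-trains conditional and unconditional models on the
remaining classes (the focal class is entirely absent from pre-training),
fine-tunes each on the focal fine-tuning side, samples candidates for every
test instance at the instance's experimental potency, and counts exactly
reproduced test compounds — including the no-fine-tuning control, which
samples from the pre-trained conditional model directly. Reproduction
requires genuine composition: test compounds pair scaffolds whose
substituted forms were seen only on the fine-tuning side cores' complement
with substituent pairs seen only on other scaffolds.

Desk-scale statistics deserve a caveat stated plainly: per-class
exact-reproduction counts here are single digits (the corpus is ~1000x
smaller than a real ChEMBL extract), so the conditional-vs-unconditional
count comparison carries substantial seed-to-seed noise even though
likelihood probes show the conditional model scores held-out compounds
1.7-4 nats higher under their true potency bin than under bins 0.5 pKi
units away. The no-fine-tuning control is the stable result: with
class-disjoint substituent chemistry it reproduces nothing.

## Numerical and degenerate-input conventions

- Tanimoto over equal-length bit vectors; 1.0 when both are all-zero.
- 1-NN similarity is the per-query maximum over the reference set,
  vectorised as an integer matrix product and asserted equal to the
  brute-force pairwise oracle.
- Potency-distribution comparisons use two-sided Welch t-tests (equal
  variances not assumed) with the star scheme **** ≤ 1e−4 < *** ≤ 1e−3 <
  ** ≤ 0.01 < * ≤ 0.05 < ns; groups smaller than 2 annotate "NA".
- SA scores come from RDKit's shipped fragment-contribution implementation
  (1 = easy to 10 = hard).
- A sampled candidate counts as valid only if its canonical SMILES itself
  re-parses (RDKit can, rarely, canonicalise a parseable string into an
  unparseable one).
- Sampling per test instance stops at 100 valid candidates or 1000 attempts
  (40 and 160 in the desk probe); pooled class-level candidate sets keep
  unique canonical strings, and both unique and raw draw counts are
  reported.

## Problem sizes

Tests and the acceptance script run the desk profile end to end: 180-triple
worlds, 120-triple pre-training corpora, 30-compound fine-tuning sets, 30
test instances with 40 valid samples each, five-seed repetition for the
conditioning comparison. These sizes exercise every stage of the pipeline
in minutes on one CPU; the trade-offs they impose on the reproduction
statistics are discussed above.

## Known limitations

- Checkpoint selection by training loss can pick late overfit epochs on
  tiny fine-tuning sets; the probe tolerates this by sampling broadly.
- The built-in embedder ignores residue order beyond 3-mers; two targets
  with identical 3-mer profiles would collide (vanishingly unlikely for
  random sequences).
- The fragmentation rule list is a practical subset of published
  retrosynthetic rules; molecules whose only cuttable bonds fall outside it
  become singletons.
- Desk-scale results quantify nothing about full-scale behaviour beyond
  qualitative ordering (conditional ≥ unconditional, control ≈ 0).
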