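# Methods

## Task and data model

One screen row ties an ordered drug pair (d1, d2) to a cell line c of tissue
t, with single-drug sensitivities ri1, ri2 (relative inhibition) and a Loewe
synergy score on a [-100, 75] scale. The binary target is Loewe > 5, strictly
— 5.0 itself is negative; the threshold is a parameter so more conservative
cutoffs (>10, >30) are one argument away. Pair order is preserved as stored
(no canonical sorting); an opt-in `canonicalize_pair_order` exists because
synergy is order-symmetric, but the default mirrors how screens are exported.
Replicate (d1, d2, c) rows are kept; `deduplicate` is an optional, logged
filter. Out-of-range Loewe scores warn by default and reject under
`strict_range` — rejecting silently would bias prevalence estimates.

Tissues with fewer than 4,000 rows (strict) are *rare*; the k-shot protocol
treats each rare tissue as an adaptation target and all common tissues,
pooled, as the base training corpus.

## Serialization

The template renders the six feature fields into one sentence block; the
classification prompt is `instruction + " " + sentence + " " + "Synergy:"`.
The sentence block already ends with a period, so the join adds none —
avoiding ".." artifacts that would otherwise enter the token stream. Numeric
fields render from the input file's original strings when present (loaders
keep them in `raw_text`), falling back to the shortest round-trip decimal;
this makes serialization reproducible byte-for-byte across read/write
cycles. Class verbalizers are "Positive" / "Not positive".

## The LM classification stack

The backbone contract is: tokenize, produce per-position hidden states, and
produce next-token distributions. The bundled implementation is a
from-scratch decoder-only transformer — 2 pre-norm blocks, width 64, 4
heads, GELU MLPs, learned positional embeddings, tied LM head — over a
word-level whitespace/punctuation tokenizer fitted to the common-tissue
prompt corpus plus the verbalizers. Rare-tissue words absent from that
corpus map to `<unk>`, the text-side analogue of the tabular models'
unseen-category handling. A pretrained-checkpoint backbone source is part of
the interface but not bundled.

Classification reads a linear 2-logit head off the hidden state of the last
token. Batches are left-padded; position ids count only real tokens
(cumulative attention mask), and pad keys are masked out of attention, which
together make head logits exactly invariant to the amount of padding — the
property the padding-invariance and batch-invariance tests assert at 1e-5.

Fine-tuning is cross-entropy with AdamW (decoupled weight decay on matrices
only, global-norm clipping at 1.0, no schedule), batch size 8, shuffled
deterministically per seed. Defaults follow the regime a pretrained backbone
needs: 4 epochs, learning rate 5e-5, weight decay 0.01. The from-scratch
tiny backbone starts from random weights, so its preset raises the learning
rate to 1e-3 and, for k-shot fine-tuning only, multiplies the epoch count by
4 (16 passes over ≤128 examples); at 5e-5 × 4 epochs a random-initialized
2-layer model barely moves. Deeper k-shot training (24–32 epochs) was not
better on held-out data — it memorizes shot noise — so 16 is the default.

Zero-shot semantics differ by path, deliberately: a never-trained head is
pure noise, so the direct path scores k=0 by verbalizer likelihood — p =
L("Positive") / (L("Positive") + L("Not positive")), each verbalizer
teacher-forced after the prompt — while the two-stage path uses its stage-1
head. Stage 1 trains on pooled common tissues with an 80/20 stratified
holdout and keeps the epoch checkpoint with the best validation AUPRC
(AUPRC, not AUROC, because the label is heavily imbalanced).

## Tabular baselines

Both baselines build their categorical vocabularies from common-tissue data
only and never see tissue as a feature: the model is evaluated on a tissue
absent from training, whose indicator could carry no information.

* Gradient-boosted trees (XGBoost): one-hot drugs and cell line plus the two
  raw sensitivities; boosting rate 0.3, 1,000 trees, depth 20. Trees admit
  no gradient fine-tuning, so the k-shot update is *continued boosting*: 50
  extra rounds at the same rate fit on the shots, starting from the
  common-tissue ensemble (full retraining on common + shots is available via
  `retrain_from_scratch`). Unseen categories encode as all-zero blocks.
* TabTransformer: shared drug-embedding table for both drug slots plus a
  cell-line table and slot embeddings (index 0 reserved for unknown), 6
  attention layers of 8 heads over the 3 category tokens (embed dim 32),
  contextual embeddings flattened and concatenated with sensitivities
  standardized to common-tissue moments, then a feed-forward 2-logit head.
  Learning rate 1e-4, weight decay 0.01, 50 common-tissue epochs with
  best-validation-AUPRC checkpointing, one-epoch k-shot fine-tuning. Depth,
  width and head count follow the original TabTransformer configuration;
  standardizing the continuous features is standard practice and is logged.

## Splits, shot plans, metrics

Per rare tissue: one stratified 80/20 split per seed. "Equally represented"
labels are read as *proportional* stratification (test class ratios mirror
the tissue) — a forced 50/50 is impossible at the observed imbalance.
Integer allocation uses largest-remainder rounding with a floor of one test
example per present class. Shot sets take prefixes of per-class
permutations of the training pool, so nesting (`shots[k] ⊂ shots[2k]`) holds
by construction; per-class counts follow tissue proportions with the floor
that every set of size ≥ 2 contains both classes, the floor overriding
proportionality when the minority share of k rounds to zero. All sampling
streams are seeded per (tissue, seed) so any run is reconstructable from the
JSON shot-plan manifest. Grids exceeding the pool are an error pointing at
`truncate_k_grid`, matching how very small tissues force shorter grids.

AUROC is the Mann–Whitney probability computed from midranks (ties credit
0.5). AUPRC is average precision with tied scores entering as one group —
no trapezoidal interpolation, which overestimates PR area. Both are pure
functions, order-invariant under ties, and refuse single-class test sets;
the experiment runner records such cells as "undefined" rather than a
number. Each k > 0 evaluation fine-tunes from the method's base state — no
accumulation across k beyond the nesting of the shot sets themselves.

## Synthetic screens

The generator writes `loewe = w(d1,d2) + cell_effect(c) + tissue_shift(t) +
ε`. Pair effects are symmetric and shared across tissues — the transfer
premise under test. Each drug carries a latent mechanism class (balanced
across drugs); the class-pair component of `w` sits at one of K(K+1)/2
evenly spaced levels scaled by `pair_effect_sd` (well-separated interaction
regimes rather than a Gaussian cloud, so the calibrated threshold falls
between regimes, not inside one), plus per-pair Gaussian scatter
(`pair_noise_frac`). Tissue shifts are zero for common tissues and Gaussian
for rare ones. Sensitivities are a logistic response of mechanism vector ×
cell-line latent state scaled to [0, 100], written as fixed 3-decimal
strings for byte-stable serialization. Prevalence is calibrated by a
quantile shift of the score distribution (achieved fraction within ±0.02 of
target or the generator errors), then scores are clamped to [-100, 75] with
the clamped fraction logged. With `encode_names`, drug names embed the
mechanism class (`drug017-mechC`), making complementarity learnable from
text alone — the mechanism the serialization pathway is supposed to carry.

Cell effects are centred to zero within each tissue, and the calibration
offset is stored in the ground truth; the recovery oracle regresses
`loewe - offset` on pair and cell indicators under the per-tissue
sum-to-zero constraint, making pair effects exactly identified — on
noiseless rows the refit reproduces them to numerical precision (the suite
asserts < 1e-6; observed ~1e-13).

Presets freeze the study conditions: `smoke` (≤ 2,000 rows), `table1_shape`
(the seven rare-tissue sizes 39/68/213/352/1190/2458/3985 plus a 12,000-row
common pool), `strong_signal` (1,200 common + 400 rare rows, high
signal-to-noise, names encoded, prevalence 0.2 so 128-shot sets hold ~26
positives), and `no_signal` (1,600 + 400 rows, all effect scales zero).

What the generator does *not* emulate: dose–response surfaces (Loewe scores
are consumed, never derived), real marginal distributions of drugs and cell
lines, correlated replicate noise, and any chemical or genomic structure
beyond the latent classes. Passing tests therefore demonstrate that the
pipeline's machinery — serialization, padding, shot protocol, transfer,
metrics — behaves correctly and that the text pathway can carry signal; they
say nothing about accuracy on real screens, which depends on a pretrained
backbone and real data.

## Problem sizes and numerical choices

The shipped experiments are sized for a single CPU: tiny backbone (2×64),
1,200–1,600 common rows, 400-row rare tissues, 3–5 replicate seeds. The
learnability benchmark's operating point (mean k=128 AUROC ≈ 0.8 for the
tiny backbone) is a property of these frozen conditions. Determinism is
end-to-end: every stochastic step (splits, shots, init, batch order,
boosting) draws from a generator seeded by the run seed; two runs with the
same seed are bit-identical. Degenerate inputs are handled explicitly:
single-class tissues log a warning and their test cells are reported
undefined; empty shot lists return the base model; all-equal generator
scores warn about single-class output.

## Known limitations

* The tiny backbone has no pretraining, so its verbalizer zero-shot is
  noise around 0.5 by design; only the two-stage path has meaningful k=0.
* Stage-1 checkpoint selection uses a single stratified holdout, not
  cross-validation; with very small validation sets AUPRC is coarse.
* Continued boosting for the tree baseline is one reading of tabular
  "fine-tuning"; the alternative (full retrain on common + shots) is
  implemented but not default.
* The closed-API fine-tuning path for hosted models is out of scope; the
  backbone contract is the seam where such a model would plug in.
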