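# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, what the synthetic data does and does not
emulate, and the numerical conventions the tests rely on.

## Pipeline and conventions

Coordinates are 0-based with half-open spans everywhere; PubTator
character offsets are converted at read time against a deterministic
tokenizer (word runs `\w+`, single punctuation, sentences split after
`.` `!` `?`). Mentions that overlap within a sentence or cross a
sentence boundary are rejected — the `&`-marker wrapping scheme is
ill-defined for them — with a per-document report rather than a silent
drop. Documents with more than `N` entities are rejected at load; `N`
is the pair-matrix size and a model constant.

The marked sequence wraps every sentence in `[CLS] ... [SEP]` and every
mention in a pair of `&` tokens; the *leading* `&` row is the mention
representation. Total length is exactly
`Σ len(sentence) + 2·#sentences + 2·#mentions`, and marker insertion is
independent of the order in which mentions are listed.

## Reference encoder

An embedding table plus a learnable mixing window of half-width `k`
(default 1): row `i` is `Σ_j w_j · E[t_{i+j}]`, zero-padded at the
edges, followed by layer normalization with learnable gain/bias. With
`k = 0` and normalization off the encoder is a pure table lookup, which
the tests use as an oracle. The window is what lets a leading `&`
absorb the adjacent surface or trigger token, and a `[CLS]` absorb its
sentence opening. An external pre-trained encoder can replace this
through `encoding.EncoderProtocol` (anything mapping a marked sequence
to a row-aligned matrix of the configured width); none ships with the
package, and long-document windowing is that adapter's concern.

## Hierarchical tree graph

Node features: sentence = its `[CLS]` row; document = mean of retained
sentence features; mention = its leading `&` row; local context =
elementwise max over the region's token rows, where regions are the
maximal runs of non-mention tokens bordering a mention (a run between
two mentions attaches to both; empty runs are omitted; control tokens
never enter a region). Sentences without mentions contribute no nodes.

The graph convolution uses one weight matrix per edge type *and
direction* (6 relation matrices per layer) plus a self matrix, with
`c_nr = |N_n^r|` normalisation over set-valued neighbourhoods and ReLU.
The per-layer concatenation `[h^(0); ...; h^(L)]` includes the input
state (the layer index starts at zero) and a learned linear projection
restores `d_emb`, since downstream pooling and the pair matrix consume
`d_emb`-width vectors. Default depth `L_g = 2`: two hops connect a
mention to its sentence's other mentions and to the document node.
The graph depth and the RS depth are independent hyperparameters.

## Pair matrix and relation segmentation

Entity vectors are logsumexp pools of their mention vectors (max-shift
for stability; gradient is the softmax weighting). Entities are ordered
by first mention position. The pair matrix is `N x N x D` with cell
`(s, o) = e_s ⊙ e_o`, the diagonal computed but never scored, and a
boolean mask marking the `n_e x n_e` valid block; padding cells are
exactly zero and are re-zeroed after every RS block.

Each RS block is conv(5×5, same zero-padding, D→D channels) → BatchNorm
→ ReLU → criss-cross attention. Choices that the published block leaves
open, and how they are resolved here:

- **Attention weights.** Learned query/key projections (width `D/2`),
  scaled dot-product affinities over the row∪column set, softmax,
  learned value projection. The self cell, which appears in both its
  row and its column, enters the softmax once (a `2·n_e − 1` set); a
  residual connection adds the aggregate to the input. Both the
  residual and the projections are config-toggleable.
- **`W_M`.** A `D x D` channel-mixing linear map (not a scalar gate).
- **BatchNorm statistics** are computed over the *valid* cells only and
  running averages are used at evaluation. Including padding cells
  would make the statistics depend on how much padding a document
  happens to have — which both breaks invariance of valid-cell outputs
  to enlarging `N` and injects document-size noise into evaluation.
- **Initialization** is identity-leaning: `W_M = I + ε`, conv kernels a
  centered delta plus noise, small value projections. The stack then
  starts near a pass-through and learns deviations; with plain random
  init the randomly mixed features slow optimization markedly at this
  model size.
- **Dropout 0.25** on post-ReLU features inside each block (training
  only, inverted scaling, seeded). At desk-scale corpus sizes the pair
  table is expressive enough to memorise training pairs; dropout was
  the one regulariser that reduced held-out variance without hurting
  fit (weight decay and a block-level residual were tried and made
  generalisation worse).

Padding never influences valid cells: masked softmax, masked
normalisation statistics and per-block re-zeroing together make
valid-cell outputs invariant to enlarging `N`, which a dedicated test
checks.

## Classifier, loss, decoding

`z_s = tanh(W_s e_s + M_so)`, `z_o = tanh(W_o e_o + M_so)`, per-label
bilinear logits `z_s^T W_r z_o + b_r` over the relation vocabulary plus
the threshold class TH. Losses and decoding operate on raw logits; the
sigmoid is applied only when probabilities are requested. The
adaptive-threshold loss is the per-pair sum of L1 (softmax over the
positive set plus TH) and L2 (softmax over the negative set plus TH),
averaged over valid off-diagonal ordered pairs; the negative set is all
non-gold labels of the pair. An empty positive set contributes L1 = 0
exactly. A pair with `k` positives has an intrinsic L1 floor of
`k·log k` because the positives share one softmax — the loss can reach
zero only for single-label pairs, which is how the loss/decode
consistency test is phrased. Decoding predicts `r` iff
`logit_r > logit_TH` strictly; ties are not predicted.

Masked softmax terms use an additive −1e30, which underflows to exactly
zero mass in double precision, so the closed forms (L1 = 0, the
two-way-tie `log 2`) hold to 1e-9 rather than approximately.

## Metrics

Micro precision/recall/F1 over (document, head, tail, label) instances.
TNR (specificity) counts pair-level negatives: a pair is negative iff
it has no gold label at all, and a false positive iff any label is
predicted for it; a label-level variant was considered and rejected as
the default because multi-label pairs would then be counted partly
negative. A gold instance is *intra* iff some sentence contains a
mention of both entities, else *inter*; the class F1s restrict both
gold and credited predictions to pairs of that class. Ordered pairs are
scored independently in both directions.

## Training

Adam (lr 2e-3, β = 0.9/0.999), one document per optimization step,
early stopping on dev micro-F1 with patience 15 within a 100-epoch
budget, ties between equal dev scores resolved to the later (more
converged) checkpoint. The learning rate was raised from an initial
1e-3 because the full model plateaued there while converging cleanly at
2-3e-3. All randomness flows through one seeded generator; checkpoints
store every parameter group, the BatchNorm running statistics, the
vocabulary, the config and the per-epoch log, and reloading reproduces
evaluation bit-for-bit.

Problem sizes used throughout (a desk-scale choice): d_emb 32, N = 8,
L_g = L_rs = 2, corpora of 96 documents split 64/16/16. A full
training run takes ~10-30 s on one CPU; the three-seed paired ablation
experiment ~2-3 minutes.

## Synthetic data: what it emulates, what it does not

Each document: 3-6 sentences, 3-6 entities over three concept-type
pools (variant/gene/disease-like), 1-3 mentions per entity with an
alias surface used with probability 0.5 (exercising multi-mention
logsumexp pooling), filler tokens from a 40-token vocabulary. At most
one trigger fact per sentence (`head-mention trigger tail-mention`)
creates the intra-sentence instances; the gold set is closed one step
under the composition rule (associates ∘ contributes → causes), and
composed pairs are kept strictly inter-sentence — mention placement
never lets both ends co-occur. The conclusion label has no trigger rule
of its own, so composed instances cannot be recovered per-sentence.
Label noise, when enabled, *drops* gold instances rather than
relabelling them (relabeling would create contradictory supervision).
Deeper-than-one-step closure is deliberately not applied.

Not emulated: realistic biomedical language, the class priors or entity
densities of CDR/GDA/BioRED, nested/overlapping mentions, coreference,
annotation errors beyond uniform dropping. Passing on this generator
shows the machinery is correct and that the architecture can learn
compositional inter-sentence structure at small scale; it does not
certify benchmark-level performance on real corpora.

One finding worth stating plainly: under these conditions the
no-RS ablation is itself strong on composed instances, because two
graph-convolution hops already carry the bridge entity's surface into
both end-entity embeddings and the bilinear classifier can match them.
The full model's inter-F1 advantage over that ablation is therefore
modest and seed-sensitive — the paired comparison holds on average at
the evaluated seeds but is not a large-margin effect, and the ablation
experiment should be read as directional, not as a magnitude claim.

## Known limitations

- The reference encoder is not a language model; its job is to give the
  pipeline a differentiable, deterministic stand-in with just enough
  context width.
- One composition step only; chains needing three or more hops are out
  of the generator's scope.
- The autodiff core implements exactly the operations this model needs;
  it is not a general framework (no broadcasting matmul beyond numpy's
  rules, no higher-order gradients).
- Documents are processed one at a time; there is no cross-document
  batching.
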