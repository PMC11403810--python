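# Methods

`symptner` implements the technique stack commonly used for symptom
mention recognition in Spanish clinical text (label `SINTOMA`): BIO
token classification over subwords, with three add-ons that can be
switched on independently — BPE-dropout input regularization, a
linear-chain CRF output layer with biased transition initialization, and
sub-subword (character n-gram) feature embeddings — plus majority-vote
ensembling and strict/overlapping entity-level evaluation.  This note
records the models, the defaults and why, and the limits of what the
synthetic experiments show.

## Corpus model and offsets

All offsets are 0-based, end-exclusive character offsets (the BRAT /
standoff TSV convention: `filename  label  start_span  end_span  text`).
Every span must satisfy the substring invariant `doc.text[start:end] ==
span.text`; the reader refuses to repair violations silently.  Sentence
segmentation proposes boundaries with a rule-based splitter (sentence
punctuation followed by whitespace) and *discards any boundary that
falls strictly inside an entity span*, merging the two candidate
sentences, so labelled entities are never split.  The splitter is a
parameter: any function returning candidate boundary offsets (e.g. a
punkt model) can be substituted; the default is rule-based so that no
model download is ever required.

BIO encoding operates on word tokens (`\w+` runs or single punctuation
marks).  Overlapping gold spans are rejected at encode time — BIO cannot
represent them — and an entity boundary strictly inside a token is an
error rather than a silent shift.  On decoding, orphan `I-` tags (after
`O`, at sequence start, or after a different label) are promoted to
`B-`: the recall-maximising repair, needed because a softmax head can
emit invalid sequences.

## BPE and BPE-dropout

The BPE model stores only a base alphabet and an ordered merge list;
rank order is the whole model.  Dropout encoding follows the standard
BPE-dropout formulation: at each merge step, every candidate merge
position is vetoed independently with probability *p* (default 0.1),
the best-ranked survivor is applied, and vetoed merges may re-enter
later.  Limits are exact: *p*=0 is deterministic encoding, *p*=1 is
character-level segmentation.  Dropout is used only for training-epoch
re-segmentation; inference always encodes deterministically.

Words are encoded independently (whitespace/punctuation
pre-tokenization) so each subword carries an exact character interval;
this is what lets predicted tags map back to document offsets.
Characters outside the learned alphabet pass through as
single-character tokens (keeping concatenation exact) and map to the
`<unk>` id only at vocabulary lookup.

Label alignment supervises the *first* subword of each word with the
word's tag; continuation subwords carry `I-<label>`/`O` but are masked
out of the loss by default (a `supervise_continuations` switch enables
the alternative), and decoding reads only word-start positions.

## CRF layer

Path score = start + emissions + transitions + end; the partition
function uses the forward recursion with stable log-sum-exp, decoding
uses Viterbi with ties broken toward the lowest label index.  Biased
initialization sets the invalid-BIO entries — `O→I-x`, `start→I-x`, and
`B/I-y→I-x` for `y≠x` — to −10 000 (effectively −∞ at float32 without
NaN risk in logsumexp); a `mode="o_to_i"` switch restricts the bias to
the literal `O→I` entries only.  Biased entries stay trainable (a
freeze flag exists); in practice the optimizer never recovers them from
−10 000, so decoding is BIO-valid throughout training — the acceptance
checks assert zero invalid transitions over arbitrary batches.

## Sub-subword feature embeddings

Each subword is wrapped in boundary markers (`^tos$`) and represented by
the count vector of its character n-grams (default orders 1–4 in the
library, 1–3 inside the tagger) over a fixed inventory.  The inventory
always contains every order-1 n-gram of the vocabulary (coverage floor —
no subword can have an empty feature vector) and fills the remaining
budget with the highest-frequency higher-order n-grams, ties broken
lexicographically.  This frequency heuristic is a deliberate, documented
stand-in for more elaborate selection algorithms and is replaceable via
the `SSWInventory` interface.

The feature-to-embedding (FTE) network is a feed-forward net with
exactly three hidden layers (tanh units; default width 3072, the
geometry used at submission scale — desk-scale runs shrink it).  Before
joint training it can be pre-fitted by MSE against an existing embedding
matrix, so the host model starts near its original lookup table; after
that the FTE trains jointly with the rest of the model.  Two subwords
with identical feature vectors necessarily share an embedding, which
puts an analytic floor of ‖t₁−t₂‖²/(4·dim) on the pre-fit MSE for a
colliding pair — asserted in the tests.  We replace only the token
embedding table; positional embeddings stay free parameters.

## Tagger and training loop

The default encoder is a tiny trainable transformer (2 layers, width 64,
2 heads, feed-forward 128, learned positional embeddings) implemented on
an in-package reverse-mode autodiff engine over float64 numpy arrays;
the whole stack trains in seconds–minutes on one CPU.  An externally
trained encoder can be mirrored by importing its merge list and
embedding matrix; nothing in the package or its tests requires one.

Loss is the negative CRF log-likelihood over word-start positions, or
masked cross-entropy for the softmax head.  Training uses AdamW over
shuffled batches; training sentences are re-segmented with BPE-dropout
every epoch; each epoch ends with a deterministic-encoding evaluation on
the validation set and the checkpoint with the best validation strict F1
is kept (strict F1 is our choice of selection metric).  An optional
single extra epoch on train+validation, and a fixed-budget mode
(`--epochs 4 --no-selection`), cover the two published training
variants.  `TrainConfig` defaults (25 epochs, batch 15, lr 2e-5) are the
fine-tuning recipe for a large pretrained encoder; the from-scratch tiny
encoder cannot move at lr 2e-5, so all desk-scale recipes
(`reproduce-ablation`, tests, the acceptance script) use lr 3e-3 with
12–20 epochs.  Checkpoints round-trip bit-identically (asserted).

## Ensembling

A span is emitted iff at least `threshold` members predicted the
*identical* (doc, start, end, label) span; the default threshold is a
strict majority ⌊n/2⌋+1 (2 of 3, 4 of 6, 7 of 12 — even pools need the
explicit convention).  Surviving overlaps are resolved deterministically:
more votes, then longer span, then earlier start.  Voting is defined on
span sets, so it works file-level on standoff TSVs from any system.

## Evaluation

Strict TP = exact (doc, start, end, label) matches.  Overlapping TP
(`o_` scores) pairs same-document, same-label spans with intersecting
intervals under a **maximum-cardinality** one-to-one bipartite matching
(scipy csgraph) per group.  We chose maximum matching over greedy
pairing because the reported counts should equal what a brute-force
maximal matcher finds — greedy-by-overlap can under-count on
interlocking span configurations — and the tests enforce exactly that
equivalence against an independent networkx matcher.  Conventions:
empty gold ∧ empty predictions → P=R=F1=1; multi-run aggregation uses
the sample SD (n−1 denominator; a single run reports SD 0).  `o_F1 ≥ F1`
holds universally under this policy and is fuzz-tested.

## Synthetic corpus

The generator emulates the *shape* of a symptom-NER corpus: `n_docs`
documents of 4–8 sentences, each sentence 6–12 distractor words
(Spanish clinical filler), each sentence carrying a gazetteer symptom
phrase with probability `entity_rate` (default 0.6, Bernoulli per
sentence).  `ambiguity_rate` inserts lone gazetteer *tokens* as
unlabelled text, which defeats context-free memorization and is what
makes the ablation directional: boundary mistakes appear, the CRF and
its bias repair them.  `corrupt_predictions` perturbs gold into
predictions with known expected behaviour (strict recall ≈ 1−drop_rate;
pure offset noise keeps o_F1 = 1 while breaking strict F1).

What passing on this corpus does **not** show: real clinical language
(no grammar, no abbreviations, no de-identification artefacts, no
nested or discontinuous mentions), realistic entity-surface variability,
or transfer across annotation guidelines.  Published leaderboard-scale
scores additionally require the external gold corpus and a pretrained
Spanish clinical encoder, both out of scope here.

## Problem sizes and reproduction recipes

Desk-scale study conditions, chosen once: 40 documents (≈250 sentences,
split 70/15/15), tiny encoder, lr 3e-3.  End-to-end recovery uses
`ambiguity_rate` 0 and 12 epochs and is expected to reach strict
F1 ≥ 0.9 on held-out sentences.  The ablation ladder uses
`ambiguity_rate` 0.35 and 20 epochs over 3 seeds; means are compared as
a non-strict ordering with a tolerance of 0.05 (one seed-level SD at
n=3), and the majority-vote ensemble of the three CRF+bias runs is
required to be at least as good as its weakest member.  The
invalid-transition contrast uses a 5-epoch softmax model (argmax
decoding of an undertrained model reliably emits `I` after `O`) against
the fully trained biased-CRF models, which must emit zero.

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
all of the above from scratch in a few minutes on one CPU.

## Known limitations

* The tiny encoder is a correctness vehicle, not a quality vehicle;
  absolute F1 values on synthetic data say nothing about clinical text.
* Feature selection for SSW is frequency-based, not the information-
  theoretic selection used in the original formulation.
* The ensemble votes on exact span identity; partial-overlap voting is
  available only as a non-default extension point.
* Multi-label overlapping gold spans are rejected, not modelled.
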