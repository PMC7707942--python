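# Methods

## Task and model

Clinical named entity recognition over Chinese electronic-medical-record
(EMR) prose is treated as character-level sequence labeling: an input
sentence `a_1 … a_n` of unicode characters is mapped to a tag sequence
`b_1 … b_n` under the BIO scheme, where `B-c` opens an entity of class
`c`, `I-c` continues it and `O` marks non-entity characters.  With the
four clinical classes — disease (`dis`), symptom (`sym`), drug (`dru`),
operation (`ope`) — the label set has 2·4 + 1 = 9 elements.  No word
segmentation is performed anywhere: Chinese EMR text has unreliable word
boundaries, and the character is the annotation unit throughout.

A tagger is the composition

    char ids → trainable embedding → encoder → linear projection (L=9) → linear-chain CRF

Two encoder families are implemented.

**BiLSTM.**  The cell follows the standard gate formulation over the
concatenation `[h_{t−1}, x_t]`:

    C̃_t = tanh(W_c·[h,x] + b_c)
    Γ_u, Γ_f, Γ_o = σ(W_{u,f,o}·[h,x] + b_{u,f,o})
    c_t = Γ_u ⊙ C̃_t + Γ_f ⊙ c_{t−1}
    h_t = Γ_o ⊙ tanh(c_t)

Some presentations write the last line with the update gate Γ_u in place
of the output gate; because the prose definition of Γ_o (the gate that
"controls the proportion of the output") only makes sense with Γ_o, the
output-gate form is the default and `ht_gate="update"` preserves the
alternative literal reading.  Forward and backward passes are
independent LSTMs whose hidden states are concatenated per position
(output dimension 2·hidden).

**Transformer encoder.**  `n_layers` blocks of multi-head scaled
dot-product self-attention, `Z = softmax(QKᵀ/√d_k)·V`, followed by a
position-wise ReLU feed-forward network `FFN(Z) = max(0, Z·W_1+b_1)·W_2+b_2`,
each sublayer wrapped in residual + layer norm (post-norm, as in the
original architecture).  Fixed sinusoidal positional encodings are added
to the input.  Only the encoder stack exists here: tagging emits one
label per input position and needs no autoregressive decoder.

**CRF.**  Path score = start(t₁) + Σ emissions + Σ transitions + end(t_n);
the log-partition is computed exactly by the forward recursion in
log-space (log-sum-exp); decoding is Viterbi; the training loss is the
negative log-likelihood `log Z − score(gold)`.  BIO legality
(`O→I-c`, `B-c→I-c′`, `I-c→I-c′` with c′≠c, and `I-c` at sentence start
are illegal) is enforced as a *hard* mask — an additive penalty of
−10⁷ in score space, applied identically in training and decoding — so
decoded output is always well-formed.  −10⁷ underflows `exp` to exactly
0 in float64, so masked paths carry no probability mass, while all
arithmetic stays finite.  Viterbi ties break toward the lowest label
index (the `O`-first label order makes this deterministic).
Start/end scores are learned parameters.

## Embedding pretraining

Character vectors are pretrained with skip-gram and negative sampling
(SGNS) on unlabeled text: window 5, 5 negative samples per pair drawn
from the unigram^0.75 distribution, min_count 1, 5 epochs, linearly
decaying learning rate from 0.025 — conventional word2vec settings, since
the choice is not otherwise constrained.  The implementation is plain
numpy (vectorized minibatch SGD with `np.add.at` scatter-updates), which
makes single-threaded runs bit-reproducible under a seed; that
determinism contract is the reason for in-house SGNS rather than a
multithreaded library trainer.  Tables read and write the word2vec text
format.  Out-of-vocabulary characters map to a single shared vector
frozen at table construction (`random_fixed`, uniform on
[−0.5/dim, 0.5/dim]) or to zeros (`zero`); the shared-vector default
keeps tests deterministic where per-token hashing would not.  The
embedding matrix remains trainable inside the tagger: pretraining sets
the starting point, not the final values.

## Training

Mean per-sentence CRF NLL minimized by Adam (lr 1e-3 from scratch,
1e-4 when fine-tuning), batch 32, gradient clipping at global norm 5,
dropout 0.1 after the embedding and between Transformer layers, early
stopping on dev Macro-F1 with patience 5.  The few-hundred-sentence
regime typical of annotated clinical corpora needs the dropout; all
other values are ordinary defaults and config-exposed.  Batches are padded and masked: padded positions are
excluded from LSTM state updates (the state is carried through), from
attention (masked keys get −10⁹ before the softmax), and from the CRF
recursion and loss (the forward variable is frozen past each sentence
end).  Early stopping keys on the pair (dev Macro-F1, −train loss): a
loss drop counts as progress while dev F1 is flat, so the initial
all-`O` phase of training does not exhaust patience, and the restored
best snapshot is never an earlier, worse model.

Gradients come from a small reverse-mode autodiff engine over float64
numpy arrays (`emrner.autodiff`); every composite (LSTM steps, attention,
layer norm, the batched CRF recursion) is checked against central finite
differences in the test suite.  Everything is single-threaded and
seeded, so the full train→predict path is bit-reproducible — the
determinism experiment asserts exactly that.

## Transfer learning

The donor-model recipe: a tagger trained on a related annotated corpus
donates its embedding and encoder weights; the output layer is remapped
to the target tag set — projection columns and CRF entries of labels
present in both schemes are copied, new labels are freshly initialized —
and training continues on the target corpus at lr 1e-4.  Freeze
policies: `none` (default; all layers trainable at the reduced lr),
`encoder`, `all_but_output`.  The default mirrors the common practice of
whole-model fine-tuning; the frozen variants exist for ablation and are
covered by bitwise tests.

## Evaluation

Entity-level exact match only: a predicted (start, end, class) triple is
a true positive iff the identical triple is in the gold annotation; no
partial or overlap credit.  Per class, P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R), in percent, with 0 for empty denominators.  Two
corpus-level averages are always reported, labeled distinctly:

* **macro** — unweighted means of per-class P and R; Macro-F1 is the
  harmonic mean *of the two macros*, not the mean of per-class F1;
* **support-weighted** — per-class P and R weighted by gold entity
  counts (≈ micro-averaging).

Both are kept because published "Average" rows are sometimes computed
one way while the stated formula is the other; the acceptance suite
demonstrates a reported-values case where the weighted mean, not the
unweighted macro, reproduces the printed average.  Tables round half-up
to 2 decimals.

On decoding, an `I-c` with no preceding `B-c`/`I-c` is repaired as a
span start ("I-as-B"), matching common evaluation practice; a strict
mode raises instead.  CRF-decoded output never needs the repair.

## Synthetic corpus generator

Real Chinese clinical corpora are privacy-restricted, so the toolkit
ships a seeded generator that reproduces the statistical structure the
task assumes rather than any real text:

* class mix proportional to a reported clinical training distribution,
  701 : 2648 : 546 : 2138 (dis : sym : dru : ope);
* entity lengths from a core distribution on 2–6 characters plus a 6%
  long tail at 11–14, giving a mean near 4 — including the super-long
  (>10 character) entities that make clinical NER hard;
* class-typical word formation: each class draws from its own disjoint
  CJK sub-alphabet, and disease strings end in 病 or 症;
* context-dependent ambiguity: a configurable fraction (default 5%) of
  entity surface forms belongs to two gazetteers, so only context
  decides the label;
* dense entity packing (1–4 entities per sentence) and fragment-style
  sentences — no subject, comma-chained clauses — imitating terse EMR
  prose.

Gold spans are emitted alongside the BIO tags, so evaluation tests can
bypass tag decoding.  A "related corpus" variant shares templates and
sub-alphabets but resamples a `divergence` fraction of each gazetteer;
it stands in for the donor task in transfer experiments (divergence 0 ⇒
identical corpus, 1 ⇒ disjoint entity vocabulary).

What passing on this material does and does not show: the generator's
class-specific alphabets make the synthetic task more separable than
real clinical text, so absolute scores here are upper bounds on realism
and only the *relative* findings (pretrained > random embeddings,
BiLSTM ≥ Transformer at small scale, fine-tuning ≥ scratch) are the
claims being exercised.  Linguistic realism of the prose is explicitly a
non-goal.

## Experiment problem sizes

The canned experiments (`emrner.experiments`) run at desk scale, chosen
once as the smallest sizes at which the phenomena are stable:

* **learnability** — 2,000 sentences (1,600 train), ambiguity 0, 150-d
  skip-gram (3 epochs), BiLSTM hidden 50, ≤ 30 epochs with early
  stopping;
* **encoder comparison** — 500 sentences (400 train), 96-d embeddings,
  hidden 48, 2-layer/4-head Transformer, 12 epochs, median over 3
  training seeds;
* **transfer** — 220-sentence target corpus (~120 train), 800-sentence
  donor corpus at divergence 0.5, donor 12 epochs, each arm 15 epochs,
  median over 3 seeds;
* **determinism** — 100 sentences, 3 epochs, trained twice and compared
  bit-exactly.

## Numerical and degenerate-input choices

* float64 throughout; log-space dynamic programming with max-shifted
  log-sum-exp.
* Glorot-uniform weight init; LSTM forget bias starts at 1.
* Empty sentences are invalid everywhere (readers skip blank-line runs;
  encoders reject length-0 input).
* An over-constrained legality mask (no path above the masked floor)
  raises rather than returning a masked path.
* Zero-denominator P/R/F1 are 0 by convention; classes with zero gold
  support are excluded from the weighted average and would be errors if
  passed explicitly.
* Checkpoints are single-file `.npz` archives carrying the tag scheme,
  architecture hyperparameters, vocabulary and every tensor; loading is
  bit-exact, version-checked, and corrupted files raise a clear error.

## Known limitations

* No nested or discontinuous entities; spans are contiguous and
  non-overlapping by construction.
* The Transformer uses fixed sinusoidal positions and post-norm; no
  pretrained contextual language models.
* SGNS has no subsampling of frequent tokens and fixed (non-shrinking)
  windows; adequate at these corpus sizes, not tuned for web-scale text.
* The generator's filler text is i.i.d. characters, far simpler than
  clinical prose; models that exploit richer context would not be
  differentiated by it.
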