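"""End-to-end tagger training, donor fine-tuning, prediction, checkpoints.

A tagger is the composition

    char ids -> trainable embedding -> encoder (BiLSTM | Transformer)
             -> linear projection to label space -> linear-chain CRF

trained by minimizing the mean CRF negative log-likelihood with Adam on
padded mini-batches (padded positions are excluded from the LSTM states,
the attention, and the loss).  The embedding matrix is initialized from a
pretrained table and stays trainable — pretraining fixes the starting
point, not the values.

Transfer learning follows the donor-model recipe: a tagger trained on a
related annotated corpus initializes embedding and encoder weights; the
output layer (projection + CRF) is remapped to the target tag set — rows
of labels present in both schemes are copied, new labels are freshly
initialized — and training continues on the target corpus at a reduced
learning rate, optionally with layers frozen.

All randomness (init, batch order, dropout, dev split) flows from
``TrainConfig.seed``; single-threaded numpy makes runs bit-reproducible.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor, clip_gradients
from .corpus import TaggedSentence, TagScheme
from .crf import CRFLayer, viterbi_decode
from .embeddings import EmbeddingTable
from .encoders import BiLSTMEncoder, Linear, TransformerEncoder
from .evaluation import evaluate_corpus

__all__ = [
    "TrainConfig",
    "TaggerModel",
    "build_model",
    "train",
    "fine_tune",
    "remap_output_layer",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults: Adam at 1e-3 from scratch (use 1e-4 when fine-tuning),
    batches of 32, early stopping on dev Macro-F1 with patience 5,
    gradient clipping at global norm 5, dropout 0.1.
    """

    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 5
    clip_norm: float = 5.0
    dropout: float = 0.1
    hidden: int = 50          # BiLSTM hidden size per direction
    n_layers: int = 2         # Transformer encoder depth
    n_heads: int = 4
    d_ff: int | None = None   # Transformer FFN width, default 4 * model dim
    ht_gate: str = "output"   # LSTM output-gate convention; "update" = literal alt
    dev_frac: float = 0.1

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class TaggerModel:
    """A trained (or trainable) encoder+CRF tagger.

    Holds the tag scheme, the character vocabulary (one extra row for the
    shared OOV vector), the trainable embedding matrix, the encoder, the
    label projection and the CRF layer.
    """

    def __init__(self, scheme: TagScheme, vocab: Sequence[str],
                 embedding: np.ndarray, encoder_kind: str, encoder,
                 projection: Linear, crf: CRFLayer, hyper: dict):
        self.scheme = scheme
        self.vocab = list(vocab)
        self._index = {t: i for i, t in enumerate(self.vocab)}
        self.oov_id = len(self.vocab)
        self.embedding = embedding if isinstance(embedding, Parameter) \
            else Parameter(embedding)
        if self.embedding.data.shape[0] != len(self.vocab) + 1:
            raise ValueError("embedding matrix must have |vocab|+1 rows (OOV last)")
        self.encoder_kind = encoder_kind
        self.encoder = encoder
        self.projection = projection
        self.crf = crf
        self.hyper = dict(hyper)

    # -- parameter bookkeeping --------------------------------------------

    def named_parameters(self) -> dict[str, Parameter]:
        out = {"embedding": self.embedding,
               "projection.W": self.projection.W,
               "projection.b": self.projection.b,
               "crf.transitions": self.crf.transitions,
               "crf.start": self.crf.start,
               "crf.end": self.crf.end}
        if self.encoder_kind == "bilstm":
            for direction in ("fwd", "bwd"):
                layer = getattr(self.encoder, direction)
                for name in ("Wc", "Wu", "Wf", "Wo", "bc", "bu", "bf", "bo"):
                    out[f"encoder.{direction}.{name}"] = getattr(layer, name)
        else:
            for i, layer in enumerate(self.encoder.layers):
                pre = f"encoder.layer{i}"
                for name in ("Wq", "Wk", "Wv", "Wo"):
                    out[f"{pre}.attn.{name}"] = getattr(layer.attn, name)
                out[f"{pre}.norm1.gamma"] = layer.norm1.gamma
                out[f"{pre}.norm1.beta"] = layer.norm1.beta
                for name in ("W1", "b1", "W2", "b2"):
                    out[f"{pre}.ffn.{name}"] = getattr(layer.ffn, name)
                out[f"{pre}.norm2.gamma"] = layer.norm2.gamma
                out[f"{pre}.norm2.beta"] = layer.norm2.beta
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def encoder_parameters(self) -> list[Parameter]:
        return [p for name, p in self.named_parameters().items()
                if name.startswith("encoder.")]

    def output_parameters(self) -> list[Parameter]:
        return [p for name, p in self.named_parameters().items()
                if name.startswith(("projection.", "crf."))]

    # -- forward ----------------------------------------------------------

    def batch_ids(self, sentences: Sequence[Sequence[str]]
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Token-id matrix (B, T) and float padding mask (B, T)."""
        B = len(sentences)
        T = max(len(s) for s in sentences)
        ids = np.full((B, T), self.oov_id, dtype=np.int64)
        mask = np.zeros((B, T))
        for b, sent in enumerate(sentences):
            for t, tok in enumerate(sent):
                ids[b, t] = self._index.get(tok, self.oov_id)
            mask[b, :len(sent)] = 1.0
        return ids, mask

    def emissions(self, ids: np.ndarray, pad_mask: np.ndarray, *,
                  rng: np.random.Generator | None = None,
                  dropout: float = 0.0) -> Tensor:
        x = self.embedding.take_rows(ids)            # (B, T, d)
        if dropout > 0.0 and rng is not None:
            keep = (rng.random(x.shape) >= dropout) / (1.0 - dropout)
            x = x * Tensor(keep)
        h = self.encoder.forward(x, pad_mask, rng=rng, dropout=dropout)
        return self.projection(h)                    # (B, T, L)

    def predict(self, sentences: Sequence[TaggedSentence] | Sequence[str],
                scheme: TagScheme | None = None,
                batch_size: int = 64) -> list[TaggedSentence]:
        """Viterbi-decode tags for raw strings or TaggedSentences.

        Output tags are always BIO-legal (the CRF mask guarantees it).  If
        *scheme* is given it must equal the model's own scheme."""
        if scheme is not None and scheme != self.scheme:
            raise ValueError(
                f"scheme mismatch: model tags {self.scheme.classes}, "
                f"evaluation requested {scheme.classes}")
        if not sentences:
            raise ValueError("no sentences to predict")
        token_seqs = [tuple(s.tokens) if isinstance(s, TaggedSentence) else tuple(s)
                      for s in sentences]
        labels = self.scheme.labels
        out: list[TaggedSentence] = []
        params = self.crf.to_params()
        for lo in range(0, len(token_seqs), batch_size):
            chunk = token_seqs[lo:lo + batch_size]
            ids, mask = self.batch_ids(chunk)
            emis = self.emissions(ids, mask).data
            for b, toks in enumerate(chunk):
                path, _ = viterbi_decode(emis[b, :len(toks)], params)
                out.append(TaggedSentence(toks, tuple(labels[i] for i in path)))
        return out


def _model_dim_ok(dim: int, heads: int) -> int:
    if dim % heads != 0:
        raise ValueError(f"embedding dim {dim} not divisible by {heads} heads")
    return dim


def build_model(scheme: TagScheme, embeddings: EmbeddingTable,
                encoder_kind: str, config: TrainConfig) -> TaggerModel:
    """Assemble a fresh tagger initialized from a pretrained table."""
    if encoder_kind not in ("bilstm", "transformer"):
        raise ValueError(f"unknown encoder kind {encoder_kind!r}")
    rng = np.random.default_rng((config.seed, 10))
    emb = np.vstack([embeddings.vectors, embeddings.oov_vector[None, :]])
    if encoder_kind == "bilstm":
        encoder = BiLSTMEncoder(embeddings.dim, config.hidden, rng,
                                ht_gate=config.ht_gate)
    else:
        encoder = TransformerEncoder(
            _model_dim_ok(embeddings.dim, config.n_heads),
            n_heads=config.n_heads, n_layers=config.n_layers,
            d_ff=config.d_ff, rng=rng)
    projection = Linear(encoder.out_dim, scheme.n_labels, rng)
    crf = CRFLayer(scheme, seed=int(rng.integers(2 ** 31)))
    hyper = {"dim": embeddings.dim, "hidden": config.hidden,
             "n_layers": config.n_layers, "n_heads": config.n_heads,
             "d_ff": config.d_ff, "ht_gate": config.ht_gate,
             "encoder_kind": encoder_kind}
    return TaggerModel(scheme, embeddings.vocab, Parameter(emb),
                       encoder_kind, encoder, projection, crf, hyper)


def _as_sentences(corpus) -> list[TaggedSentence]:
    if hasattr(corpus, "sentences"):
        return list(corpus.sentences)
    return list(corpus)


def _snapshot(model: TaggerModel) -> dict[str, np.ndarray]:
    return {k: p.data.copy() for k, p in model.named_parameters().items()}


def _restore(model: TaggerModel, snap: dict[str, np.ndarray]) -> None:
    for k, p in model.named_parameters().items():
        p.data[...] = snap[k]


def _run_training(model: TaggerModel, train_sents: list[TaggedSentence],
                  dev_sents: list[TaggedSentence], config: TrainConfig,
                  trainable: list[Parameter]) -> list[dict]:
    """Mini-batch Adam loop with early stopping on dev Macro-F1."""
    scheme = model.scheme
    rng = np.random.default_rng((config.seed, 11))
    opt = Adam(trainable, lr=config.lr)
    history: list[dict] = []
    # best = (dev F1, -train loss): a loss drop counts as progress while
    # dev F1 is flat (e.g. the early all-O phase), so patience measures
    # genuine stagnation rather than a slow start
    best_key = (-1.0, -np.inf)
    best_snap, stale = _snapshot(model), 0

    # fixed length-sorted batches; batch order is reshuffled every epoch
    order = sorted(range(len(train_sents)), key=lambda i: len(train_sents[i]))
    batches = [order[i:i + config.batch_size]
               for i in range(0, len(order), config.batch_size)]
    tag_ids = {lab: i for i, lab in enumerate(scheme.labels)}

    for epoch in range(config.epochs):
        rng.shuffle(batches)
        total_loss, total_n = 0.0, 0
        for batch in batches:
            sents = [train_sents[i] for i in batch]
            ids, mask = model.batch_ids([s.tokens for s in sents])
            B, T = ids.shape
            tags = np.zeros((B, T), dtype=np.int64)
            for b, s in enumerate(sents):
                tags[b, :len(s)] = [tag_ids[t] for t in s.tags]
            emis = model.emissions(ids, mask, rng=rng, dropout=config.dropout)
            loss = model.crf.nll(emis, tags, mask)
            opt.zero_grad()
            loss.backward()
            clip_gradients(trainable, config.clip_norm)
            opt.step()
            total_loss += float(loss.data) * B
            total_n += B
        epoch_loss = total_loss / total_n
        dev_f1 = float("nan")
        if dev_sents:
            report = evaluate_corpus(dev_sents, model.predict(dev_sents), scheme)
            dev_f1 = report.macro_f1
        history.append({"epoch": epoch + 1, "train_loss": epoch_loss,
                        "dev_macro_f1": dev_f1})
        if dev_sents:
            key = (dev_f1, -epoch_loss)
            if key > best_key:
                best_key, best_snap, stale = key, _snapshot(model), 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    if dev_sents and best_key[0] >= 0:
        _restore(model, best_snap)
    return history


def _split_dev(sents: list[TaggedSentence], config: TrainConfig
               ) -> tuple[list[TaggedSentence], list[TaggedSentence]]:
    if config.dev_frac <= 0 or len(sents) < 3:
        return sents, []
    rng = np.random.default_rng((config.seed, 12))
    order = rng.permutation(len(sents))
    n_dev = max(1, int(round(config.dev_frac * len(sents))))
    dev = [sents[i] for i in order[:n_dev]]
    tr = [sents[i] for i in order[n_dev:]]
    return tr, dev


def train(corpus, embeddings: EmbeddingTable, config: TrainConfig,
          encoder_kind: str = "bilstm", dev=None,
          scheme: TagScheme | None = None) -> tuple[TaggerModel, list[dict]]:
    """Train a tagger from scratch on *corpus*.

    *corpus* is a list of TaggedSentences or a SyntheticCorpus; if *dev*
    is None a seeded ``dev_frac`` slice of the corpus is held out for
    early stopping.  Returns the best-on-dev model and the per-epoch
    history (train loss, dev Macro-F1).
    """
    sents = _as_sentences(corpus)
    if not sents:
        raise ValueError("empty training corpus")
    if scheme is None:
        scheme = TagScheme()
        try:
            for s in sents:
                s.validate(scheme)
        except ValueError:
            classes = sorted({t[2:] for s in sents for t in s.tags if t != "O"})
            scheme = TagScheme(tuple(classes))
    for s in sents:
        s.validate(scheme)
    if dev is None:
        train_sents, dev_sents = _split_dev(sents, config)
    else:
        train_sents, dev_sents = sents, _as_sentences(dev)
    model = build_model(scheme, embeddings, encoder_kind, config)
    history = _run_training(model, train_sents, dev_sents, config,
                            model.parameters())
    return model, history


def remap_output_layer(donor: TaggerModel, target_scheme: TagScheme,
                       seed: int = 0) -> TaggerModel:
    """Transfer a donor tagger to a new tag set.

    Embedding and encoder weights are copied as-is.  In the projection and
    CRF, every label present in both schemes keeps the donor's learned
    rows/entries; labels new to the target scheme are freshly initialized
    from *seed*.
    """
    rng = np.random.default_rng((seed, 13))
    src_labels = donor.scheme.labels
    dst_labels = target_scheme.labels
    src_idx = {lab: i for i, lab in enumerate(src_labels)}
    L_new = target_scheme.n_labels
    H = donor.projection.W.data.shape[0]

    projection = Linear(H, L_new, rng)
    crf = CRFLayer(target_scheme, seed=int(rng.integers(2 ** 31)))
    for j, lab in enumerate(dst_labels):
        i = src_idx.get(lab)
        if i is None:
            continue
        projection.W.data[:, j] = donor.projection.W.data[:, i]
        projection.b.data[j] = donor.projection.b.data[i]
        crf.start.data[j] = donor.crf.start.data[i]
        crf.end.data[j] = donor.crf.end.data[i]
        for j2, lab2 in enumerate(dst_labels):
            i2 = src_idx.get(lab2)
            if i2 is not None:
                crf.transitions.data[j, j2] = donor.crf.transitions.data[i, i2]

    clone = _clone_architecture(donor)
    model = TaggerModel(target_scheme, donor.vocab,
                        Parameter(donor.embedding.data.copy()),
                        donor.encoder_kind, clone, projection, crf,
                        donor.hyper)
    # copy encoder weights
    donor_named = donor.named_parameters()
    for name, p in model.named_parameters().items():
        if name.startswith("encoder."):
            p.data[...] = donor_named[name].data
    return model


def _clone_architecture(model: TaggerModel):
    """Fresh encoder of the same shape (weights overwritten by caller)."""
    rng = np.random.default_rng(0)
    h = model.hyper
    if model.encoder_kind == "bilstm":
        return BiLSTMEncoder(h["dim"], h["hidden"], rng, ht_gate=h["ht_gate"])
    return TransformerEncoder(h["dim"], n_heads=h["n_heads"],
                              n_layers=h["n_layers"], d_ff=h["d_ff"], rng=rng)


def fine_tune(donor: TaggerModel, corpus, config: TrainConfig,
              freeze_policy: str = "none",
              target_scheme: TagScheme | None = None,
              dev=None) -> tuple[TaggerModel, list[dict]]:
    """Continue training a donor tagger on a new corpus.

    freeze_policy: ``"none"`` (all layers trainable, typically at a
    reduced lr), ``"encoder"`` (encoder frozen), or ``"all_but_output"``
    (only projection + CRF trainable).  If *target_scheme* differs from
    the donor's, the output layer is remapped first.
    """
    if freeze_policy not in ("none", "encoder", "all_but_output"):
        raise ValueError(f"unknown freeze_policy {freeze_policy!r}")
    sents = _as_sentences(corpus)
    if not sents:
        raise ValueError("empty fine-tuning corpus")
    target_scheme = target_scheme or donor.scheme
    model = remap_output_layer(donor, target_scheme, seed=config.seed)
    for s in sents:
        s.validate(target_scheme)
    if dev is None:
        train_sents, dev_sents = _split_dev(sents, config)
    else:
        train_sents, dev_sents = sents, _as_sentences(dev)
    if freeze_policy == "none":
        trainable = model.parameters()
    elif freeze_policy == "encoder":
        frozen = {id(p) for p in model.encoder_parameters()}
        trainable = [p for p in model.parameters() if id(p) not in frozen]
    else:
        trainable = model.output_parameters()
    history = _run_training(model, train_sents, dev_sents, config, trainable)
    return model, history


def predict(model: TaggerModel, sentences,
            scheme: TagScheme | None = None) -> list[TaggedSentence]:
    """Module-level alias for :meth:`TaggerModel.predict`."""
    return model.predict(_as_sentences(sentences) if hasattr(sentences, "sentences")
                         else sentences, scheme=scheme)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: TaggerModel, path) -> None:
    """Single-file archive: JSON metadata + every parameter tensor."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "classes": list(model.scheme.classes),
        "encoder_kind": model.encoder_kind,
        "hyper": model.hyper,
        "vocab": model.vocab,
    }
    arrays = {f"param::{k}": p.data for k, p in model.named_parameters().items()}
    np.savez(path, meta=np.frombuffer(
        json.dumps(meta, ensure_ascii=False).encode("utf-8"), dtype=np.uint8),
        **arrays)


def load_checkpoint(path) -> TaggerModel:
    """Rebuild a tagger bit-exactly from :func:`save_checkpoint` output."""
    path = Path(path)
    if not path.exists():
        alt = path.with_suffix(path.suffix + ".npz")
        if alt.exists():
            path = alt
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            arrays = {k[len("param::"):]: data[k] for k in data.files
                      if k.startswith("param::")}
    except (zipfile.BadZipFile, OSError, KeyError, json.JSONDecodeError,
            ValueError, UnicodeDecodeError) as e:
        raise ValueError(f"corrupted or invalid checkpoint {path}: {e}") from e
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {meta.get('version')} unsupported "
            f"(expected {CHECKPOINT_VERSION})")

    scheme = TagScheme(tuple(meta["classes"]))
    hyper = meta["hyper"]
    rng = np.random.default_rng(0)
    if meta["encoder_kind"] == "bilstm":
        encoder = BiLSTMEncoder(hyper["dim"], hyper["hidden"], rng,
                                ht_gate=hyper["ht_gate"])
    else:
        encoder = TransformerEncoder(hyper["dim"], n_heads=hyper["n_heads"],
                                     n_layers=hyper["n_layers"],
                                     d_ff=hyper["d_ff"], rng=rng)
    projection = Linear(encoder.out_dim, scheme.n_labels, rng)
    crf = CRFLayer(scheme, seed=0)
    model = TaggerModel(scheme, meta["vocab"],
                        Parameter(arrays["embedding"]),
                        meta["encoder_kind"], encoder, projection, crf, hyper)
    for name, p in model.named_parameters().items():
        if name not in arrays:
            raise ValueError(f"checkpoint missing tensor {name!r}")
        p.data = np.array(arrays[name], dtype=np.float64)
    return model
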