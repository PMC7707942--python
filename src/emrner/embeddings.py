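"""Character embedding pretraining and word2vec-text I/O.

The tagger is initialized from dense character vectors pretrained on
unlabeled in-domain text with the skip-gram model (negative sampling).
Because annotation is per character, embeddings are per character too —
there is no word segmentation step anywhere in the toolkit.

Training is a plain numpy implementation of skip-gram with negative
sampling (SGNS): for each (center, context) pair within a symmetric
window the center vector is pushed toward the context's output vector and
away from ``negative`` sampled noise tokens drawn from the unigram^0.75
distribution.  Single-threaded and fully deterministic under a seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmbeddingTable",
    "train_skipgram",
    "load_word2vec_text",
    "save_word2vec_text",
    "random_table",
]


@dataclass
class EmbeddingTable:
    """A token -> dense-vector map with a fixed out-of-vocabulary policy.

    ``oov_policy`` is either ``"random_fixed"`` — every OOV token maps to
    one shared random vector frozen at table construction (drawn from the
    table's seed, uniform on [-0.5/dim, 0.5/dim]) — or ``"zero"``.
    """

    vocab: list[str]
    vectors: np.ndarray
    oov_policy: str = "random_fixed"
    seed: int = 0
    _index: dict = field(init=False, repr=False)
    _oov_vector: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocab):
            raise ValueError("vectors must be |vocab| x dim")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("duplicate token in vocab")
        if self.oov_policy not in ("random_fixed", "zero"):
            raise ValueError(f"unknown oov_policy {self.oov_policy!r}")
        self._index = {tok: i for i, tok in enumerate(self.vocab)}
        if self.oov_policy == "zero":
            self._oov_vector = np.zeros(self.dim)
        else:
            rng = np.random.default_rng(self.seed)
            self._oov_vector = rng.uniform(-0.5 / self.dim, 0.5 / self.dim,
                                           size=self.dim)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.vocab)

    @property
    def oov_vector(self) -> np.ndarray:
        return self._oov_vector.copy()

    def lookup(self, token: str) -> np.ndarray:
        """Vector for *token*; OOV tokens all share the policy vector."""
        i = self._index.get(token)
        if i is None:
            return self._oov_vector.copy()
        return self.vectors[i].copy()

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Stack lookups for a token sequence into an (n, dim) matrix."""
        return np.stack([self.lookup(t) for t in tokens])


def _sentences_from(corpus_text) -> list[list[str]]:
    """Character-tokenize input: a string (one sentence per line) or an
    iterable of strings.  Whitespace is not a token."""
    if isinstance(corpus_text, str):
        lines = corpus_text.splitlines()
    else:
        lines = list(corpus_text)
    sents = []
    for line in lines:
        chars = [c for c in line if not c.isspace()]
        if chars:
            sents.append(chars)
    return sents


def train_skipgram(corpus_text, dim: int, window: int = 5, epochs: int = 5,
                   min_count: int = 1, negative: int = 5, lr: float = 0.025,
                   seed: int = 0, oov_policy: str = "random_fixed",
                   batch: int = 512) -> EmbeddingTable:
    """Pretrain character vectors with skip-gram negative sampling.

    Parameters mirror word2vec conventions: symmetric context *window*,
    *negative* noise samples per positive pair from the unigram^0.75
    distribution, linearly decaying learning rate starting at *lr*.
    Deterministic for a fixed *seed* (single-threaded numpy).
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    sents = _sentences_from(corpus_text)
    if not sents:
        raise ValueError("empty corpus")

    counts: dict[str, int] = {}
    for s in sents:
        for c in s:
            counts[c] = counts.get(c, 0) + 1
    # deterministic vocab order: frequency desc, then codepoint
    vocab = [t for t, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
             if n >= min_count]
    if not vocab:
        raise ValueError("no token reaches min_count")
    index = {t: i for i, t in enumerate(vocab)}

    # all (center, context) pairs within the window, as flat id arrays
    centers, contexts = [], []
    for s in sents:
        ids = [index[c] for c in s if c in index]
        for i, ci in enumerate(ids):
            lo = max(0, i - window)
            hi = min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(ci)
                    contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    if centers.size == 0:
        raise ValueError("corpus too small: no context pairs")

    freq = np.array([counts[t] for t in vocab], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(V, dim))
    W_out = np.zeros((V, dim))

    n_pairs = centers.size
    total_steps = epochs * n_pairs
    seen = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = order[start:start + batch]
            c_ids = centers[sel]
            pos_ids = contexts[sel]
            B = c_ids.size
            cur_lr = max(lr * (1.0 - seen / total_steps), lr * 1e-4)
            seen += B

            neg_ids = rng.choice(V, size=(B, negative), p=noise)
            v_c = W_in[c_ids]                       # (B, d)
            u_pos = W_out[pos_ids]                  # (B, d)
            u_neg = W_out[neg_ids]                  # (B, k, d)

            s_pos = 1.0 / (1.0 + np.exp(-np.sum(v_c * u_pos, axis=1)))
            s_neg = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", v_c, u_neg)))

            g_pos = (s_pos - 1.0)[:, None]          # d/d(score) of -log sigma
            g_neg = s_neg[:, :, None]

            grad_c = g_pos * u_pos + np.einsum("bk,bkd->bd", s_neg, u_neg)
            np.add.at(W_in, c_ids, -cur_lr * grad_c)
            np.add.at(W_out, pos_ids, -cur_lr * (g_pos * v_c))
            np.add.at(W_out, neg_ids.ravel(),
                      -cur_lr * (g_neg * v_c[:, None, :]).reshape(-1, dim))

    return EmbeddingTable(vocab, W_in, oov_policy=oov_policy, seed=seed)


def random_table(vocab: Sequence[str], dim: int, seed: int = 0,
                 oov_policy: str = "random_fixed") -> EmbeddingTable:
    """Baseline table with entries i.i.d. uniform on [-0.5/dim, 0.5/dim]."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    vocab = list(vocab)
    if not vocab:
        raise ValueError("empty vocab")
    rng = np.random.default_rng(seed)
    vectors = rng.uniform(-0.5 / dim, 0.5 / dim, size=(len(vocab), dim))
    return EmbeddingTable(vocab, vectors, oov_policy=oov_policy, seed=seed)


def load_word2vec_text(stream, oov_policy: str = "random_fixed",
                       seed: int = 0) -> EmbeddingTable:
    """Load a table in word2vec text format.

    First line ``<vocab_size> <dim>``; each following line
    ``<token> <v1> ... <vdim>``.  Any row whose value count disagrees with
    the header dimension, a vocab-size mismatch, or a duplicate token is an
    error.
    """
    if isinstance(stream, (str, Path)):
        text = Path(stream).read_text(encoding="utf-8")
    elif hasattr(stream, "read"):
        text = stream.read()
    else:
        text = "\n".join(stream)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty embedding file")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError(f"bad header {lines[0]!r}: expected '<vocab_size> <dim>'")
    n, dim = int(header[0]), int(header[1])
    if len(lines) - 1 != n:
        raise ValueError(f"header promises {n} rows, file has {len(lines) - 1}")
    vocab, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(" ")
        if len(parts) != dim + 1:
            raise ValueError(
                f"line {lineno}: expected token + {dim} values, got {len(parts) - 1}"
            )
        vocab.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return EmbeddingTable(vocab, np.array(rows), oov_policy=oov_policy, seed=seed)


def save_word2vec_text(table: EmbeddingTable, stream=None) -> str | None:
    """Write *table* in word2vec text format (see :func:`load_word2vec_text`)."""
    buf = io.StringIO()
    buf.write(f"{len(table.vocab)} {table.dim}\n")
    for tok, row in zip(table.vocab, table.vectors):
        buf.write(tok + " " + " ".join(f"{v:.8g}" for v in row) + "\n")
    text = buf.getvalue()
    if stream is None:
        return text
    if isinstance(stream, (str, Path)):
        Path(stream).write_text(text, encoding="utf-8")
        return None
    stream.write(text)
    return None
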