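"""Linear-chain conditional random field over BIO label sequences.

A path ``t_1 .. t_n`` through an emission matrix scores

    start[t_1] + sum_i emissions[i, t_i] + sum_i transitions[t_i, t_{i+1}] + end[t_n]

The CRF normalizes globally: the log-partition is computed exactly with
the forward recursion in log-space, decoding uses Viterbi, and training
minimizes the negative log-likelihood ``logZ - score(gold)``.

BIO legality is enforced as a hard constraint rather than learned: a
boolean mask forbids transitions that would produce malformed entities
(``O -> I-c``, ``B-c -> I-c'``, ``I-c -> I-c'`` for c' != c, and starting
a sentence with any ``I-c``).  Masked transitions receive a large negative
additive penalty (``MASKED_SCORE``) in every scoring path, so decoded
sequences are always well-formed while the arithmetic stays finite.

The plain-numpy functions here are the reference/inference path and
operate on one sentence at a time; :class:`CRFLayer` is the batched,
differentiable version used during training (the two are tested against
each other and against exhaustive path enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .autodiff import Parameter, Tensor
from .corpus import TagScheme

__all__ = [
    "MASKED_SCORE",
    "CRFParams",
    "build_legality_mask",
    "path_score",
    "log_partition",
    "viterbi_decode",
    "nll_loss",
    "CRFLayer",
]

#: Additive score for a forbidden transition; exp(MASKED_SCORE) underflows
#: to exactly 0 in float64, so masked paths carry zero probability mass,
#: and any path crossing one masked edge stays below -1e6 even after the
#: ordinary finite score terms are added.
MASKED_SCORE = -1.0e7


def build_legality_mask(scheme: TagScheme) -> tuple[np.ndarray, np.ndarray]:
    """BIO transition legality for *scheme*.

    Returns ``(allowed, start_allowed)``: an L x L boolean matrix where
    ``allowed[i, j]`` permits label j to follow label i, and an L-vector
    permitting labels at sentence start.  Forbidden: ``O -> I-c``,
    ``B-c -> I-c'`` and ``I-c -> I-c'`` with c' != c, and ``I-c`` at the
    start.  Everything else is allowed.
    """
    labels = scheme.labels
    L = len(labels)
    allowed = np.ones((L, L), dtype=bool)
    start_allowed = np.ones(L, dtype=bool)
    for j, to in enumerate(labels):
        if not to.startswith("I-"):
            continue
        cls = to[2:]
        start_allowed[j] = False
        for i, frm in enumerate(labels):
            legal = frm == f"B-{cls}" or frm == f"I-{cls}"
            if not legal:
                allowed[i, j] = False
    return allowed, start_allowed


@dataclass
class CRFParams:
    """Transition/start/end scores plus the BIO legality mask.

    ``transitions[i, j]`` scores label j following label i.  Masked-out
    entries contribute ``MASKED_SCORE`` additively in every computation.
    """

    transitions: np.ndarray
    start: np.ndarray
    end: np.ndarray
    mask: np.ndarray | None = None
    start_mask: np.ndarray | None = None

    def __post_init__(self):
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.start = np.asarray(self.start, dtype=np.float64)
        self.end = np.asarray(self.end, dtype=np.float64)
        L = self.transitions.shape[0]
        if self.transitions.shape != (L, L):
            raise ValueError("transitions must be square")
        if self.start.shape != (L,) or self.end.shape != (L,):
            raise ValueError("start/end must be length-L vectors")
        if self.mask is None:
            self.mask = np.ones((L, L), dtype=bool)
        if self.start_mask is None:
            self.start_mask = np.ones(L, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.start_mask = np.asarray(self.start_mask, dtype=bool)

    @property
    def n_labels(self) -> int:
        return self.transitions.shape[0]

    @property
    def effective_transitions(self) -> np.ndarray:
        return self.transitions + np.where(self.mask, 0.0, MASKED_SCORE)

    @property
    def effective_start(self) -> np.ndarray:
        return self.start + np.where(self.start_mask, 0.0, MASKED_SCORE)

    @classmethod
    def for_scheme(cls, scheme: TagScheme, seed: int | None = None,
                   scale: float = 0.01) -> "CRFParams":
        """Fresh parameters (zeros, or small random values when seeded)
        with the BIO legality mask for *scheme*."""
        L = scheme.n_labels
        allowed, start_allowed = build_legality_mask(scheme)
        if seed is None:
            trans = np.zeros((L, L))
            start = np.zeros(L)
            end = np.zeros(L)
        else:
            rng = np.random.default_rng(seed)
            trans = rng.normal(0, scale, (L, L))
            start = rng.normal(0, scale, L)
            end = rng.normal(0, scale, L)
        return cls(trans, start, end, allowed, start_allowed)


def _check(emissions: np.ndarray) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be (n >= 1, L)")
    return emissions


def path_score(emissions: np.ndarray, params: CRFParams,
               tags: np.ndarray) -> float:
    """Score of one label path (see module docstring for the formula)."""
    emissions = _check(emissions)
    tags = np.asarray(tags, dtype=np.int64)
    n, L = emissions.shape
    if tags.shape != (n,):
        raise ValueError(f"need {n} tags, got shape {tags.shape}")
    if tags.min() < 0 or tags.max() >= L:
        raise IndexError("tag index out of range")
    trans = params.effective_transitions
    score = params.effective_start[tags[0]] + params.end[tags[-1]]
    score += emissions[np.arange(n), tags].sum()
    score += trans[tags[:-1], tags[1:]].sum()
    return float(score)


def log_partition(emissions: np.ndarray, params: CRFParams) -> float:
    """log sum over all label paths of exp(path score), by the forward
    recursion in log-space."""
    emissions = _check(emissions)
    trans = params.effective_transitions
    alpha = params.effective_start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = logsumexp(alpha[:, None] + trans, axis=0) + emissions[t]
    return float(logsumexp(alpha + params.end))


def viterbi_decode(emissions: np.ndarray,
                   params: CRFParams) -> tuple[list[int], float]:
    """Highest-scoring label path and its score.

    Ties break toward the lowest label index (argmax returns the first
    maximum).  If the mask admits no path with score above the masked
    floor, the instance is over-constrained and an error is raised.
    """
    emissions = _check(emissions)
    n, L = emissions.shape
    trans = params.effective_transitions
    score = params.effective_start + emissions[0]
    back: list[np.ndarray] = []
    for t in range(1, n):
        cand = score[:, None] + trans          # (from, to)
        best_from = np.argmax(cand, axis=0)
        back.append(best_from)
        score = cand[best_from, np.arange(L)] + emissions[t]
    score = score + params.end
    last = int(np.argmax(score))
    best_score = float(score[last])
    if best_score <= MASKED_SCORE / 2:
        raise ValueError("no legal path: legality mask is over-constrained")
    path = [last]
    for bp in reversed(back):
        path.append(int(bp[path[-1]]))
    path.reverse()
    return path, best_score


def nll_loss(emissions: np.ndarray, params: CRFParams,
             gold_tags: np.ndarray) -> float:
    """Negative log-likelihood ``logZ - score(gold)``; always >= 0.

    The gold path must be legal under the mask; an illegal transition is
    reported by name.
    """
    gold_tags = np.asarray(gold_tags, dtype=np.int64)
    if not params.start_mask[gold_tags[0]]:
        raise ValueError(f"illegal gold start: label index {gold_tags[0]}")
    for a, b in zip(gold_tags[:-1], gold_tags[1:]):
        if not params.mask[a, b]:
            raise ValueError(f"illegal gold transition: {int(a)} -> {int(b)}")
    return log_partition(emissions, params) - path_score(emissions, params, gold_tags)


class CRFLayer:
    """Batched differentiable CRF used inside a tagger.

    Transition, start and end scores are trainable :class:`Parameter`
    tensors; the legality mask is fixed.  ``nll`` consumes a batch of
    emission Tensors with a padding mask and returns the mean per-sentence
    negative log-likelihood as a graph node.
    """

    def __init__(self, scheme: TagScheme, seed: int = 0, scale: float = 0.01):
        self.scheme = scheme
        L = scheme.n_labels
        rng = np.random.default_rng(seed)
        self.transitions = Parameter(rng.normal(0, scale, (L, L)))
        self.start = Parameter(rng.normal(0, scale, L))
        self.end = Parameter(rng.normal(0, scale, L))
        allowed, start_allowed = build_legality_mask(scheme)
        self.trans_penalty = np.where(allowed, 0.0, MASKED_SCORE)
        self.start_penalty = np.where(start_allowed, 0.0, MASKED_SCORE)

    def parameters(self) -> list[Parameter]:
        return [self.transitions, self.start, self.end]

    def to_params(self) -> CRFParams:
        allowed = self.trans_penalty == 0.0
        start_allowed = self.start_penalty == 0.0
        return CRFParams(self.transitions.data.copy(), self.start.data.copy(),
                         self.end.data.copy(), allowed, start_allowed)

    def nll(self, emissions: Tensor, tags: np.ndarray,
            pad_mask: np.ndarray) -> Tensor:
        """Mean NLL over a padded batch.

        emissions: (B, T, L) Tensor; tags: (B, T) int array (anything at a
        padded position is ignored); pad_mask: (B, T) floats, 1 for real
        positions.  Position 0 is always real.
        """
        B, T, L = emissions.shape
        tags = np.asarray(tags, dtype=np.int64)
        lengths = pad_mask.sum(axis=1).astype(np.int64)
        trans = self.transitions + Tensor(self.trans_penalty)
        start = self.start + Tensor(self.start_penalty)

        # --- gold path score (vectorized gathers) ---
        b_idx = np.arange(B)
        # emissions[b, t, tags[b, t]] as a flat gather
        flat_ids = np.arange(B * T) * L + tags.ravel()
        emit_scores = emissions.reshape(B * T * L)[flat_ids].reshape(B, T)
        gold = (emit_scores * Tensor(pad_mask)).sum(axis=1)
        gold = gold + start.reshape(L)[tags[:, 0]]
        # transitions along the gold path, masked to real adjacent pairs
        pair_mask = pad_mask[:, 1:]
        pair_ids = tags[:, :-1] * L + tags[:, 1:]
        gold = gold + (trans.reshape(L * L)[pair_ids.ravel()].reshape(B, T - 1)
                       * Tensor(pair_mask)).sum(axis=1)
        gold = gold + self.end[tags[b_idx, lengths - 1]]

        # --- log partition by masked forward recursion ---
        alpha = start.reshape(1, L) + emissions[:, 0, :]
        for t in range(1, T):
            cand = alpha.reshape(B, L, 1) + trans.reshape(1, L, L)
            new_alpha = cand.logsumexp(axis=1) + emissions[:, t, :]
            m = pad_mask[:, t][:, None]
            alpha = new_alpha * Tensor(m) + alpha * Tensor(1.0 - m)
        logZ = (alpha + self.end.reshape(1, L)).logsumexp(axis=1)

        nll = (logZ - gold).sum() * (1.0 / B)
        return nll

    def viterbi(self, emissions: np.ndarray, lengths: np.ndarray) -> list[list[int]]:
        """Decode each sentence of a padded (B, T, L) emission batch."""
        params = self.to_params()
        out = []
        for b, n in enumerate(lengths):
            path, _ = viterbi_decode(emissions[b, :n], params)
            out.append(path)
        return out
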