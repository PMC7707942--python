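"""Sequence encoders: BiLSTM and Transformer encoder stacks.

Both encoders map an embedded character sequence to per-position hidden
vectors which a linear projection turns into CRF emission scores, one per
BIO label.  Two families are provided:

* **BiLSTM** — two LSTMs read the sentence left-to-right and
  right-to-left; their hidden states are concatenated per position, so
  every output sees both past and future context.  The LSTM cell follows
  the standard gate formulation: candidate ``C~ = tanh(Wc.[h,x]+bc)``,
  update/forget/output gates ``sigmoid(W.[h,x]+b)``,
  ``c_t = Gu*C~ + Gf*c_{t-1}`` and, by default, ``h_t = Go*tanh(c_t)``.
  ``ht_gate="update"`` switches the last line to ``h_t = Gu*tanh(c_t)``
  (an alternative reading found in some presentations of the cell).

* **Transformer encoder** — ``n_layers`` blocks of multi-head scaled
  dot-product self-attention and a position-wise ReLU feed-forward
  network, each followed by a residual connection and layer norm
  (post-norm), with fixed sinusoidal positional encodings added to the
  input.  Only the encoder stack is used: sequence tagging needs no
  autoregressive decoder.

The classes operate on autodiff Tensors in padded batches ``(B, T, d)``
with a padding mask; the module-level functions are the single-sentence
numpy API and delegate to the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, concat, stack

__all__ = [
    "LSTMParams",
    "lstm_cell_step",
    "bilstm_encode",
    "scaled_dot_attention",
    "multi_head",
    "ffn",
    "transformer_encode",
    "project_emissions",
    "sinusoidal_positional_encoding",
    "Linear",
    "LSTMLayer",
    "BiLSTMEncoder",
    "MultiHeadSelfAttention",
    "TransformerEncoder",
]


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out))


# ---------------------------------------------------------------------------
# trainable layers (Tensor in, Tensor out)
# ---------------------------------------------------------------------------

class Linear:
    """Affine map ``x @ W + b`` with Glorot-uniform init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Parameter(_glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class LSTMLayer:
    """One direction of an LSTM over a padded batch.

    Weights act on the concatenation ``[h_{t-1}, x_t]``; the forget-gate
    bias starts at 1.0 (standard trick to ease gradient flow early on).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 ht_gate: str = "output"):
        if ht_gate not in ("output", "update"):
            raise ValueError(f"ht_gate must be 'output' or 'update', got {ht_gate!r}")
        self.d_in, self.hidden, self.ht_gate = d_in, hidden, ht_gate
        z = d_in + hidden
        self.Wc = Parameter(_glorot(rng, z, hidden))
        self.Wu = Parameter(_glorot(rng, z, hidden))
        self.Wf = Parameter(_glorot(rng, z, hidden))
        self.Wo = Parameter(_glorot(rng, z, hidden))
        self.bc = Parameter(np.zeros(hidden))
        self.bu = Parameter(np.zeros(hidden))
        self.bf = Parameter(np.ones(hidden))
        self.bo = Parameter(np.zeros(hidden))

    def parameters(self) -> list[Parameter]:
        return [self.Wc, self.Wu, self.Wf, self.Wo,
                self.bc, self.bu, self.bf, self.bo]

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = concat([h, x_t], axis=-1)
        c_tilde = (z @ self.Wc + self.bc).tanh()
        g_u = (z @ self.Wu + self.bu).sigmoid()
        g_f = (z @ self.Wf + self.bf).sigmoid()
        g_o = (z @ self.Wo + self.bo).sigmoid()
        c_new = g_u * c_tilde + g_f * c
        gate = g_o if self.ht_gate == "output" else g_u
        h_new = gate * c_new.tanh()
        return h_new, c_new

    def forward(self, x: Tensor, pad_mask: np.ndarray,
                reverse: bool = False) -> Tensor:
        """x: (B, T, d_in); pad_mask: (B, T) of {0,1}. Returns (B, T, hidden).

        Padded steps hold the state constant, so a reversed pass over a
        right-padded batch starts contributing only at each sentence's
        real tail."""
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outs: dict[int, Tensor] = {}
        for t in order:
            h_new, c_new = self.step(x[:, t, :], h, c)
            m = Tensor(pad_mask[:, t][:, None])
            keep = Tensor(1.0 - pad_mask[:, t][:, None])
            h = h_new * m + h * keep
            c = c_new * m + c * keep
            outs[t] = h
        return stack([outs[t] for t in range(T)], axis=1)


class BiLSTMEncoder:
    """Concatenated forward/backward LSTM states per position (2*hidden)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 ht_gate: str = "output"):
        self.fwd = LSTMLayer(d_in, hidden, rng, ht_gate)
        self.bwd = LSTMLayer(d_in, hidden, rng, ht_gate)
        self.out_dim = 2 * hidden

    def parameters(self) -> list[Parameter]:
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, x: Tensor, pad_mask: np.ndarray, *,
                rng: np.random.Generator | None = None,
                dropout: float = 0.0) -> Tensor:
        hf = self.fwd.forward(x, pad_mask, reverse=False)
        hb = self.bwd.forward(x, pad_mask, reverse=True)
        return concat([hf, hb], axis=-1)


def sinusoidal_positional_encoding(n: int, d: int) -> np.ndarray:
    """The fixed sin/cos position code of the original Transformer."""
    pos = np.arange(n)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / (10000.0 ** (2 * i / d))
    pe = np.zeros((n, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : d - d // 2])
    return pe


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention with ``n_heads`` subspaces."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(f"model dim {d_model} not divisible by {n_heads} heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_k = d_model // n_heads
        self.Wq = Parameter(_glorot(rng, d_model, d_model))
        self.Wk = Parameter(_glorot(rng, d_model, d_model))
        self.Wv = Parameter(_glorot(rng, d_model, d_model))
        self.Wo = Parameter(_glorot(rng, d_model, d_model))

    def parameters(self) -> list[Parameter]:
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        # (B, T, d_model) -> (B, heads, T, d_k)
        return x.reshape(B, T, self.n_heads, self.d_k).swapaxes(1, 2)

    def forward(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        q = self._split(x @ self.Wq, B, T)
        k = self._split(x @ self.Wk, B, T)
        v = self._split(x @ self.Wv, B, T)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        # padded keys get -inf-like scores so they receive zero weight
        key_bias = (1.0 - pad_mask)[:, None, None, :] * -1e9
        weights = (scores + Tensor(key_bias)).softmax(axis=-1)
        z = weights @ v                              # (B, h, T, d_k)
        z = z.swapaxes(1, 2).reshape(B, T, self.d_model)
        return z @ self.Wo


class FeedForward:
    """Position-wise two-layer ReLU network."""

    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.W1 = Parameter(_glorot(rng, d_model, d_ff))
        self.b1 = Parameter(np.zeros(d_ff))
        self.W2 = Parameter(_glorot(rng, d_ff, d_model))
        self.b2 = Parameter(np.zeros(d_model))

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W1 + self.b1).relu() @ self.W2 + self.b2

    def parameters(self) -> list[Parameter]:
        return [self.W1, self.b1, self.W2, self.b2]


class TransformerLayer:
    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.norm2 = LayerNorm(d_model)

    def parameters(self) -> list[Parameter]:
        return (self.attn.parameters() + self.norm1.parameters()
                + self.ffn.parameters() + self.norm2.parameters())

    def forward(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.attn.forward(x, pad_mask))
        x = self.norm2(x + self.ffn(x))
        return x


class TransformerEncoder:
    """Post-norm Transformer encoder stack with sinusoidal positions.

    ``positional=False`` disables the position code, which makes the whole
    stack permutation-equivariant (useful as a correctness probe)."""

    def __init__(self, d_model: int, n_heads: int = 4, n_layers: int = 2,
                 d_ff: int | None = None, rng: np.random.Generator | None = None,
                 positional: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        d_ff = d_ff if d_ff is not None else 4 * d_model
        self.d_model, self.n_heads, self.n_layers = d_model, n_heads, n_layers
        self.d_ff, self.positional = d_ff, positional
        self.layers = [TransformerLayer(d_model, n_heads, d_ff, rng)
                       for _ in range(n_layers)]
        self.out_dim = d_model

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x: Tensor, pad_mask: np.ndarray, *,
                rng: np.random.Generator | None = None,
                dropout: float = 0.0) -> Tensor:
        B, T, _ = x.shape
        if self.positional:
            pe = sinusoidal_positional_encoding(T, self.d_model)
            x = x + Tensor(pe[None, :, :])
        for layer in self.layers:
            if dropout > 0.0 and rng is not None:
                keep = (rng.random(x.shape) >= dropout) / (1.0 - dropout)
                x = x * Tensor(keep)
            x = layer.forward(x, pad_mask)
        return x


# ---------------------------------------------------------------------------
# single-sentence functional API (numpy in, numpy out)
# ---------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """Plain-array LSTM cell weights over the concatenation [h, x].

    Each W has shape (hidden + d_in, hidden); biases have shape (hidden,).
    """

    Wc: np.ndarray
    Wu: np.ndarray
    Wf: np.ndarray
    Wo: np.ndarray
    bc: np.ndarray
    bu: np.ndarray
    bf: np.ndarray
    bo: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.Wc.shape[1]

    @classmethod
    def random(cls, d_in: int, hidden: int, seed: int = 0) -> "LSTMParams":
        rng = np.random.default_rng(seed)
        z = d_in + hidden
        return cls(*(_glorot(rng, z, hidden) for _ in range(4)),
                   *(rng.normal(0, 0.1, hidden) for _ in range(4)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_cell_step(params: LSTMParams, x_t: np.ndarray, h_prev: np.ndarray,
                   c_prev: np.ndarray, ht_gate: str = "output"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update on a single position (1-D arrays)."""
    z = np.concatenate([h_prev, x_t])
    if z.shape[0] != params.Wc.shape[0]:
        raise ValueError(
            f"[h, x] has length {z.shape[0]}, weights expect {params.Wc.shape[0]}")
    c_tilde = np.tanh(z @ params.Wc + params.bc)
    g_u = _sigmoid(z @ params.Wu + params.bu)
    g_f = _sigmoid(z @ params.Wf + params.bf)
    g_o = _sigmoid(z @ params.Wo + params.bo)
    c_t = g_u * c_tilde + g_f * c_prev
    gate = g_o if ht_gate == "output" else g_u
    if ht_gate not in ("output", "update"):
        raise ValueError(f"unknown ht_gate {ht_gate!r}")
    h_t = gate * np.tanh(c_t)
    return h_t, c_t


def bilstm_encode(embedded_seq: np.ndarray, fwd_params: LSTMParams,
                  bwd_params: LSTMParams, ht_gate: str = "output") -> np.ndarray:
    """Encode one sentence (n, d_in) -> (n, 2*hidden)."""
    x = np.asarray(embedded_seq, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("embedded_seq must be (n >= 1, d)")
    n = x.shape[0]
    H = fwd_params.hidden_size

    def run(params, idx_order):
        h = np.zeros(params.hidden_size)
        c = np.zeros(params.hidden_size)
        out = np.zeros((n, params.hidden_size))
        for t in idx_order:
            h, c = lstm_cell_step(params, x[t], h, c, ht_gate)
            out[t] = h
        return out

    hf = run(fwd_params, range(n))
    hb = run(bwd_params, range(n - 1, -1, -1))
    return np.concatenate([hf, hb], axis=1)


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                         d_k: int | None = None) -> np.ndarray:
    """``softmax(Q K^T / sqrt(d_k)) V`` with rows of weights summing to 1."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[0] != V.shape[0]:
        raise ValueError("Q/K/V dimensions are inconsistent")
    d_k = d_k if d_k is not None else Q.shape[-1]
    scores = Q @ K.T / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


@dataclass
class MultiHeadParams:
    """Projection weights of one multi-head self-attention block."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    Wo: np.ndarray
    n_heads: int

    @classmethod
    def random(cls, d_model: int, n_heads: int, seed: int = 0) -> "MultiHeadParams":
        rng = np.random.default_rng(seed)
        return cls(*(_glorot(rng, d_model, d_model) for _ in range(4)), n_heads)


def multi_head(params: MultiHeadParams, X: np.ndarray) -> np.ndarray:
    """Multi-head self-attention on one sentence (n, d_model)."""
    X = np.asarray(X, dtype=np.float64)
    d = X.shape[-1]
    if d % params.n_heads != 0:
        raise ValueError(f"model dim {d} not divisible by {params.n_heads} heads")
    d_k = d // params.n_heads
    q, k, v = X @ params.Wq, X @ params.Wk, X @ params.Wv
    outs = []
    for h in range(params.n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        outs.append(scaled_dot_attention(q[:, sl], k[:, sl], v[:, sl], d_k))
    return np.concatenate(outs, axis=1) @ params.Wo


def ffn(Z: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray,
        b2: np.ndarray) -> np.ndarray:
    """Position-wise feed-forward: ``max(0, Z W1 + b1) W2 + b2``."""
    Z = np.asarray(Z, dtype=np.float64)
    return np.maximum(0.0, Z @ W1 + b1) @ W2 + b2


def transformer_encode(encoder: TransformerEncoder,
                       embedded_seq: np.ndarray) -> np.ndarray:
    """Run the trainable encoder stack on one sentence (n, d_model)."""
    x = np.asarray(embedded_seq, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("embedded_seq must be (n >= 1, d)")
    t = Tensor(x[None, :, :])
    mask = np.ones((1, x.shape[0]))
    return encoder.forward(t, mask).data[0]


def project_emissions(hidden_seq: np.ndarray, W: np.ndarray,
                      b: np.ndarray | None = None) -> np.ndarray:
    """Linear map from hidden vectors to per-label emission scores (n, L)."""
    hidden_seq = np.asarray(hidden_seq, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if hidden_seq.shape[-1] != W.shape[0]:
        raise ValueError(
            f"hidden dim {hidden_seq.shape[-1]} != projection input {W.shape[0]}")
    out = hidden_seq @ W
    if b is not None:
        out = out + b
    return out
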