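"""BiLSTM and Transformer encoder arithmetic."""

import numpy as np
import pytest

from emrner.autodiff import Tensor
from emrner.encoders import (BiLSTMEncoder, Linear, LSTMLayer, LSTMParams,
                             MultiHeadParams, TransformerEncoder,
                             bilstm_encode, ffn, lstm_cell_step, multi_head,
                             project_emissions, scaled_dot_attention,
                             sinusoidal_positional_encoding,
                             transformer_encode)


def scalar_lstm_reference(params, x, h, c):
    """Independent per-element cell implementation (explicit loops)."""
    H = params.hidden_size
    z = list(h) + list(x)
    def dot(W, b, j):
        return sum(z[i] * W[i][j] for i in range(len(z))) + b[j]
    h_new, c_new = [0.0] * H, [0.0] * H
    for j in range(H):
        c_t = np.tanh(dot(params.Wc, params.bc, j))
        g_u = 1 / (1 + np.exp(-dot(params.Wu, params.bu, j)))
        g_f = 1 / (1 + np.exp(-dot(params.Wf, params.bf, j)))
        g_o = 1 / (1 + np.exp(-dot(params.Wo, params.bo, j)))
        c_new[j] = g_u * c_t + g_f * c[j]
        h_new[j] = g_o * np.tanh(c_new[j])
    return np.array(h_new), np.array(c_new)


class TestLSTMCell:
    def test_all_zero_weights_give_zero_state(self):
        p = LSTMParams(*(np.zeros((5, 3)) for _ in range(4)),
                       *(np.zeros(3) for _ in range(4)))
        h, c = lstm_cell_step(p, np.ones(2), np.zeros(3), np.zeros(3))
        np.testing.assert_array_equal(h, 0)
        np.testing.assert_array_equal(c, 0)

    def test_open_gates_carry_cell_state(self):
        # huge gate biases force all gates to 1; Wc=0, bc=0 makes the
        # candidate 0, so c_t == c_prev exactly in the limit
        big = 1e3
        p = LSTMParams(*(np.zeros((5, 3)) for _ in range(4)),
                       np.zeros(3), *(np.full(3, big) for _ in range(3)))
        c_prev = np.array([0.3, -0.2, 0.9])
        h, c = lstm_cell_step(p, np.ones(2), np.zeros(3), c_prev)
        np.testing.assert_allclose(c, c_prev, atol=1e-12)
        np.testing.assert_allclose(h, np.tanh(c_prev), atol=1e-12)

    def test_matches_independent_scalar_implementation(self):
        p = LSTMParams.random(3, 2, seed=4)
        rng = np.random.default_rng(5)
        x, h0, c0 = rng.normal(0, 1, 3), rng.normal(0, 1, 2), rng.normal(0, 1, 2)
        h, c = lstm_cell_step(p, x, h0, c0)
        h_ref, c_ref = scalar_lstm_reference(p, x, h0, c0)
        np.testing.assert_allclose(h, h_ref, atol=1e-10)
        np.testing.assert_allclose(c, c_ref, atol=1e-10)

    def test_update_gate_variant_differs_and_follows_formula(self):
        p = LSTMParams.random(3, 2, seed=6)
        rng = np.random.default_rng(7)
        x, h0, c0 = rng.normal(0, 1, 3), rng.normal(0, 1, 2), rng.normal(0, 1, 2)
        h_out, c_out = lstm_cell_step(p, x, h0, c0, ht_gate="output")
        h_upd, c_upd = lstm_cell_step(p, x, h0, c0, ht_gate="update")
        np.testing.assert_allclose(c_out, c_upd)
        assert not np.allclose(h_out, h_upd)

    def test_gates_strictly_inside_unit_interval(self):
        p = LSTMParams.random(4, 3, seed=8)
        rng = np.random.default_rng(9)
        z = np.concatenate([rng.normal(0, 2, 3), rng.normal(0, 2, 4)])
        for W, b in [(p.Wu, p.bu), (p.Wf, p.bf), (p.Wo, p.bo)]:
            g = 1 / (1 + np.exp(-(z @ W + b)))
            assert np.all(g > 0) and np.all(g < 1)


class TestBiLSTM:
    def test_length_one_output_size(self):
        p = LSTMParams.random(3, 4, seed=0)
        out = bilstm_encode(np.ones((1, 3)), p, p)
        assert out.shape == (1, 8)

    def test_palindrome_symmetry_with_shared_params(self):
        p = LSTMParams.random(2, 3, seed=1)
        rng = np.random.default_rng(2)
        half = rng.normal(0, 1, (3, 2))
        x = np.vstack([half, half[::-1]])       # palindromic input
        out = bilstm_encode(x, p, p)
        fwd, bwd = out[:, :3], out[:, 3:]
        # reversing positions swaps the roles of the two directions
        np.testing.assert_allclose(fwd, bwd[::-1], atol=1e-12)

    def test_reversal_swaps_direction_halves(self):
        fp = LSTMParams.random(2, 3, seed=3)
        bp = LSTMParams.random(2, 3, seed=4)
        x = np.random.default_rng(5).normal(0, 1, (6, 2))
        out = bilstm_encode(x, fp, bp)
        out_rev = bilstm_encode(x[::-1], bp, fp)
        np.testing.assert_allclose(out[:, :3], out_rev[::-1, 3:], atol=1e-12)
        np.testing.assert_allclose(out[:, 3:], out_rev[::-1, :3], atol=1e-12)

    def test_empty_sequence_rejected(self):
        p = LSTMParams.random(2, 3, seed=6)
        with pytest.raises(ValueError):
            bilstm_encode(np.zeros((0, 2)), p, p)

    def test_batched_layer_matches_functional_path(self):
        """The padded-batch trainable encoder and the single-sentence
        functional API must compute identical numbers."""
        rng = np.random.default_rng(7)
        enc = BiLSTMEncoder(3, 4, rng)
        fp = LSTMParams(enc.fwd.Wc.data, enc.fwd.Wu.data, enc.fwd.Wf.data,
                        enc.fwd.Wo.data, enc.fwd.bc.data, enc.fwd.bu.data,
                        enc.fwd.bf.data, enc.fwd.bo.data)
        bp = LSTMParams(enc.bwd.Wc.data, enc.bwd.Wu.data, enc.bwd.Wf.data,
                        enc.bwd.Wo.data, enc.bwd.bc.data, enc.bwd.bu.data,
                        enc.bwd.bf.data, enc.bwd.bo.data)
        x1 = rng.normal(0, 1, (5, 3))
        x2 = rng.normal(0, 1, (3, 3))
        batch = np.zeros((2, 5, 3))
        batch[0], batch[1, :3] = x1, x2
        mask = np.array([[1, 1, 1, 1, 1], [1, 1, 1, 0, 0]], float)
        out = enc.forward(Tensor(batch), mask).data
        np.testing.assert_allclose(out[0], bilstm_encode(x1, fp, bp), atol=1e-12)
        np.testing.assert_allclose(out[1, :3], bilstm_encode(x2, fp, bp), atol=1e-12)

    def test_context_reaches_distant_positions(self):
        # perturbing the first character changes encodings far away
        p1 = LSTMParams.random(2, 3, seed=8)
        p2 = LSTMParams.random(2, 3, seed=9)
        x = np.random.default_rng(10).normal(0, 1, (8, 2))
        base = bilstm_encode(x, p1, p2)
        x2 = x.copy()
        x2[0] += 0.5
        moved = bilstm_encode(x2, p1, p2)
        assert np.abs(moved[5:] - base[5:]).max() > 1e-8


class TestAttention:
    def test_single_key_returns_value(self):
        Z = scaled_dot_attention(np.random.default_rng(0).normal(0, 1, (3, 4)),
                                 np.ones((1, 4)), np.array([[7.0, 8.0]]))
        np.testing.assert_allclose(Z, np.tile([7.0, 8.0], (3, 1)))

    def test_identical_keys_average_values(self):
        K = np.ones((2, 3))
        V = np.array([[1.0, 0.0], [0.0, 2.0]])
        Z = scaled_dot_attention(np.ones((1, 3)), K, V)
        np.testing.assert_allclose(Z, [[0.5, 1.0]])

    def test_matches_naive_dense_computation(self):
        rng = np.random.default_rng(1)
        Q, K, V = rng.normal(0, 1, (3, 4)), rng.normal(0, 1, (5, 4)), rng.normal(0, 1, (5, 2))
        scores = Q @ K.T / 2.0                  # sqrt(d_k) = 2
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(scaled_dot_attention(Q, K, V), w @ V, atol=1e-10)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 2)))


class TestMultiHead:
    def test_single_head_identity_projections_reduce_to_attention(self):
        X = np.random.default_rng(2).normal(0, 1, (4, 3))
        p = MultiHeadParams(np.eye(3), np.eye(3), np.eye(3), np.eye(3), 1)
        np.testing.assert_allclose(multi_head(p, X),
                                   scaled_dot_attention(X, X, X), atol=1e-12)

    def test_permutation_equivariance(self):
        X = np.random.default_rng(3).normal(0, 1, (5, 4))
        p = MultiHeadParams.random(4, 2, seed=4)
        perm = np.array([3, 0, 4, 1, 2])
        np.testing.assert_allclose(multi_head(p, X[perm]),
                                   multi_head(p, X)[perm], atol=1e-10)

    def test_output_shape_and_divisibility(self):
        p = MultiHeadParams.random(6, 3, seed=5)
        assert multi_head(p, np.ones((7, 6))).shape == (7, 6)
        bad = MultiHeadParams.random(6, 3, seed=5)
        bad.n_heads = 4
        with pytest.raises(ValueError):
            multi_head(bad, np.ones((2, 6)))


class TestFFN:
    def test_zero_first_layer_broadcasts_b2(self):
        Z = np.random.default_rng(6).normal(0, 1, (4, 3))
        out = ffn(Z, np.zeros((3, 5)), np.zeros(5), np.zeros((5, 2)),
                  np.array([1.0, -2.0]))
        np.testing.assert_allclose(out, np.tile([1.0, -2.0], (4, 1)))

    def test_relu_zeroes_negative_preactivation(self):
        Z = np.ones((2, 2))
        out = ffn(Z, -np.eye(2), np.zeros(2), np.eye(2), np.array([3.0, 4.0]))
        np.testing.assert_allclose(out, np.tile([3.0, 4.0], (2, 1)))

    def test_matches_hand_rolled_arithmetic(self):
        rng = np.random.default_rng(7)
        Z, W1, b1 = rng.normal(0, 1, (3, 4)), rng.normal(0, 1, (4, 6)), rng.normal(0, 1, 6)
        W2, b2 = rng.normal(0, 1, (6, 2)), rng.normal(0, 1, 2)
        expect = np.maximum(0, Z @ W1 + b1) @ W2 + b2
        np.testing.assert_allclose(ffn(Z, W1, b1, W2, b2), expect, atol=1e-10)


class TestTransformer:
    def test_zero_layers_is_input_plus_positional(self):
        enc = TransformerEncoder(4, n_layers=0)
        x = np.random.default_rng(8).normal(0, 1, (5, 4))
        expect = x + sinusoidal_positional_encoding(5, 4)
        np.testing.assert_allclose(transformer_encode(enc, x), expect, atol=1e-12)

    def test_output_shape_preserved(self):
        enc = TransformerEncoder(8, n_heads=2, n_layers=2,
                                 rng=np.random.default_rng(9))
        assert transformer_encode(enc, np.ones((6, 8))).shape == (6, 8)

    def test_no_positional_encoding_is_permutation_equivariant(self):
        enc = TransformerEncoder(4, n_heads=2, n_layers=2,
                                 rng=np.random.default_rng(10), positional=False)
        x = np.random.default_rng(11).normal(0, 1, (5, 4))
        perm = np.array([4, 2, 0, 1, 3])
        np.testing.assert_allclose(transformer_encode(enc, x[perm]),
                                   transformer_encode(enc, x)[perm], atol=1e-9)

    def test_context_reaches_distant_positions(self):
        enc = TransformerEncoder(4, n_heads=2, n_layers=1,
                                 rng=np.random.default_rng(12))
        x = np.random.default_rng(13).normal(0, 1, (7, 4))
        x2 = x.copy()
        x2[0] += 0.5
        diff = np.abs(transformer_encode(enc, x2) - transformer_encode(enc, x))
        assert diff[3:].max() > 1e-8

    def test_empty_input_rejected(self):
        enc = TransformerEncoder(4, n_layers=1)
        with pytest.raises(ValueError):
            transformer_encode(enc, np.zeros((0, 4)))


class TestProjection:
    def test_zero_weights_zero_emissions(self):
        out = project_emissions(np.ones((3, 4)), np.zeros((4, 9)))
        np.testing.assert_array_equal(out, np.zeros((3, 9)))

    def test_nine_labels_for_four_classes(self, scheme):
        W = np.random.default_rng(14).normal(0, 1, (6, scheme.n_labels))
        out = project_emissions(np.ones((5, 6)), W)
        assert out.shape == (5, 9)

    def test_matches_direct_matrix_multiply(self):
        rng = np.random.default_rng(15)
        H, W, b = rng.normal(0, 1, (4, 5)), rng.normal(0, 1, (5, 3)), rng.normal(0, 1, 3)
        np.testing.assert_allclose(project_emissions(H, W, b), H @ W + b, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project_emissions(np.ones((3, 4)), np.zeros((5, 9)))
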