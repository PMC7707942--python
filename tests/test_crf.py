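"""Linear-chain CRF: scoring, partition, Viterbi, loss, legality mask."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from emrner.autodiff import Tensor
from emrner.corpus import TagScheme
from emrner.crf import (CRFLayer, CRFParams, MASKED_SCORE, build_legality_mask,
                        log_partition, nll_loss, path_score, viterbi_decode)


def all_paths(n, L):
    return itertools.product(range(L), repeat=n)


def random_instance(rng, n, L):
    emis = rng.normal(0, 2, (n, L))
    params = CRFParams(rng.normal(0, 1, (L, L)), rng.normal(0, 1, L),
                       rng.normal(0, 1, L))
    return emis, params


class TestPathScore:
    def test_single_position_only_emission_survives(self):
        params = CRFParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        assert path_score(np.array([[2.0]]), params, [0]) == pytest.approx(2.0)

    def test_hand_computed_two_step(self):
        # score = start[0] + e[0,0] + trans[0,1] + e[1,1] + end[1]
        params = CRFParams(np.array([[0.1, 0.2], [0.3, 0.4]]),
                           np.array([0.5, 0.6]), np.array([0.7, 0.8]))
        emis = np.array([[1.0, 2.0], [3.0, 4.0]])
        expected = 0.5 + 1.0 + 0.2 + 4.0 + 0.8
        assert path_score(emis, params, [0, 1]) == pytest.approx(expected)

    def test_masked_transition_below_minus_1e6(self):
        mask = np.array([[True, False], [True, True]])
        params = CRFParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2), mask)
        emis = np.ones((2, 2))
        assert path_score(emis, params, [0, 1]) <= -1e6

    def test_tag_out_of_range(self):
        params = CRFParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(IndexError):
            path_score(np.zeros((1, 2)), params, [5])


class TestLogPartition:
    def test_two_equal_paths_gives_log2(self):
        params = CRFParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        assert log_partition(np.zeros((1, 2)), params) == pytest.approx(np.log(2))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n, L = int(rng.integers(1, 6)), int(rng.integers(1, 5))
            emis, params = random_instance(rng, n, L)
            brute = logsumexp([path_score(emis, params, p)
                               for p in all_paths(n, L)])
            assert log_partition(emis, params) == pytest.approx(brute, abs=1e-8)

    def test_dominates_every_path_score(self):
        rng = np.random.default_rng(2)
        emis, params = random_instance(rng, 4, 3)
        lz = log_partition(emis, params)
        for p in all_paths(4, 3):
            assert lz >= path_score(emis, params, p)

    def test_shift_invariance(self):
        # adding c to every emission at one position adds c to logZ and
        # to every path score
        rng = np.random.default_rng(3)
        emis, params = random_instance(rng, 4, 3)
        shifted = emis.copy()
        shifted[2] += 1.7
        assert log_partition(shifted, params) == pytest.approx(
            log_partition(emis, params) + 1.7)

    def test_path_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        emis, params = random_instance(rng, 3, 3)
        lz = log_partition(emis, params)
        total = sum(np.exp(path_score(emis, params, p) - lz)
                    for p in all_paths(3, 3))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestViterbi:
    def test_single_position_argmax(self):
        params = CRFParams(np.zeros((3, 3)), np.array([0.0, 1.0, 0.0]),
                           np.array([0.0, 0.0, 2.0]))
        path, score = viterbi_decode(np.array([[1.0, 0.5, 0.0]]), params)
        assert path == [2] and score == pytest.approx(2.0)

    def test_matches_brute_force_with_tie_break(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n, L = int(rng.integers(1, 6)), int(rng.integers(1, 5))
            emis, params = random_instance(rng, n, L)
            path, score = viterbi_decode(emis, params)
            scores = {p: path_score(emis, params, p) for p in all_paths(n, L)}
            best = max(scores.values())
            # lowest-lexicographic argmax == lowest label index tie-break
            expect = min(p for p, s in scores.items() if s == pytest.approx(best, abs=1e-12))
            assert tuple(path) == expect
            assert score == pytest.approx(best, abs=1e-9)

    def test_decoded_path_respects_bio_mask(self, scheme):
        allowed, start_allowed = build_legality_mask(scheme)
        rng = np.random.default_rng(6)
        L = scheme.n_labels
        for _ in range(50):
            n = int(rng.integers(1, 10))
            params = CRFParams(rng.normal(0, 3, (L, L)), rng.normal(0, 3, L),
                               rng.normal(0, 3, L), allowed, start_allowed)
            path, _ = viterbi_decode(rng.normal(0, 3, (n, L)), params)
            assert start_allowed[path[0]]
            for a, b in zip(path, path[1:]):
                assert allowed[a, b]

    def test_over_constrained_mask_errors(self):
        mask = np.zeros((2, 2), dtype=bool)
        params = CRFParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2),
                           mask, np.zeros(2, dtype=bool))
        with pytest.raises(ValueError, match="no legal path"):
            viterbi_decode(np.zeros((2, 2)), params)


class TestNLL:
    def test_equals_brute_force_neg_log_prob(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, L = int(rng.integers(1, 5)), int(rng.integers(1, 4))
            emis, params = random_instance(rng, n, L)
            gold = rng.integers(0, L, n)
            lz = logsumexp([path_score(emis, params, p) for p in all_paths(n, L)])
            expected = lz - path_score(emis, params, gold)
            assert nll_loss(emis, params, gold) == pytest.approx(expected, abs=1e-8)
            assert nll_loss(emis, params, gold) >= -1e-12

    def test_loss_vanishes_when_gold_is_only_legal_path(self):
        # mask admits exactly one start label and one self-transition
        mask = np.array([[True, False], [False, False]])
        start_mask = np.array([True, False])
        params = CRFParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2),
                           mask, start_mask)
        loss = nll_loss(np.zeros((3, 2)), params, [0, 0, 0])
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_illegal_gold_transition_named(self):
        mask = np.array([[True, False], [True, True]])
        params = CRFParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2), mask)
        with pytest.raises(ValueError, match="0 -> 1"):
            nll_loss(np.zeros((2, 2)), params, [0, 1])


class TestLegalityMask:
    def test_four_classes_shape_and_o_row(self, scheme):
        allowed, start_allowed = build_legality_mask(scheme)
        assert allowed.shape == (9, 9)
        # O may be followed by O and each of the 4 B-c labels only
        assert allowed[0].sum() == 5
        assert not start_allowed[scheme.label_index("I-dis")]

    def test_single_class_transition_count(self):
        # {O,B,I}^2 minus the single forbidden O->I leaves 8 pairs; the
        # start constraint lives in the separate start mask
        allowed, start_allowed = build_legality_mask(TagScheme(("a",)))
        assert allowed.shape == (3, 3)
        assert allowed.sum() == 8
        assert start_allowed.tolist() == [True, True, False]

    def test_b_to_matching_i_always_allowed(self, scheme):
        allowed, _ = build_legality_mask(scheme)
        for c in scheme.classes:
            i = scheme.label_index(f"B-{c}")
            j = scheme.label_index(f"I-{c}")
            assert allowed[i, j]


class TestBatchedLayer:
    def test_batched_nll_matches_per_sentence_reference(self, scheme):
        """The trainable padded-batch loss must equal the mean of the
        single-sentence reference NLLs."""
        rng = np.random.default_rng(8)
        L = scheme.n_labels
        layer = CRFLayer(scheme, seed=9)
        params = layer.to_params()
        allowed, start_allowed = build_legality_mask(scheme)
        lengths = [5, 3, 1]
        B, T = len(lengths), max(lengths)
        emis = rng.normal(0, 1, (B, T, L))
        pad = np.zeros((B, T))
        tags = np.zeros((B, T), dtype=np.int64)
        ref = []
        for b, n in enumerate(lengths):
            pad[b, :n] = 1
            # build a BIO-legal gold path
            cur = 0
            for t in range(n):
                choices = np.flatnonzero(allowed[cur]) if t else np.flatnonzero(start_allowed)
                cur = int(rng.choice(choices))
                tags[b, t] = cur
            ref.append(nll_loss(emis[b, :n], params, tags[b, :n]))
        batched = layer.nll(Tensor(emis), tags, pad)
        assert float(batched.data) == pytest.approx(np.mean(ref), abs=1e-10)

    def test_viterbi_batch_matches_reference(self, scheme):
        rng = np.random.default_rng(10)
        L = scheme.n_labels
        layer = CRFLayer(scheme, seed=11)
        emis = rng.normal(0, 1, (2, 6, L))
        lengths = np.array([6, 4])
        paths = layer.viterbi(emis, lengths)
        params = layer.to_params()
        for b, n in enumerate(lengths):
            expect, _ = viterbi_decode(emis[b, :n], params)
            assert paths[b] == expect
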