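"""CRF branch against enumeration oracles; type branch against closed forms."""

import itertools

import numpy as np
import pytest
from scipy.special import erf, logsumexp as sp_logsumexp

from lexner.autodiff import Parameter, Tensor
from lexner.corpus_io import NONE_TYPE
from lexner.heads import (BOUNDARY_LABELS, CrfParams, TypeHeadParams,
                          asoftmax_loss, conv1d_same, crf_log_partition,
                          crf_loss, crf_path_score, radical_features,
                          resolve_span_type, viterbi_decode)

RNG = np.random.default_rng(123)
L = len(BOUNDARY_LABELS)


def free_crf(rng=None, scale=1.0):
    """CRF with random transitions and no structural constraints."""
    rng = rng or RNG
    crf = CrfParams.init(rng, forbid_invalid=False)
    crf.trans.data[...] = scale * rng.normal(size=crf.trans.data.shape)
    return crf


def enumerate_scores(emissions, crf):
    """Score of every label path by explicit summation (independent oracle)."""
    trans = crf.trans.data + crf.constraint_mask()
    T = emissions.shape[0]
    scores = {}
    for path in itertools.product(range(L), repeat=T):
        s = trans[crf.start, path[0]] + emissions[0, path[0]]
        for t in range(1, T):
            s += trans[path[t - 1], path[t]] + emissions[t, path[t]]
        s += trans[path[-1], crf.stop]
        scores[path] = s
    return scores


class TestCrfPathScore:
    def test_all_zero_scores_give_zero(self):
        crf = CrfParams.init(np.random.default_rng(0), forbid_invalid=False)
        crf.trans.data[...] = 0.0
        emissions = np.zeros((4, L))
        for path in ([0, 1, 2, 1], [2, 2, 2, 2]):
            assert crf_path_score(emissions, crf, path).item() == 0.0

    def test_single_step_expansion(self):
        crf = free_crf()
        emissions = RNG.normal(size=(1, L))
        y = 1
        expected = crf.trans.data[crf.start, y] + emissions[0, y] \
            + crf.trans.data[y, crf.stop]
        assert np.isclose(crf_path_score(emissions, crf, [y]).item(), expected)

    def test_matches_explicit_summation(self):
        crf = free_crf()
        emissions = RNG.normal(size=(3, L))
        path = (0, 2, 1)
        assert np.isclose(crf_path_score(emissions, crf, list(path)).item(),
                          enumerate_scores(emissions, crf)[path])

    def test_invalid_label_raises(self):
        crf = free_crf()
        with pytest.raises(ValueError):
            crf_path_score(np.zeros((2, L)), crf, [0, 5])


class TestCrfLogPartition:
    def test_uniform_scores_give_log_label_count_power(self):
        crf = CrfParams.init(np.random.default_rng(0), forbid_invalid=False)
        crf.trans.data[...] = 0.0
        for T in (1, 2, 5):
            z = crf_log_partition(np.zeros((T, L)), crf).item()
            assert np.isclose(z, T * np.log(L))

    def test_single_step_is_logsumexp_of_scores(self):
        crf = free_crf()
        emissions = RNG.normal(size=(1, L))
        expected = sp_logsumexp(crf.trans.data[crf.start, :L] + emissions[0]
                                + crf.trans.data[:L, crf.stop])
        assert np.isclose(crf_log_partition(emissions, crf).item(), expected)

    def test_matches_enumeration(self):
        for T in range(1, 7):
            crf = free_crf()
            emissions = RNG.normal(size=(T, L)) * 2.0
            expected = sp_logsumexp(list(enumerate_scores(emissions, crf).values()))
            assert abs(crf_log_partition(emissions, crf).item() - expected) < 1e-6

    def test_dominates_any_path_score(self):
        crf = free_crf()
        emissions = RNG.normal(size=(4, L))
        z = crf_log_partition(emissions, crf).item()
        for path in itertools.product(range(L), repeat=4):
            assert z > crf_path_score(emissions, crf, list(path)).item()

    def test_path_probabilities_sum_to_one(self):
        crf = free_crf()
        emissions = RNG.normal(size=(4, L))
        z = crf_log_partition(emissions, crf).item()
        total = sum(np.exp(s - z) for s in enumerate_scores(emissions, crf).values())
        assert np.isclose(total, 1.0)


class TestCrfLoss:
    def test_uniform_case_equals_sequence_entropy(self):
        crf = CrfParams.init(np.random.default_rng(0), forbid_invalid=False)
        crf.trans.data[...] = 0.0
        loss = crf_loss(np.zeros((2, L)), crf, [0, 1]).item()
        assert np.isclose(loss, np.log(9.0))

    def test_non_negative_on_random_instances(self):
        for _ in range(200):
            crf = free_crf()
            T = int(RNG.integers(1, 6))
            emissions = RNG.normal(size=(T, L)) * 3.0
            path = list(RNG.integers(0, L, size=T))
            assert crf_loss(emissions, crf, path).item() >= -1e-12

    def test_dominant_gold_emission_drives_loss_to_zero(self):
        crf = CrfParams.init(np.random.default_rng(0), forbid_invalid=False)
        crf.trans.data[...] = 0.0
        emissions = np.zeros((3, L))
        gold = [1, 2, 0]
        for t, y in enumerate(gold):
            emissions[t, y] = 50.0
        assert crf_loss(emissions, crf, gold).item() < 1e-6


class TestViterbi:
    def test_zero_transitions_reduce_to_per_step_argmax(self):
        crf = CrfParams.init(np.random.default_rng(0), forbid_invalid=False)
        crf.trans.data[...] = 0.0
        emissions = RNG.normal(size=(5, L))
        assert viterbi_decode(emissions, crf) == list(emissions.argmax(axis=1))

    def test_achieves_enumerated_maximum(self):
        for T in range(1, 7):
            crf = free_crf()
            emissions = RNG.normal(size=(T, L)) * 2.0
            path = viterbi_decode(emissions, crf)
            scores = enumerate_scores(emissions, crf)
            assert np.isclose(scores[tuple(path)], max(scores.values()))

    def test_forbidden_transition_never_decoded(self):
        O, I = BOUNDARY_LABELS.index("O"), BOUNDARY_LABELS.index("I")
        for trial in range(50):
            crf = CrfParams.init(np.random.default_rng(trial), forbid_invalid=True)
            crf.trans.data[...] = RNG.normal(size=crf.trans.data.shape) * 3.0
            emissions = RNG.normal(size=(6, L)) * 3.0
            path = viterbi_decode(emissions, crf)
            assert path[0] != I
            for a, b in zip(path, path[1:]):
                assert not (a == O and b == I)

    def test_invariant_to_constant_emission_shift(self):
        crf = free_crf()
        emissions = RNG.normal(size=(5, L))
        shifted = emissions.copy()
        shifted[2] += 7.5
        assert viterbi_decode(emissions, crf) == viterbi_decode(shifted, crf)


def _gelu(x):
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


class TestRadicalCnn:
    def test_width_two_convolution_matches_hand_computation(self):
        x = Tensor(RNG.normal(size=(1, 3, 2)))
        W = Parameter(RNG.normal(size=(4, 1)))
        b = Parameter(np.zeros(1))
        out = conv1d_same(x, W, b, 2).data[0, :, 0]
        xp = np.vstack([x.data[0], [0.0, 0.0]])  # width 2 pads on the right
        expected = [_gelu(np.concatenate([xp[i], xp[i + 1]]) @ W.data[:, 0])
                    for i in range(3)]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_constant_input_gives_translation_equivariant_interior(self):
        x = Tensor(np.ones((1, 8, 3)))
        W = Parameter(RNG.normal(size=(9, 2)))
        b = Parameter(RNG.normal(size=2))
        out = conv1d_same(x, W, b, 3).data[0]
        for t in range(2, 6):
            np.testing.assert_allclose(out[t], out[1])

    def make_head(self, d=6, n_rad=5, n_classes=3, seed=0):
        return TypeHeadParams.init(d, n_rad, n_classes,
                                   np.random.default_rng(seed),
                                   widths=(2, 3), n_filters=4, d_feat=8)

    def test_disabled_radical_branch_equals_zeroed_radical_activations(self):
        params = self.make_head()
        states = Tensor(RNG.normal(size=(1, 5, 6)))
        rads = RNG.integers(0, 5, size=(1, 5))
        off = radical_features(states, rads, params, use_radical_branch=False).data
        for w in params.widths:  # zero weights+bias => conv output gelu(0)=0
            params.convs[("rad", w)]["W"].data[...] = 0.0
            params.convs[("rad", w)]["b"].data[...] = 0.0
        zeroed = radical_features(states, rads, params).data
        np.testing.assert_allclose(off, zeroed)

    def test_radical_table_change_alters_features(self):
        params = self.make_head()
        states = Tensor(RNG.normal(size=(1, 5, 6)))
        r1 = np.zeros((1, 5), dtype=int)
        r2 = np.ones((1, 5), dtype=int)
        a = radical_features(states, r1, params).data
        b = radical_features(states, r2, params).data
        assert not np.allclose(a, b)


def cosine_softmax_oracle(x, W, labels):
    """Independent cross-entropy over ||x|| cos(theta_j) logits."""
    Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    logits = (x / xn) @ Wn.T * xn
    return float(np.mean(sp_logsumexp(logits, axis=1)
                         - logits[np.arange(len(labels)), labels]))


class TestASoftmax:
    def test_margin_one_equals_cosine_softmax(self):
        for trial in range(100):
            rng = np.random.default_rng(trial)
            N, d, C = 6, 5, 4
            x = Tensor(rng.normal(size=(N, d)) * 2.0)
            W = Parameter(rng.normal(size=(C, d)))
            labels = rng.integers(0, C, size=N)
            ours = asoftmax_loss(x, labels, W, m=1, lam=float(trial % 7)).item()
            assert abs(ours - cosine_softmax_oracle(x.data, W.data, labels)) < 1e-6

    def test_aligned_feature_closed_form(self):
        # feature on its class direction, other class directions orthogonal
        d, C = 4, 3
        W = Parameter(np.eye(C, d))
        r = 2.5
        x = Tensor(np.array([[r, 0.0, 0.0, 0.0]]))
        loss = asoftmax_loss(x, np.array([0]), W, m=1).item()
        # cos within the loss is clipped to 1 - 1e-7; closed form to that tol
        expected = -np.log(np.exp(r) / (np.exp(r) + (C - 1)))
        assert abs(loss - expected) < 1e-5

    def test_margin_increases_loss_on_correct_instance(self):
        d, C = 4, 3
        W = Parameter(np.eye(C, d))
        x = Tensor(np.array([[1.5, 0.3, 0.0, 0.0]]))
        l1 = asoftmax_loss(x, np.array([0]), W, m=1).item()
        l4 = asoftmax_loss(x, np.array([0]), W, m=4, lam=0.0).item()
        assert l4 >= l1

    def test_loss_decreases_as_gold_angle_shrinks(self):
        d, C = 3, 3
        W = Parameter(np.eye(C, d))
        losses = []
        for ang in (1.2, 0.8, 0.4, 0.1):
            x = Tensor(np.array([[np.cos(ang), np.sin(ang), 0.0]]) * 2.0)
            losses.append(asoftmax_loss(x, np.array([0]), W, m=4, lam=0.0).item())
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_zero_norm_feature_is_finite(self):
        W = Parameter(np.eye(3, 4))
        x = Tensor(np.zeros((1, 4)))
        assert np.isfinite(asoftmax_loss(x, np.array([1]), W, m=4).item())

    def test_invalid_margin_raises(self):
        W = Parameter(np.eye(3, 4))
        x = Tensor(np.ones((1, 4)))
        with pytest.raises(ValueError):
            asoftmax_loss(x, np.array([0]), W, m=0)


class TestResolveSpanType:
    def test_majority_vote(self):
        assert resolve_span_type(["Dis", "Dis", "Dru"]) == "Dis"

    def test_tie_broken_by_mean_probability(self):
        probs = np.array([[0.0, 0.6, 0.4], [0.0, 0.6, 0.4]])
        names = [NONE_TYPE, "Dis", "Dru"]
        assert resolve_span_type(["Dis", "Dru"], (probs, names), 0) == "Dis"
        probs2 = probs[:, [0, 2, 1]]
        names2 = [NONE_TYPE, "Dis", "Dru"]
        assert resolve_span_type(["Dis", "Dru"], (probs2, names2), 0) == "Dru"

    def test_all_none_votes_take_best_non_none_probability(self):
        probs = np.array([[0.8, 0.05, 0.15]])
        names = [NONE_TYPE, "Dis", "Dru"]
        assert resolve_span_type([NONE_TYPE], (probs, names), 0) == "Dru"

    def test_single_token_span(self):
        assert resolve_span_type(["Dru"]) == "Dru"

    def test_no_scores_all_none_returns_none_sentinel(self):
        assert resolve_span_type([NONE_TYPE, NONE_TYPE]) == NONE_TYPE
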