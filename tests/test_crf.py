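"""CRF: biased init, forward algorithm, Viterbi — against path enumeration."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from symptner.crf import (CRFParameters, count_invalid_transitions,
                          init_transitions, log_likelihood, log_partition,
                          random_transitions, sequence_score, viterbi_decode)

LABELS = ("O", "B-S", "I-S")


def enumerate_paths(emissions, params):
    """Independent oracle: score of every |labels|^T path."""
    T, L = emissions.shape
    scores = []
    for path in itertools.product(range(L), repeat=T):
        s = params.start_scores[path[0]] + emissions[0, path[0]]
        for t in range(1, T):
            s += params.transitions[path[t - 1], path[t]] + emissions[t, path[t]]
        s += params.end_scores[path[-1]]
        scores.append((s, path))
    return scores


class TestInit:
    def test_outside_to_inside_biased(self):
        p = init_transitions(LABELS, bias_value=-1e4)
        assert p.transitions[p.index("O"), p.index("I-S")] == -1e4

    def test_start_to_inside_biased(self):
        p = init_transitions(LABELS, bias_value=-1e4)
        assert p.start_scores[p.index("I-S")] == -1e4

    def test_legal_transition_finite_and_unbiased(self):
        p = init_transitions(LABELS, bias_value=-1e4)
        v = p.transitions[p.index("B-S"), p.index("I-S")]
        assert np.isfinite(v) and v != -1e4 and abs(v) < 1.0

    def test_cross_label_inside_biased_in_all_mode(self):
        labs = ("O", "B-A", "I-A", "B-B", "I-B")
        p = init_transitions(labs, bias_value=-1e4, mode="all")
        assert p.transitions[p.index("B-A"), p.index("I-B")] == -1e4
        assert p.transitions[p.index("B-A"), p.index("I-A")] != -1e4

    def test_literal_mode_biases_only_o_to_i(self):
        labs = ("O", "B-A", "I-A", "B-B", "I-B")
        p = init_transitions(labs, bias_value=-1e4, mode="o_to_i")
        assert p.transitions[p.index("O"), p.index("I-A")] == -1e4
        assert p.transitions[p.index("B-A"), p.index("I-B")] != -1e4
        assert p.start_scores[p.index("I-A")] != -1e4

    def test_empty_labels_error(self):
        with pytest.raises(ValueError):
            init_transitions(())


class TestForward:
    def test_uniform_two_labels_single_step(self):
        p = CRFParameters(("O", "B"), np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        assert log_partition(np.zeros((1, 2)), p) == pytest.approx(np.log(2))

    def test_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(300):
            T = int(rng.integers(1, 5))
            L = int(rng.integers(2, 5))
            p = random_transitions(tuple(f"L{i}" for i in range(L)),
                                   seed=trial, init_scale=1.5)
            em = rng.normal(0, 2, (T, L))
            oracle = logsumexp([s for s, _ in enumerate_paths(em, p)])
            assert log_partition(em, p) == pytest.approx(oracle, abs=1e-6)

    def test_emission_shift_property(self):
        rng = np.random.default_rng(1)
        p = random_transitions(LABELS, seed=1)
        em = rng.normal(0, 1, (4, 3))
        shifted = em.copy()
        shifted[2] += 2.5
        assert log_partition(shifted, p) == pytest.approx(
            log_partition(em, p) + 2.5)

    def test_nonfinite_emissions_error(self):
        p = random_transitions(LABELS)
        em = np.zeros((2, 3))
        em[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            log_partition(em, p)


class TestLikelihood:
    def test_single_label_degenerate_path(self):
        p = CRFParameters(("O",), np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        assert log_likelihood(np.zeros((3, 1)), ["O", "O", "O"], p) == \
            pytest.approx(0.0)

    def test_path_score_bounded_by_partition(self):
        rng = np.random.default_rng(2)
        p = random_transitions(LABELS, seed=2, init_scale=1.0)
        for _ in range(50):
            em = rng.normal(0, 2, (3, 3))
            tags = [LABELS[i] for i in rng.integers(0, 3, 3)]
            assert sequence_score(em, tags, p) <= log_partition(em, p) + 1e-9

    def test_path_likelihoods_normalize(self):
        rng = np.random.default_rng(3)
        p = random_transitions(LABELS, seed=3, init_scale=1.0)
        em = rng.normal(0, 1, (3, 3))
        total = sum(
            np.exp(log_likelihood(em, [LABELS[i] for i in path], p))
            for path in itertools.product(range(3), repeat=3))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_unknown_tag_errors(self):
        p = random_transitions(LABELS)
        with pytest.raises(KeyError):
            sequence_score(np.zeros((1, 3)), ["B-X"], p)


class TestViterbi:
    def test_favoured_begin_inside_path(self):
        p = init_transitions(LABELS, seed=0)
        em = np.array([[0.0, 5.0, 0.0], [0.0, 0.0, 5.0]])
        tags, _ = viterbi_decode(em, p)
        assert tags == ["B-S", "I-S"]

    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(4)
        for trial in range(300):
            T = int(rng.integers(1, 5))
            L = int(rng.integers(2, 4))
            p = random_transitions(tuple(f"L{i}" for i in range(L)),
                                   seed=1000 + trial, init_scale=1.5)
            em = rng.normal(0, 2, (T, L))
            best_score, best_path = max(enumerate_paths(em, p),
                                        key=lambda sp: sp[0])
            tags, score = viterbi_decode(em, p)
            assert score == pytest.approx(best_score, abs=1e-9)
            assert score == pytest.approx(
                sequence_score(em, tags, p), abs=1e-9)

    def test_tie_breaks_to_lowest_label_index(self):
        p = CRFParameters(("a", "b"), np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        tags, _ = viterbi_decode(np.zeros((3, 2)), p)
        assert tags == ["a", "a", "a"]

    def test_bias_forbids_inside_after_outside(self):
        p = init_transitions(LABELS, bias_value=-1e4, seed=5)
        rng = np.random.default_rng(6)
        for _ in range(100):
            em = rng.normal(0, 3, (5, 3))
            em[:, 2] += 3.0  # push towards I-S
            tags, _ = viterbi_decode(em, p)
            assert count_invalid_transitions(tags) == 0
            assert tags[0] != "I-S"


def test_count_invalid_transitions():
    assert count_invalid_transitions(["O", "I-S"]) == 1
    assert count_invalid_transitions(["I-S"]) == 1
    assert count_invalid_transitions(["B-S", "I-S", "O"]) == 0
    assert count_invalid_transitions(["B-A", "I-B"]) == 1
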