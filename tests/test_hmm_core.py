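"""The generic pair-HMM engine against brute-force path enumeration."""
import math

import numpy as np
import pytest

import _oracles as oracle
from sffalign.errors import InputError, ModelError
from sffalign.hmm import (EmissionClass, PairHMM, forward_backward,
                          sample_path, state_column_posteriors,
                          validate_model, viterbi_path)
from sffalign.models import build_three_state


def single_path_model():
    """start -> A (match) -> end with probability 1; emits ('A','A') only."""
    m = PairHMM()
    e = np.zeros((4, 4))
    e[0, 0] = 1.0
    m.add_state("A", EmissionClass.BOTH, e)
    m.add_transition("start", "A", 1.0)
    m.add_transition("A", "end", 1.0)
    return m


class TestValidateModel:
    def test_well_formed_model_is_valid(self, three_state_model):
        assert validate_model(three_state_model) == []

    def test_bad_outgoing_sum_names_the_state(self):
        m = single_path_model()
        m.transitions["A"]["end"] = 0.9
        msgs = validate_model(m)
        assert any("'A'" in v and "0.9" in v for v in msgs)

    def test_silent_cycle_is_reported(self):
        m = PairHMM()
        m.add_state("s1", EmissionClass.SILENT)
        m.add_state("s2", EmissionClass.SILENT)
        m.add_transition("start", "s1", 1.0)
        m.add_transition("s1", "s2", 1.0)
        m.add_transition("s2", "s1", 0.5)
        m.add_transition("s2", "end", 0.5)
        assert any("silent cycle" in v for v in validate_model(m))

    def test_bad_emission_sum_is_reported(self):
        m = single_path_model()
        m.emissions["A"] = np.full((4, 4), 0.9 / 16)
        assert any("emission" in v for v in validate_model(m))


class TestForwardBackward:
    def test_empty_sequences_give_start_to_end_mass(self, three_state_model):
        t = forward_backward(three_state_model, "", "")
        # only the direct start->end transition generates two empty sequences
        expected = math.log(three_state_model.transitions["start"]["end"])
        assert t.log_total_forward == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("X,Y", [("A", "C"), ("AG", "A"), ("ACG", "AC"),
                                     ("A", ""), ("", "GT")])
    def test_total_matches_path_enumeration(self, three_state_model, X, Y):
        t = forward_backward(three_state_model, X, Y)
        total = oracle.enum_total(three_state_model, X, Y)
        assert t.log_total_forward == pytest.approx(math.log(total), abs=1e-9)

    def test_forward_equals_backward_on_random_models(self, rng):
        for _ in range(25):
            m = oracle.random_pair_hmm(rng, with_context=True)
            X, Y = oracle.random_dna(rng), oracle.random_dna(rng)
            t = forward_backward(m, X, Y)
            if t.log_total_forward == -math.inf:
                assert t.log_total_backward == -math.inf
            else:
                assert t.log_total_forward == pytest.approx(
                    t.log_total_backward, rel=1e-6)

    def test_lowercase_accepted_and_bad_symbol_rejected(self, three_state_model):
        t1 = forward_backward(three_state_model, "acg", "ac")
        t2 = forward_backward(three_state_model, "ACG", "AC")
        assert t1.log_total_forward == t2.log_total_forward
        with pytest.raises(InputError):
            forward_backward(three_state_model, "ACN", "AC")

    def test_no_underflow_on_long_sequences(self, three_state_model, rng):
        # 10 kb against 1 kb keeps the full lattice small while pushing the
        # path log-probabilities far beyond linear-space range
        X = "".join("ACGT"[c] for c in rng.integers(0, 4, 10_000))
        Y = "".join("ACGT"[c] for c in rng.integers(0, 4, 1_000))
        t = forward_backward(three_state_model, X, Y)
        assert np.isfinite(t.log_total_forward)
        assert t.log_total_forward == pytest.approx(t.log_total_backward,
                                                    rel=1e-6)


class TestViterbi:
    def test_single_path_model(self):
        m = single_path_model()
        path, lp = viterbi_path(m, "A", "A")
        assert path == ["A"]
        assert lp == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("X,Y", [("AG", "A"), ("A", "C"), ("ACG", "A")])
    def test_matches_enumeration_max(self, three_state_model, X, Y):
        _, lp = viterbi_path(three_state_model, X, Y)
        _, best = oracle.enum_best_path(three_state_model, X, Y)
        assert lp == pytest.approx(math.log(best), abs=1e-9)

    def test_viterbi_not_above_forward_total(self, rng):
        for _ in range(20):
            m = oracle.random_pair_hmm(rng)
            X, Y = oracle.random_dna(rng), oracle.random_dna(rng)
            _, lp = viterbi_path(m, X, Y)
            total = forward_backward(m, X, Y).log_total_forward
            assert lp <= total + 1e-9

    def test_no_generating_path_flagged(self):
        m = single_path_model()
        path, lp = viterbi_path(m, "C", "C")  # emission prob 0 for ('C','C')
        assert path == [] and lp == -math.inf

    def test_path_generates_the_sequences(self, rng):
        for _ in range(20):
            m = oracle.random_pair_hmm(rng)
            X, Y = oracle.random_dna(rng), oracle.random_dna(rng)
            path, lp = viterbi_path(m, X, Y)
            if lp == -math.inf:
                continue
            nx = sum(1 for s in path
                     if m.emission_class[s] in (EmissionClass.BOTH,
                                                EmissionClass.X_ONLY))
            ny = sum(1 for s in path
                     if m.emission_class[s] in (EmissionClass.BOTH,
                                                EmissionClass.Y_ONLY))
            assert (nx, ny) == (len(X), len(Y))


class TestStateColumnPosteriors:
    def test_deterministic_model_has_unit_posteriors(self):
        m = single_path_model()
        P = state_column_posteriors(m, "A", "A")
        idx = m.compiled().index["A"]
        assert P[idx, 1, 1] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_matches_enumeration(self, three_state_model):
        P = state_column_posteriors(three_state_model, "AC", "AG")
        ref, _ = oracle.enum_state_posteriors(three_state_model, "AC", "AG")
        index = three_state_model.compiled().index
        for (s, i, j), v in ref.items():
            assert P[index[s], i, j] == pytest.approx(v, abs=1e-9)
        assert P.sum() == pytest.approx(
            sum(ref.values()), abs=1e-9)

    def test_normalization_per_consumed_symbol(self, three_state_model):
        X, Y = "ACG", "AT"
        P = state_column_posteriors(three_state_model, X, Y)
        comp = three_state_model.compiled()
        consumes_x = np.isin(comp.cls, (0, 1))
        for i in range(1, len(X) + 1):
            assert P[consumes_x, i, :].sum() == pytest.approx(1.0, abs=1e-6)


class TestSamplePath:
    def test_same_seed_reproduces(self, tiny_sff):
        a = sample_path(tiny_sff.hmm, 42)
        b = sample_path(tiny_sff.hmm, 42)
        assert a[0] == b[0] and a[1] == b[1] and a[3] == b[3]
        assert a[2] == b[2]

    def test_single_path_model_always_same(self):
        m = single_path_model()
        outs = {sample_path(m, seed)[:2] for seed in range(5)}
        assert outs == {("A", "A")}

    def test_transition_frequencies_within_three_sigma(self):
        # state with a 0.3 / 0.7 branch; 10,000 draws
        m = PairHMM()
        e = np.zeros(4)
        e[0] = 1.0
        m.add_state("a", EmissionClass.X_ONLY, e)
        m.add_state("b", EmissionClass.X_ONLY, e)
        m.add_transition("start", "a", 1.0)
        m.add_transition("a", "b", 0.3)
        m.add_transition("a", "end", 0.7)
        m.add_transition("b", "end", 1.0)
        rng = np.random.default_rng(7)
        hits = sum("b" in sample_path(m, rng)[3] for _ in range(10_000))
        p = 0.3
        sigma = math.sqrt(p * (1 - p) * 10_000)
        assert abs(hits - 10_000 * p) < 3 * sigma

    def test_unreachable_end_raises(self):
        m = PairHMM()
        e = np.zeros(4)
        e[0] = 1.0
        m.add_state("a", EmissionClass.X_ONLY, e)
        m.add_transition("start", "a", 1.0)
        m.add_transition("a", "a", 1.0)
        with pytest.raises(ModelError):
            sample_path(m, 1)


class TestSerialization:
    def test_exact_json_round_trip(self, tiny_sff):
        model = tiny_sff.hmm
        clone = PairHMM.from_json(model.to_json())
        assert clone.states == model.states
        assert clone.transitions == model.transitions
        assert clone.meta == model.meta
        for s in model.states:
            a, b = model.emissions[s], clone.emissions[s]
            assert (a is None and b is None) or np.array_equal(a, b)
        t1 = forward_backward(model, "ACA", "AC").log_total_forward
        t2 = forward_backward(clone, "ACA", "AC").log_total_forward
        assert t1 == t2
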