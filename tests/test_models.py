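"""Model builders: Jukes-Cantor emissions, sunflowers, SFF, SRF, TANTAN."""
import math

import numpy as np
import pytest

import _oracles as oracle
from sffalign.errors import ParameterError
from sffalign.hmm import forward_backward, validate_model, viterbi_path
from sffalign.models import (MotifLibrary, SffModel, SunflowerParams,
                             TantanParams, ThreeStateParams, build_sff,
                             build_srf, build_sunflower, build_tantan_pair,
                             build_three_state, jc_substitution,
                             motif_prior_from_counts)
from sffalign.simulate import sample_instance


class TestJukesCantor:
    def test_zero_time_is_deterministic(self):
        d = jc_substitution("A", 0.0)
        assert d[0] == pytest.approx(1.0) and d[1:].sum() == pytest.approx(0.0)

    def test_large_time_reaches_uniform(self):
        d = jc_substitution("C", 1e6)
        assert np.allclose(d, 0.25)

    def test_closed_form_at_default_time(self):
        t = 0.05
        d = jc_substitution("A", t)
        e = math.exp(-4 * t / 3)
        assert d[0] == pytest.approx(0.25 + 0.75 * e, abs=1e-12)
        for b in range(1, 4):
            assert d[b] == pytest.approx(0.25 * (1 - e), abs=1e-12)
        assert d.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            jc_substitution("A", -0.1)


class TestSunflower:
    def test_default_rates_wiring(self):
        frag = build_sunflower("ACG", SunflowerParams())
        assert validate_model(frag) == []
        matches = [s for s in frag.states
                   if frag.state_meta[s].get("role") == "match"]
        assert len(matches) == 3
        # per the wiring: M_j -> I_j with the insert rate, M_j -> delete
        # successor with the delete rate (0.005 each)
        assert frag.transitions["R:M0"]["R:I0"] == pytest.approx(0.005)
        assert frag.transitions["R:M0"]["R:D1"] == pytest.approx(0.005)

    def test_single_base_motif_has_no_delete_chain(self):
        frag = build_sunflower("A", SunflowerParams())
        assert validate_model(frag) == []
        assert not any(frag.state_meta[s].get("role", "").startswith("delete")
                       for s in frag.states)

    def test_pure_match_copy_count_is_geometric(self):
        params = SunflowerParams(t=0.0)
        frag = build_sunflower("AG", params)
        # probability of emitting exactly c perfect copies via matches only
        def pure_path_prob(c):
            per_copy = (1 - params.delete_rate) if c else 1.0
            p = 1 - params.delete_rate  # entry to M0
            step = 1 - params.insert_rate - params.delete_rate  # M0 -> M1
            wrap = (1 - params.insert_rate) * params.copy_continue
            exit_ = (1 - params.insert_rate) * (1 - params.copy_continue)
            return p * step * (wrap * step) ** (c - 1) * exit_

        ratio = pure_path_prob(3) / pure_path_prob(2)
        expected = (1 - params.insert_rate) * params.copy_continue * \
            (1 - params.insert_rate - params.delete_rate)
        assert ratio == pytest.approx(expected, rel=1e-12)
        # and the engine agrees with the closed form for c copies
        for c in (1, 2, 3):
            t = forward_backward(frag, "AG" * c, "")
            assert t.log_total_forward >= math.log(pure_path_prob(c)) - 1e-9

    def test_no_silent_cycle_and_delete_chain_cannot_close_a_period(self):
        frag = build_sunflower("ACGT", SunflowerParams())
        assert validate_model(frag) == []
        # a path through delete states only can never emit or wrap:
        # check structurally that no sequence of silent transitions returns
        # to column 0
        silent = {s for s in frag.states
                  if not frag.is_emitting(s) and s not in (frag.start, frag.end)}
        for s in silent:
            stack, seen = [s], set()
            while stack:
                u = stack.pop()
                for v in frag.transitions.get(u, {}):
                    if v in silent and v not in seen:
                        col_u = frag.state_meta[u].get("column", 0)
                        col_v = frag.state_meta[v].get("column", 0)
                        assert col_v > col_u  # silent moves only go forward
                        seen.add(v)
                        stack.append(v)

    def test_empty_motif_rejected(self):
        with pytest.raises(ParameterError):
            build_sunflower("", SunflowerParams())


class TestBuildSff:
    def test_empty_library_equals_three_state(self, rng):
        sff = build_sff(MotifLibrary([]), ThreeStateParams(), SunflowerParams())
        ts = build_three_state(ThreeStateParams())
        for _ in range(5):
            X = oracle.random_dna(rng, 6)
            Y = oracle.random_dna(rng, 6)
            a = forward_backward(sff, X, Y).log_total_forward
            b = forward_backward(ts, X, Y).log_total_forward
            assert a == pytest.approx(b, abs=1e-9)

    def test_entry_probabilities_proportional_to_priors(self, tiny_sff):
        hmm = tiny_sff.hmm
        e0 = hmm.transitions["hub"]["R0X:s"]
        e1 = hmm.transitions["hub"]["R1X:s"]
        assert e0 / e1 == pytest.approx(3.0, rel=1e-12)
        assert e0 + e1 == pytest.approx(tiny_sff.sunflower.motif_entry)

    def test_copy_counts_in_x_and_y_are_uncorrelated(self):
        # repeats are emitted per sequence with independent geometric copy
        # counts, so the sample correlation across sides should vanish
        sff = SffModel(MotifLibrary([("AC", 1.0)]),
                       sunflower=SunflowerParams(motif_entry=0.05))
        rng = np.random.default_rng(11)
        cx, cy = [], []
        while len(cx) < 5000:
            inst = sample_instance(sff, rng)
            for r in inst.repeats:
                cx.append(r.copies_x)
                cy.append(r.copies_y)
        r = np.corrcoef(cx[:5000], cy[:5000])[0, 1]
        assert abs(r) < 0.05

    def test_all_built_models_validate(self, tiny_sff):
        assert validate_model(tiny_sff.hmm) == []
        assert validate_model(build_tantan_pair(TantanParams(K=4))) == []
        assert validate_model(build_srf("ACG")) == []


class TestMotifPriors:
    @pytest.mark.parametrize("counts,expected", [
        ({"A": 1, "AC": 1}, [0.5, 0.5]),
        ({"A": 3, "AC": 1}, [0.75, 0.25]),
    ])
    def test_priors_proportional_to_counts(self, counts, expected):
        lib = motif_prior_from_counts(counts)
        assert np.allclose(sorted(lib.priors, reverse=True),
                           sorted(expected, reverse=True))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ParameterError):
            motif_prior_from_counts({"A": 0, "AC": 0})

    def test_full_scale_library_priors_normalize(self):
        # library of the size used with genome-scale repeat catalogues
        k = 310_091
        def motif(i):
            s = []
            v = i
            for _ in range(10):
                s.append("ACGT"[v % 4])
                v //= 4
            return "".join(s)
        counts = {motif(i): (i % 97) + 1 for i in range(k)}
        lib = motif_prior_from_counts(counts)
        assert len(lib) == k
        assert abs(lib.priors.sum() - 1.0) < 1e-9


class TestTantan:
    def test_zero_time_repeats_previous_symbol(self):
        model = build_tantan_pair(TantanParams(K=1, t=0.0))
        e = model.emissions["TX:R1"]
        for c in range(4):
            assert e[c, c] == pytest.approx(1.0)

    def test_model_validates_for_various_periods(self):
        for K in (1, 2, 5):
            assert validate_model(build_tantan_pair(TantanParams(K=K))) == []

    def test_period_two_conservation_matches_jukes_cantor(self):
        params = TantanParams(K=2, t=0.05)
        model = build_tantan_pair(params)
        e = model.emissions["TX:R2"]
        assert model.context_order["TX:R2"] == 2
        for c in range(4):
            assert np.allclose(e[c], jc_substitution(c, 0.05))


class TestSrf:
    def test_planted_tandem_repeat_recovered(self):
        rng = np.random.default_rng(3)
        left = "".join("ACGT"[c] for c in rng.integers(0, 4, 20))
        right = "".join("ACGT"[c] for c in rng.integers(0, 4, 20))
        seq = left + "ACGT" * 5 + right
        model = build_srf("ACGT")
        path, _ = viterbi_path(model, seq, "")
        labels = [1 if model.is_repeat_state(s) else 0
                  for s in path if model.is_emitting(s)]
        start = labels.index(1)
        end = len(labels) - labels[::-1].index(1)
        assert abs(start - 20) <= 2 and abs(end - 40) <= 2

    def test_dissimilar_sequence_yields_no_repeat(self):
        model = build_srf("AGT")
        path, _ = viterbi_path(model, "C" * 30, "")
        assert not any(model.is_repeat_state(s) for s in path)

    def test_repeat_at_sequence_start_allowed(self):
        model = build_srf("AC")
        path, _ = viterbi_path(model, "ACACACAC" + "GTTG", "")
        labels = [1 if model.is_repeat_state(s) else 0
                  for s in path if model.is_emitting(s)]
        assert labels[0] == 1
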