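"""Banding, TRF parsing, SRF reannotation, library restriction, realignment."""
import numpy as np
import pytest

from sffalign.alignment import (Alignment, RepeatAnnotation,
                                from_gapped_strings, validate_alignment)
from sffalign.decoding import decode
from sffalign.errors import FormatError
from sffalign.heuristics import (RepeatIntervalSets, band_mask, parse_trf_dat,
                                 realign_repeat_blocks, restrict_library,
                                 restricted_sff, split_windows,
                                 srf_reannotate, window_realign)
from sffalign.hmm import forward_backward
from sffalign.models import (MotifLibrary, SffModel, SunflowerParams,
                             ThreeStateParams, build_three_state)

TRF_SAMPLE = """Tandem Repeats Finder Program written by some author

Sequence: chrTest



Parameters: 2 7 7 80 10 50 500


10 21 4 3.0 4 95 0 24 25 25 25 25 1.9 ACGT ACGTACGTACGT
30 41 6 2.0 6 90 5 20 25 25 25 25 1.9 ACGTAC ACGTACACGTAC
50 59 5 2.0 5 100 0 20 25 25 25 25 1.9 AATGG AATGGAATGG
"""


class TestBandMask:
    def test_zero_width_keeps_only_guide_cells(self):
        guide = from_gapped_strings("ACG", "ACG")
        mask = band_mask(guide, 0)
        allowed = mask.to_array(3, 3)
        expected = np.zeros((4, 4), dtype=np.uint8)
        for i in range(4):
            expected[i, i] = 1
        assert np.array_equal(allowed, expected)

    def test_wide_band_equals_unbanded_forward(self, three_state_model):
        X, Y = "ACGTAC", "AGTAC"
        guide = from_gapped_strings("ACGTAC", "A-GTAC")
        mask = band_mask(guide, max(len(X), len(Y)))
        full = forward_backward(three_state_model, X, Y).log_total_forward
        banded = forward_backward(three_state_model, X, Y,
                                  band=mask).log_total_forward
        assert banded == pytest.approx(full, abs=1e-9)

    def test_mask_widens_around_gap_runs(self):
        guide = from_gapped_strings("ACGT----", "ACGTACGT")
        mask = band_mask(guide, 1)
        assert mask.contains_path(guide)
        # the horizontal run sits at i = 4; the row must span it
        assert mask.lo[4] <= 3 and mask.hi[4] >= 8 - 1

    def test_guide_always_inside_its_own_mask(self, rng):
        for _ in range(20):
            moves = [int(rng.integers(0, 3)) for _ in range(10)]
            guide = Alignment(moves)
            for width in (0, 2, 30):
                assert band_mask(guide, width).contains_path(guide)


class TestParseTrf:
    def test_three_records_hand_parsed(self):
        recs = parse_trf_dat(TRF_SAMPLE)
        assert len(recs) == 3
        assert recs[0].interval == (9, 21)
        assert recs[0].period == 4
        assert recs[0].consensus == "ACGT"
        assert recs[1].interval == (29, 41)
        assert recs[2].copy_number == pytest.approx(2.0)

    def test_header_only_file_gives_no_records(self):
        assert parse_trf_dat("Tandem Repeats Finder Program\n\n") == []
        assert parse_trf_dat("") == []

    def test_malformed_record_names_the_line(self):
        with pytest.raises(FormatError, match="line 1"):
            parse_trf_dat("10 oops 4 3.0 4 95 0 24 25 25 25 25 1.9 ACGT AC")


class TestSrfReannotate:
    def test_orthologous_interval_recovered_from_one_sided_discovery(self):
        rng = np.random.default_rng(8)
        flank = lambda: "".join("ACGT"[c] for c in rng.integers(0, 4, 25))
        X = flank() + "AGGC" * 6 + flank()
        Y = flank() + "AGGC" * 5 + flank()
        # consensus discovered in X only (e.g. by an external annotator)
        out = srf_reannotate({"AGGC"}, X, Y)
        assert any(abs(a - 25) <= 2 and abs(b - 49) <= 2
                   for a, b in out.intervals("X"))
        assert any(abs(a - 25) <= 2 and abs(b - 45) <= 2
                   for a, b in out.intervals("Y"))

    def test_empty_consensus_set(self):
        out = srf_reannotate(set(), "ACGT", "ACGT")
        assert out.t_x == [] and out.t_y == []

    def test_absent_motif_changes_nothing(self):
        out = srf_reannotate({"AGT"}, "C" * 40, "C" * 40)
        assert out.t_x == [] and out.t_y == []

    def test_planted_repeat_recovered_in_most_seeded_trials(self):
        params = SunflowerParams()
        hits = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            left = "".join("ACGT"[c] for c in rng.integers(0, 4, 20))
            right = "".join("ACGT"[c] for c in rng.integers(0, 4, 20))
            X = left + "ACT" * 7 + right
            out = srf_reannotate({"ACT"}, X, "", params)
            if any(abs(a - 20) <= 2 and abs(b - 41) <= 2
                   for a, b in out.intervals("X")):
                hits += 1
        assert hits >= 95


class TestRestrictLibrary:
    def test_kept_motifs_retain_original_entry_weights(self):
        lib = MotifLibrary([("A", 0.6), ("AC", 0.3), ("ACG", 0.1)])
        sub = restrict_library(lib, {"AC"})
        assert sub.motifs == [("AC", 0.3)]

    def test_novel_consensus_enters_at_minimum_prior(self):
        lib = MotifLibrary([("A", 0.6), ("AC", 0.3), ("ACG", 0.1)])
        sub = restrict_library(lib, {"AC", "AGGG"})
        assert dict(sub.motifs)["AGGG"] == pytest.approx(0.1)

    def test_full_observation_keeps_library_unchanged(self):
        lib = MotifLibrary([("A", 0.6), ("AC", 0.4)])
        sub = restrict_library(lib, {"A", "AC"})
        assert dict(sub.motifs) == dict(lib.motifs)

    def test_restricted_sff_keeps_hub_entry_probability(self):
        sff = SffModel(MotifLibrary([("A", 0.6), ("AC", 0.4)]))
        sub = restricted_sff(sff, {"AC"})
        full_entry = sff.hmm.transitions["hub"]["R1X:s"]  # motif AC
        sub_entry = sub.hmm.transitions["hub"]["R0X:s"]
        assert sub_entry == pytest.approx(full_entry, rel=1e-12)


class TestRealignRepeatBlocks:
    def test_identical_substrings_become_all_match(self):
        # a repeat block aligned as X-first/Y-second turns into matches
        aln = Alignment([0, 1, 1, 2, 2, 0])
        ann = RepeatAnnotation([0, 1, 1, 1, 1, 0])
        X, Y = "GACT", "GACT"
        out, out_ann = realign_repeat_blocks(aln, ann, X, Y)
        assert list(out.moves) == [0, 0, 0, 0]
        assert validate_alignment(out, 4, 4) == []

    def test_no_repeat_blocks_is_identity(self):
        aln = from_gapped_strings("AC-G", "ACTG")
        ann = RepeatAnnotation([0, 0, 0, 0])
        out, _ = realign_repeat_blocks(aln, ann, "ACG", "ACTG")
        assert out == aln

    def test_adjacent_gap_run_absorbed(self):
        # gap columns to the left of the repeat block join the realignment
        aln = Alignment([0, 1, 1, 2, 2, 0])
        ann = RepeatAnnotation([0, 0, 1, 1, 1, 0])
        X, Y = "GACT", "GACT"
        out, out_ann = realign_repeat_blocks(aln, ann, X, Y)
        assert list(out.moves) == [0, 0, 0, 0]
        # the absorbed gap columns are relabeled with the repeat block
        assert list(out_ann.labels) == [0, 1, 1, 0]

    def test_preserves_symbol_multisets(self, rng):
        for _ in range(10):
            moves = [0] + [int(rng.integers(0, 3)) for _ in range(8)] + [0]
            aln = Alignment(moves)
            ann = RepeatAnnotation([int(rng.integers(0, 2))
                                    for _ in range(len(moves))])
            X = "".join("ACGT"[c] for c in rng.integers(0, 4, aln.n))
            Y = "".join("ACGT"[c] for c in rng.integers(0, 4, aln.m))
            out, _ = realign_repeat_blocks(aln, ann, X, Y)
            assert out.n == aln.n and out.m == aln.m
            assert validate_alignment(out, aln.n, aln.m) == []


class TestWindowRealign:
    @pytest.fixture()
    def instance(self):
        rng = np.random.default_rng(21)
        flank = lambda k: "".join("ACGT"[c] for c in rng.integers(0, 4, k))
        left, right = flank(60), flank(60)
        X = left + "ACT" * 8 + right
        Y = left + "ACT" * 6 + right
        guide_rows = (left + "ACT" * 6 + "ACTACT" + right,
                      left + "ACT" * 6 + "------" + right)
        guide = from_gapped_strings(*guide_rows)
        ivs = RepeatIntervalSets([(60, 84, "ACT")], [(60, 78, "ACT")])
        return X, Y, guide, ivs

    def test_windows_partition_the_guide(self, instance):
        X, Y, guide, ivs = instance
        windows = split_windows(guide, ivs)
        assert windows[0].cols[0] == 0
        assert windows[-1].cols[1] == len(guide)
        for a, b in zip(windows[:-1], windows[1:]):
            assert a.cols[1] == b.cols[0]
            assert a.x[1] == b.x[0] and a.y[1] == b.y[0]

    def test_spliced_result_is_valid_and_repeat_window_is_redecoded(self, instance):
        X, Y, guide, ivs = instance
        sff = SffModel(MotifLibrary([("ACT", 1.0)]))

        def decoder(xs, ys, local):
            sub = restricted_sff(sff, {c for _, _, c in local.t_x + local.t_y}
                                 or {"ACT"})
            return decode(sub.hmm, xs, ys, "marginalized")

        out, ann = window_realign(guide, X, Y, ivs, decoder)
        assert validate_alignment(out, len(X), len(Y)) == []
        assert ann.labels.sum() > 0  # the repeat window found its repeat

    def test_no_repeat_windows_preserve_guide(self):
        guide = from_gapped_strings("ACGTACGTAC", "ACGTACGTAC")
        ivs = RepeatIntervalSets([], [])
        called = []

        def decoder(xs, ys, local):  # pragma: no cover - must not run
            called.append(1)
            raise AssertionError

        out, _ = window_realign(guide, "ACGTACGTAC", "ACGTACGTAC", ivs, decoder)
        assert out == guide and not called
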