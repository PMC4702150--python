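"""Dot-bracket parsing, hairpin screens and the 2-nt 3'-overhang duplex rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sramap as sm
from sramap.precursor_structure import StructureError, read_vienna, write_vienna

from conftest import perfect_hairpin


class TestParseDotBracket:
    def test_nested_pairs(self):
        pm = sm.parse_dot_bracket("((((....))))")
        assert pm.partner == {
            1: 12, 12: 1, 2: 11, 11: 2, 3: 10, 10: 3, 4: 9, 9: 4
        }

    def test_unpaired_only(self):
        pm = sm.parse_dot_bracket("...")
        assert pm.partner == {}

    def test_unclosed_brackets_raise_with_position(self):
        with pytest.raises(StructureError, match="3 unclosed"):
            sm.parse_dot_bracket("(((")

    def test_unmatched_close_raises_with_position(self):
        with pytest.raises(StructureError, match="position 1"):
            sm.parse_dot_bracket(").)")

    def test_other_bracket_alphabets_rejected(self):
        with pytest.raises(StructureError, match=r"\["):
            sm.parse_dot_bracket("[..]")

    balanced = st.recursive(
        st.just("."),
        lambda s: st.tuples(s, s).map(lambda t: "(" + t[0] + ")" + t[1]),
        max_leaves=30,
    )

    @settings(derandomize=True, max_examples=200)
    @given(balanced)
    def test_round_trip_reproduces_input(self, struct):
        pm = sm.parse_dot_bracket(struct)
        assert pm.to_dot_bracket() == struct
        for i, j in pm.partner.items():
            assert pm.partner[j] == i
            assert i != j


class TestBracketCoverage:
    def test_fully_paired_locus_passes(self):
        _seq, struct = perfect_hairpin(arm=40)
        pm = sm.parse_dot_bracket(struct)
        locus = sm.Locus("t", 15, 35)
        res = sm.bracket_coverage_screen(pm, locus)
        assert res.verdict and res.coverage == 1.0 and res.direction == "("

    def test_under_half_paired_fails(self):
        # 10 of 21 positions paired: coverage 0.476 < 0.5
        struct = "(" * 10 + "." * 11 + "...." + ")" * 10
        pm = sm.parse_dot_bracket(struct)
        res = sm.bracket_coverage_screen(pm, sm.Locus("t", 1, 21))
        assert res.coverage == pytest.approx(10 / 21)
        assert not res.verdict

    def test_mixed_direction_fails_despite_coverage(self):
        # 12 of 21 paired but 6 "(" and 6 ")": locus straddles a loop
        struct = "." * 4 + "(" * 6 + "...." + ")" * 6 + "." * 5 + "." * 4
        pm = sm.parse_dot_bracket(struct)
        res = sm.bracket_coverage_screen(pm, sm.Locus("t", 5, 25))
        assert res.coverage >= 0.5
        assert res.direction is None
        assert not res.verdict

    def test_locus_out_of_range_is_error(self):
        pm = sm.parse_dot_bracket("(((...)))")
        with pytest.raises(ValueError, match="exceeds"):
            sm.bracket_coverage_screen(pm, sm.Locus("t", 5, 50))


class TestDetectStemLoop:
    def test_mir_on_stem_arm_detected(self):
        _seq, struct = perfect_hairpin(arm=30, loop=6, flank5=5, flank3=5)
        pm = sm.parse_dot_bracket(struct)
        locus = sm.Locus("t", 8, 28)
        call = sm.detect_stem_loop(pm, locus)
        assert call is not None
        assert call.contains_mir
        assert call.n_pairs == 30
        assert call.arm5 == (6, 35)
        assert call.loop == (36, 41)
        assert call.arm3 == (42, 71)

    def test_locus_straddling_loop_rejected(self):
        _seq, struct = perfect_hairpin(arm=30, loop=6, flank5=0, flank3=0)
        pm = sm.parse_dot_bracket(struct)
        # spans the end of the 5' arm, the loop and the start of the 3' arm
        assert sm.detect_stem_loop(pm, sm.Locus("t", 25, 45)) is None

    def test_short_hairpins_below_min_stem_pairs_rejected(self):
        struct = "(" * 8 + "...." + ")" * 8 + ".." + "(" * 8 + "...." + ")" * 8
        pm = sm.parse_dot_bracket(struct)
        assert sm.detect_stem_loop(pm, sm.Locus("t", 1, 8)) is None
        assert sm.detect_stem_loop(pm, sm.Locus("t", 1, 8), min_stem_pairs=8) is not None

    def test_helix_extends_through_small_bulge(self):
        # 10 pairs, a 2-nt interior bulge on the 5' side, 10 more pairs
        struct = "(" * 10 + ".." + "(" * 10 + "...." + ")" * 20
        pm = sm.parse_dot_bracket(struct)
        call = sm.detect_stem_loop(pm, sm.Locus("t", 1, 10), min_stem_pairs=20)
        assert call is not None and call.n_pairs == 20

    def test_large_interior_loop_splits_helix(self):
        struct = "(" * 10 + "." * 20 + "(" * 10 + "...." + ")" * 10 + "." * 0 + ")" * 10
        pm = sm.parse_dot_bracket(struct)
        # with the default 12-nt cap the outer 10 pairs do not extend the helix
        assert sm.detect_stem_loop(pm, sm.Locus("t", 1, 10), min_stem_pairs=15) is None


class TestFindStar:
    def _setup(self, arm=40, loop=6, flank5=10, flank3=10, rng=None):
        seq, struct = perfect_hairpin(arm, loop, flank5, flank3, rng)
        return seq, sm.parse_dot_bracket(struct)

    def test_star_locus_and_overhangs_on_perfect_stem(self):
        # hand-derivable on a perfect stem: arm 40, loop 6, flank 10 pairs
        # i <-> 107-i, so mir 15..35 gives
        # star = [partner(33), partner(15)+2] = [74, 94]
        seq, pm = self._setup()
        mir = sm.Locus("t", 15, 35, seq[14:35])
        call = sm.find_star(pm, mir, [], seq)
        assert call is not None
        assert (call.star.start, call.star.end) == (74, 94)
        assert (call.overhang_3prime_mir, call.overhang_3prime_star) == (2, 2)
        assert not call.star_detected

    def test_unpaired_anchor_gives_none(self):
        # bulge at the mir's e-2 anchor
        struct = "." * 2 + "(" * 18 + "." + "(" * 10 + "...." + ")" * 28 + "." * 2
        pm = sm.parse_dot_bracket(struct)
        seq = "A" * pm.length
        mir = sm.Locus("t", 3, 23)  # e-2 = 21 is the bulged dot
        assert sm.find_star(pm, mir, [], seq) is None

    def test_star_detection_flag_from_libraries(self, design):
        seq, pm = self._setup()
        mir = sm.Locus("t", 15, 35, seq[14:35])
        star_seq = seq[73:94]
        lib = sm.SRNALibrary("stem", "1", {star_seq: 3})
        call = sm.find_star(pm, mir, [lib], seq)
        assert call is not None and call.star_detected
        assert call.star_rpm["stem_1"] == pytest.approx(1e6)

    def test_involution_and_overhangs_on_random_hairpins(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            arm = int(rng.integers(25, 61))
            loop = int(rng.integers(4, 13))
            seq, pm = self._setup(arm=arm, loop=loop, rng=rng)
            offset = int(rng.integers(0, arm - 21 + 1))
            s = 11 + offset
            mir = sm.Locus("t", s, s + 20, seq[s - 1 : s + 20])
            cov = sm.bracket_coverage_screen(pm, mir)
            assert cov.verdict and cov.coverage == 1.0
            call = sm.find_star(pm, mir, [], seq)
            assert call is not None
            assert (call.overhang_3prime_mir, call.overhang_3prime_star) == (2, 2)
            back = sm.find_star(pm, call.star, [], seq)
            assert back is not None
            assert (back.star.start, back.star.end) == (mir.start, mir.end)

    @pytest.mark.parametrize("shift,expected", [(1, (3, 3)), (-1, (1, 1))])
    def test_shifted_star_measures_wrong_overhangs(self, shift, expected):
        seq, pm = self._setup()
        mir = sm.Locus("t", 15, 35, seq[14:35])
        true_star = sm.find_star(pm, mir, [], seq).star
        shifted = sm.Locus(
            "t", true_star.start + shift, true_star.end + shift
        )
        assert sm.duplex_overhangs(pm, mir, shifted) == expected
        assert sm.duplex_overhangs(pm, mir, shifted) != (2, 2)

    def test_star_beyond_transcript_bounds_gives_none(self):
        seq, struct = perfect_hairpin(arm=40, loop=6, flank5=10, flank3=1)
        pm = sm.parse_dot_bracket(struct)
        mir = sm.Locus("t", 11, 31, seq[10:31])
        # partner(11)+2 exceeds the sequence end (flank3 too short)
        assert sm.find_star(pm, mir, [], seq) is None


class TestViennaIO:
    def test_round_trip(self, tmp_path):
        seq, struct = perfect_hairpin(arm=20, loop=4, flank5=3, flank3=3)
        p = tmp_path / "s.vienna"
        write_vienna({"hp": (seq, struct)}, p, rna=False)
        back = read_vienna(p)
        assert back == {"hp": (seq, struct)}

    def test_energy_suffix_tolerated(self, tmp_path):
        p = tmp_path / "s.vienna"
        p.write_text(">x\nACGTACGT\n((....)) (-1.20)\n")
        assert read_vienna(p)["x"] == ("ACGTACGT", "((....))")

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "s.vienna"
        p.write_text(">x\nACGT\n((....))\n")
        with pytest.raises(StructureError, match="mismatch"):
            read_vienna(p)
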