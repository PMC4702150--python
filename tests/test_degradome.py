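"""Degradome processing evidence, target scoring and cleavage validation."""

import numpy as np
import pytest

import sramap as sm
from sramap.degradome import OrganVerdict, _library_verdict
from sramap.sequencing_io import revcomp


def _deg(organ, entries, total=1_000_000):
    """entries: list of (transcript, position, seq, count)."""
    tags: dict[str, int] = {}
    placements = []
    for tid, pos, seq, count in entries:
        tags[seq] = tags.get(seq, 0) + count
        placements.append((tid, pos, seq))
    tags["A" * 40] = total - sum(tags.values())
    return sm.DegradomeLibrary(
        organ=organ, tags=tags, placements=placements, total=total
    )


def _tag(i, length=20):
    rng = np.random.default_rng(1000 + i)
    return "".join(rng.choice(list("ACGT"), size=length))


class TestProcessingEvidence:
    locus = sm.Locus("t1", 50, 70)

    def test_tag_at_three_prime_end(self):
        deg = _deg("stem", [("t1", 71, _tag(0), 30)])
        ev = sm.processing_evidence(deg, [self.locus])
        assert len(ev) == 1
        assert ev[0].end == "3p" and ev[0].expected_position == 71
        assert ev[0].rpm == pytest.approx(30.0)

    def test_tag_outside_tolerance_ignored(self):
        deg = _deg("stem", [("t1", 73, _tag(0), 30)])
        assert sm.processing_evidence(deg, [self.locus]) == []
        assert len(sm.processing_evidence(deg, [self.locus], tolerance=2)) == 1

    def test_both_ends_give_two_records(self):
        deg = _deg("stem", [("t1", 50, _tag(0), 5), ("t1", 71, _tag(1), 7)])
        ev = sm.processing_evidence(deg, [self.locus])
        assert sorted(e.end for e in ev) == ["3p", "5p"]


class TestScoreSite:
    mir = "TGACCTTGAAGCAGTCCAAGA"  # 21 nt

    def test_perfect_complement_scores_zero(self):
        site = sm.score_site(self.mir, revcomp(self.mir))
        assert site.score == 0.0
        assert site.alignment == "|" * 21

    def test_wobble_outside_core_is_half(self):
        window = list(revcomp(self.mir))
        # miRNA position 20 pairs window position L-20+1 = 2 (0-based 1)
        # mir[19] = 'G'; make the target 'T' -> G:U wobble
        assert self.mir[19] == "G"
        window[1] = "T"
        site = sm.score_site(self.mir, "".join(window))
        assert site.score == pytest.approx(0.5)
        assert site.alignment[19] == "o"

    def test_mismatch_in_core_is_doubled(self):
        window = list(revcomp(self.mir))
        # miRNA position 5 pairs window position 17 (0-based 16)
        current = window[16]
        window[16] = {"A": "C", "C": "A", "G": "A", "T": "C"}[current]
        site = sm.score_site(self.mir, "".join(window))
        assert site.score == pytest.approx(2.0)
        assert site.alignment[4] == "x"

    def test_position_10_coordinate(self):
        site = sm.score_site(self.mir, revcomp(self.mir), target_start=101)
        assert site.position_10 == 101 + 21 - 10
        assert site.position_11 == site.position_10 - 1

    def test_predict_sites_finds_embedded_complement(self):
        rng = np.random.default_rng(9)
        body = "".join(rng.choice(list("ACGT"), size=200))
        seq = body[:80] + revcomp(self.mir) + body[80:]
        catalog = sm.TranscriptCatalog({"t1": seq})
        sites = sm.predict_sites(self.mir, catalog, threshold=0.0)
        assert any(s.target_start == 81 and s.score == 0.0 for s in sites)


def _site(tid="t1", pos10=100):
    return sm.TargetSite(
        mir_id="miR-1", transcript_id=tid, target_start=pos10 - 11,
        alignment="|" * 21, position_10=pos10, score=0.0,
    )


class TestValidateCleavage:
    def test_rule1_boundary_inclusive(self):
        # site signatures 40 and 60 RPM (avg 50), surround 5,5,10,20 (avg 10)
        entries = [("t1", 100, _tag(0), 40), ("t1", 100, _tag(1), 60)]
        for i, c in enumerate((5, 5, 10, 20)):
            entries.append(("t1", 10 + 7 * i, _tag(2 + i), c))
        call = sm.validate_cleavage(_site(), [_deg("flower", entries)])
        v = call.per_organ["flower"]
        assert v.avg_site == pytest.approx(50.0)
        assert v.avg_surround == pytest.approx(10.0)
        assert v.rule1 and v.overall

    def test_rule1_fails_below_fold(self):
        entries = [("t1", 100, _tag(0), 49)]
        for i, c in enumerate((5, 5, 10, 20)):
            entries.append(("t1", 10 + 7 * i, _tag(1 + i), c))
        call = sm.validate_cleavage(_site(), [_deg("flower", entries)])
        assert not call.per_organ["flower"].rule1
        assert not call.validated

    @pytest.mark.parametrize("n_decoys,expected", [(11, True), (12, False), (13, False)])
    def test_rule2_top_twelve_ranking(self, n_decoys, expected):
        # decoys all more abundant than the site's best signature; verify the
        # rank against a brute-force sort of the signature counts
        entries = [("t1", 100, _tag(0), 10)]
        decoy_counts = [20 + i for i in range(n_decoys)]
        for i, c in enumerate(decoy_counts):
            entries.append(("t1", 200 + 25 * i, _tag(1 + i), c))
        deg = _deg("flower", entries, total=10_000_000)
        v = _library_verdict(deg, _site(), 100, fold=5.0, top_k=12)
        all_counts = sorted([10] + decoy_counts, reverse=True)
        brute_rank = all_counts.index(10) + 1
        assert (brute_rank <= 12) == expected
        assert v.rule2 == expected

    def test_rule2_tie_shares_better_rank(self):
        # 12 decoys, one tied with the site's best -> 11 strictly greater
        entries = [("t1", 100, _tag(0), 10)]
        counts = [10] + [20 + i for i in range(11)]
        for i, c in enumerate(counts):
            entries.append(("t1", 200 + 25 * i, _tag(1 + i), c))
        deg = _deg("flower", entries, total=10_000_000)
        v = _library_verdict(deg, _site(), 100, fold=5.0, top_k=12)
        assert v.rule2

    def test_rule3_position_convention(self):
        entries = [("t1", 100, _tag(0), 50)]
        deg = _deg("flower", entries)
        # opposite nt 10 (position 100) and nt 11 (99) pass; nt 9 (101) fails
        assert sm.validate_cleavage(_site(), [deg]).per_organ["flower"].rule3
        v11 = sm.validate_cleavage(_site(), [deg], cleavage_position=99)
        assert v11.per_organ["flower"].rule3
        v9 = sm.validate_cleavage(_site(), [deg], cleavage_position=101)
        assert not v9.per_organ["flower"].rule3

    def test_no_placements_gives_all_false(self):
        deg = _deg("flower", [("other", 5, _tag(0), 3)])
        v = sm.validate_cleavage(_site(), [deg]).per_organ["flower"]
        assert not (v.rule1 or v.rule2 or v.rule3 and v.overall)
        assert not v.overall

    def test_monotone_in_fold_and_top_k(self):
        rng = np.random.default_rng(17)
        entries = [("t1", 100, _tag(0), 30)]
        for i in range(15):
            entries.append(
                ("t1", 150 + 20 * i, _tag(1 + i), int(rng.integers(1, 60)))
            )
        deg = _deg("flower", entries, total=10_000_000)
        for fold, top_k in [(2, 15), (5, 12), (10, 6), (50, 2)]:
            loose = _library_verdict(deg, _site(), 100, fold=fold, top_k=top_k)
            strict = _library_verdict(
                deg, _site(), 100, fold=fold * 2, top_k=max(1, top_k // 2)
            )
            assert not (strict.rule1 and not loose.rule1)
            assert not (strict.rule2 and not loose.rule2)

    def test_library_order_invariance(self):
        entries = [("t1", 100, _tag(0), 40), ("t1", 30, _tag(1), 4)]
        degs = [_deg("root", entries), _deg("flower", entries)]
        a = sm.validate_cleavage(_site(), degs)
        b = sm.validate_cleavage(_site(), degs[::-1])
        for organ in ("root", "flower"):
            assert a.per_organ[organ] == b.per_organ[organ]


class TestOrganSpecificity:
    def _call(self, verdicts: dict[str, bool]):
        call = sm.CleavageSiteCall(site=_site(), cleavage_position=100)
        for organ, ok in verdicts.items():
            call.per_organ[organ] = OrganVerdict(
                avg_site=1.0, avg_surround=0.0, rule1=ok, rule2=ok, rule3=ok
            )
        return call

    def test_single_organ_is_specific(self):
        cls = sm.organ_specificity_of_regulation(
            self._call({"root": False, "stem": False, "leaf": False,
                        "flower": True})
        )
        assert cls["organ_specific"] == "flower"
        assert cls["label"] == "flower-specific"

    def test_leaf_and_stem_is_vegetative(self):
        cls = sm.organ_specificity_of_regulation(
            self._call({"root": False, "stem": True, "leaf": True,
                        "flower": False})
        )
        assert cls["organ_specific"] is None
        assert cls["vegetative_specific"]
        assert cls["label"] == "vegetative-specific"

    def test_all_true_is_constitutive(self):
        cls = sm.organ_specificity_of_regulation(
            self._call({o: True for o in ("root", "stem", "leaf", "flower")})
        )
        assert cls["label"] == "constitutive"
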