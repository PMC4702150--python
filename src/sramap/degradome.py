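"""Degradome (PARE) evidence: precursor processing and cleavage validation.

A degradome tag's 5' end marks the 5' end of an uncapped RNA fragment.
Two kinds of evidence are extracted:

* *Processing evidence* — Dicer-like 1 excision of a duplex from its
  precursor leaves fragment ends at the duplex boundaries, so a tag whose
  5' end sits exactly one base past a locus's 3' end (position ``end + 1``)
  or exactly at its 5' end (position ``start``) supports processing.

* *Cleavage-site validation* — AGO1 slices a target between nucleotides 10
  and 11 of the guide miRNA.  A candidate site passes in a degradome
  library iff three rules hold: (1) the mean RPM of the distinct signatures
  at the site is at least ``fold`` (default 5) times the mean RPM of the
  distinct signatures elsewhere on the transcript; (2) the most abundant
  site signature ranks within the ``top_k`` (default 12) most abundant
  signatures on the transcript, ties sharing the better rank; (3) the site
  lies opposite miRNA nucleotide 10 or 11.  A site is retained when all
  three rules hold in at least one library.

The complementarity scorer is deliberately simple plumbing: a gapless
per-position penalty sum (mismatch 1, G:U wobble 0.5, doubled over miRNA
positions 2-13) standing in for external target prediction; predicted
sites may equally be supplied as a TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .sequencing_io import (
    DegradomeLibrary,
    TranscriptCatalog,
    normalize_seq,
    revcomp,
)
from .precursor_structure import Locus

VEGETATIVE_ORGANS = ("root", "stem", "leaf")

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class ProcessingEvidence:
    """A degradome signature at one end of a duplex/block locus."""

    transcript_id: str
    locus: Locus
    end: str                  # "5p" or "3p"
    expected_position: int
    organ: str
    tag_sequence: str
    rpm: float


@dataclass
class TargetSite:
    """A candidate miRNA binding site on a target transcript.

    ``alignment`` has one state per miRNA position, 5'->3': ``|`` paired,
    ``o`` G:U wobble, ``x`` mismatch.  ``position_10`` is the target
    coordinate opposite miRNA nucleotide 10 (the canonical cleavage
    position); nucleotide 11 sits one base 5' of it on the target.
    """

    mir_id: str
    transcript_id: str
    target_start: int         # 1-based start of the site window
    alignment: str
    position_10: int
    score: float

    @property
    def mir_length(self) -> int:
        return len(self.alignment)

    @property
    def position_11(self) -> int:
        return self.position_10 - 1


@dataclass
class OrganVerdict:
    avg_site: float
    avg_surround: float
    rule1: bool
    rule2: bool
    rule3: bool

    @property
    def overall(self) -> bool:
        return self.rule1 and self.rule2 and self.rule3


@dataclass
class CleavageSiteCall:
    site: TargetSite
    cleavage_position: int
    per_organ: dict[str, OrganVerdict] = field(default_factory=dict)

    @property
    def validated(self) -> bool:
        return any(v.overall for v in self.per_organ.values())

    @property
    def organs_validated(self) -> list[str]:
        return [o for o, v in self.per_organ.items() if v.overall]


# ---------------------------------------------------------------------------
# precursor processing evidence
# ---------------------------------------------------------------------------

def processing_evidence(
    deg: DegradomeLibrary,
    loci: Iterable[Locus],
    tolerance: int = 0,
) -> list[ProcessingEvidence]:
    """Signatures at the 5' end or one-past-the-3'-end of each locus.

    For a locus ``[s, e]`` the 3'-end expectation is a tag 5' end at
    ``e + 1`` and the 5'-end expectation a tag 5' end at ``s``, each within
    ``tolerance`` nucleotides.
    """
    out: list[ProcessingEvidence] = []
    for locus in loci:
        placements = deg.placements_on(locus.transcript_id)
        for end, expected in (("5p", locus.start), ("3p", locus.end + 1)):
            for pos, seq in placements:
                if abs(pos - expected) <= tolerance:
                    out.append(
                        ProcessingEvidence(
                            transcript_id=locus.transcript_id,
                            locus=locus,
                            end=end,
                            expected_position=expected,
                            organ=deg.organ,
                            tag_sequence=seq,
                            rpm=deg.rpm(seq),
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# complementarity scoring (plumbing)
# ---------------------------------------------------------------------------

def _pair_state(mir_nt: str, target_nt: str) -> str:
    """Pairing state of one miRNA nucleotide against its target partner.

    Both are given in DNA space and in the sense of their own strands; the
    miRNA pairs antiparallel with the target, so a match means the target
    nucleotide is the Watson-Crick complement of the miRNA nucleotide.
    G:U wobbles (mir G vs target T, or mir T vs target G) count as ``o``.
    """
    if _COMPLEMENT.get(mir_nt) == target_nt:
        return "|"
    if (mir_nt, target_nt) in (("G", "T"), ("T", "G")):
        return "o"
    return "x"


def score_site(
    mir_seq: str,
    target_window: str,
    mir_id: str = "",
    transcript_id: str = "",
    target_start: int = 1,
) -> TargetSite:
    """Score a gapless miRNA/target alignment by penalty sum.

    The target window (5'->3', same length as the miRNA) is aligned
    antiparallel: miRNA nucleotide ``i`` (1-based from its 5' end) pairs
    with window position ``L - i + 1``.  Penalties: mismatch 1.0, G:U
    wobble 0.5, doubled at miRNA positions 2-13 (the slicing-critical
    core).  The target position opposite miRNA nucleotide 10 is
    ``target_start + L - 10``.
    """
    mir = normalize_seq(mir_seq)
    window = normalize_seq(target_window)
    if len(window) != len(mir):
        raise ValueError("target window length must equal miRNA length")
    L = len(mir)
    states = []
    score = 0.0
    for i in range(1, L + 1):
        state = _pair_state(mir[i - 1], window[L - i])
        states.append(state)
        penalty = {"|": 0.0, "o": 0.5, "x": 1.0}[state]
        if 2 <= i <= 13:
            penalty *= 2.0
        score += penalty
    return TargetSite(
        mir_id=mir_id,
        transcript_id=transcript_id,
        target_start=target_start,
        alignment="".join(states),
        position_10=target_start + L - 10,
        score=score,
    )


def predict_sites(
    mir_seq: str,
    catalog: TranscriptCatalog,
    mir_id: str = "",
    threshold: float = 4.0,
) -> list[TargetSite]:
    """Scan every transcript window and keep sites scoring <= threshold."""
    mir = normalize_seq(mir_seq)
    L = len(mir)
    sites: list[TargetSite] = []
    for tid in sorted(catalog.records):
        seq = catalog.records[tid]
        for start in range(1, len(seq) - L + 2):
            site = score_site(
                mir, seq[start - 1 : start - 1 + L],
                mir_id=mir_id, transcript_id=tid, target_start=start,
            )
            if site.score <= threshold:
                sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# cleavage-site validation
# ---------------------------------------------------------------------------

def _library_verdict(
    deg: DegradomeLibrary,
    site: TargetSite,
    cleavage_position: int,
    fold: float,
    top_k: int,
) -> OrganVerdict:
    placements = deg.placements_on(site.transcript_id)
    if not placements:
        return OrganVerdict(
            avg_site=0.0, avg_surround=0.0,
            rule1=False, rule2=False, rule3=False,
        )
    site_seqs = sorted({s for p, s in placements if p == cleavage_position})
    other_seqs = sorted({s for p, s in placements if p != cleavage_position})
    avg_site = (
        sum(deg.rpm(s) for s in site_seqs) / len(site_seqs) if site_seqs else 0.0
    )
    avg_surround = (
        sum(deg.rpm(s) for s in other_seqs) / len(other_seqs)
        if other_seqs
        else 0.0
    )
    # rule 1: site mean at least fold x surrounding mean; a silent site never
    # passes, and an empty surrounding (5 x 0 = 0) does not block a real site
    rule1 = bool(site_seqs) and avg_site >= fold * avg_surround
    # rule 2: best site signature within the top_k most abundant signatures
    # on the transcript; ties share the better rank
    if site_seqs:
        best = max(deg.tags[s] for s in site_seqs)
        all_counts = [deg.tags[s] for s in {s for _, s in placements}]
        rank = 1 + sum(1 for c in all_counts if c > best)
        rule2 = rank <= top_k
    else:
        rule2 = False
    rule3 = cleavage_position in (site.position_10, site.position_11)
    return OrganVerdict(
        avg_site=avg_site,
        avg_surround=avg_surround,
        rule1=rule1,
        rule2=rule2,
        rule3=rule3,
    )


def validate_cleavage(
    site: TargetSite,
    degs: Sequence[DegradomeLibrary],
    cleavage_position: Optional[int] = None,
    fold: float = 5.0,
    top_k: int = 12,
) -> CleavageSiteCall:
    """Evaluate the three degradome rules for a site in every library.

    ``cleavage_position`` defaults to the position opposite miRNA
    nucleotide 10; passing another position lets a caller test arbitrary
    candidate cleavage positions (rule 3 then fails unless it is opposite
    nucleotide 10 or 11).  A transcript with no placements in a library
    yields an all-false verdict for that library.
    """
    pos = cleavage_position if cleavage_position is not None else site.position_10
    call = CleavageSiteCall(site=site, cleavage_position=pos)
    for deg in degs:
        call.per_organ[deg.organ] = _library_verdict(deg, site, pos, fold, top_k)
    return call


def organ_specificity_of_regulation(
    call: CleavageSiteCall,
    vegetative: Sequence[str] = VEGETATIVE_ORGANS,
    reproductive: str = "flower",
) -> dict[str, object]:
    """Classify a validated miRNA-target pair by the organs supporting it.

    organ-specific: overall verdict true in exactly one organ.
    vegetative-specific: true in at least one vegetative organ (root, stem
    or leaf) and false in the reproductive organ.  Constitutive: true in
    every organ; unsupported: true in none.
    """
    validated = call.organs_validated
    n = len(validated)
    organ_specific = validated[0] if n == 1 else None
    vegetative_specific = (
        any(o in validated for o in vegetative) and reproductive not in validated
    )
    if n == 0:
        label = "unsupported"
    elif n == len(call.per_organ):
        label = "constitutive"
    elif organ_specific is not None:
        label = f"{organ_specific}-specific"
    elif vegetative_specific:
        label = "vegetative-specific"
    else:
        label = "mixed"
    return {
        "organs_validated": validated,
        "organ_specific": organ_specific,
        "vegetative_specific": vegetative_specific,
        "label": label,
    }
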