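"""Phase-distributed miRNA-like sRNAs on long precursor stems.

Long hairpin stems can be processed progressively by Dicer-like 1, releasing
a ladder of short duplexes: small RNAs tile one arm head-to-tail and each
tiling locus forms a duplex with a partner on the other arm, every duplex
carrying the diagnostic 2-nt 3' overhangs.  "In phase" is operationalized
as exact head-to-tail adjacency (next start = previous end + 1) on the
seeding arm; a small adjacency tolerance is exposed because natural
registers can slip by a nucleotide.

Chains are seeded on whichever arm carries more perfectly mapped loci; the
partner arm is derived through the duplex geometry rather than chained
independently, so a duplex is never reported twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .precursor_structure import (
    DuplexCall,
    Locus,
    PairingMap,
    StemLoopCall,
    find_star,
)
from .sequencing_io import SRNALibrary


@dataclass
class PhasedBlock:
    """A chain of adjacent sRNA loci on one arm with their duplex partners.

    ``partners[i]`` is None for a singleton: a chained locus whose
    geometric partner sequence was not detected in any library (or whose
    duplex geometry failed).
    """

    transcript_id: str
    loci: list[Locus]
    partners: list[Optional[Locus]]
    overhangs: list[Optional[tuple[int, int]]]
    rpm: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_duplexes(self) -> int:
        return sum(1 for p in self.partners if p is not None)

    @property
    def n_singletons(self) -> int:
        return sum(1 for p in self.partners if p is None)


def map_srnas_to_stem(
    libs: list[SRNALibrary],
    transcript_id: str,
    transcript_seq: str,
    stem: StemLoopCall,
    min_len: int = 18,
    max_len: int = 26,
) -> list[Locus]:
    """Perfect sense placements of library sRNAs fully inside a stem arm.

    Only sequences within the length bounds are considered; a placement
    straddling the loop or an arm boundary is excluded.  Loci are
    deduplicated by interval and sorted by (start, end).
    """
    sequences = sorted(
        {s for lib in libs for s in lib.counts if min_len <= len(s) <= max_len}
    )
    arms = [stem.arm5, stem.arm3]
    loci: dict[tuple[int, int], Locus] = {}
    for seq in sequences:
        start = transcript_seq.find(seq)
        while start != -1:
            s, e = start + 1, start + len(seq)
            if any(a0 <= s and e <= a1 for a0, a1 in arms):
                loci.setdefault((s, e), Locus(transcript_id, s, e, seq))
            start = transcript_seq.find(seq, start + 1)
    return [loci[k] for k in sorted(loci)]


def _chains(
    loci: list[Locus], tolerance: int
) -> list[list[Locus]]:
    """Greedy head-to-tail chaining of sorted, deduplicated loci."""
    chains: list[list[Locus]] = []
    for locus in sorted(loci, key=lambda l: (l.start, l.end)):
        if chains and abs(locus.start - (chains[-1][-1].end + 1)) <= tolerance:
            chains[-1].append(locus)
        else:
            chains.append([locus])
    return chains


def find_phased_blocks(
    loci: list[Locus],
    pm: PairingMap,
    transcript_seq: str,
    libs: list[SRNALibrary],
    stem: Optional[StemLoopCall] = None,
    min_chain: int = 2,
    tolerance: int = 0,
) -> list[PhasedBlock]:
    """Report chains of >= ``min_chain`` adjacent loci with duplex partners.

    When ``stem`` is given, chaining is seeded on whichever arm carries
    more mapped loci and the other arm is reached only through the duplex
    geometry; otherwise all loci are chained together.  For each chained
    locus a partner call is attempted with the 2-nt 3'-overhang rule and
    the partner is kept only if its sequence is detected (raw count >= 1)
    in at least one library; undetected partners leave the locus flagged
    as a singleton within its block.
    """
    if stem is not None:
        arm5 = [l for l in loci if stem.arm_of(l.start) == "5p"]
        arm3 = [l for l in loci if stem.arm_of(l.start) == "3p"]
        seed = arm5 if len(arm5) >= len(arm3) else arm3
    else:
        seed = list(loci)
    blocks: list[PhasedBlock] = []
    for chain in _chains(seed, tolerance):
        if len(chain) < min_chain:
            continue
        partners: list[Optional[Locus]] = []
        overhangs: list[Optional[tuple[int, int]]] = []
        rpm: dict[str, dict[str, float]] = {}
        for locus in chain:
            call = find_star(pm, locus, libs, transcript_seq)
            if call is not None and call.star_detected:
                partners.append(call.star)
                overhangs.append(
                    (call.overhang_3prime_mir, call.overhang_3prime_star)
                )
                rpm[f"{call.star.start}-{call.star.end}"] = call.star_rpm
            else:
                partners.append(None)
                overhangs.append(None)
            rpm[f"{locus.start}-{locus.end}"] = {
                lib.name: lib.rpm(locus.sequence) for lib in libs
            }
        blocks.append(
            PhasedBlock(
                transcript_id=chain[0].transcript_id,
                loci=chain,
                partners=partners,
                overhangs=overhangs,
                rpm=rpm,
            )
        )
    return blocks
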