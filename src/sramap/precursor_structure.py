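"""Secondary-structure screening of candidate miRNA precursors.

The screens operate on Vienna dot-bracket strings (pseudoknot-free, over
``(``, ``)`` and ``.``):

1. *Bracket coverage*: at least half of a candidate miRNA locus must be
   paired, and all paired positions in the locus must carry the same
   bracket direction (the locus sits on one helix arm, not across a loop).
2. *Stem-loop detection*: the locus's base-pair partners must lie within
   one arm of a single hairpin — a maximal helix run (interior loops and
   bulges up to a configurable size allowed) closing on an unpaired
   terminal loop — with a minimum number of stem pairs.
3. *Duplex (miRNA*) calling*: Dicer-like 1 excises the miRNA/miRNA* duplex
   with 2-nt 3' overhangs at both ends, so for a miRNA at positions
   ``s..e`` the star locus is ``[partner(e-2), partner(s)+2]``.  Overhangs
   are re-measured from the pairing map and both must equal exactly 2;
   bulged or shifted constructions whose measured overhangs deviate are
   rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .sequencing_io import SRNALibrary, normalize_seq


class StructureError(ValueError):
    """Malformed dot-bracket string; message carries the first bad position."""


# ---------------------------------------------------------------------------
# pairing map
# ---------------------------------------------------------------------------

@dataclass
class PairingMap:
    """Base-pair partner table of a dot-bracket structure (1-based)."""

    length: int
    partner: dict[int, int]
    bracket: str

    def is_paired(self, i: int) -> bool:
        return i in self.partner

    def to_dot_bracket(self) -> str:
        return self.bracket

    def pairs(self) -> list[tuple[int, int]]:
        """All (i, j) pairs with i < j, ascending."""
        return sorted((i, j) for i, j in self.partner.items() if i < j)


def parse_dot_bracket(structure: str) -> PairingMap:
    """Stack-parse a dot-bracket string into a full partner table.

    Only ``(``, ``)`` and ``.`` are accepted; unbalanced brackets raise
    :class:`StructureError` naming the position of the first violation.
    """
    partner: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {pos}")
            i = stack.pop()
            partner[i] = pos
            partner[pos] = i
        elif ch != ".":
            raise StructureError(
                f"invalid character {ch!r} at position {pos}"
            )
    if stack:
        raise StructureError(
            f"{len(stack)} unclosed '(' at end of string"
            f" (first at position {stack[0]})"
        )
    return PairingMap(length=len(structure), partner=partner, bracket=structure)


# ---------------------------------------------------------------------------
# loci and calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A contiguous 1-based inclusive interval on a transcript."""

    transcript_id: str
    start: int
    end: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad locus interval {self.start}..{self.end}")
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError("locus sequence length mismatch")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def overlaps(self, other: "Locus") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class CoverageResult:
    verdict: bool
    coverage: float
    direction: Optional[str]  # "(", ")" or None when unpaired/mixed


@dataclass
class StemLoopCall:
    """One hairpin: two arm intervals closing on an unpaired terminal loop."""

    transcript_id: str
    arm5: tuple[int, int]
    arm3: tuple[int, int]
    loop: tuple[int, int]
    n_pairs: int
    contains_mir: bool = False

    def arm_of(self, pos: int) -> Optional[str]:
        if self.arm5[0] <= pos <= self.arm5[1]:
            return "5p"
        if self.arm3[0] <= pos <= self.arm3[1]:
            return "3p"
        return None


@dataclass
class DuplexCall:
    """A miRNA/miRNA* locus pair with measured 3' overhangs."""

    mir: Locus
    star: Locus
    overhang_3prime_mir: int
    overhang_3prime_star: int
    star_detected: bool = False
    star_rpm: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def bracket_coverage_screen(
    pm: PairingMap, locus: Locus, min_frac: float = 0.5
) -> CoverageResult:
    """Same-direction bracket coverage of a candidate miRNA locus.

    Passes iff the fraction of paired positions in the locus is at least
    ``min_frac`` and every paired position carries the same bracket
    character (all ``(`` or all ``)``).
    """
    if locus.end > pm.length:
        raise ValueError(
            f"locus {locus.start}..{locus.end} exceeds structure length {pm.length}"
        )
    chars = {pm.bracket[i - 1] for i in locus.positions() if pm.is_paired(i)}
    paired = sum(1 for i in locus.positions() if pm.is_paired(i))
    coverage = paired / locus.length
    same_direction = len(chars) == 1
    verdict = coverage >= min_frac and same_direction
    return CoverageResult(
        verdict=verdict,
        coverage=coverage,
        direction=next(iter(chars)) if same_direction else None,
    )


def _hairpins(pm: PairingMap, max_interior: int) -> list[StemLoopCall]:
    """Enumerate hairpins: helix runs closing on terminal loops.

    A hairpin is seeded at each innermost pair (no paired position strictly
    inside it) and extended outward pair by pair while the unpaired gap
    introduced on the two sides together stays within ``max_interior``.
    """
    out: list[StemLoopCall] = []
    for a, b in pm.pairs():
        if any(pm.is_paired(k) for k in range(a + 1, b)):
            continue  # not innermost
        loop = (a + 1, b - 1)
        i, j = a, b
        n_pairs = 1
        while True:
            i2 = i - 1
            while i2 >= 1 and not pm.is_paired(i2):
                i2 -= 1
            if i2 < 1:
                break
            j2 = pm.partner[i2]
            if j2 <= j:
                break  # left a nested context; helix cannot continue outward
            gap = (i - i2 - 1) + (j2 - j - 1)
            if gap > max_interior:
                break
            i, j = i2, j2
            n_pairs += 1
        out.append(
            StemLoopCall(
                transcript_id="",
                arm5=(i, a),
                arm3=(b, j),
                loop=loop,
                n_pairs=n_pairs,
            )
        )
    return out


def detect_stem_loop(
    pm: PairingMap,
    locus: Locus,
    min_stem_pairs: int = 15,
    max_interior: int = 12,
) -> Optional[StemLoopCall]:
    """Hairpin carrying the locus on one stem arm, or None.

    The locus's paired positions must all fall within a single arm of one
    hairpin whose helix holds at least ``min_stem_pairs`` base pairs.
    Interior loops/bulges up to ``max_interior`` unpaired nucleotides per
    extension step are tolerated inside the helix.
    """
    paired_positions = [i for i in locus.positions() if pm.is_paired(i)]
    if not paired_positions:
        return None
    for hp in _hairpins(pm, max_interior):
        arms = {hp.arm_of(i) for i in paired_positions}
        if len(arms) == 1 and None not in arms and hp.n_pairs >= min_stem_pairs:
            hp.transcript_id = locus.transcript_id
            hp.contains_mir = True
            return hp
    return None


# ---------------------------------------------------------------------------
# duplex rule
# ---------------------------------------------------------------------------

def duplex_overhangs(
    pm: PairingMap, mir: Locus, star: Locus
) -> Optional[tuple[int, int]]:
    """Measured 3' overhangs of a candidate miRNA/miRNA* locus pair.

    The miRNA-side overhang is the distance from the miRNA 3' end to the
    outermost miRNA position whose partner lies inside the star locus, and
    symmetrically for the star side.  Returns None when the two loci share
    no base pair.
    """
    mir_inner = [
        i for i in mir.positions()
        if pm.is_paired(i) and star.start <= pm.partner[i] <= star.end
    ]
    star_inner = [
        j for j in star.positions()
        if pm.is_paired(j) and mir.start <= pm.partner[j] <= mir.end
    ]
    if not mir_inner or not star_inner:
        return None
    return (mir.end - max(mir_inner), star.end - max(star_inner))


def find_star(
    pm: PairingMap,
    mir: Locus,
    libs: list[SRNALibrary],
    transcript_seq: str,
) -> Optional[DuplexCall]:
    """Call the miRNA* locus of ``mir`` by the 2-nt 3'-overhang geometry.

    The star interval is ``[partner(e-2), partner(s)+2]`` for a miRNA at
    ``s..e``; it must fall inside the transcript, not overlap the miRNA,
    and its re-measured overhangs must both equal exactly 2.  Star
    detection (raw count >= 1 in any library) is recorded but does not
    reject the call: a precursor can have valid duplex geometry with an
    unconfirmed star.
    """
    s, e = mir.start, mir.end
    if not (pm.is_paired(s) and pm.is_paired(e - 2)):
        return None
    star_start = pm.partner[e - 2]
    star_end = pm.partner[s] + 2
    if star_start > star_end:
        return None  # mir on the 3' arm would invert the interval
    if star_start < 1 or star_end > len(transcript_seq) or star_end > pm.length:
        return None
    star_seq = transcript_seq[star_start - 1 : star_end]
    star = Locus(mir.transcript_id, star_start, star_end, star_seq)
    if star.overlaps(mir):
        return None
    measured = duplex_overhangs(pm, mir, star)
    if measured != (2, 2):
        return None
    detected = any(lib.count(star_seq) >= 1 for lib in libs)
    star_rpm = {lib.name: lib.rpm(star_seq) for lib in libs}
    return DuplexCall(
        mir=mir,
        star=star,
        overhang_3prime_mir=measured[0],
        overhang_3prime_star=measured[1],
        star_detected=detected,
        star_rpm=star_rpm,
    )


# ---------------------------------------------------------------------------
# Vienna-style structure I/O
# ---------------------------------------------------------------------------

def read_vienna(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read Vienna records: ``>id``, sequence line, dot-bracket[ energy].

    Returns id -> (sequence DNA-space, dot-bracket).
    """
    records: dict[str, tuple[str, str]] = {}
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"{path}: expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise StructureError(f"{path}: truncated record {name!r}")
        seq = normalize_seq(lines[i + 1])
        struct = lines[i + 2].split()[0]  # strip trailing free energy
        if len(struct) != len(seq):
            raise StructureError(
                f"{path}: structure/sequence length mismatch for {name!r}"
            )
        parse_dot_bracket(struct)  # validate
        records[name] = (seq, struct)
        i += 3
    if not records:
        raise StructureError(f"{path}: no structure records")
    return records


def write_vienna(
    records: dict[str, tuple[str, str]], path: str | Path, rna: bool = True
) -> None:
    with open(path, "w") as fh:
        for name in sorted(records):
            seq, struct = records[name]
            fh.write(f">{name}\n{normalize_seq(seq, 'U' if rna else 'T')}\n{struct}\n")


def fold_with_external(seq: str, command: str = "RNAfold") -> tuple[str, str]:
    """Optional hook: fold one sequence with an external Vienna-style folder.

    Off by default everywhere; the pipeline consumes dot-bracket files as
    input.  Returns (sequence, dot-bracket).
    """
    import subprocess

    rna = normalize_seq(seq, "U")
    proc = subprocess.run(
        [command, "--noPS"], input=rna + "\n", capture_output=True,
        text=True, check=True,
    )
    lines = proc.stdout.strip().splitlines()
    if len(lines) < 2:
        raise StructureError(f"{command} produced no structure")
    struct = lines[1].split()[0]
    parse_dot_bracket(struct)
    return rna, struct
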