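"""Synthetic sequencing bundles with planted ground truth.

Generates, from a single seed, every input the pipeline consumes — a
transcript catalog, eight collapsed sRNA libraries (four organs x two
replicates), four per-organ degradome libraries, a raw read-count matrix,
dot-bracket structures for the hairpin transcripts and a mature-miRNA
reference — together with a machine-readable record of what was planted:

* organ-high transcripts at a configured fold (default 8x) with lognormal
  replicate noise, plus just-below-threshold transcripts (default 4.5x)
  that the 5-fold screen must exclude;
* organ-specific sRNAs (>= 10 RPM in one organ, absent elsewhere) over a
  stochastic background of ubiquitous low-count sequences;
* hairpin precursor transcripts built by construction (dot-bracket emitted
  directly, no folding), carrying a miRNA on the 5' arm and its miRNA*
  derived by the 2-nt 3'-overhang geometry; one long-stem hairpin carries a
  phased block of k adjacent duplexes;
* degradome libraries with processing spikes at duplex ends and a strong
  cleavage spike opposite miRNA nucleotide 10 on planted target
  transcripts, over a uniform low background.

Library totals are padded to their configured sizes with a single long
filler sequence so RPM values are exact by construction.  Everything is
deterministic: one seed, byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .expression_screen import DEFAULT_ORGANS, OrganDesign
from .precursor_structure import Locus, parse_dot_bracket
from .sequencing_io import (
    CountMatrix,
    DegradomeLibrary,
    SRNALibrary,
    TranscriptCatalog,
    revcomp,
    write_collapsed_tsv,
    write_degradome_tsv,
)

import pandas as pd

_NT = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinSpec:
    """Geometry of one constructed hairpin transcript.

    ``phased_k = 0`` plants a single miRNA at ``mir_offset`` on the 5' arm;
    ``phased_k > 0`` instead plants k head-to-tail 21-nt duplexes from the
    arm base (a long-stem phased block).  ``bulges`` lists 0-based offsets
    within the 3' arm after which one unpaired nucleotide is inserted.
    """

    name: str
    arm_len: int = 60
    loop_len: int = 6
    flank5: int = 20
    flank3: int = 20
    mir_offset: int = 4
    mir_len: int = 21
    bulges: tuple[int, ...] = ()
    organ: str = "stem"
    star_in_libraries: bool = True
    phased_k: int = 0


def _default_hairpins() -> tuple[HairpinSpec, ...]:
    return (
        HairpinSpec(name="hp1", organ="stem"),
        HairpinSpec(name="hp2", organ="leaf", star_in_libraries=False),
        # offset 2 keeps every duplex partner (star end = partner(start)+2)
        # inside the 3' arm
        HairpinSpec(name="hp3", arm_len=70, organ="stem", phased_k=3,
                    mir_offset=2),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    organs: tuple[str, ...] = DEFAULT_ORGANS
    replicates: int = 2
    # expression matrix
    n_transcripts: int = 200
    transcript_len_range: tuple[int, int] = (300, 1200)
    n_high_per_organ: int = 5
    planted_fold: float = 8.0
    n_subthreshold_per_organ: int = 1
    subthreshold_fold: float = 4.5
    replicate_cv: float = 0.05
    base_count_range: tuple[float, float] = (100.0, 1000.0)
    # sRNA libraries
    hairpins: tuple[HairpinSpec, ...] = field(default_factory=_default_hairpins)
    n_organ_specific_srnas: int = 3
    organ_specific_rpm: float = 15.0
    n_background_srnas: int = 300
    background_presence: float = 0.9
    background_geom_p: float = 0.5
    srna_library_total: int = 1_000_000
    mir_home_rpm: float = 50.0
    mir_away_rpm: float = 2.0
    star_home_rpm: float = 20.0
    star_away_rpm: float = 1.0
    phased_home_rpm: float = 20.0
    phased_away_rpm: float = 1.0
    # degradome
    n_targets: int = 2
    degradome_total: int = 500_000
    degradome_site_rpm: float = 100.0
    degradome_background_rpm: float = 2.0
    degradome_processing_rpm: float = 50.0
    n_decoy_signatures: int = 8
    degradome_organ: str = "flower"
    tag_len: int = 20
    # mature reference
    n_reference_decoys: int = 10

    def design(self) -> OrganDesign:
        return OrganDesign(organs=self.organs, replicates=self.replicates)


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class HairpinTruth:
    transcript_id: str
    sequence: str
    structure: str
    organ: str
    mir: Optional[Locus] = None
    star: Optional[Locus] = None
    star_in_libraries: bool = True
    phased_loci: list[Locus] = field(default_factory=list)
    phased_partners: list[Locus] = field(default_factory=list)


@dataclass
class CleavageTruth:
    mir_sequence: str
    transcript_id: str
    target_start: int
    position_10: int
    organ: str


@dataclass
class GroundTruth:
    organ_high: dict[str, list[str]] = field(default_factory=dict)
    subthreshold: dict[str, list[str]] = field(default_factory=dict)
    organ_specific_srnas: dict[str, list[str]] = field(default_factory=dict)
    hairpins: list[HairpinTruth] = field(default_factory=list)
    cleavage_sites: list[CleavageTruth] = field(default_factory=list)


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    truth: GroundTruth
    catalog: TranscriptCatalog
    structures: dict[str, tuple[str, str]]       # id -> (seq, dot-bracket)
    srna_libs: list[SRNALibrary]
    degradome_libs: list[DegradomeLibrary]
    expression: CountMatrix                      # raw counts
    lengths: dict[str, int]
    reference: dict[str, str]                    # mature-miRNA name -> seq


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def _fresh_seq(
    rng: np.random.Generator,
    length: int,
    used: set[str],
    forbidden_hosts: list[str],
) -> str:
    """A random sequence colliding with nothing planted or mappable."""
    while True:
        s = _random_seq(rng, length)
        if s in used:
            continue
        if any(s in host for host in forbidden_hosts):
            continue
        used.add(s)
        return s


def make_hairpin(
    spec: HairpinSpec, rng: np.random.Generator, transcript_id: str
) -> HairpinTruth:
    """Construct a hairpin transcript, its dot-bracket and planted loci.

    sequence = 5' flank + arm + loop + reverse complement of the arm (with
    the configured bulge insertions) + 3' flank; the structure string is
    emitted by construction, never by folding.  Planted miRNA(*) and
    phased-block loci are derived from the parsed pairing map with the
    2-nt 3'-overhang rule, so the truth is consistent with the structure by
    definition.
    """
    need = spec.mir_offset + spec.mir_len * max(1, spec.phased_k)
    if spec.arm_len < need:
        raise ValueError(
            f"hairpin {spec.name!r}: arm {spec.arm_len} nt cannot hold"
            f" {need} nt of planted loci"
        )
    arm5 = _random_seq(rng, spec.arm_len)
    loop = _random_seq(rng, spec.loop_len)
    flank5 = _random_seq(rng, spec.flank5)
    flank3 = _random_seq(rng, spec.flank3)
    arm3_seq: list[str] = []
    arm3_struct: list[str] = []
    rc = revcomp(arm5)
    for k, base in enumerate(rc):
        arm3_seq.append(base)
        arm3_struct.append(")")
        if k in spec.bulges:
            arm3_seq.append(_random_seq(rng, 1))
            arm3_struct.append(".")
    sequence = flank5 + arm5 + loop + "".join(arm3_seq) + flank3
    structure = (
        "." * spec.flank5
        + "(" * spec.arm_len
        + "." * spec.loop_len
        + "".join(arm3_struct)
        + "." * spec.flank3
    )
    pm = parse_dot_bracket(structure)
    truth = HairpinTruth(
        transcript_id=transcript_id,
        sequence=sequence,
        structure=structure,
        organ=spec.organ,
        star_in_libraries=spec.star_in_libraries,
    )

    def locus_at(start: int, length: int) -> Locus:
        return Locus(
            transcript_id, start, start + length - 1,
            sequence[start - 1 : start + length - 1],
        )

    def star_of(mir: Locus) -> Locus:
        s2 = pm.partner[mir.end - 2]
        e2 = pm.partner[mir.start] + 2
        return locus_at(s2, e2 - s2 + 1)

    arm_base = spec.flank5 + 1
    if spec.phased_k == 0:
        mir = locus_at(arm_base + spec.mir_offset, spec.mir_len)
        truth.mir = mir
        truth.star = star_of(mir)
    else:
        for i in range(spec.phased_k):
            locus = locus_at(
                arm_base + spec.mir_offset + i * spec.mir_len, spec.mir_len
            )
            truth.phased_loci.append(locus)
            truth.phased_partners.append(star_of(locus))
    return truth


def make_transcripts(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[TranscriptCatalog, GroundTruth, dict[str, tuple[str, str]]]:
    """Plain transcripts, hairpin transcripts and target transcripts."""
    truth = GroundTruth()
    records: dict[str, str] = {}
    lo, hi = cfg.transcript_len_range
    for i in range(cfg.n_transcripts):
        records[f"t{i + 1:04d}"] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
    structures: dict[str, tuple[str, str]] = {}
    for spec in cfg.hairpins:
        tid = f"hairpin_{spec.name}"
        hp = make_hairpin(spec, rng, tid)
        records[tid] = hp.sequence
        structures[tid] = (hp.sequence, hp.structure)
        truth.hairpins.append(hp)
    # target transcripts: embed the reverse complement of a planted miRNA
    # (a perfect-complement binding site) away from the transcript ends
    mirs = [hp.mir for hp in truth.hairpins if hp.mir is not None]
    for j in range(cfg.n_targets):
        mir = mirs[j % len(mirs)]
        tid = f"target{j + 1:02d}"
        body = _random_seq(rng, 500)
        insert_at = int(rng.integers(100, 350))  # 0-based
        site = revcomp(mir.sequence)
        seq = body[:insert_at] + site + body[insert_at:]
        records[tid] = seq
        target_start = insert_at + 1
        truth.cleavage_sites.append(
            CleavageTruth(
                mir_sequence=mir.sequence,
                transcript_id=tid,
                target_start=target_start,
                position_10=target_start + len(mir.sequence) - 10,
                organ=cfg.degradome_organ,
            )
        )
    return TranscriptCatalog(records), truth, structures


def make_expression(
    cfg: SimulationConfig,
    truth: GroundTruth,
    catalog: TranscriptCatalog,
    rng: np.random.Generator,
) -> tuple[CountMatrix, dict[str, int]]:
    """Raw count matrix with planted organ-high and subthreshold transcripts.

    Per-transcript base level is log-uniform over ``base_count_range``;
    the planted organ multiplies it by the configured fold; replicate noise
    is lognormal with the configured coefficient of variation.
    """
    design = cfg.design()
    tids = sorted(catalog.records)
    plain = [t for t in tids if t.startswith("t")]
    picked = iter(
        rng.permutation(np.array(plain))[
            : len(cfg.organs) * (cfg.n_high_per_organ + cfg.n_subthreshold_per_organ)
        ]
    )
    fold_of: dict[str, tuple[str, float]] = {}
    for organ in cfg.organs:
        highs = [str(next(picked)) for _ in range(cfg.n_high_per_organ)]
        subs = [str(next(picked)) for _ in range(cfg.n_subthreshold_per_organ)]
        truth.organ_high[organ] = sorted(highs)
        truth.subthreshold[organ] = sorted(subs)
        for t in highs:
            fold_of[t] = (organ, cfg.planted_fold)
        for t in subs:
            fold_of[t] = (organ, cfg.subthreshold_fold)
    sigma = float(np.sqrt(np.log1p(cfg.replicate_cv ** 2)))
    lo, hi = cfg.base_count_range
    data = {}
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(tids)))
    for organ in cfg.organs:
        for col in design.columns(organ):
            mult = np.ones(len(tids))
            for i, t in enumerate(tids):
                if t in fold_of and fold_of[t][0] == organ:
                    mult[i] = fold_of[t][1]
            noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=len(tids))
            data[col] = np.rint(base * mult * noise).astype(int)
    df = pd.DataFrame(data, index=tids)
    return CountMatrix(df, is_rpkm=False), catalog.lengths()


def make_srna_libraries(
    cfg: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> list[SRNALibrary]:
    """Eight collapsed libraries with planted and background sequences.

    Hairpin-derived sequences (miRNA, miRNA*, phased sRNAs) are enriched in
    their home organ but present at low counts everywhere, so they never
    masquerade as organ-specific.  Planted organ-specific sRNAs appear at
    ``organ_specific_rpm`` in both replicates of one organ and nowhere
    else.  Background sequences are present in each library with a fixed
    probability and geometric counts.  Totals are padded to
    ``srna_library_total`` with a 30-nt filler sequence.
    """
    design = cfg.design()
    total = cfg.srna_library_total
    used: set[str] = set()
    hosts = [hp.sequence for hp in truth.hairpins]
    for hp in truth.hairpins:
        for locus in [hp.mir, hp.star] + hp.phased_loci + hp.phased_partners:
            if locus is not None:
                used.add(locus.sequence)

    def rpm_count(rpm: float) -> int:
        return max(1, int(round(rpm * total / 1e6)))

    planted: list[tuple[str, str, float, float]] = []  # seq, organ, home, away
    for hp in truth.hairpins:
        if hp.mir is not None:
            planted.append(
                (hp.mir.sequence, hp.organ, cfg.mir_home_rpm, cfg.mir_away_rpm)
            )
            if hp.star_in_libraries:
                planted.append(
                    (hp.star.sequence, hp.organ, cfg.star_home_rpm,
                     cfg.star_away_rpm)
                )
        for locus in hp.phased_loci + hp.phased_partners:
            planted.append(
                (locus.sequence, hp.organ, cfg.phased_home_rpm,
                 cfg.phased_away_rpm)
            )
    for organ in cfg.organs:
        seqs = sorted(
            _fresh_seq(rng, 21, used, hosts)
            for _ in range(cfg.n_organ_specific_srnas)
        )
        truth.organ_specific_srnas[organ] = seqs
    background = [
        _fresh_seq(rng, int(rng.integers(21, 25)), used, hosts)
        for _ in range(cfg.n_background_srnas)
    ]
    filler = _fresh_seq(rng, 30, used, hosts)

    libs: list[SRNALibrary] = []
    for organ in cfg.organs:
        for rep in range(1, cfg.replicates + 1):
            counts: dict[str, int] = {}
            for seq, home, home_rpm, away_rpm in planted:
                rpm = home_rpm if organ == home else away_rpm
                counts[seq] = counts.get(seq, 0) + rpm_count(rpm)
            for o, seqs in truth.organ_specific_srnas.items():
                if o == organ:
                    for seq in seqs:
                        counts[seq] = rpm_count(cfg.organ_specific_rpm)
            for seq in background:
                if rng.random() < cfg.background_presence:
                    counts[seq] = int(rng.geometric(cfg.background_geom_p))
            pad = total - sum(counts.values())
            if pad < 0:
                raise ValueError("library total too small for planted counts")
            if pad > 0:
                counts[filler] = pad
            libs.append(
                SRNALibrary(organ=organ, replicate=str(rep), counts=counts)
            )
    return libs


def make_degradome(
    cfg: SimulationConfig,
    truth: GroundTruth,
    catalog: TranscriptCatalog,
    rng: np.random.Generator,
) -> list[DegradomeLibrary]:
    """Four per-organ degradome libraries with planted spikes.

    Spikes: (a) processing signatures at the 5' end of each planted miRNA
    and one past the 3' end of each planted miRNA*/phased locus, in the
    hairpin's home organ; (b) a strong cleavage signature whose 5' end sits
    opposite miRNA nucleotide 10 on each planted target, in the configured
    degradome organ, over decoy signatures elsewhere on the target.  Counts
    are derived from the configured RPM values against the padded total.
    """
    total = cfg.degradome_total

    def rpm_count(rpm: float) -> int:
        return max(1, int(round(rpm * total / 1e6)))

    def tag_at(tid: str, pos: int) -> Optional[str]:
        seq = catalog.records[tid]
        if pos < 1 or pos + cfg.tag_len - 1 > len(seq):
            return None
        return seq[pos - 1 : pos - 1 + cfg.tag_len]

    libs: list[DegradomeLibrary] = []
    plain = sorted(t for t in catalog.records if t.startswith("t"))
    for organ in cfg.organs:
        tags: dict[str, int] = {}
        placements: list[tuple[str, int, str]] = []

        def add(tid: str, pos: int, count: int) -> None:
            seq = tag_at(tid, pos)
            if seq is None:
                return
            tags[seq] = tags.get(seq, 0) + count
            if (tid, pos, seq) not in placements:
                placements.append((tid, pos, seq))

        for hp in truth.hairpins:
            if hp.organ != organ:
                continue
            if hp.mir is not None:
                add(hp.transcript_id, hp.mir.start,
                    rpm_count(cfg.degradome_processing_rpm))
                add(hp.transcript_id, hp.star.end + 1,
                    rpm_count(cfg.degradome_processing_rpm))
            for locus in hp.phased_loci:
                add(hp.transcript_id, locus.end + 1,
                    rpm_count(cfg.degradome_processing_rpm))
        for ct in truth.cleavage_sites:
            if ct.organ == organ:
                add(ct.transcript_id, ct.position_10,
                    rpm_count(cfg.degradome_site_rpm))
            # decoy background signatures on the target in every organ
            tlen = len(catalog.records[ct.transcript_id])
            step = max(1, (tlen - cfg.tag_len) // (cfg.n_decoy_signatures + 1))
            k = 0
            pos = 1
            while k < cfg.n_decoy_signatures and pos + cfg.tag_len - 1 <= tlen:
                if abs(pos - ct.position_10) > cfg.tag_len:
                    add(ct.transcript_id, pos,
                        rpm_count(cfg.degradome_background_rpm))
                    k += 1
                pos += step
        # sparse background on random plain transcripts
        for tid in plain[:20]:
            pos = int(rng.integers(1, max(2, len(catalog.records[tid]) - cfg.tag_len)))
            add(tid, pos, rpm_count(cfg.degradome_background_rpm))
        pad = total - sum(tags.values())
        if pad > 0:
            filler = _random_seq(rng, 40)
            tags[filler] = pad
        libs.append(
            DegradomeLibrary(
                organ=organ, tags=tags, placements=placements, total=total
            )
        )
    return libs


def make_reference(
    cfg: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, str]:
    """Mature-miRNA reference: planted miRNAs (one redundantly named twice)
    plus decoy entries absent from every library.

    A phased hairpin's first block locus doubles as a reference miRNA: long
    stems are reached through a catalog miRNA placement, and on real
    precursors the phased ladder sits beside an annotated miRNA."""
    ref: dict[str, str] = {}
    anchors = [
        hp.mir if hp.mir is not None else hp.phased_loci[0]
        for hp in truth.hairpins
        if hp.mir is not None or hp.phased_loci
    ]
    for i, locus in enumerate(anchors, start=1):
        ref[f"refA-miR{i}"] = locus.sequence
        if i == 1:
            ref[f"refB-miR{i}"] = locus.sequence  # redundant synonym
    used = {l.sequence for l in anchors}
    hosts = [hp.sequence for hp in truth.hairpins]
    for j in range(cfg.n_reference_decoys):
        ref[f"dec-miR{j + 1}"] = _fresh_seq(rng, 21, used, hosts)
    return ref


def generate_bundle(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate the full input bundle for one seed, with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    catalog, truth, structures = make_transcripts(cfg, rng)
    expression, lengths = make_expression(cfg, truth, catalog, rng)
    srna_libs = make_srna_libraries(cfg, truth, rng)
    degradome_libs = make_degradome(cfg, truth, catalog, rng)
    reference = make_reference(cfg, truth, rng)
    return SyntheticBundle(
        config=cfg,
        truth=truth,
        catalog=catalog,
        structures=structures,
        srna_libs=srna_libs,
        degradome_libs=degradome_libs,
        expression=expression,
        lengths=lengths,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _locus_dict(locus: Optional[Locus]) -> Optional[dict]:
    if locus is None:
        return None
    return {
        "transcript_id": locus.transcript_id,
        "start": locus.start,
        "end": locus.end,
        "sequence": locus.sequence,
    }


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "organ_high": truth.organ_high,
        "subthreshold": truth.subthreshold,
        "organ_specific_srnas": truth.organ_specific_srnas,
        "hairpins": [
            {
                "transcript_id": hp.transcript_id,
                "organ": hp.organ,
                "star_in_libraries": hp.star_in_libraries,
                "mir": _locus_dict(hp.mir),
                "star": _locus_dict(hp.star),
                "phased_loci": [_locus_dict(l) for l in hp.phased_loci],
                "phased_partners": [_locus_dict(l) for l in hp.phased_partners],
            }
            for hp in truth.hairpins
        ],
        "cleavage_sites": [dataclasses.asdict(c) for c in truth.cleavage_sites],
    }


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit the bundle in the formats the pipeline consumes.

    Returns a name -> path mapping of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["transcripts"] = outdir / "transcripts.fasta"
    bundle.catalog.to_fasta(paths["transcripts"])
    paths["structures"] = outdir / "structures.vienna"
    from .precursor_structure import write_vienna

    write_vienna(bundle.structures, paths["structures"], rna=False)
    for lib in bundle.srna_libs:
        key = f"srna_{lib.name}"
        paths[key] = outdir / f"{key}.tsv"
        write_collapsed_tsv(lib, paths[key])
    for deg in bundle.degradome_libs:
        key = f"degradome_{deg.organ}"
        paths[key] = outdir / f"{key}.tsv"
        write_degradome_tsv(deg, paths[key])
    paths["expression"] = outdir / "expression_counts.tsv"
    bundle.expression.to_tsv(paths["expression"])
    paths["reference"] = outdir / "mature_reference.fasta"
    with open(paths["reference"], "w") as fh:
        for name in sorted(bundle.reference):
            fh.write(f">{name}\n{bundle.reference[name]}\n")
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth_to_dict(bundle.truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
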