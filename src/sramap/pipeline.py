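"""End-to-end orchestration: screens, catalog, precursors, phasing, degradome.

The pipeline consumes a directory of standard-format inputs (FASTA
transcripts, collapsed sRNA TSVs, Vienna structures, a raw count matrix,
per-organ degradome TSVs, a mature-miRNA reference) and writes per-stage
TSVs, a run manifest (package version, configuration hash, input checksums,
per-stage in/filtered/out counters) and a summary JSON with the headline
set sizes.  Every threshold is carried in :class:`PipelineConfig`; the
defaults are the screening rules the stages document.

Outputs are fully deterministic: the same configuration and inputs yield
byte-identical summary JSONs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .degradome import (
    organ_specificity_of_regulation,
    predict_sites,
    processing_evidence,
    validate_cleavage,
    TargetSite,
)
from .expression_screen import (
    DEFAULT_ORGANS,
    OrganDesign,
    library_overlap,
    organ_specific_srnas,
    organ_specific_transcripts,
)
from .mirna_catalog import catalog_table, expression_filter, match_reference
from .phasing import find_phased_blocks, map_srnas_to_stem
from .precursor_structure import (
    Locus,
    bracket_coverage_screen,
    detect_stem_loop,
    find_star,
    parse_dot_bracket,
    read_vienna,
)
from .sequencing_io import (
    CountMatrix,
    TranscriptCatalog,
    compute_rpkm,
    map_perfect,
    read_collapsed_srna,
    read_degradome_tsv,
    read_mature_fasta,
)

logger = logging.getLogger("sramap")


@dataclass
class PipelineConfig:
    """Input locations, organ design and every stage threshold."""

    # inputs
    transcripts: Path
    expression_counts: Path
    srna_libraries: list[tuple[Path, str, str]]   # (path, organ, replicate)
    structures: Optional[Path] = None
    reference: Optional[Path] = None
    degradome: list[tuple[Path, str]] = field(default_factory=list)
    sites: Optional[Path] = None                  # precomputed target sites TSV
    # organ design
    organs: tuple[str, ...] = DEFAULT_ORGANS
    replicates: int = 2
    # thresholds (stage defaults)
    fold: float = 5.0
    alpha: float = 0.05
    floor: float = 1.0
    srna_rpm_min: float = 10.0
    catalog_min_rpm: float = 5.0
    mir_prefix: str = "miR"
    min_coverage: float = 0.5
    min_stem_pairs: int = 15
    max_interior: int = 12
    long_stem_pairs: int = 40
    phasing_min_chain: int = 2
    phasing_tolerance: int = 0
    degradome_fold: float = 5.0
    degradome_top_k: int = 12
    processing_tolerance: int = 0
    site_score_threshold: float = 4.0
    # output
    outdir: Path = Path("sramap_run")

    def design(self) -> OrganDesign:
        return OrganDesign(organs=self.organs, replicates=self.replicates)

    def threshold_dict(self) -> dict:
        skip = {"transcripts", "expression_counts", "srna_libraries",
                "structures", "reference", "degradome", "sites", "outdir"}
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in skip
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig, checksums: dict[str, str]) -> str:
    payload = json.dumps(
        {"thresholds": cfg.threshold_dict(), "inputs": checksums},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def read_sites_tsv(path: Path) -> list[TargetSite]:
    """Precomputed site list: mir id, transcript, position opposite nt 10,
    alignment string, target window start (optional 5th column)."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: expected >=4 columns at line {lineno}")
            mir_id, tid, pos10, alignment = fields[:4]
            pos10 = int(pos10)
            start = int(fields[4]) if len(fields) > 4 else pos10 + 10 - len(alignment)
            sites.append(
                TargetSite(
                    mir_id=mir_id, transcript_id=tid, target_start=start,
                    alignment=alignment, position_10=pos10, score=-1.0,
                )
            )
    return sites


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; return the run manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = cfg.design()
    manifest: dict = {
        "version": __version__,
        "thresholds": {k: str(v) if isinstance(v, Path) else v
                       for k, v in cfg.threshold_dict().items()},
        "stages": {},
        "skipped": [],
    }
    checksums: dict[str, str] = {}

    def stage(name: str, **counters) -> None:
        manifest["stages"][name] = counters
        logger.info("stage %s: %s", name, counters)

    # ---- load inputs ------------------------------------------------------
    catalog = TranscriptCatalog.from_fasta(cfg.transcripts)
    checksums["transcripts"] = _sha256(cfg.transcripts)
    raw = CountMatrix.from_tsv(cfg.expression_counts)
    checksums["expression_counts"] = _sha256(cfg.expression_counts)
    libs = []
    for path, organ, rep in cfg.srna_libraries:
        libs.append(read_collapsed_srna(path, organ, rep))
        checksums[f"srna_{organ}_{rep}"] = _sha256(path)
    structures = {}
    if cfg.structures is not None:
        structures = read_vienna(cfg.structures)
        checksums["structures"] = _sha256(cfg.structures)
    reference = {}
    if cfg.reference is not None:
        reference = read_mature_fasta(cfg.reference)
        checksums["reference"] = _sha256(cfg.reference)
    degs = []
    for path, organ in cfg.degradome:
        degs.append(read_degradome_tsv(path, organ))
        checksums[f"degradome_{organ}"] = _sha256(path)
    manifest["input_checksums"] = checksums
    manifest["config_hash"] = _config_hash(cfg, checksums)

    # ---- expression screen ------------------------------------------------
    rpkm = compute_rpkm(raw, catalog.lengths())
    rpkm.to_tsv(outdir / "expression_rpkm.tsv")
    organ_high = organ_specific_transcripts(
        rpkm, design, cfg.fold, cfg.alpha, cfg.floor
    )
    pd.DataFrame(
        [(o, t) for o in design.organs for t in sorted(organ_high[o])],
        columns=["organ", "transcript"],
    ).to_csv(outdir / "organ_specific_transcripts.tsv", sep="\t", index=False)
    stage(
        "expression_screen",
        transcripts_in=len(rpkm.transcripts),
        organ_high={o: len(s) for o, s in organ_high.items()},
    )

    # ---- sRNA screen ------------------------------------------------------
    srna_specific = organ_specific_srnas(libs, design, cfg.srna_rpm_min)
    pd.DataFrame(
        [(o, s) for o in design.organs for s in sorted(srna_specific[o])],
        columns=["organ", "sequence"],
    ).to_csv(outdir / "organ_specific_srnas.tsv", sep="\t", index=False)
    overlap = library_overlap(libs, design)
    overlap.to_csv(outdir / "library_overlap.tsv", sep="\t")
    stage(
        "srna_screen",
        sequences_in=len({s for l in libs for s in l.counts}),
        organ_specific={o: len(s) for o, s in srna_specific.items()},
    )

    # ---- miRNA catalog ----------------------------------------------------
    filtered = []
    if reference:
        cat = match_reference(reference, libs, design, prefix=cfg.mir_prefix)
        filtered = expression_filter(cat, cfg.catalog_min_rpm)
        catalog_table(cat).to_csv(outdir / "mirna_catalog.tsv", sep="\t",
                                  index=False)
        stage(
            "mirna_catalog",
            reference_entries=len(reference),
            detected=len(cat),
            above_min_rpm=len(filtered),
        )
    else:
        manifest["skipped"].append("mirna_catalog (no reference)")

    # ---- precursor structure screen --------------------------------------
    duplexes: list[tuple[str, str, object, object]] = []
    stems: dict[tuple[str, int, int], object] = {}
    precursor_rows = []
    n_placed = n_cov = n_stem = n_geom = n_star = 0
    for cand in filtered:
        for tid, start, end in map_perfect(cand.sequence, catalog):
            if tid not in structures:
                continue
            n_placed += 1
            seq, struct = structures[tid]
            pm = parse_dot_bracket(struct)
            locus = Locus(tid, start, end, cand.sequence)
            cov = bracket_coverage_screen(pm, locus, cfg.min_coverage)
            row = {
                "mir_id": cand.assigned_id, "transcript": tid,
                "start": start, "end": end,
                "coverage": round(cov.coverage, 4),
                "coverage_pass": cov.verdict,
                "stem_loop": False, "star_start": "", "star_end": "",
                "overhangs": "", "star_detected": "",
            }
            if cov.verdict:
                n_cov += 1
                stem = detect_stem_loop(
                    pm, locus, cfg.min_stem_pairs, cfg.max_interior
                )
                if stem is not None:
                    n_stem += 1
                    row["stem_loop"] = True
                    stems[(tid, stem.arm5[0], stem.arm3[1])] = (stem, pm, seq)
                    call = find_star(pm, locus, libs, seq)
                    if call is not None:
                        n_geom += 1
                        duplexes.append((cand.assigned_id, tid, call, pm))
                        row["star_start"] = call.star.start
                        row["star_end"] = call.star.end
                        row["overhangs"] = "2,2"
                        row["star_detected"] = call.star_detected
                        if call.star_detected:
                            n_star += 1
            precursor_rows.append(row)
    pd.DataFrame(precursor_rows).to_csv(
        outdir / "precursor_report.tsv", sep="\t", index=False
    )
    stage(
        "precursor_structure",
        candidates_in=len(filtered),
        placements=n_placed,
        coverage_pass=n_cov,
        stem_loop=n_stem,
        duplex_geometry=n_geom,
        star_detected=n_star,
    )

    # ---- phasing ----------------------------------------------------------
    blocks = []
    for (tid, _a, _b), (stem, pm, seq) in sorted(stems.items()):
        if stem.n_pairs < cfg.long_stem_pairs:
            continue
        loci = map_srnas_to_stem(libs, tid, seq, stem)
        blocks.extend(
            find_phased_blocks(
                loci, pm, seq, libs, stem=stem,
                min_chain=cfg.phasing_min_chain,
                tolerance=cfg.phasing_tolerance,
            )
        )
    block_rows = []
    for bi, blk in enumerate(blocks, start=1):
        for locus, partner in zip(blk.loci, blk.partners):
            block_rows.append({
                "block": bi, "transcript": blk.transcript_id,
                "start": locus.start, "end": locus.end,
                "partner_start": partner.start if partner else "",
                "partner_end": partner.end if partner else "",
                "singleton": partner is None,
            })
    pd.DataFrame(block_rows).to_csv(
        outdir / "phased_blocks.tsv", sep="\t", index=False
    )
    stage(
        "phasing",
        long_stems=sum(
            1 for (_t, _a, _b), (s, _p, _q) in stems.items()
            if s.n_pairs >= cfg.long_stem_pairs
        ),
        blocks=len(blocks),
        duplexes=sum(b.n_duplexes for b in blocks),
        singletons=sum(b.n_singletons for b in blocks),
    )

    # ---- degradome --------------------------------------------------------
    n_validated = 0
    if degs:
        evidence_rows = []
        for mir_id, tid, call, _pm in duplexes:
            for deg in degs:
                for ev in processing_evidence(
                    deg, [call.mir, call.star], cfg.processing_tolerance
                ):
                    evidence_rows.append({
                        "mir_id": mir_id, "transcript": ev.transcript_id,
                        "locus_start": ev.locus.start,
                        "locus_end": ev.locus.end,
                        "end": ev.end, "organ": ev.organ,
                        "position": ev.expected_position,
                        "rpm": round(ev.rpm, 4),
                    })
        pd.DataFrame(evidence_rows).to_csv(
            outdir / "processing_evidence.tsv", sep="\t", index=False
        )
        if cfg.sites is not None:
            sites = read_sites_tsv(cfg.sites)
        else:
            sites = []
            for cand in filtered:
                sites.extend(
                    predict_sites(
                        cand.sequence, catalog, mir_id=cand.assigned_id,
                        threshold=cfg.site_score_threshold,
                    )
                )
        validation_rows = []
        pair_rows = []
        for site in sites:
            call = validate_cleavage(
                site, degs, fold=cfg.degradome_fold, top_k=cfg.degradome_top_k
            )
            for organ, v in sorted(call.per_organ.items()):
                validation_rows.append({
                    "mir_id": site.mir_id, "transcript": site.transcript_id,
                    "position": call.cleavage_position, "organ": organ,
                    "avg_site": round(v.avg_site, 4),
                    "avg_surround": round(v.avg_surround, 4),
                    "rule1": v.rule1, "rule2": v.rule2, "rule3": v.rule3,
                    "overall": v.overall,
                })
            if call.validated:
                n_validated += 1
                cls = organ_specificity_of_regulation(call)
                pair_rows.append({
                    "mir_id": site.mir_id, "transcript": site.transcript_id,
                    "position": call.cleavage_position,
                    "organs": ";".join(cls["organs_validated"]),
                    "label": cls["label"],
                })
        pd.DataFrame(validation_rows).to_csv(
            outdir / "cleavage_validation.tsv", sep="\t", index=False
        )
        pd.DataFrame(pair_rows).to_csv(
            outdir / "validated_pairs.tsv", sep="\t", index=False
        )
        stage(
            "degradome",
            processing_evidence=len(evidence_rows),
            sites_tested=len(sites),
            validated_pairs=n_validated,
        )
    else:
        manifest["skipped"].append("degradome (no degradome inputs)")
        logger.warning("degradome inputs missing; stage skipped")

    # ---- summary ----------------------------------------------------------
    summary = {
        "organ_high_transcripts": {o: len(s) for o, s in sorted(organ_high.items())},
        "organ_specific_srnas": {o: len(s) for o, s in sorted(srna_specific.items())},
        "mirna_candidates": len(filtered),
        "precursor_funnel": {
            "placements": n_placed,
            "coverage_pass": n_cov,
            "stem_loop": n_stem,
            "duplex_geometry": n_geom,
            "star_detected": n_star,
        },
        "phased_blocks": len(blocks),
        "phased_duplexes": sum(b.n_duplexes for b in blocks),
        "validated_pairs": n_validated,
        "config_hash": manifest["config_hash"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["summary"] = summary
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def config_for_bundle_dir(indir: str | Path, outdir: str | Path,
                          organs: tuple[str, ...] = DEFAULT_ORGANS,
                          replicates: int = 2,
                          **thresholds) -> PipelineConfig:
    """PipelineConfig pointing at a directory written by ``write_bundle``."""
    indir = Path(indir)
    srna = []
    for organ in organs:
        for rep in range(1, replicates + 1):
            p = indir / f"srna_{organ}_{rep}.tsv"
            if p.exists():
                srna.append((p, organ, str(rep)))
    deg = [
        (indir / f"degradome_{organ}.tsv", organ)
        for organ in organs
        if (indir / f"degradome_{organ}.tsv").exists()
    ]
    structures = indir / "structures.vienna"
    reference = indir / "mature_reference.fasta"
    return PipelineConfig(
        transcripts=indir / "transcripts.fasta",
        expression_counts=indir / "expression_counts.tsv",
        srna_libraries=srna,
        structures=structures if structures.exists() else None,
        reference=reference if reference.exists() else None,
        degradome=deg,
        organs=organs,
        replicates=replicates,
        outdir=Path(outdir),
        **thresholds,
    )
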