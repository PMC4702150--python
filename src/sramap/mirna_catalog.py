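"""Candidate mature-miRNA catalog from a reference set and sRNA libraries.

Reference mature miRNAs (miRBase-style) are matched by exact full-length
sequence identity against the sequenced libraries; entries undetectable in
every library are discarded, redundant sequences are merged (source names
collected), and the survivors are renamed with a uniform prefix in a
deterministic order.  Per-organ accumulation (mean replicate RPM) supports
the downstream >= 5 RPM precursor filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .expression_screen import OrganDesign
from .sequencing_io import SRNALibrary, normalize_seq


@dataclass
class MatureCandidate:
    """One unique detected mature-miRNA sequence with its accumulation."""

    assigned_id: str
    sequence: str
    source_ids: list[str]
    counts: dict[str, int] = field(default_factory=dict)   # library name -> raw
    rpm: dict[str, float] = field(default_factory=dict)    # library name -> RPM
    organ_mean_rpm: dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def max_organ_rpm(self) -> float:
        return max(self.organ_mean_rpm.values()) if self.organ_mean_rpm else 0.0


def match_reference(
    reference: dict[str, str],
    libs: list[SRNALibrary],
    design: OrganDesign,
    prefix: str = "miR",
) -> list[MatureCandidate]:
    """Build the detected, de-duplicated, renamed candidate catalog.

    One candidate per unique reference sequence with a raw count >= 1 in at
    least one library.  Ids are ``{prefix}-{n}`` from 1, assigned by
    descending total raw count and then lexicographic sequence, so
    identical inputs always yield identical naming.
    """
    if not reference:
        raise ValueError("empty reference")
    by_seq: dict[str, list[str]] = {}
    for name, seq in reference.items():
        by_seq.setdefault(normalize_seq(seq), []).append(name)
    candidates: list[MatureCandidate] = []
    for seq, names in by_seq.items():
        counts = {lib.name: lib.count(seq) for lib in libs}
        if sum(counts.values()) == 0:
            continue  # undetectable in all libraries
        rpm = {lib.name: lib.rpm(seq) for lib in libs}
        organ_mean = {}
        for organ in design.organs:
            cols = design.columns(organ)
            vals = [rpm[c] for c in cols if c in rpm]
            organ_mean[organ] = sum(vals) / len(vals) if vals else 0.0
        candidates.append(
            MatureCandidate(
                assigned_id="",
                sequence=seq,
                source_ids=sorted(names),
                counts=counts,
                rpm=rpm,
                organ_mean_rpm=organ_mean,
            )
        )
    candidates.sort(key=lambda c: (-c.total_count, c.sequence))
    for i, cand in enumerate(candidates, start=1):
        cand.assigned_id = f"{prefix}-{i}"
    return candidates


def expression_filter(
    catalog: list[MatureCandidate], min_rpm: float = 5.0
) -> list[MatureCandidate]:
    """Candidates reaching ``min_rpm`` mean RPM in at least one organ.

    The organ mean is averaged over replicates before thresholding, so a
    single-replicate burst below twice the threshold does not qualify.
    """
    return [c for c in catalog if c.max_organ_rpm >= min_rpm]


def catalog_table(catalog: list[MatureCandidate]) -> pd.DataFrame:
    rows = []
    for c in catalog:
        row: dict[str, object] = {
            "id": c.assigned_id,
            "sequence": c.sequence,
            "sources": ";".join(c.source_ids),
            "total_count": c.total_count,
        }
        row.update({f"rpm_{k}": v for k, v in sorted(c.rpm.items())})
        row.update(
            {f"mean_rpm_{k}": v for k, v in sorted(c.organ_mean_rpm.items())}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_catalog(catalog: list[MatureCandidate], path: str | Path) -> None:
    catalog_table(catalog).to_csv(path, sep="\t", index=False)
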