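"""Reading, holding and normalizing short-read count data on transcripts.

Containers for transcript catalogs, collapsed small-RNA libraries, degradome
tag libraries and read-count matrices, plus the two normalizations used
throughout the pipeline (RPM for sRNA/degradome libraries, RPKM for
transcript expression) and perfect-match placement of short sequences on
transcripts.

Conventions
-----------
* Sequences are stored DNA-space (T) internally; the structure module
  converts to U for display.  ``normalize_seq`` performs the T/U
  unification.
* All coordinates are 1-based inclusive; an interval's end equals
  ``start + length - 1``.
* Mapping is sense-strand only by default: a precursor transcript carries
  its small RNAs in sense.  Antisense search is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_ALPHABET = set("ACGTUN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line or record."""


def normalize_seq(seq: str, to: str = "T") -> str:
    """Uppercase a nucleotide string and unify T/U to one alphabet.

    Parameters
    ----------
    seq : nucleotide string (DNA or RNA spelling).
    to : "T" for DNA-space (internal default) or "U" for RNA-space.
    """
    s = seq.strip().upper()
    s = s.replace("U", "T") if to == "T" else s.replace("T", "U")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space."""
    return str(Seq(normalize_seq(seq)).reverse_complement())


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TranscriptCatalog:
    """Identifier -> sequence mapping for an assembled transcript set."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for tid, seq in self.records.items():
            s = normalize_seq(seq)
            if not s:
                raise ValueError(f"empty sequence for transcript {tid!r}")
            clean[tid] = s
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, tid: str) -> bool:
        return tid in self.records

    def __getitem__(self, tid: str) -> str:
        return self.records[tid]

    def length(self, tid: str) -> int:
        return len(self.records[tid])

    def lengths(self) -> dict[str, int]:
        return {tid: len(s) for tid, s in self.records.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TranscriptCatalog":
        recs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in recs:
                raise ParseError(f"duplicate transcript id {rec.id!r}")
            recs[rec.id] = str(rec.seq)
        if not recs:
            raise ParseError(f"no FASTA records in {path}")
        return cls(recs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.records):
                fh.write(f">{tid}\n{self.records[tid]}\n")


@dataclass
class SRNALibrary:
    """One sequencing replicate's collapsed small-RNA counts.

    ``counts`` maps unique read sequence to raw count; ``total`` is the
    library size used for RPM normalization and always equals the sum of
    the counts.
    """

    organ: str
    replicate: str
    counts: dict[str, int]
    total: int = 0

    def __post_init__(self) -> None:
        self.counts = {normalize_seq(s): int(c) for s, c in self.counts.items()}
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative raw count")
        tot = sum(self.counts.values())
        if self.total == 0:
            self.total = tot
        elif self.total != tot:
            raise ValueError(
                f"library total {self.total} != sum of counts {tot}"
            )
        if self.total <= 0:
            raise ValueError("empty library")

    @property
    def name(self) -> str:
        return f"{self.organ}_{self.replicate}"

    def count(self, seq: str) -> int:
        return self.counts.get(normalize_seq(seq), 0)

    def rpm(self, seq: str) -> float:
        return normalize_rpm(self, seq)


@dataclass
class DegradomeLibrary:
    """Per-organ degradome (PARE) 5'-tag counts placed on transcripts.

    A placement ``(transcript_id, position, sequence)`` records a perfect
    sense match of the tag whose 5'-most nucleotide sits at ``position``
    (1-based) on the transcript.  Each tag's 5' end marks the 5' end of an
    uncapped RNA fragment, i.e. a candidate cleavage position.
    """

    organ: str
    tags: dict[str, int]
    placements: list[tuple[str, int, str]] = field(default_factory=list)
    total: int = 0
    # RPM denominator: "raw" = all sequenced tags, "placed" = placed tags only
    rpm_basis: str = "raw"

    def __post_init__(self) -> None:
        self.tags = {normalize_seq(s): int(c) for s, c in self.tags.items()}
        if self.total == 0:
            self.total = sum(self.tags.values())
        if self.total <= 0:
            raise ValueError("empty degradome library")
        self.placements = [
            (tid, int(pos), normalize_seq(seq)) for tid, pos, seq in self.placements
        ]
        for tid, pos, seq in self.placements:
            if pos < 1:
                raise ValueError(f"placement position {pos} < 1 on {tid}")

    def _denominator(self) -> int:
        if self.rpm_basis == "placed":
            placed = {seq for _, _, seq in self.placements}
            return sum(self.tags[s] for s in placed if s in self.tags)
        return self.total

    def rpm(self, seq: str) -> float:
        denom = self._denominator()
        if denom <= 0:
            raise ValueError("zero RPM denominator")
        return 1e6 * self.tags.get(normalize_seq(seq), 0) / denom

    def placements_on(self, transcript_id: str) -> list[tuple[int, str]]:
        """(position, tag sequence) placements on one transcript."""
        return [(p, s) for t, p, s in self.placements if t == transcript_id]

    def place_on(self, catalog: TranscriptCatalog) -> None:
        """Recompute placements as all perfect sense matches on the catalog."""
        self.placements = []
        for seq in sorted(self.tags):
            for tid, start, _end in map_perfect(seq, catalog):
                self.placements.append((tid, start, seq))


@dataclass
class CountMatrix:
    """Transcripts x samples read-count matrix; cells raw counts or RPKM."""

    values: pd.DataFrame
    is_rpkm: bool = False

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative cells")

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, is_rpkm: bool = False) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(float), is_rpkm=is_rpkm)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_collapsed_srna(
    path: str | Path,
    organ: str,
    replicate: str,
    delimiter: str = "_",
) -> SRNALibrary:
    """Read a collapsed sRNA library from collapsed FASTA or two-column TSV.

    Collapsed FASTA headers carry the read count as the last
    ``delimiter``-separated token (">id_count").  TSV rows are
    ``sequence<TAB>count``.  Counts for identical sequences are aggregated.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"empty library: {path}")
    counts: dict[str, int] = {}
    if text.lstrip().startswith(">"):
        record_no = 0
        header: str | None = None
        seq_parts: list[str] = []

        def flush() -> None:
            if header is None:
                return
            token = header.split()[0].rsplit(delimiter, 1)
            if len(token) != 2 or not token[1].isdigit():
                raise ParseError(
                    f"{path}: cannot read count from header {header!r}"
                    f" (record {record_no})"
                )
            seq = normalize_seq("".join(seq_parts))
            if not seq:
                raise ParseError(f"{path}: empty sequence at record {record_no}")
            counts[seq] = counts.get(seq, 0) + int(token[1])

        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                record_no += 1
                header = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
        flush()
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: expected 2 columns at line {lineno}")
            seq_raw, count_raw = fields
            try:
                count = int(count_raw)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-integer count {count_raw!r} at line {lineno}"
                ) from exc
            seq = normalize_seq(seq_raw)
            counts[seq] = counts.get(seq, 0) + count
    if not counts:
        raise ParseError(f"empty library: {path}")
    return SRNALibrary(organ=organ, replicate=replicate, counts=counts)


def write_collapsed_tsv(lib: SRNALibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sorted(lib.counts):
            fh.write(f"{seq}\t{lib.counts[seq]}\n")


def read_degradome_tsv(
    path: str | Path, organ: str, total: int | None = None
) -> DegradomeLibrary:
    """Read degradome placements TSV: transcript, position, sequence, count.

    ``total`` overrides the library size (defaults to the sum of distinct
    tag counts).
    """
    tags: dict[str, int] = {}
    placements: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: expected 4 columns at line {lineno}")
            tid, pos_raw, seq_raw, count_raw = fields
            try:
                pos, count = int(pos_raw), int(count_raw)
            except ValueError as exc:
                raise ParseError(f"{path}: bad integer at line {lineno}") from exc
            seq = normalize_seq(seq_raw)
            tags.setdefault(seq, count)
            placements.append((tid, pos, seq))
    if not tags:
        raise ParseError(f"empty degradome library: {path}")
    return DegradomeLibrary(
        organ=organ, tags=tags, placements=placements,
        total=total if total is not None else 0,
    )


def write_degradome_tsv(deg: DegradomeLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, pos, seq in sorted(deg.placements):
            fh.write(f"{tid}\t{pos}\t{seq}\t{deg.tags[seq]}\n")


def read_mature_fasta(path: str | Path) -> dict[str, str]:
    """Mature-miRNA reference FASTA; first header token is the name."""
    ref: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ref[rec.id] = normalize_seq(str(rec.seq))
    if not ref:
        raise ParseError(f"no mature miRNA records in {path}")
    return ref


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_rpm(lib: SRNALibrary, seq: str) -> float:
    """Reads-per-million of one sequence: 1e6 * raw count / library total."""
    if lib.total <= 0:
        raise ValueError("library total must be positive")
    return 1e6 * lib.count(seq) / lib.total


def compute_rpkm(
    raw: CountMatrix, lengths: Mapping[str, int]
) -> CountMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    cell = reads / (column total in millions x transcript length in kb),
    column totals taken over all rows of the matrix.
    """
    if raw.is_rpkm:
        raise ValueError("matrix is already RPKM")
    missing = [t for t in raw.transcripts if t not in lengths]
    if missing:
        raise ValueError(f"missing length for transcript(s): {missing[:5]}")
    df = raw.values.astype(float)
    col_totals = df.sum(axis=0)
    if (col_totals <= 0).any():
        zero = list(col_totals.index[col_totals <= 0])
        raise ValueError(f"zero mapped-read total in sample(s): {zero}")
    len_kb = pd.Series(
        {t: lengths[t] / 1e3 for t in raw.transcripts}, dtype=float
    )
    if (len_kb <= 0).any():
        raise ValueError("non-positive transcript length")
    rpkm = df.div(col_totals / 1e6, axis=1).div(len_kb, axis=0)
    return CountMatrix(rpkm, is_rpkm=True)


# ---------------------------------------------------------------------------
# perfect-match placement
# ---------------------------------------------------------------------------

def map_perfect(
    query: str,
    catalog: TranscriptCatalog,
    antisense: bool = False,
    min_len: int = 1,
) -> list[tuple[str, int, int]]:
    """All exact sense-strand occurrences of ``query`` in the catalog.

    Returns ``(transcript id, start, end)`` tuples, 1-based inclusive,
    sorted by transcript id then start.  With ``antisense=True`` the
    reverse complement of the query is searched as well (same coordinate
    convention; such hits are rare on precursor transcripts and off by
    default).
    """
    q = normalize_seq(query)
    if len(q) < min_len:
        raise ValueError(f"query shorter than {min_len} nt")
    queries = [q] + ([revcomp(q)] if antisense and revcomp(q) != q else [])
    hits: list[tuple[str, int, int]] = []
    for tid in catalog.records:
        subject = catalog.records[tid]
        for qq in queries:
            start = subject.find(qq)
            while start != -1:
                hits.append((tid, start + 1, start + len(qq)))
                start = subject.find(qq, start + 1)
    hits.sort()
    return hits
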