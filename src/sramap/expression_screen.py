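"""Organ-specificity screens for transcripts (RPKM) and small RNAs (RPM).

A transcript is called highly expressed in organ A versus organ B when its
replicate-averaged RPKM in A is at least ``fold`` (default 5) times that in
B, a two-sample two-tailed Student t-test on the replicate values gives
p < ``alpha`` (default 0.05), and the A-average is at least ``floor``
(default 1 RPKM).  A transcript is organ-specific when it wins all pairwise
comparisons against every other organ (three-way intersection with four
organs).

A small RNA is organ-specific when it reaches ``rpm_min`` (default 10 RPM)
in at least one replicate of one organ and has a raw count of zero in every
library of every other organ ("could not be detected").

All threshold comparisons are inclusive (>=, or p strictly < alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sequencing_io import CountMatrix, SRNALibrary

DEFAULT_ORGANS = ("root", "stem", "leaf", "flower")


@dataclass(frozen=True)
class OrganDesign:
    """Organ x replicate layout of the experiment.

    Sample (column) ids follow the ``{organ}_{replicate}`` convention with
    replicates numbered from 1.
    """

    organs: tuple[str, ...] = DEFAULT_ORGANS
    replicates: int = 2

    def __post_init__(self) -> None:
        if len(self.organs) < 2:
            raise ValueError("need at least 2 organs")
        if len(set(self.organs)) != len(self.organs):
            raise ValueError("organ labels must be unique")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per organ")

    def columns(self, organ: str) -> list[str]:
        if organ not in self.organs:
            raise ValueError(f"unknown organ {organ!r}")
        return [f"{organ}_{r}" for r in range(1, self.replicates + 1)]

    def samples(self) -> list[str]:
        return [c for o in self.organs for c in self.columns(o)]


@dataclass
class OrganSpecificCall:
    """Per-entity record of the organ-specificity screen components."""

    entity_id: str
    organ: str
    organ_means: dict[str, float]
    # transcript screen: per opposing organ -> (fold ratio or inf, p-value)
    comparisons: dict[str, tuple[float, float]] = field(default_factory=dict)
    verdict: bool = False


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed p of the pooled-variance two-sample Student t-test.

    Degenerate zero-variance groups: if the pooled SD is 0 the statistic's
    limit is +/-inf for unequal means (p -> 0) and 0 for equal means
    (p -> 1).
    """
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("t-test needs >=2 replicates per organ")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        return 0.0 if diff != 0.0 else 1.0
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return 2.0 * stats.t.sf(abs(t), df=na + nb - 2)


def pairwise_high(
    rpkm: CountMatrix,
    organ_a: str,
    organ_b: str,
    design: OrganDesign,
    fold: float = 5.0,
    alpha: float = 0.05,
    floor: float = 1.0,
) -> set[str]:
    """Transcripts highly expressed in ``organ_a`` versus ``organ_b``.

    Included iff mean_A >= fold * mean_B, t-test p < alpha and
    mean_A >= floor.  When mean_B is zero the fold ratio is undefined;
    presence/absence is taken as the strongest possible fold and the fold
    criterion passes whenever mean_A >= floor.
    """
    if not rpkm.is_rpkm:
        raise ValueError("pairwise_high expects an RPKM matrix")
    a = rpkm.values[design.columns(organ_a)].to_numpy(dtype=float)
    b = rpkm.values[design.columns(organ_b)].to_numpy(dtype=float)
    out: set[str] = set()
    for i, tid in enumerate(rpkm.transcripts):
        mean_a, mean_b = a[i].mean(), b[i].mean()
        if mean_a < floor:
            continue
        if mean_b > 0 and mean_a < fold * mean_b:
            continue
        if _pooled_ttest(a[i], b[i]) >= alpha:
            continue
        out.add(tid)
    return out


def organ_specific_transcripts(
    rpkm: CountMatrix,
    design: OrganDesign,
    fold: float = 5.0,
    alpha: float = 0.05,
    floor: float = 1.0,
) -> dict[str, set[str]]:
    """Organ -> transcripts high versus every other organ (intersection)."""
    result: dict[str, set[str]] = {}
    for organ in design.organs:
        sets = [
            pairwise_high(rpkm, organ, other, design, fold, alpha, floor)
            for other in design.organs
            if other != organ
        ]
        result[organ] = set.intersection(*sets) if sets else set()
    return result


def transcript_call_table(
    rpkm: CountMatrix,
    design: OrganDesign,
    fold: float = 5.0,
    alpha: float = 0.05,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Long-form table of every organ x transcript screen component."""
    rows = []
    arrays = {
        o: rpkm.values[design.columns(o)].to_numpy(dtype=float)
        for o in design.organs
    }
    specific = organ_specific_transcripts(rpkm, design, fold, alpha, floor)
    for organ in design.organs:
        others = [o for o in design.organs if o != organ]
        for i, tid in enumerate(rpkm.transcripts):
            mean_o = arrays[organ][i].mean()
            row: dict[str, object] = {
                "transcript": tid,
                "organ": organ,
                f"mean_{organ}": mean_o,
            }
            for other in others:
                mean_x = arrays[other][i].mean()
                ratio = mean_o / mean_x if mean_x > 0 else math.inf
                row[f"fold_vs_{other}"] = ratio
                row[f"p_vs_{other}"] = _pooled_ttest(
                    arrays[organ][i], arrays[other][i]
                )
            row["verdict"] = tid in specific[organ]
            rows.append(row)
    return pd.DataFrame(rows)


def organ_specific_srnas(
    libs: list[SRNALibrary],
    design: OrganDesign,
    rpm_min: float = 10.0,
) -> dict[str, set[str]]:
    """Organ -> small-RNA sequences accumulated in that organ only.

    A sequence qualifies for organ O iff its RPM reaches ``rpm_min`` in at
    least one replicate library of O and its raw count is zero in every
    library of every other organ.  The exclusion side is literal detection
    (raw count >= 1 anywhere else disqualifies), with no RPM threshold.
    """
    by_organ: dict[str, list[SRNALibrary]] = {o: [] for o in design.organs}
    for lib in libs:
        if lib.organ not in by_organ:
            raise ValueError(f"library organ {lib.organ!r} not in design")
        by_organ[lib.organ].append(lib)
    for organ, group in by_organ.items():
        if not group:
            raise ValueError(f"no libraries for organ {organ!r}")
    result: dict[str, set[str]] = {}
    for organ in design.organs:
        others = [l for o, g in by_organ.items() if o != organ for l in g]
        chosen: set[str] = set()
        candidates = set().union(*(set(l.counts) for l in by_organ[organ]))
        for seq in candidates:
            if all(l.count(seq) == 0 for l in others) and any(
                l.rpm(seq) >= rpm_min for l in by_organ[organ]
            ):
                chosen.add(seq)
        result[organ] = chosen
    return result


def library_overlap(
    libs: list[SRNALibrary], design: OrganDesign
) -> pd.DataFrame:
    """Pairwise intersection sizes of per-organ non-redundant sequence sets.

    Each organ's set is the union of its replicates' sequences; the
    diagonal holds the organ set sizes.
    """
    organ_sets: dict[str, set[str]] = {o: set() for o in design.organs}
    for lib in libs:
        organ_sets[lib.organ] |= set(lib.counts)
    organs = list(design.organs)
    mat = pd.DataFrame(0, index=organs, columns=organs, dtype=int)
    for a in organs:
        for b in organs:
            mat.loc[a, b] = len(organ_sets[a] & organ_sets[b])
    return mat
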