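"""Candidate-gene ranking: intersect absence evidence with panel effects.

A gene becomes a candidate when the saturation scan calls it absent from
the mutant bulk or a deletion call fully contains it.  Candidates are then
ordered so that genes inside a called deletion rank before merely
low-saturation genes, and — the decisive criterion — genes with no
dysfunctional polymorphism in the control panel rank before genes whose
function is already disrupted in fertile cultivars (a gene broken in
fertile material cannot be the recessive sterility gene).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .coverage_saturation import GeneAbsenceReport
from .io_formats import GeneModel, write_bed
from .sv_breakpoints import DeletionCall
from .variant_filter import DYSFUNCTIONAL_EFFECTS

__all__ = [
    "CandidateGene",
    "genes_in_interval",
    "rank_candidates",
    "write_report",
]


@dataclass
class CandidateGene:
    gene_id: str
    in_deletion: bool
    absent: bool
    gene_saturation: float
    panel_dysfunctional_count: int
    evidence: str  # comma-joined provenance flags

    @property
    def rank_score(self) -> tuple:
        """Sort key: deletion containment, absence, fewer panel-dysfunctional
        variants, then gene_id as the documented tie-break."""
        return (
            not self.in_deletion,
            not self.absent,
            self.panel_dysfunctional_count,
            self.gene_id,
        )


def genes_in_interval(
    genes: Sequence[GeneModel],
    interval: tuple[str, int, int],
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Split genes into (fully contained, merely overlapping) an interval.

    The interval is (contig, start, end), 1-based inclusive.  Containment —
    not overlap — is what qualifies a gene as deleted; genes straddling a
    breakpoint are reported separately, never silently promoted.
    """
    contig, start, end = interval
    contained, overlapping = [], []
    for g in genes:
        if g.contig != contig:
            continue
        if start <= g.start and g.end <= end:
            contained.append(g)
        elif g.start <= end and g.end >= start:
            overlapping.append(g)
    return contained, overlapping


def rank_candidates(
    absence_reports: Iterable[GeneAbsenceReport],
    deletion_calls: Sequence[DeletionCall],
    panel_effects: Mapping[str, list] | None,
    genes: Sequence[GeneModel],
) -> list[CandidateGene]:
    """Build and order the candidate-gene list.

    ``panel_effects`` maps gene_id -> [(site, effect), ...] from
    :func:`recessivemap.variant_filter.annotate_panel_effects`.  The
    dysfunctional count enters as an ascending sort key, not a hard filter:
    it chooses among absent genes without absolutely excluding any.
    """
    by_id = {g.gene_id: g for g in genes}
    contained_ids: set[str] = set()
    for call in deletion_calls:
        contained, _ = genes_in_interval(
            genes, (call.contig, call.left_breakpoint, call.right_breakpoint)
        )
        contained_ids.update(g.gene_id for g in contained)

    candidates: list[CandidateGene] = []
    for rep in absence_reports:
        in_del = rep.gene_id in contained_ids
        if not (rep.absent or in_del):
            continue
        n_dys = 0
        if panel_effects is not None:
            n_dys = sum(
                1 for _site, eff in panel_effects.get(rep.gene_id, ())
                if eff in DYSFUNCTIONAL_EFFECTS
            )
        flags = [f for f, on in (("absent", rep.absent), ("in_deletion", in_del)) if on]
        candidates.append(
            CandidateGene(
                gene_id=rep.gene_id,
                in_deletion=in_del,
                absent=rep.absent,
                gene_saturation=rep.gene_saturation,
                panel_dysfunctional_count=n_dys,
                evidence=",".join(flags),
            )
        )
    # deletion-contained genes missing from the absence reports still qualify
    reported = {c.gene_id for c in candidates} | {r.gene_id for r in absence_reports}
    for gid in sorted(contained_ids - reported):
        n_dys = 0
        if panel_effects is not None:
            n_dys = sum(
                1 for _s, eff in panel_effects.get(gid, ()) if eff in DYSFUNCTIONAL_EFFECTS
            )
        candidates.append(
            CandidateGene(
                gene_id=gid, in_deletion=True, absent=False, gene_saturation=float("nan"),
                panel_dysfunctional_count=n_dys, evidence="in_deletion",
            )
        )
    candidates.sort(key=lambda c: c.rank_score)
    return candidates


def write_report(
    candidates: Sequence[CandidateGene],
    stream_or_path: IO[str] | str | Path,
    genes: Sequence[GeneModel] = (),
    bed_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the ranked candidate TSV (and optionally a BED of gene bodies)."""
    frame = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "gene_id": c.gene_id,
                "in_deletion": c.in_deletion,
                "absent": c.absent,
                "gene_saturation": round(c.gene_saturation, 6),
                "panel_dysfunctional_count": c.panel_dysfunctional_count,
                "evidence": c.evidence,
            }
            for i, c in enumerate(candidates)
        ],
        columns=[
            "rank", "gene_id", "in_deletion", "absent", "gene_saturation",
            "panel_dysfunctional_count", "evidence",
        ],
    )
    if isinstance(stream_or_path, (str, Path)):
        frame.to_csv(stream_or_path, sep="\t", index=False)
    else:
        frame.to_csv(stream_or_path, sep="\t", index=False)
    if bed_path is not None:
        by_id = {g.gene_id: g for g in genes}
        rows = [
            (by_id[c.gene_id].contig, by_id[c.gene_id].start, by_id[c.gene_id].end, c.gene_id)
            for c in candidates if c.gene_id in by_id
        ]
        write_bed(rows, bed_path)
    return frame
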