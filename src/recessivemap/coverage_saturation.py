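"""Coverage, sequencing saturation and the presence/absence (PAV) scan.

Sequencing saturation is defined as breadth of coverage: the fraction of
positions in a region covered by at least ``min_covered_depth`` deduplicated
reads (1.0 = fully covered).  Per-base depth is capped (default 150x) before
averaging so over-represented repeats cannot inflate window means.  A gene
whose body saturation falls below the absence threshold (default 0.03) is
flagged absent from the sequenced bulk — the hallmark of a gene lost to a
presence/absence variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignmentRecord, Contig, GeneModel, VariantSite, to_one_based

__all__ = [
    "ScanParams",
    "CoverageTrack",
    "WindowStats",
    "GeneAbsenceReport",
    "deduplicate",
    "build_depth",
    "window_stats",
    "gene_saturation",
    "absent_regions",
]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the saturation scan.

    window_size
        Tiling window for genome-wide summaries (bp).
    depth_cap
        Per-base depth truncation applied before averaging (fold-coverage).
    saturation_threshold
        Breadth below which a gene is called absent.
    flank
        Flanking span reported alongside each gene body (bp, each side).
    min_covered_depth
        Depth a position needs to count as covered.
    """

    window_size: int = 50_000
    depth_cap: int = 150
    saturation_threshold: float = 0.03
    flank: int = 5_000
    min_covered_depth: int = 1

    def __post_init__(self) -> None:
        if min(self.window_size, self.depth_cap, self.flank, self.min_covered_depth) <= 0:
            raise ValueError("ScanParams fields must be positive")
        if not 0.0 < self.saturation_threshold < 1.0:
            raise ValueError("saturation_threshold must be in (0,1)")


@dataclass
class CoverageTrack:
    contig: str
    depth: np.ndarray  # one non-negative int per base

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or (self.depth.size and self.depth.min() < 0):
            raise ValueError("depth must be a 1-D non-negative array")

    @property
    def length(self) -> int:
        return int(self.depth.size)

    def saturation(self, start0: int, end0: int, min_depth: int = 1) -> float:
        """Breadth of coverage on a 0-based half-open interval."""
        start0, end0 = max(0, start0), min(self.length, end0)
        if end0 <= start0:
            return 0.0
        window = self.depth[start0:end0]
        return float(np.count_nonzero(window >= min_depth) / window.size)


@dataclass
class WindowStats:
    contig: str
    start: int  # 1-based inclusive
    end: int
    mean_capped_depth: float
    saturation: float
    n_polymorphic_sites: int
    mean_alt_frequency: float | None


@dataclass
class GeneAbsenceReport:
    gene_id: str
    gene_saturation: float
    flank_saturation: float
    mean_capped_depth: float
    absent: bool


def deduplicate(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Drop positional duplicates, keeping the first record per key.

    The duplicate key is (contig, pos, strand bit, tlen): exact re-sequencing
    of one physical fragment reproduces all four, while distinct fragments
    differ in at least one.  Unmapped records are dropped.
    """
    seen: set[tuple[str, int, int, int]] = set()
    kept: list[AlignmentRecord] = []
    for rec in records:
        if rec.is_unmapped:
            continue
        key = (rec.rname, rec.pos, rec.flag & 0x10, rec.tlen)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept


def build_depth(records: Iterable[AlignmentRecord], contig: Contig) -> CoverageTrack:
    """Per-base depth over reference-consuming CIGAR operations (M/=/X/D).

    Soft/hard clips and insertions consume no reference.  A record extending
    past the contig end raises, naming the record.
    """
    diff = np.zeros(contig.length + 1, dtype=np.int64)
    for rec in records:
        if rec.is_unmapped or rec.rname != contig.name:
            continue
        if rec.ref_end0 > contig.length:
            raise ValueError(
                f"record {rec.qname} at {rec.rname}:{rec.pos} extends past contig end "
                f"({rec.ref_end0} > {contig.length})"
            )
        for s0, e0 in rec.aligned_blocks0():
            diff[s0] += 1
            diff[e0] -= 1
    return CoverageTrack(contig.name, np.cumsum(diff[:-1]))


def window_stats(
    track: CoverageTrack,
    sites: Sequence[VariantSite] = (),
    params: ScanParams = ScanParams(),
) -> list[WindowStats]:
    """Tile the contig and summarise capped depth, saturation and site stats.

    The last window may be short and is reported with its true length.
    ``mean_alt_frequency`` is None for windows without polymorphic sites.
    """
    if params.window_size <= 0:
        raise ValueError("window_size must be positive")
    capped = np.minimum(track.depth, params.depth_cap)
    covered = track.depth >= params.min_covered_depth
    # alt fractions aligned with site_pos (sites with zero depth excluded)
    pairs = [(s.pos, s.bulk_alt_depth / s.total_depth)
             for s in sites if s.contig == track.contig and s.total_depth > 0]
    site_pos = np.array([p for p, _ in pairs], dtype=np.int64)
    site_af = np.array([f for _, f in pairs])

    out: list[WindowStats] = []
    for s0 in range(0, track.length, params.window_size):
        e0 = min(s0 + params.window_size, track.length)
        in_win = (site_pos > s0) & (site_pos <= e0)  # pos is 1-based
        n_sites = int(np.count_nonzero(in_win))
        start1, end1 = to_one_based(s0, e0)
        out.append(
            WindowStats(
                contig=track.contig,
                start=start1,
                end=end1,
                mean_capped_depth=float(capped[s0:e0].mean()),
                saturation=float(np.count_nonzero(covered[s0:e0]) / (e0 - s0)),
                n_polymorphic_sites=n_sites,
                mean_alt_frequency=float(site_af[in_win].mean()) if n_sites else None,
            )
        )
    return out


def gene_saturation(
    track: CoverageTrack,
    gene: GeneModel,
    params: ScanParams = ScanParams(),
) -> GeneAbsenceReport:
    """Saturation over a gene body and its flanks; absence call on the body.

    Flanks (``params.flank`` bp each side) are clipped at contig ends.
    """
    g0s, g0e = gene.interval0
    body_sat = track.saturation(g0s, g0e, params.min_covered_depth)
    left = track.saturation(g0s - params.flank, g0s, params.min_covered_depth)
    right = track.saturation(g0e, g0e + params.flank, params.min_covered_depth)
    left_len = g0s - max(0, g0s - params.flank)
    right_len = min(track.length, g0e + params.flank) - min(g0e, track.length)
    total_flank = left_len + right_len
    flank_sat = (
        (left * left_len + right * right_len) / total_flank if total_flank else 0.0
    )
    capped = np.minimum(track.depth[g0s:g0e], params.depth_cap)
    return GeneAbsenceReport(
        gene_id=gene.gene_id,
        gene_saturation=body_sat,
        flank_saturation=float(flank_sat),
        mean_capped_depth=float(capped.mean()) if capped.size else 0.0,
        absent=body_sat < params.saturation_threshold,
    )


def absent_regions(
    track: CoverageTrack,
    params: ScanParams = ScanParams(),
    merge_distance: int = 100,
) -> list[tuple[str, int, int]]:
    """Maximal uncovered runs, merged across covered gaps <= merge_distance.

    Returns 1-based inclusive (contig, start, end) intervals.
    """
    uncovered = track.depth < params.min_covered_depth
    if not uncovered.any():
        return []
    padded = np.concatenate([[False], uncovered, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts0, ends0 = edges[::2], edges[1::2]
    merged: list[list[int]] = [[int(starts0[0]), int(ends0[0])]]
    for s0, e0 in zip(starts0[1:], ends0[1:]):
        if s0 - merged[-1][1] <= merge_distance:
            merged[-1][1] = int(e0)
        else:
            merged.append([int(s0), int(e0)])
    return [(track.contig, *to_one_based(s0, e0)) for s0, e0 in merged]
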