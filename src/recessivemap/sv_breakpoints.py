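"""Large-deletion detection from discordant read pairs.

A deletion removes template between a pair's two reads, so pairs that
straddle it map with an inflated template length and lose the proper-pair
flag.  The caller (1) estimates the library insert model from proper pairs,
(2) collects deletion-signature discordant pairs, (3) clusters them by
single linkage, and (4) refines each cluster's breakpoints with coverage
edges and, when available, soft-clipped read stacks (base-exact evidence).
Calling is fully deterministic.
"""

from __future__ import annotations

import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .coverage_saturation import CoverageTrack
from .io_formats import AlignmentRecord

__all__ = [
    "InsertModel",
    "DiscordantPair",
    "DiscordantCluster",
    "ClipEvidence",
    "DeletionCall",
    "SvParams",
    "estimate_insert_model",
    "find_discordant_pairs",
    "cluster_discordant",
    "collect_clip_evidence",
    "refine_breakpoints",
    "call_deletions",
]


@dataclass(frozen=True)
class InsertModel:
    """Library insert-size model; |tlen| beyond mean + k_sigma*sd is discordant."""

    mean: float
    sd: float
    k_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("insert model requires mean > 0 and sd >= 0")

    @property
    def max_concordant_tlen(self) -> float:
        return self.mean + self.k_sigma * self.sd


@dataclass(frozen=True)
class SvParams:
    min_support: int = 3
    #: minimum clipped reads stacking at one position to count as breakpoint
    min_clip_support: int = 2
    #: depth fraction of the flanking median below which a base reads "deleted"
    refine_fraction: float = 0.1
    #: the low-depth run must persist this long to be a deletion edge
    min_run: int = 50
    #: span of flanking sequence used for the median depth
    flank_span: int = 2000


@dataclass(frozen=True)
class DiscordantPair:
    qname: str
    contig: str
    left_read_end: int  # 1-based rightmost base of the leftward read
    right_read_start: int  # 1-based leftmost base of the rightward read
    observed_tlen: int

    def __post_init__(self) -> None:
        if self.left_read_end >= self.right_read_start:
            raise ValueError("not a deletion-type pair: reads overlap or are inverted")


@dataclass
class DiscordantCluster:
    contig: str
    pairs: list[DiscordantPair] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.pairs)

    @property
    def max_left_end(self) -> int:
        return max(p.left_read_end for p in self.pairs)

    @property
    def min_right_start(self) -> int:
        return min(p.right_read_start for p in self.pairs)


@dataclass
class ClipEvidence:
    """Soft-clip stack positions: candidate breakpoints with read support.

    ``left_candidates`` maps a candidate first-deleted base (1-based) to the
    number of reads whose alignment ends just before it with a trailing
    clip; ``right_candidates`` maps a candidate last-deleted base to leading-
    clip support.
    """

    left_candidates: Counter = field(default_factory=Counter)
    right_candidates: Counter = field(default_factory=Counter)


@dataclass
class DeletionCall:
    contig: str
    left_breakpoint: int  # 1-based first deleted base
    right_breakpoint: int  # 1-based last deleted base
    support: int
    left_uncertainty: int
    right_uncertainty: int
    evidence: str = "coverage"  # "clip", "coverage" or "discordant"

    def __post_init__(self) -> None:
        if self.left_breakpoint > self.right_breakpoint:
            raise ValueError("left breakpoint beyond right breakpoint")

    @property
    def estimated_size(self) -> int:
        return self.right_breakpoint - self.left_breakpoint + 1


def estimate_insert_model(
    records: list[AlignmentRecord],
    k_sigma: float = 5.0,
    min_pairs: int = 100,
) -> InsertModel:
    """Mean and sd of |tlen| over proper pairs, counting each pair once."""
    tlens = [rec.tlen for rec in records if rec.is_proper_pair and rec.tlen > 0]
    if len(tlens) < min_pairs:
        raise ValueError(
            f"only {len(tlens)} proper pairs (< {min_pairs}); supply an explicit InsertModel"
        )
    mean = statistics.fmean(tlens)
    sd = statistics.pstdev(tlens)
    return InsertModel(mean=mean, sd=sd, k_sigma=k_sigma)


def find_discordant_pairs(
    records: list[AlignmentRecord],
    insert_model: InsertModel,
) -> list[DiscordantPair]:
    """Deletion-signature discordant pairs.

    A pair qualifies when its proper-pair bit is unset or |tlen| exceeds the
    insert model's concordance bound, and both mates map to the same contig
    in convergent (forward...reverse) orientation with the forward read
    entirely left of the reverse read.
    """
    mates: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        if rec.is_unmapped or not rec.is_paired:
            continue
        mates[rec.qname].append(rec)

    out: list[DiscordantPair] = []
    for qname, pair in mates.items():
        if len(pair) != 2:
            continue
        a, b = pair
        if a.rname != b.rname:
            continue
        discordant = (not a.is_proper_pair) or abs(a.tlen) > insert_model.max_concordant_tlen
        if not discordant:
            continue
        fwd = next((r for r in pair if not r.is_reverse), None)
        rev = next((r for r in pair if r.is_reverse), None)
        if fwd is None or rev is None:
            continue
        left_end = fwd.ref_end0  # 1-based rightmost base == 0-based half-open end
        right_start = rev.pos
        if left_end >= right_start:
            continue
        out.append(
            DiscordantPair(
                qname=qname,
                contig=a.rname,
                left_read_end=left_end,
                right_read_start=right_start,
                observed_tlen=abs(a.tlen),
            )
        )
    out.sort(key=lambda p: (p.contig, p.left_read_end, p.right_read_start))
    return out


def cluster_discordant(
    pairs: list[DiscordantPair],
    max_gap: float,
    min_support: int = 3,
) -> list[DiscordantCluster]:
    """Single-linkage clustering of deletion-signature pairs.

    A pair joins a cluster when its left_read_end is within ``max_gap`` of
    the cluster's rightmost left_read_end and its right_read_start is within
    ``max_gap`` of the cluster's right_read_start range (single linkage on
    both coordinates); clusters below ``min_support`` are discarded.
    """
    clusters: list[DiscordantCluster] = []
    by_contig: dict[str, list[DiscordantCluster]] = defaultdict(list)
    for pair in sorted(pairs, key=lambda p: (p.contig, p.left_read_end)):
        for cl in by_contig[pair.contig]:
            lo = min(p.right_read_start for p in cl.pairs)
            hi = max(p.right_read_start for p in cl.pairs)
            right_dist = max(lo - pair.right_read_start, pair.right_read_start - hi, 0)
            if pair.left_read_end - cl.max_left_end <= max_gap and right_dist <= max_gap:
                cl.pairs.append(pair)
                break
        else:
            cl = DiscordantCluster(contig=pair.contig, pairs=[pair])
            clusters.append(cl)
            by_contig[pair.contig].append(cl)
    return [c for c in clusters if c.support >= min_support]


def collect_clip_evidence(
    records: list[AlignmentRecord],
    min_clip: int = 5,
) -> dict[str, ClipEvidence]:
    """Tally soft-clip stack positions per contig.

    A read ending in >= ``min_clip`` soft-clipped bases proposes the base
    after its aligned end as a first-deleted base; a read starting with a
    clip proposes the base before its aligned start as a last-deleted base.
    """
    out: dict[str, ClipEvidence] = defaultdict(ClipEvidence)
    for rec in records:
        if rec.is_unmapped:
            continue
        if rec.trailing_softclip() >= min_clip:
            out[rec.rname].left_candidates[rec.ref_end0 + 1] += 1
        if rec.leading_softclip() >= min_clip:
            out[rec.rname].right_candidates[rec.pos - 1] += 1
    return dict(out)


def _scan_depth_edge(
    depth: np.ndarray,
    start0: int,
    stop0: int,
    step: int,
    threshold: float,
    min_run: int,
) -> int | None:
    """First 0-based index moving from start0 toward stop0 (exclusive) where
    depth < threshold persists for min_run bases in the scan direction."""
    n = depth.size
    idx = max(0, min(n - 1, start0))
    stop0 = max(-1, min(n, stop0))
    while idx != stop0 and 0 <= idx < n:
        if depth[idx] < threshold:
            if step > 0:
                run = depth[idx: min(n, idx + min_run)]
            else:
                run = depth[max(0, idx - min_run + 1): idx + 1]
            if run.size >= min_run and bool((run < threshold).all()):
                return idx
        idx += step
    return None


def refine_breakpoints(
    cluster: DiscordantCluster,
    track: CoverageTrack,
    insert_model: InsertModel,
    clips: ClipEvidence | None = None,
    params: SvParams = SvParams(),
) -> DeletionCall | None:
    """Turn a discordant cluster into a breakpoint-refined deletion call.

    The discordant-implied interval is (max left_read_end + 1,
    min right_read_start - 1).  Each edge is then refined to the first
    position, scanning inward from one insert length outside the implied
    edge, where depth drops below ``refine_fraction`` x the flanking median
    and stays low; a soft-clip stack inside the search window overrides the
    coverage edge because clip evidence is base-exact.  Returns None when
    the coverage shows no deletion (spurious cluster), or the
    discordant-implied interval with insert-sized uncertainty when the
    flanking median is zero.
    """
    init_left = cluster.max_left_end + 1  # 1-based candidate first deleted base
    init_right = cluster.min_right_start - 1
    if init_left > init_right:
        return None
    span = int(insert_model.mean)
    depth = track.depth
    n = depth.size

    lo0 = max(0, init_left - 1 - span - params.flank_span)
    left_flank = depth[lo0: max(lo0 + 1, init_left - 1 - span)]
    hi0 = min(n, init_right + span + params.flank_span)
    right_flank = depth[min(hi0 - 1, init_right + span): hi0]
    flank_median = float(np.median(np.concatenate([left_flank, right_flank])))

    if flank_median <= 0:
        return DeletionCall(
            contig=cluster.contig,
            left_breakpoint=init_left,
            right_breakpoint=init_right,
            support=cluster.support,
            left_uncertainty=span,
            right_uncertainty=span,
            evidence="discordant",
        )

    threshold = params.refine_fraction * flank_median

    left0 = _scan_depth_edge(
        depth, init_left - 1 - span, init_right, +1, threshold, params.min_run
    )
    right0 = _scan_depth_edge(
        depth, init_right - 1 + span, init_left - 2, -1, threshold, params.min_run
    )
    evidence = "coverage"
    left_bp = left0 + 1 if left0 is not None else None
    right_bp = right0 + 1 if right0 is not None else None

    if clips is not None:
        win_lo, win_hi = init_left - span, init_left + span
        cand = [
            (count, pos) for pos, count in clips.left_candidates.items()
            if win_lo <= pos <= win_hi and count >= params.min_clip_support
        ]
        if cand:
            left_bp = max(cand)[1]
            evidence = "clip"
        win_lo, win_hi = init_right - span, init_right + span
        cand = [
            (count, pos) for pos, count in clips.right_candidates.items()
            if win_lo <= pos <= win_hi and count >= params.min_clip_support
        ]
        if cand:
            right_bp = max(cand)[1]
            evidence = "clip"

    if left_bp is None or right_bp is None or left_bp > right_bp:
        return None
    return DeletionCall(
        contig=cluster.contig,
        left_breakpoint=left_bp,
        right_breakpoint=right_bp,
        support=cluster.support,
        left_uncertainty=abs(left_bp - init_left),
        right_uncertainty=abs(right_bp - init_right),
        evidence=evidence,
    )


def call_deletions(
    records: list[AlignmentRecord],
    track: CoverageTrack,
    insert_model: InsertModel | None = None,
    params: SvParams = SvParams(),
) -> list[DeletionCall]:
    """End-to-end deletion calling: estimate -> find -> cluster -> refine."""
    if insert_model is None:
        insert_model = estimate_insert_model(records)
    pairs = find_discordant_pairs(records, insert_model)
    max_gap = insert_model.mean + 3 * insert_model.sd
    clusters = cluster_discordant(pairs, max_gap=max_gap, min_support=params.min_support)
    clips = collect_clip_evidence(records)
    calls: list[DeletionCall] = []
    for cl in clusters:
        call = refine_breakpoints(
            cl, track, insert_model, clips.get(cl.contig), params
        )
        if call is not None:
            calls.append(call)
    # collapse overlapping calls (redundant clusters of one event): keep the
    # best-supported call per overlap group
    calls.sort(key=lambda c: (c.contig, c.left_breakpoint, -c.support))
    kept: list[DeletionCall] = []
    for call in sorted(calls, key=lambda c: -c.support):
        if any(
            k.contig == call.contig
            and call.left_breakpoint <= k.right_breakpoint
            and call.right_breakpoint >= k.left_breakpoint
            for k in kept
        ):
            continue
        kept.append(call)
    kept.sort(key=lambda c: (c.contig, c.left_breakpoint))
    return kept
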