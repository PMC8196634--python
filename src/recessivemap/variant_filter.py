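"""Small-variant candidate filtering for a homozygous mutant bulk.

Because every plant in the mutant bulk is homozygous for the causal allele,
a causal small variant must be *fixed* within the bulk (within-bulk minor
allele frequency of zero, up to sequencing error) and *novel* relative to
the control cultivar panel (fertile commercial cultivars cannot carry a
recessive sterility allele at appreciable frequency).  The filter keeps
sites that pass both conditions; an empty result is itself informative — it
says small variants do not explain the trait and points at structural
variation instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .io_formats import GeneModel, VariantSite

__all__ = [
    "FilterParams",
    "CandidateVariant",
    "DYSFUNCTIONAL_EFFECTS",
    "bulk_alt_fraction",
    "candidate_small_variants",
    "classify_effect",
    "annotate_panel_effects",
]

DYSFUNCTIONAL_EFFECTS = frozenset(
    {"frameshift", "nonsense", "start_loss", "splice_disruption"}
)

EFFECTS = DYSFUNCTIONAL_EFFECTS | {"missense", "synonymous", "noncoding"}


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the fixed-and-novel rule.

    epsilon
        Tolerated within-bulk minor allele fraction; absorbs base-call error
        so that a truly fixed site with a handful of erroneous reference
        reads still passes.
    min_site_depth
        Sites below this total depth are excluded — fixation cannot be
        asserted from a few reads.
    panel_max_frequency
        Highest panel allele frequency still counted as "novel"; 0 means the
        allele must never have been observed in any cultivar.
    """

    epsilon: float = 0.02
    min_site_depth: int = 10
    panel_max_frequency: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if not 0.0 <= self.panel_max_frequency < 1.0:
            raise ValueError("panel_max_frequency must be in [0, 1)")


@dataclass
class CandidateVariant:
    site: VariantSite
    bulk_alt_fraction: float
    effect: str = "noncoding"

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")

    @property
    def dysfunctional(self) -> bool:
        return self.effect in DYSFUNCTIONAL_EFFECTS


def bulk_alt_fraction(site: VariantSite) -> float:
    """Alternative-allele fraction in the bulk: alt / (ref + alt) depths."""
    total = site.total_depth
    if total == 0:
        raise ValueError(f"{site.contig}:{site.pos}: zero total depth")
    return site.bulk_alt_depth / total


def candidate_small_variants(
    sites: Iterable[VariantSite],
    params: FilterParams = FilterParams(),
) -> list[CandidateVariant]:
    """Sites fixed for ALT in the bulk and novel against the panel.

    A site is retained when total depth >= ``min_site_depth``, the bulk
    alternative fraction is >= 1 - epsilon (the ALT allele is the fixed one)
    and the panel frequency is <= ``panel_max_frequency``.  Zero-depth sites
    are excluded.  The returned list is ordered by position and may be empty.
    """
    out: list[CandidateVariant] = []
    for site in sites:
        if site.total_depth < params.min_site_depth or site.total_depth == 0:
            continue
        frac = bulk_alt_fraction(site)
        if frac < 1.0 - params.epsilon:
            continue
        if site.panel_alt_frequency > params.panel_max_frequency:
            continue
        out.append(CandidateVariant(site=site, bulk_alt_fraction=frac))
    out.sort(key=lambda c: (c.site.contig, c.site.pos))
    return out


def _cds_sequence(gene: GeneModel, contig_seq: str) -> str:
    parts = [contig_seq[s - 1:e] for s, e in gene.cds_intervals]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _cds_index(gene: GeneModel, pos1: int) -> int | None:
    """Index of a genomic position within the strand-oriented CDS, or None."""
    offset = 0
    for s, e in gene.cds_intervals:
        if s <= pos1 <= e:
            idx = offset + (pos1 - s)
            total = gene.cds_length()
            return idx if gene.strand == "+" else total - 1 - idx
        offset += e - s + 1
    return None


def _near_interior_boundary(gene: GeneModel, pos1: int, margin: int = 2) -> bool:
    """True within ``margin`` bp of a CDS edge that faces an intron."""
    if len(gene.cds_intervals) == 0:
        return False
    first_start = gene.cds_intervals[0][0]
    last_end = gene.cds_intervals[-1][1]
    for s, e in gene.cds_intervals:
        if s != first_start and 0 < s - pos1 <= margin:
            return True
        if e != last_end and 0 < pos1 - e <= margin:
            return True
    return False


def classify_effect(
    site: VariantSite,
    gene: GeneModel,
    contig_seq: str,
) -> str:
    """Predict a variant's effect on a gene model.

    Order of precedence: CDS indel with non-codon length change ->
    frameshift; SNP destroying the initiator codon -> start_loss; SNP
    creating a stop codon -> nonsense; variant within 2 bp of an
    intron-facing CDS boundary -> splice_disruption; other CDS SNP ->
    missense or synonymous by codon translation; anything else (including
    in-frame indels and variants in genes without CDS) -> noncoding or
    missense as appropriate.
    """
    if site.contig != gene.contig or not gene.cds_intervals:
        return "noncoding"
    pos = site.pos
    in_cds = gene.in_cds(pos)

    if site.is_indel:
        if in_cds:
            shift = abs(len(site.alt_allele) - len(site.ref_allele))
            return "frameshift" if shift % 3 else "missense"
        if _near_interior_boundary(gene, pos):
            return "splice_disruption"
        return "noncoding"

    if not in_cds:
        return "splice_disruption" if _near_interior_boundary(gene, pos) else "noncoding"

    cds = _cds_sequence(gene, contig_seq)
    idx = _cds_index(gene, pos)
    assert idx is not None
    base = site.alt_allele
    if gene.strand == "-":
        base = str(Seq(base).complement())
    mutated = cds[:idx] + base + cds[idx + 1:]

    if idx < 3:
        if mutated[:3] != "ATG":
            return "start_loss"
        return "synonymous"

    codon_i = idx // 3
    old_codon = cds[codon_i * 3: codon_i * 3 + 3]
    new_codon = mutated[codon_i * 3: codon_i * 3 + 3]
    if len(new_codon) < 3:
        return "noncoding"  # trailing partial codon
    old_aa = str(Seq(old_codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == "*" and old_aa != "*":
        return "nonsense"
    return "synonymous" if new_aa == old_aa else "missense"


def annotate_panel_effects(
    panel_sites: Iterable[VariantSite],
    genes: Sequence[GeneModel],
    sequences: dict[str, str],
) -> dict[str, list[tuple[VariantSite, str]]]:
    """Classify panel variants against every gene body they fall in.

    Returns gene_id -> [(site, effect), ...]; used downstream to count
    dysfunctional panel polymorphisms per candidate gene.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    out: dict[str, list[tuple[VariantSite, str]]] = {g.gene_id: [] for g in genes}
    for site in panel_sites:
        for g in by_contig.get(site.contig, ()):
            if g.start <= site.pos <= g.end:
                seq = sequences.get(site.contig)
                effect = classify_effect(site, g, seq) if seq else "noncoding"
                out[g.gene_id].append((site, effect))
    return out
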