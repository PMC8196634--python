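"""Desk-scale simulator for the single-mutant-bulk mapping design.

Generates a toy reference carrying gene models, plants a causal multi-gene
deletion fixed in the mutant bulk plus small variants with the statistical
structure the analysis assumes (fixed in the bulk, absent or segregating in a
control cultivar panel), and emits already-aligned paired-end reads by
coordinate lift-over from the mutant haplotype to the reference.  Because no
aligner is involved, every downstream truth — absent genes, breakpoint
coordinates, discordant-pair counts, duplicate fragments — is exact by
construction and recorded in a :class:`TruthRecord`.

The default parameter set is the package's study preset: a 200-kb contig
with 10 genes, a 10-kb homozygous deletion spanning 2 of them, 30x
deduplicated depth, 100-bp reads with 300+-30-bp inserts, a 20-cultivar
control panel, 500 segregating background SNPs and 1 causal fixed site.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AlignmentRecord,
    Contig,
    GeneModel,
    write_fasta,
    write_sam,
)

__all__ = [
    "SimulationParams",
    "TruthRecord",
    "SimulatedBundle",
    "make_reference",
    "plant_deletion",
    "plant_variants",
    "simulate_paired_reads",
    "simulate_bundle",
    "write_bundle",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the simulator; defaults are the study preset."""

    contig_name: str = "chr1"
    contig_length: int = 200_000
    n_genes: int = 10
    #: 1-based inclusive interval excised from the mutant haplotype, or None.
    deletion_interval: tuple[int, int] | None = (95_001, 105_000)
    #: genes placed fully inside the deletion (the planted absent genes)
    n_deleted_genes: int = 2
    #: deleted genes that additionally receive a dysfunctional panel variant;
    #: the remaining deleted genes are the "clean" candidates
    n_panel_dysfunctional_genes: int = 1
    n_snps: int = 500
    n_causal_fixed_sites: int = 1
    panel_size: int = 20
    read_length: int = 100
    mean_depth: float = 30.0
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    sequencing_error_rate: float = 0.001
    duplicate_rate: float = 0.05
    #: fraction of fragments drawn from the deletion haplotype (1.0 = the
    #: deletion is fixed in the bulk, as for a bulk of homozygous mutants)
    deletion_frequency: float = 1.0
    #: emit reads overlapping the deletion junction with soft-clips at the
    #: junction; when False such fragments are suppressed entirely
    emit_junction_clips: bool = True
    #: Poisson mean for simulated VCF allele depths (defaults to mean_depth)
    site_depth: float | None = None
    panel_missing_rate: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.deletion_interval is not None:
            s, e = self.deletion_interval
            if not (1 <= s <= e <= self.contig_length):
                raise ValueError(f"deletion interval {self.deletion_interval} outside contig")
        for rate in (self.sequencing_error_rate, self.duplicate_rate,
                     self.deletion_frequency, self.panel_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate out of [0,1]: {rate}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if self.deletion_interval is None and self.n_deleted_genes:
            object.__setattr__(self, "n_deleted_genes", 0)

    @property
    def vcf_depth(self) -> float:
        return self.mean_depth if self.site_depth is None else self.site_depth

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthRecord:
    """Ground truth written by construction, consumed only by tests."""

    deletion_interval: tuple[int, int] | None
    causal_site_positions: list[int]
    absent_gene_ids: list[str]
    per_site_bulk_alt_frequency: dict[int, float]
    clean_gene_ids: list[str] = field(default_factory=list)
    panel_dysfunctional_positions: dict[str, int] = field(default_factory=dict)
    n_unique_fragments: int = 0
    n_unique_records: int = 0
    n_duplicate_records: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["per_site_bulk_alt_frequency"] = {
            str(k): v for k, v in self.per_site_bulk_alt_frequency.items()
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["per_site_bulk_alt_frequency"] = {
            int(k): v for k, v in d["per_site_bulk_alt_frequency"].items()
        }
        if d["deletion_interval"] is not None:
            d["deletion_interval"] = tuple(d["deletion_interval"])
        d["panel_dysfunctional_positions"] = dict(d["panel_dysfunctional_positions"])
        return cls(**d)


# ---------------------------------------------------------------------------
# reference and gene placement


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    contig: str,
    slot_start1: int,
    slot_end1: int,
    strand: str,
) -> GeneModel:
    """Place one gene with 2-3 CDS exons inside a 1-based slot."""
    slot_len = slot_end1 - slot_start1 + 1
    gene_len = int(rng.integers(1800, min(3600, slot_len - 200) + 1))
    start = slot_start1 + int(rng.integers(0, slot_len - gene_len + 1))
    end = start + gene_len - 1
    n_ex = int(rng.integers(2, 4))
    # alternate exon/intron chunks spanning the gene body
    n_chunks = 2 * n_ex - 1
    weights = rng.uniform(0.5, 1.5, n_chunks)
    sizes = np.maximum(60, (weights / weights.sum() * gene_len).astype(int))
    sizes[int(np.argmax(sizes))] += gene_len - int(sizes.sum())
    cds: list[tuple[int, int]] = []
    cursor = start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            cds.append((cursor, cursor + int(size) - 1))
        cursor += int(size)
    # trim the last exon so total CDS length is a codon multiple
    total = sum(e - s + 1 for s, e in cds)
    trim = total % 3
    if trim:
        s, e = cds[-1]
        cds[-1] = (s, e - trim)
    return GeneModel(gene_id=gene_id, contig=contig, start=start, end=end,
                     strand=strand, cds_intervals=cds)


def make_reference(params: SimulationParams) -> tuple[Contig, list[GeneModel]]:
    """Build a uniform-random reference with non-overlapping gene models.

    When a deletion interval is configured, ``n_deleted_genes`` genes are
    placed fully inside it (clear of the breakpoints) and the remaining genes
    outside it, so the set of planted absent genes is exact by construction.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng([params.seed, 0])
    seq = _random_sequence(rng, params.contig_length)

    slots: list[tuple[int, int, bool]] = []  # (start1, end1, inside_deletion)
    edge, bp_margin = 1500, 500
    if params.deletion_interval is not None and params.n_deleted_genes > 0:
        ds, de = params.deletion_interval
        inner_lo, inner_hi = ds + bp_margin, de - bp_margin
        span = inner_hi - inner_lo + 1
        per = span // params.n_deleted_genes
        if per < 2100:
            raise ValueError("deletion too small for the requested deleted genes")
        for i in range(params.n_deleted_genes):
            slots.append((inner_lo + i * per, inner_lo + (i + 1) * per - 1, True))
        outer_regions = [(edge, ds - bp_margin), (de + bp_margin, params.contig_length - edge)]
    else:
        outer_regions = [(edge, params.contig_length - edge)]

    n_outer = params.n_genes - sum(1 for s in slots if s[2])
    if n_outer < 0:
        raise ValueError("n_deleted_genes exceeds n_genes")
    lengths = [max(0, e - s + 1) for s, e in outer_regions]
    total = sum(lengths)
    counts = [round(n_outer * l / total) for l in lengths] if total else [0] * len(lengths)
    while sum(counts) > n_outer:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_outer:
        counts[int(np.argmax(lengths))] += 1
    for (rs, re_), k in zip(outer_regions, counts):
        if k == 0:
            continue
        per = (re_ - rs + 1) // k
        if per < 2100:
            raise ValueError("contig too small to place genes without overlap")
        for i in range(k):
            slots.append((rs + i * per, rs + (i + 1) * per - 1, False))

    slots.sort()
    genes: list[GeneModel] = []
    for i, (s1, e1, _inside) in enumerate(slots):
        strand = "+" if i % 2 == 0 else "-"
        genes.append(_make_gene(rng, f"gene{i + 1:02d}", params.contig_name, s1, e1, strand))

    # give each gene a proper initiator codon at its CDS 5' end
    for g in genes:
        if g.strand == "+":
            s = g.cds_intervals[0][0] - 1
            seq[s:s + 3] = list("ATG")
        else:
            e = g.cds_intervals[-1][1]
            seq[e - 3:e] = list("CAT")

    contig = Contig(params.contig_name, params.contig_length, "".join(seq))
    return contig, genes


def plant_deletion(sequence: str, interval1: tuple[int, int]) -> str:
    """Excise a 1-based inclusive interval from the reference sequence."""
    s, e = interval1
    if not (1 <= s <= e <= len(sequence)):
        raise ValueError(f"deletion interval {interval1} out of bounds")
    return sequence[: s - 1] + sequence[e:]


# ---------------------------------------------------------------------------
# small variants


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _panel_calls(
    rng: np.random.Generator, ref: str, alt: str, p_alt: float,
    panel_size: int, missing_rate: float, force_alt: bool,
) -> list[str]:
    calls = []
    for _ in range(panel_size):
        if rng.random() < missing_rate:
            calls.append(".")
        elif rng.random() < p_alt:
            calls.append(alt)
        else:
            calls.append(ref)
    if force_alt and alt not in calls:
        idx = next((i for i, c in enumerate(calls) if c != "."), 0)
        calls[idx] = alt
    return calls


def plant_variants(
    reference: Contig,
    genes: Sequence[GeneModel],
    params: SimulationParams,
) -> tuple[list[dict], list[dict], TruthRecord]:
    """Plant bulk and panel small variants.

    Returns ``(bulk_records, panel_records, truth)`` where bulk_records feed
    the bulk VCF (pos, ref, alt, AD) and panel_records the cultivar panel
    table.  Causal fixed sites have bulk alternative fraction 1.0 and never
    appear in the panel; background sites segregate in both.  Deleted genes
    selected for a dysfunctional panel variant get a 1-bp frameshift
    insertion in their CDS observed only in the panel (the mutant bulk has no
    reads over the deletion, so those sites cannot be in the bulk VCF).
    """
    rng = np.random.default_rng([params.seed, 1])
    seq = reference.sequence
    assert seq is not None
    L = reference.length
    if params.deletion_interval is not None:
        ds, de = params.deletion_interval
        available = np.concatenate([np.arange(1, ds), np.arange(de + 1, L + 1)])
    else:
        ds = de = None
        available = np.arange(1, L + 1)

    n_total = params.n_snps + params.n_causal_fixed_sites
    if n_total > available.size:
        raise ValueError("n_snps exceeds available positions outside the deletion")
    positions = rng.choice(available, size=n_total, replace=False)
    causal_pos = sorted(int(p) for p in positions[: params.n_causal_fixed_sites])
    background_pos = sorted(int(p) for p in positions[params.n_causal_fixed_sites:])

    bulk_records: list[dict] = []
    panel_records: list[dict] = []
    per_site_freq: dict[int, float] = {}

    def _depth() -> int:
        return max(1, int(rng.poisson(params.vcf_depth)))

    for pos in causal_pos:
        ref = seq[pos - 1]
        alt = _other_base(rng, ref)
        d = _depth()
        bulk_records.append({"pos": pos, "ref": ref, "alt": alt, "ad": (0, d)})
        per_site_freq[pos] = 1.0

    for pos in background_pos:
        ref = seq[pos - 1]
        alt = _other_base(rng, ref)
        frac = float(rng.uniform(0.05, 0.95))
        d = _depth()
        alt_d = int(rng.binomial(d, frac))
        bulk_records.append({"pos": pos, "ref": ref, "alt": alt, "ad": (d - alt_d, alt_d)})
        per_site_freq[pos] = frac
        p_alt = float(rng.uniform(0.1, 0.9))
        panel_records.append({
            "pos": pos, "ref": ref, "alt": alt,
            "calls": _panel_calls(rng, ref, alt, p_alt, params.panel_size,
                                  params.panel_missing_rate, force_alt=True),
        })

    deleted_genes = sorted(
        (g for g in genes
         if ds is not None and ds <= g.start and g.end <= de),
        key=lambda g: g.gene_id,
    )
    dys_positions: dict[str, int] = {}
    used = set(int(p) for p in positions)
    for g in deleted_genes[: params.n_panel_dysfunctional_genes]:
        # 1-bp insertion in the first CDS, clear of splice boundaries
        cs, ce = g.cds_intervals[0]
        pos = (cs + ce) // 2
        while pos in used:
            pos += 1
        used.add(pos)
        ref = seq[pos - 1]
        alt = ref + _other_base(rng, ref)
        panel_records.append({
            "pos": pos, "ref": ref, "alt": alt,
            "calls": _panel_calls(rng, ref, alt, 0.3, params.panel_size,
                                  params.panel_missing_rate, force_alt=True),
        })
        dys_positions[g.gene_id] = pos

    # a benign (intronic) panel variant in every deleted gene, so that the
    # dysfunctional count discriminates rather than merely "has any variant"
    for g in deleted_genes:
        if len(g.cds_intervals) < 2:
            continue
        intron_lo = g.cds_intervals[0][1] + 4
        intron_hi = g.cds_intervals[1][0] - 4
        if intron_lo > intron_hi:
            continue
        pos = (intron_lo + intron_hi) // 2
        while pos in used:
            pos += 1
        used.add(pos)
        ref = seq[pos - 1]
        alt = _other_base(rng, ref)
        panel_records.append({
            "pos": pos, "ref": ref, "alt": alt,
            "calls": _panel_calls(rng, ref, alt, 0.4, params.panel_size,
                                  params.panel_missing_rate, force_alt=True),
        })

    panel_records.sort(key=lambda r: r["pos"])
    bulk_records.sort(key=lambda r: r["pos"])

    absent = [g.gene_id for g in deleted_genes]
    clean = [g.gene_id for g in deleted_genes if g.gene_id not in dys_positions]
    truth = TruthRecord(
        deletion_interval=params.deletion_interval,
        causal_site_positions=causal_pos,
        absent_gene_ids=sorted(absent),
        per_site_bulk_alt_frequency=per_site_freq,
        clean_gene_ids=sorted(clean),
        panel_dysfunctional_positions=dys_positions,
    )
    return bulk_records, panel_records, truth


# ---------------------------------------------------------------------------
# paired-end reads


def _apply_errors(rng: np.random.Generator, read: str, n_err: int) -> str:
    if n_err == 0:
        return read
    arr = list(read)
    for i in rng.integers(0, len(arr), size=n_err):
        arr[i] = _other_base(rng, arr[i])
    return "".join(arr)


def simulate_paired_reads(
    reference: Contig,
    mutant_haplotype: str,
    params: SimulationParams,
) -> tuple[list[AlignmentRecord], dict]:
    """Emit aligned paired-end reads from the mutant haplotype.

    Fragments are drawn on the haplotype with truncated-normal insert sizes;
    each read's mapped coordinate is the lift-over of its haplotype
    coordinate to reference coordinates (positions at or beyond the deletion
    shift right by its length).  Pairs whose fragment spans the junction get
    the proper-pair flag cleared and a template length inflated by the
    deletion size; reads overlapping the junction itself are soft-clipped at
    the junction (or suppressed when ``emit_junction_clips`` is off).
    Duplicates are exact re-emissions of existing fragments.  Returns the
    coordinate-sorted records plus a fragment-accounting dict for the truth
    file.
    """
    rng = np.random.default_rng([params.seed, 2])
    rl = params.read_length
    if params.insert_mean < rl:
        raise ValueError("insert_mean < read_length")
    L = reference.length
    if params.deletion_interval is not None:
        ds0 = params.deletion_interval[0] - 1  # junction: first deleted base, 0-based
        D = params.deletion_interval[1] - params.deletion_interval[0] + 1
    else:
        ds0, D = None, 0
    ref_seq = reference.sequence
    assert ref_seq is not None

    haplotypes = {"mut": mutant_haplotype, "ref": ref_seq}
    records: list[AlignmentRecord] = []
    fragment_keys: set[tuple] = set()
    record_keys: set[tuple] = set()
    emitted_fragments: list[tuple[int, list[AlignmentRecord]]] = []

    n_frag = int(round(params.mean_depth * len(mutant_haplotype) / (2 * rl)))
    inserts = rng.normal(params.insert_mean, params.insert_sd, size=n_frag)
    lo = 2 * rl
    while np.any(inserts < lo):
        bad = inserts < lo
        inserts[bad] = rng.normal(params.insert_mean, params.insert_sd, size=int(bad.sum()))
    inserts = inserts.astype(int)
    haps = np.where(rng.random(n_frag) < params.deletion_frequency, "mut", "ref") \
        if params.deletion_frequency < 1.0 else np.full(n_frag, "mut")
    n_err = rng.binomial(rl, params.sequencing_error_rate, size=(n_frag, 2))

    def lift(p: int, hap: str) -> int:
        if hap == "mut" and ds0 is not None and p >= ds0:
            return p + D
        return p

    for i in range(n_frag):
        hap = str(haps[i])
        hseq = haplotypes[hap]
        insert = int(inserts[i])
        if insert > len(hseq):
            continue
        start = int(rng.integers(0, len(hseq) - insert + 1))
        r1 = (start, start + rl)
        r2 = (start + insert - rl, start + insert)

        aligned = []
        drop = False
        for a, b in (r1, r2):
            if hap == "ref" or ds0 is None or b <= ds0 or a >= ds0:
                aligned.append((lift(a, hap), f"{rl}M"))
            else:
                if not params.emit_junction_clips:
                    drop = True
                    break
                left_len, right_len = ds0 - a, b - ds0
                if left_len >= right_len:
                    aligned.append((a, f"{left_len}M{right_len}S"))
                else:
                    aligned.append((ds0 + D, f"{left_len}S{right_len}M"))
        if drop:
            continue

        key = (hap, start, insert)
        is_new = key not in fragment_keys
        fragment_keys.add(key)

        spans = [sum(n for n, op in AlignmentRecord(
            "", 0, "", p + 1, 0, cig, "=", 0, 0, "*").cigar_operations()
            if op in "MDN=X") for p, cig in aligned]
        outer_lo = min(p for p, _ in aligned)
        outer_hi = max(p + s for (p, _), s in zip(aligned, spans))
        t = outer_hi - outer_lo
        # the pair looks improper only when its two mapped segments fall on
        # opposite sides of the junction (observed template inflated by the
        # deletion); a junction read clipped onto the same side as its mate
        # maps as an ordinary proper pair
        if ds0 is not None and hap == "mut":
            on_left = [p + s <= ds0 for (p, _), s in zip(aligned, spans)]
            on_right = [p >= ds0 + D for (p, _), s in zip(aligned, spans)]
            straddle = any(on_left) and any(on_right)
        else:
            straddle = False
        proper = not straddle

        recs = []
        for ri, ((p, cig), (a, b)) in enumerate(zip(aligned, (r1, r2))):
            flag = 0x1 | (0x2 if proper else 0)
            flag |= (0x40 | 0x20) if ri == 0 else (0x80 | 0x10)
            mate_p = aligned[1 - ri][0]
            tlen = t if p <= mate_p else -t
            if p == mate_p:
                tlen = t if ri == 0 else -t
            seq = _apply_errors(rng, hseq[a:b], int(n_err[i, ri]))
            recs.append(AlignmentRecord(
                qname=f"frag{i:07d}", flag=flag, rname=reference.name, pos=p + 1,
                mapq=60, cigar=cig, rnext="=", pnext=mate_p + 1, tlen=tlen, seq=seq,
            ))
        if is_new:
            for r in recs:
                record_keys.add((r.rname, r.pos, r.flag & 0x10, r.tlen))
        records.extend(recs)
        emitted_fragments.append((i, recs))

    n_dup = int(rng.binomial(len(emitted_fragments), params.duplicate_rate)) \
        if emitted_fragments else 0
    for j, idx in enumerate(rng.integers(0, len(emitted_fragments), size=n_dup)):
        _, recs = emitted_fragments[int(idx)]
        for r in recs:
            dup = dataclasses.replace(r, qname=f"{r.qname}.dup{j}")
            records.append(dup)

    records.sort(key=lambda r: (r.rname, r.pos, r.flag, r.qname))
    accounting = {
        "n_unique_fragments": len(fragment_keys),
        "n_unique_records": len(record_keys),
        "n_duplicate_records": 2 * n_dup,
    }
    return records, accounting


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedBundle:
    params: SimulationParams
    reference: Contig
    mutant_haplotype: str
    genes: list[GeneModel]
    alignments: list[AlignmentRecord]
    bulk_records: list[dict]
    panel_records: list[dict]
    truth: TruthRecord


def simulate_bundle(params: SimulationParams | None = None) -> SimulatedBundle:
    """Run every simulation stage and return the in-memory bundle."""
    params = params or SimulationParams()
    reference, genes = make_reference(params)
    if params.deletion_interval is not None:
        mutant = plant_deletion(reference.sequence, params.deletion_interval)
    else:
        mutant = reference.sequence
    bulk, panel, truth = plant_variants(reference, genes, params)
    alignments, accounting = simulate_paired_reads(reference, mutant, params)
    truth.n_unique_fragments = accounting["n_unique_fragments"]
    truth.n_unique_records = accounting["n_unique_records"]
    truth.n_duplicate_records = accounting["n_duplicate_records"]
    return SimulatedBundle(params, reference, mutant, genes, alignments, bulk, panel, truth)


def _write_bulk_vcf(bundle: SimulatedBundle, path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={bundle.reference.name},length={bundle.reference.length}>")
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_sample("mutant_bulk")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in bundle.bulk_records:
            v = out.new_record(
                contig=bundle.reference.name, start=rec["pos"] - 1,
                alleles=(rec["ref"], rec["alt"]),
            )
            v.samples["mutant_bulk"]["AD"] = rec["ad"]
            v.samples["mutant_bulk"]["DP"] = sum(rec["ad"])
            out.write(v)


def _write_panel_tsv(bundle: SimulatedBundle, path: Path) -> None:
    cultivars = [f"cultivar{i + 1:02d}" for i in range(bundle.params.panel_size)]
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\t" + "\t".join(cultivars) + "\n")
        for rec in bundle.panel_records:
            fh.write(
                f"{bundle.reference.name}\t{rec['pos']}\t{rec['ref']}\t{rec['alt']}\t"
                + "\t".join(rec["calls"]) + "\n"
            )


def _write_gff3(bundle: SimulatedBundle, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {bundle.reference.name} 1 {bundle.reference.length}\n")
        for g in bundle.genes:
            fh.write(f"{g.contig}\trecessivemap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.contig}\trecessivemap\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.cds_intervals, start=1):
                fh.write(f"{g.contig}\trecessivemap\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={mrna}.cds{k};Parent={mrna}\n")


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA (reference + mutant haplotype), SAM, VCF, GFF3, panel TSV
    and the truth JSON into ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_fasta": outdir / "reference.fa",
        "mutant_fasta": outdir / "mutant_haplotype.fa",
        "sam": outdir / "bulk_alignments.sam",
        "bulk_vcf": outdir / "bulk_sites.vcf",
        "panel_tsv": outdir / "panel_alleles.tsv",
        "gff3": outdir / "genes.gff3",
        "truth_json": outdir / "truth.json",
    }
    write_fasta({bundle.reference.name: bundle.reference.sequence}, paths["reference_fasta"])
    write_fasta({f"{bundle.reference.name}_mutant": bundle.mutant_haplotype},
                paths["mutant_fasta"])
    write_sam(bundle.alignments, paths["sam"], [bundle.reference])
    _write_bulk_vcf(bundle, paths["bulk_vcf"])
    _write_panel_tsv(bundle, paths["panel_tsv"])
    _write_gff3(bundle, paths["gff3"])
    paths["truth_json"].write_text(bundle.truth.to_json())
    return paths
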