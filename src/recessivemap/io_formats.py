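"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
File formats keep their native conventions at the boundary: SAM, VCF and
GFF3 are 1-based inclusive; BED is 0-based half-open.  The record classes
below store coordinates as the format defines them and expose ``*_0`` /
half-open helpers so that all array arithmetic inside the package runs on
0-based half-open intervals.  :func:`to_zero_based` and
:func:`to_one_based` are the only two conversion functions in the package.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Contig",
    "AlignmentRecord",
    "VariantSite",
    "GeneModel",
    "SamFormatError",
    "parse_sam",
    "read_sam",
    "write_sam",
    "parse_vcf_sites",
    "read_panel_table",
    "read_gff3_genes",
    "write_bed",
    "read_bed",
    "read_fasta",
    "write_fasta",
    "to_zero_based",
    "to_one_based",
]

# SAM flag bits used throughout the pipeline
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# CIGAR operators that consume reference bases
_REF_CONSUMING = frozenset("MDN=X")
_QUERY_CONSUMING = frozenset("MIS=X")


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class Contig:
    """A reference sequence axis (e.g. a chromosome)."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        if self.length <= 0:
            raise ValueError(f"contig length must be positive, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.name}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass
class AlignmentRecord:
    """One mapped read with SAM pair/flag/CIGAR/template-length semantics.

    ``pos`` is 1-based (SAM convention); ``ref_start0``/``ref_end0`` give the
    0-based half-open reference interval the alignment consumes.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    def cigar_operations(self) -> list[tuple[int, str]]:
        if self.cigar == "*":
            return []
        return [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]

    def reference_span(self) -> int:
        """Number of reference bases the alignment consumes (M/D/N/=/X)."""
        return sum(n for n, op in self.cigar_operations() if op in _REF_CONSUMING)

    @property
    def ref_start0(self) -> int:
        return self.pos - 1

    @property
    def ref_end0(self) -> int:
        return self.pos - 1 + self.reference_span()

    def aligned_blocks0(self) -> list[tuple[int, int]]:
        """0-based half-open reference blocks covered by M/=/X/D operations."""
        blocks: list[tuple[int, int]] = []
        ref = self.ref_start0
        for n, op in self.cigar_operations():
            if op in "M=XD":
                blocks.append((ref, ref + n))
                ref += n
            elif op == "N":
                ref += n
        return blocks

    def leading_softclip(self) -> int:
        ops = self.cigar_operations()
        return ops[0][0] if ops and ops[0][1] == "S" else 0

    def trailing_softclip(self) -> int:
        ops = self.cigar_operations()
        return ops[-1][0] if ops and ops[-1][1] == "S" else 0

    def to_sam_line(self) -> str:
        return "\t".join(
            (
                self.qname,
                str(self.flag),
                self.rname,
                str(self.pos),
                str(self.mapq),
                self.cigar,
                self.rnext,
                str(self.pnext),
                str(self.tlen),
                self.seq,
                "*",
            )
        )


@dataclass
class VariantSite:
    """A called biallelic site with bulk allele depths and panel frequency.

    ``pos`` is 1-based (VCF convention).  ``panel_alt_frequency`` is the
    alternative-allele frequency across control cultivars with a non-missing
    call at the site; ``panel_alt_observed`` is False for sites never seen in
    the panel.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    bulk_ref_depth: int
    bulk_alt_depth: int
    panel_alt_frequency: float = 0.0
    panel_alt_observed: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.contig}:{self.pos}: ref == alt ({self.ref_allele})")
        if not 0.0 <= self.panel_alt_frequency <= 1.0:
            raise ValueError(f"panel_alt_frequency out of [0,1]: {self.panel_alt_frequency}")
        if min(self.bulk_ref_depth, self.bulk_alt_depth) < 0:
            raise ValueError("negative allele depth")

    @property
    def total_depth(self) -> int:
        return self.bulk_ref_depth + self.bulk_alt_depth

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass
class GeneModel:
    """An annotated gene interval; coordinates are 1-based inclusive (GFF3)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        ivs = sorted(set(self.cds_intervals))
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        for s, e in ivs:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: CDS ({s},{e}) outside gene body")
        self.cds_intervals = ivs

    @property
    def interval0(self) -> tuple[int, int]:
        return to_zero_based(self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def contains(self, pos1: int) -> bool:
        return self.start <= pos1 <= self.end

    def in_cds(self, pos1: int) -> bool:
        return any(s <= pos1 <= e for s, e in self.cds_intervals)


class SamFormatError(ValueError):
    """Raised for malformed SAM text; the message names the line number."""


_SAM_N_FIELDS = 11


def parse_sam(stream: IO[str] | Iterable[str]) -> Iterator[AlignmentRecord]:
    """Parse tab-delimited SAM text into :class:`AlignmentRecord` objects.

    Header lines (``@...``) are skipped.  Unmapped records are returned with
    their unmapped flag set so downstream depth code can exclude them.
    Malformed mandatory fields raise :class:`SamFormatError` naming the line.
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < _SAM_N_FIELDS:
            raise SamFormatError(
                f"SAM line {lineno}: expected >= {_SAM_N_FIELDS} fields, got {len(fields)}"
            )
        try:
            flag = int(fields[1])
            pos = int(fields[3])
            mapq = int(fields[4])
            pnext = int(fields[7])
            tlen = int(fields[8])
        except ValueError as exc:
            raise SamFormatError(f"SAM line {lineno}: non-integer mandatory field: {exc}") from exc
        cigar = fields[5]
        if cigar != "*":
            consumed = "".join(f"{n}{op}" for n, op in _CIGAR_RE.findall(cigar))
            if consumed != cigar:
                raise SamFormatError(f"SAM line {lineno}: unknown CIGAR operator in {cigar!r}")
        if pos < 0:
            raise SamFormatError(f"SAM line {lineno}: negative POS {pos}")
        yield AlignmentRecord(
            qname=fields[0], flag=flag, rname=fields[2], pos=pos, mapq=mapq,
            cigar=cigar, rnext=fields[6], pnext=pnext, tlen=tlen, seq=fields[9],
        )


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    with open(path) as fh:
        return list(parse_sam(fh))


def write_sam(
    records: Iterable[AlignmentRecord],
    stream_or_path: IO[str] | str | Path,
    contigs: Sequence[Contig] = (),
) -> None:
    """Write records as coordinate-compatible SAM text with @HD/@SQ header."""

    def _write(fh: IO[str]) -> None:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in contigs:
            fh.write(f"@SQ\tSN:{c.name}\tLN:{c.length}\n")
        for rec in records:
            fh.write(rec.to_sam_line() + "\n")

    if isinstance(stream_or_path, (str, Path)):
        with open(stream_or_path, "w") as fh:
            _write(fh)
    else:
        _write(stream_or_path)


def read_panel_table(path: str | Path) -> pd.DataFrame:
    """Read the control-panel allele table.

    Expected TSV columns: contig, pos, ref, alt, then one column per cultivar
    holding the observed allele (the ref string, the alt string, or ``.`` for
    a missing call).  Returns a frame indexed by (contig, pos, ref, alt) with
    columns ``alt_frequency`` (over non-missing calls), ``n_alt`` and
    ``n_called``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = ["contig", "pos", "ref", "alt"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"panel table missing columns: {missing}")
    cultivars = [c for c in raw.columns if c not in required]
    rows = []
    for _, row in raw.iterrows():
        calls = [row[c] for c in cultivars if row[c] != "."]
        n_alt = sum(1 for a in calls if a == row["alt"])
        n_called = len(calls)
        rows.append(
            {
                "contig": row["contig"],
                "pos": int(row["pos"]),
                "ref": row["ref"],
                "alt": row["alt"],
                "alt_frequency": n_alt / n_called if n_called else 0.0,
                "n_alt": n_alt,
                "n_called": n_called,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "alt_frequency", "n_alt", "n_called"]
    )
    return frame.set_index(["contig", "pos", "ref", "alt"])


def parse_vcf_sites(
    bulk_vcf: str | Path,
    panel: str | Path | pd.DataFrame | None = None,
    warn_stream: IO[str] | None = None,
) -> list[VariantSite]:
    """Load bulk VCF sites (with AD allele depths) joined against the panel.

    Multi-allelic records are split into biallelic sites.  Sites absent from
    the panel get ``panel_alt_observed=False`` and frequency 0.  Sites lacking
    an AD field are skipped with a warning and a reported count.
    """
    import pysam

    if panel is None:
        panel_frame = None
    elif isinstance(panel, pd.DataFrame):
        panel_frame = panel
    else:
        panel_frame = read_panel_table(panel)

    sites: list[VariantSite] = []
    n_skipped = 0
    with pysam.VariantFile(str(bulk_vcf)) as vcf:
        for rec in vcf:
            ad = None
            for sample in rec.samples.values():
                ad = sample.get("AD")
                break
            if ad is None or any(v is None for v in ad):
                n_skipped += 1
                print(
                    f"warning: {rec.chrom}:{rec.pos} has no AD field; site skipped",
                    file=warn_stream or sys.stderr,
                )
                continue
            for i, alt in enumerate(rec.alts or ()):
                freq, observed = 0.0, False
                if panel_frame is not None:
                    key = (rec.chrom, rec.pos, rec.ref, alt)
                    if key in panel_frame.index:
                        freq = float(panel_frame.loc[key, "alt_frequency"])
                        observed = True
                sites.append(
                    VariantSite(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        bulk_ref_depth=int(ad[0]),
                        bulk_alt_depth=int(ad[i + 1]),
                        panel_alt_frequency=freq,
                        panel_alt_observed=observed,
                    )
                )
    if n_skipped:
        print(f"warning: {n_skipped} site(s) skipped for missing AD", file=warn_stream or sys.stderr)
    return sites


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene + CDS, linked via Parent, possibly through mRNA).

    Genes without CDS children are retained with empty ``cds_intervals``;
    CDS features whose Parent cannot be resolved are dropped with a warning.
    CDS ranges shared by multiple mRNAs of one gene are deduplicated.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds = {
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS")
        }
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_intervals=sorted(cds),
            )
        )
    # orphan CDS check: any CDS not reachable from a gene
    reachable: set[str] = set()
    for gene in db.features_of_type("gene"):
        for c in db.children(gene, featuretype="CDS"):
            reachable.add(c.id)
    for c in db.features_of_type("CDS"):
        if c.id not in reachable:
            print(f"warning: CDS {c.id} has unresolvable Parent; dropped", file=sys.stderr)
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def write_bed(
    intervals: Iterable[tuple[str, int, int, str] | tuple[str, int, int, str, float]],
    stream_or_path: IO[str] | str | Path,
) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open) lines."""

    def _write(fh: IO[str]) -> None:
        for iv in intervals:
            contig, start1, end1, name = iv[0], iv[1], iv[2], iv[3]
            if start1 > end1:
                raise ValueError(f"interval start {start1} > end {end1}")
            start0, end0 = to_zero_based(start1, end1)
            cols = [contig, str(start0), str(end0), str(name)]
            if len(iv) > 4:
                cols.append(str(iv[4]))
            fh.write("\t".join(cols) + "\n")

    if isinstance(stream_or_path, (str, Path)):
        with open(stream_or_path, "w") as fh:
            _write(fh)
    else:
        _write(stream_or_path)


def read_bed(stream_or_path: IO[str] | str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED lines back to 1-based inclusive (contig, start, end, name)."""

    def _read(fh: IO[str]) -> list[tuple[str, int, int, str]]:
        out = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start1, end1 = to_one_based(int(f[1]), int(f[2]))
            out.append((f[0], start1, end1, f[3] if len(f) > 3 else ""))
        return out

    if isinstance(stream_or_path, (str, Path)):
        with open(stream_or_path) as fh:
            return _read(fh)
    return _read(stream_or_path)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
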