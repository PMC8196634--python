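"""Downstream diagnostics: in-silico presence/absence PCR and CRISPR-edit
truncation prediction.

The PCR predictor models the band logic of a presence/absence genotyping
assay: a "fertility" primer pair amplifies only when the deletable segment
is intact (its product would otherwise be destroyed or out of range), while
a "sterility" pair spans the deletion and amplifies only from the deleted
haplotype where its sites are brought within product range.  The truncation
predictor applies a CRISPR edit to a CDS and translates the result, giving
the length of the premature protein a frameshift or early stop produces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "PrimerPair",
    "AmpliconPrediction",
    "EditEvent",
    "TruncationPrediction",
    "Genotype",
    "in_silico_pcr",
    "genotype_sample",
    "apply_edit",
    "predict_truncation",
]

_VALID = re.compile(r"^[ACGT]+$")


def _check_nucleotides(seq: str, what: str) -> str:
    seq = seq.upper()
    if not _VALID.match(seq):
        raise ValueError(f"{what} contains non-ACGT characters: {seq!r}")
    return seq


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward_seq: str
    reverse_seq: str

    def __post_init__(self) -> None:
        for s in (self.forward_seq, self.reverse_seq):
            _check_nucleotides(s, f"primer {self.name}")
            if len(s) < 15:
                raise ValueError(f"primer {self.name}: primers must be >= 15 nt")


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    start: int  # 1-based inclusive on the template
    end: int
    primer_pair_name: str
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Genotype(str, Enum):
    fertile_homozygous_like = "fertile_homozygous_like"
    deletion_homozygous_like = "deletion_homozygous_like"
    both_bands = "both_bands"
    no_call = "no_call"


@dataclass(frozen=True)
class EditEvent:
    kind: str  # "insertion" or "deletion"
    position: int  # 1-based coordinate in the CDS
    sequence_or_length: str | int

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "insertion":
            _check_nucleotides(str(self.sequence_or_length), "inserted sequence")
        elif int(self.sequence_or_length) <= 0:
            raise ValueError("deletion length must be positive")


@dataclass(frozen=True)
class TruncationPrediction:
    protein_length: int  # residues before the first stop; stop excluded
    has_stop: bool
    frameshifted: bool
    start_lost: bool = False


def _find_all(template: str, query: str) -> list[int]:
    """0-based start positions of every exact occurrence (overlaps allowed)."""
    hits, i = [], template.find(query)
    while i != -1:
        hits.append(i)
        i = template.find(query, i + 1)
    return hits


def in_silico_pcr(
    template: str,
    primer_pair: PrimerPair,
    max_amplicon: int = 10_000,
    template_id: str = "template",
) -> list[AmpliconPrediction]:
    """Predict amplicons from exact primer matches on both strands.

    On the plus strand an amplicon runs from a forward-primer match to the
    end of a downstream reverse-complemented reverse-primer match within
    ``max_amplicon``; the minus strand is searched symmetrically with the
    primer roles swapped.  Matching is exact — the assay being modelled is a
    simple presence/absence band, not a thermodynamic prediction.
    """
    template = _check_nucleotides(template, "template")
    fwd = _check_nucleotides(primer_pair.forward_seq, "forward primer")
    rev = _check_nucleotides(primer_pair.reverse_seq, "reverse primer")

    out: list[AmpliconPrediction] = []
    seen: set[tuple[int, int]] = set()
    for a_seq, b_seq, strand in (
        (fwd, str(Seq(rev).reverse_complement()), "+"),
        (rev, str(Seq(fwd).reverse_complement()), "-"),
    ):
        a_hits = _find_all(template, a_seq)
        b_hits = _find_all(template, b_seq)
        for a0 in a_hits:
            for b0 in b_hits:
                end0 = b0 + len(b_seq)  # half-open product end
                if b0 < a0 + len(a_seq):
                    continue  # reverse site must lie downstream of the forward 3' end
                length = end0 - a0
                if length > max_amplicon:
                    continue
                span = (a0 + 1, end0)
                if span in seen:
                    continue
                seen.add(span)
                out.append(
                    AmpliconPrediction(
                        template_id=template_id,
                        start=span[0],
                        end=span[1],
                        primer_pair_name=primer_pair.name,
                        strand=strand,
                    )
                )
    out.sort(key=lambda a: (a.start, a.end))
    return out


def genotype_sample(
    templates: str | Sequence[str],
    fertility_pair: PrimerPair,
    sterility_pair: PrimerPair,
    max_amplicon: int = 10_000,
) -> Genotype:
    """Classify a sample (one or two haplotype templates) by band pattern.

    A fertility band alone reads as fertile-like, a sterility band alone as
    a deletion homozygote, both bands as a heterozygote.  Neither band gives
    ``no_call`` — the assay failed rather than genotyped.
    """
    if isinstance(templates, str):
        templates = [templates]
    fert = any(in_silico_pcr(t, fertility_pair, max_amplicon) for t in templates)
    ster = any(in_silico_pcr(t, sterility_pair, max_amplicon) for t in templates)
    if fert and ster:
        return Genotype.both_bands
    if fert:
        return Genotype.fertile_homozygous_like
    if ster:
        return Genotype.deletion_homozygous_like
    return Genotype.no_call


def apply_edit(cds: str, edit: EditEvent) -> str:
    """Apply an insertion (after ``position``) or deletion (starting at
    ``position``) to a CDS; 1-based coordinates."""
    cds = _check_nucleotides(cds, "CDS")
    pos = edit.position
    if edit.kind == "insertion":
        if not 0 <= pos <= len(cds):
            raise ValueError(f"insertion position {pos} outside CDS of length {len(cds)}")
        return cds[:pos] + str(edit.sequence_or_length) + cds[pos:]
    n = int(edit.sequence_or_length)
    if not 1 <= pos <= len(cds) or pos - 1 + n > len(cds):
        raise ValueError(
            f"deletion of {n} at {pos} extends past CDS of length {len(cds)}"
        )
    return cds[: pos - 1] + cds[pos - 1 + n:]


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def predict_truncation(cds: str, unedited_length: int | None = None) -> TruncationPrediction:
    """Translate a (possibly edited) CDS and report the premature protein.

    Translation runs in frame from the first base to the first stop codon;
    ``protein_length`` counts residues before the stop (the stop itself is
    excluded, matching the usual "N-amino-acid protein" convention).
    ``frameshifted`` reports whether the sequence length is off-frame
    relative to the unedited CDS (assumed codon-multiple when not given).
    """
    cds = _check_nucleotides(cds, "CDS")
    start_lost = not cds.startswith("ATG")
    reference_mod = (unedited_length or 0) % 3
    frameshifted = len(cds) % 3 != reference_mod

    n_aa = 0
    has_stop = False
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i: i + 3]
        if codon in _STOP_CODONS:
            has_stop = True
            break
        n_aa += 1
    return TruncationPrediction(
        protein_length=n_aa,
        has_stop=has_stop,
        frameshifted=frameshifted,
        start_lost=start_lost,
    )
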