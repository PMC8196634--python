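"""Diagnostic assays: in-silico presence/absence PCR and truncation
prediction for CRISPR edits.

The fertility primer pair sits inside the deletable segment (band only when
the segment is intact); the sterility pair flanks it at a distance
amplifiable only after the deletion shortens the template.  The truncation
predictor translates an edited CDS and reports the premature protein.
"""

import numpy as np
from Bio.Seq import Seq

from recessivemap.assay_tools import (
    EditEvent, PrimerPair, apply_edit, genotype_sample, in_silico_pcr, predict_truncation,
)

rng = np.random.default_rng(0)
bases = lambda n: "".join(rng.choice(list("ACGT"), n))
rc = lambda s: str(Seq(s).reverse_complement())

fert = PrimerPair("FERTILITY", bases(21), bases(25))
ster = PrimerPair("STERILITY", bases(30), bases(23))

inside = bases(5_000) + fert.forward_seq + bases(200) + rc(fert.reverse_seq) + bases(5_000)
left = bases(300) + ster.forward_seq + bases(100)
right = bases(100) + rc(ster.reverse_seq) + bases(300)
fertile_hap, deleted_hap = left + inside + right, left + right

for name, hap in (("fertile", fertile_hap), ("deleted", deleted_hap)):
    bands = {p.name: [a.length for a in in_silico_pcr(hap, p)] for p in (fert, ster)}
    print(f"{name} haplotype bands: {bands}")
for geno, haps in (("homozygous intact", [fertile_hap] * 2),
                   ("homozygous deleted", [deleted_hap] * 2),
                   ("heterozygous", [fertile_hap, deleted_hap])):
    print(f"  {geno:>18} -> {genotype_sample(haps, fert, ster).value}")

# truncation prediction: a 1-bp insertion causing a frameshift
cds = "ATG" + "AAA" * 60 + "TAA"  # 61-codon open reading frame, then stop
edited = apply_edit(cds, EditEvent("insertion", 9, "T"))
pred = predict_truncation(edited, unedited_length=len(cds))
print(f"\n1-bp insertion after codon 3 of a {len(cds)//3 - 1}-residue ORF:")
print(f"  protein_length={pred.protein_length}, has_stop={pred.has_stop}, "
      f"frameshifted={pred.frameshifted}")
print("the frameshift scrambles the frame and truncates the protein early")
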