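# recessivemap

Map the causal locus of a recessive trait from a **single mutant bulk**
sequenced against a **public control panel** — no wild-type bulk required.

## The problem and the approach

In a recurrent selection population maintained through a recessive
male-sterility locus, every sterile plant is homozygous for the causal
allele. Pooling many such plants and resequencing the pool deeply gives a
"mutant bulk" in which the causal allele is *fixed*. Commercial cultivars,
being fertile, essentially never carry that allele — so published cultivar
resequencing panels can stand in for the wild-type bulk of a classical
bulked-segregant analysis. Two signals identify the locus:

1. **Small variants.** A causal SNP/indel must have within-bulk minor
   allele frequency ≈ 0 (the bulk is homozygous) *and* be novel relative to
   the panel. The filter keeps sites with bulk alternative-allele fraction
   ≥ 1 − ε (default ε = 0.02, total depth ≥ 10) and panel frequency ≤ 0.
   An **empty** result is itself informative: it points at structural
   variation.
2. **Presence/absence variation (PAV).** A gene removed by a deletion gets
   no reads. For a region *R* with deduplicated per-base depth *d(i)*, the
   **sequencing saturation** is the breadth of coverage
   `sat(R) = |{i ∈ R : d(i) ≥ 1}| / |R|`, and window means use per-base
   capped depth `min(d(i), 150)` so repeats cannot inflate them. Genes with
   `sat < 0.03` are called absent. The deletion itself is called from
   discordant pairs — pairs whose mapped template length is inflated by the
   deletion size or whose proper-pair flag is unset — clustered by single
   linkage and refined to base-exact breakpoints with soft-clip stacks (or
   to ~read-length accuracy from coverage edges alone).

Among several absent genes, the causal one is the gene with **no
dysfunctional polymorphism** (frameshift, nonsense, start-loss, splice
disruption) in the control panel: a gene already broken in fertile
cultivars cannot explain a recessive sterility trait. Downstream
diagnostics — in-silico presence/absence PCR genotyping and CRISPR-edit
truncation prediction — close the loop from mapped locus to usable assay.

A synthetic-data generator plants a multi-gene deletion, bulk-fixed and
panel-segregating variants, duplicates and paired-end insert structure,
emitting already-aligned SAM by coordinate lift-over so that every truth
(absent genes, breakpoints, duplicates) is exact by construction.

## Worked example

```bash
python examples/01_simulate_bundle.py   # build the 200-kb study preset
python examples/02_pav_scan.py          # saturation scan
python examples/04_deletion_calling.py  # breakpoint calling
python examples/05_candidate_ranking.py # gene ranking
```

The preset plants a 10-kb deletion (chr1:95,001–105,000) spanning 2 of 10
genes, 500 segregating SNPs, 1 causal fixed site, and 30× paired-end
coverage. The scan prints, per gene:

```
  gene04  sat=1.000  flank_sat=1.000  depth= 30.4x
  gene05  sat=0.000  flank_sat=0.440  depth=  0.0x  <-- ABSENT
  gene06  sat=0.000  flank_sat=0.378  depth=  0.0x  <-- ABSENT
  gene07  sat=1.000  flank_sat=1.000  depth= 29.9x
```

— exactly the two planted genes drop to zero saturation while their 5-kb
flanks stay partially covered (the flanks extend beyond the deletion).
Deletion calling recovers the planted interval exactly:

```
insert model from proper pairs: 299.8 +- 29.9 bp (discordant beyond 449 bp)
deletion-signature discordant pairs: 34
call: chr1:95,001-105,000  size=10,000 bp  support=34  evidence=clip  uncertainty=(0,0) bp
```

34 pairs straddle the junction with template lengths ≈ insert + 10,000 bp,
and soft-clip stacks pin both breakpoints with zero uncertainty. Ranking
then places the deleted gene with a clean panel record first:

```
rank  gene     in_deletion  saturation  panel_dysfunctional
   1  gene06         True       0.000                    0
   2  gene05         True       0.000                    1
```

gene05 carries a planted frameshift in the control panel, so gene06 — absent
from the bulk and intact in every fertile cultivar — is the causal candidate.

The same stages run from the shell:

```bash
recessivemap simulate --outdir bundle --seed 42
recessivemap run-all --sam bundle/bulk_alignments.sam --bulk-vcf bundle/bulk_sites.vcf \
    --panel bundle/panel_alleles.tsv --gff3 bundle/genes.gff3 \
    --fasta bundle/reference.fa --outdir results
```

writing `windows.tsv`, `gene_saturation.tsv`, `absent_regions.bed`,
`candidate_variants.tsv`, `deletions.tsv/.bed`, `candidates.tsv/.bed`, a
`manifest.json` with parameter echo and input checksums, and `summary.txt`.

## Layout

- `src/recessivemap/io_formats.py` — SAM/VCF/GFF3/BED/FASTA boundary with
  explicit coordinate conventions
- `src/recessivemap/synthetic_data.py` — the simulator and truth records
- `src/recessivemap/coverage_saturation.py` — dedup, depth, saturation, PAV scan
- `src/recessivemap/variant_filter.py` — fixed-and-novel rule, effect classifier
- `src/recessivemap/sv_breakpoints.py` — discordant-pair deletion calling
- `src/recessivemap/candidate_report.py` — gene ranking and reports
- `src/recessivemap/assay_tools.py` — in-silico PCR, truncation prediction
- `src/recessivemap/pipeline.py`, `cli.py` — orchestration and shell interface

See `docs/methods.md` for the model, parameter choices and limitations.
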