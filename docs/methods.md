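# Methods

## Study design the package models

The pipeline targets a specific mapping design: a *single mutant bulk* —
pooled DNA of many plants homozygous for a recessive allele, resequenced
deeply — contrasted with a *public control panel* of resequenced fertile
cultivars that replaces the wild-type bulk of a classical bulked-segregant
analysis. Two consequences drive every stage:

- the causal small variant, if there is one, is **fixed** in the bulk
  (within-bulk minor allele frequency ≈ 0) and effectively **absent** from
  the panel;
- a causal presence/absence variant (PAV) leaves the deleted genes with
  essentially **zero read coverage** in the bulk while the panel carries
  them intact.

## Definitions and estimators

**Sequencing saturation.** For a region *R* and deduplicated per-base depth
*d(i)*, saturation is breadth of coverage: the fraction of positions with
*d(i) ≥ m*, with `min_covered_depth` m = 1 by default. This is the reading
consistent with a value of 1.0 for a genome "seamlessly covered" at high
depth and ~0 for deleted genes; m is a parameter so stricter readings
remain available. A gene is called absent when its gene-body saturation
falls below `saturation_threshold` (default 0.03). Flank saturation (5 kb
each side, clipped at contig ends) is reported alongside but does not enter
the absence call: a deletion slightly larger than the gene body should not
mask the gene's own absence.

**Depth cap.** Window summaries average `min(d(i), cap)` with cap = 150×,
applied per base *before* averaging, so over-represented repeats cannot
inflate a window mean; window saturation is unaffected by the cap.

**Duplicate removal.** Positional duplicates share
(contig, position, strand, template length); the first record per key is
kept. This is the standard positional definition used by coordinate-based
duplicate markers; the simulator re-emits fragments verbatim so the key is
exact on synthetic data.

**Fixed-and-novel variant rule.** A site passes when total allele depth ≥
`min_site_depth` (10), bulk alternative-allele fraction ≥ 1 − ε, and panel
alternative-allele frequency ≤ `panel_max_frequency`. ε (default 0.02)
absorbs base-call error at a truly fixed site; the panel cap defaults to 0
("never observed in any cultivar") but is exposed because public panels
contain genotyping error. Panel frequency is computed over cultivars with a
non-missing call at the site. Sites below the depth cut are excluded, not
imputed — fixation cannot be asserted from a handful of reads.

**Effect classification.** Within-CDS indels whose length change is not a
codon multiple are frameshifts; SNPs are classified by codon translation
(start-loss at the initiator, nonsense on stop gain, else
missense/synonymous); variants within 2 bp of an intron-facing CDS boundary
are splice disruptions. The dysfunctional set is {frameshift, nonsense,
start_loss, splice_disruption}. In-frame indels and stop-loss changes are
reported as missense: they alter protein but do not belong to the
dysfunctional set that the ranking criterion uses.

**Deletion calling.** The insert model (mean, sd of |template length| over
proper pairs) defines discordance: proper-pair flag unset or |tlen| > mean
+ k·sd with k = 5. Deletion-signature pairs (same contig, convergent
orientation, forward read entirely left of the reverse read) are clustered
by single linkage with gap mean + 3·sd, linking a new pair to a cluster
when its left-read end is within the gap of the cluster's rightmost
left-read end and its right-read start is within the gap of the cluster's
right-start *range* — the range, not a single extremum, because right-read
starts of one event spread over roughly one insert length. Clusters need
`min_support` = 3 pairs. Breakpoints are refined from the
discordant-implied interval (max left-read end + 1, min right-read start −
1) by scanning for the first position where depth drops below
`refine_fraction` (0.1) × the flanking median and stays low for `min_run`
(50) bases; a soft-clip stack (≥ 2 reads clipped ≥ 5 bases at one position)
inside the search window overrides the coverage edge because clip evidence
is base-exact. A cluster over uniformly covered sequence finds no depth
edge and is rejected. Overlapping calls from redundant clusters of one
event are collapsed to the best-supported call. Calling is deterministic.

**Candidate ranking.** A gene is a candidate when absent by saturation or
fully contained in a deletion call (containment, not overlap — straddling
genes are reported separately, never silently promoted). Candidates sort by
(in_deletion desc, absent desc, panel-dysfunctional count asc, gene id
asc). The dysfunctional count is a sort key, not a filter: the criterion
chooses among absent genes without absolutely excluding any.

**Assays.** In-silico PCR uses exact primer matching on both strands
within `max_amplicon` (10 kb); the assay being modelled is a simple
presence/absence band, so no melting-temperature model is included.
Truncation prediction translates an edited CDS from its first base with the
standard code; `protein_length` excludes the stop codon, matching the usual
"N-amino-acid protein" convention, and `frameshifted` compares sequence
length modulo 3 against the unedited CDS (assumed a codon multiple when not
supplied).

## The synthetic-data generator

The generator emits *already-aligned* reads by coordinate lift-over from
the mutant haplotype to the reference — no aligner runs — so breakpoint,
absence and duplicate truth are exact by construction. Fragments are drawn
on the haplotype with insert ~ Normal(mean, sd) truncated at 2× read
length; positions at or beyond the deletion lift right by its length. A
pair whose two mapped segments fall on opposite sides of the junction is
flagged improper with template length inflated by exactly the deletion
size; a read overlapping the junction itself is soft-clipped at the
junction on the side holding the larger share of its bases (its pair then
looks proper when both mapped segments land on one side — which is how an
aligner would report it). With clip emission disabled such fragments are
suppressed entirely, which produces the ~read-length coverage-edge
resolution the refinement tests exercise. Duplicates are verbatim
re-emissions of existing fragments. The deletion is fixed in the bulk by
default (`deletion_frequency` = 1.0, matching a bulk of homozygotes); a
mixing fraction is exposed for power exploration.

Variant planting is VCF-level: allele depths are drawn
Binomial(Poisson-depth, planted fraction) rather than derived from the
simulated reads, mirroring the pipeline's contract that an upstream caller
produced the VCF. Causal sites get alternative fraction 1.0 and never enter
the panel; background sites draw fractions uniform on [0.05, 0.95] and
always segregate in the panel. Deleted genes selected for a "dysfunctional
panel variant" receive a 1-bp frameshift insertion mid-CDS observed only in
the panel (the bulk has no reads over the deletion), plus an intronic
benign variant in every deleted gene so the ranking discriminates on effect
class, not mere variant presence.

**Preset (the package's study conditions).** 200-kb contig, 10 genes, a
10-kb deletion (positions 95,001–105,000) fully containing 2 genes, 500
background SNPs, 1 causal fixed site, 20-cultivar panel, 100-bp reads at
30× with 300 ± 30 bp inserts, 0.1% base error, 5% duplicates, seed 42.
Reduced-scale replicates for multi-seed tests use a 60-kb contig with an
8-kb deletion, same read geometry. These sizes make a full run take seconds
while leaving every per-stage signal (≈ 30 straddling pairs, ≈ 15 clipped
reads per junction, unambiguous fixation at 30×) far above its detection
threshold.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mappability and repeat structure (reads lift
over uniquely; real deletions in repetitive regions blur coverage edges),
GC and library bias, indel sequencing errors and base-quality structure,
per-plant genotype sampling within the bulk (the bulk is modelled as one
haplotype pool), segmental duplications that mimic PAV, and panel
genotyping error beyond missingness. On real data the thresholds (ε, panel
cap, saturation threshold) absorb these effects and may need adjustment;
the defaults here are the declared study conditions, not fitted values.

## Numerical and degenerate-input choices

- Internal arithmetic is 0-based half-open; SAM/VCF/GFF3 stay 1-based and
  BED 0-based at the file boundary, with exactly one conversion-helper pair.
- The last, possibly short, window is reported with its true length.
- Windows without polymorphic sites report an undefined (None) mean
  alternative-allele frequency rather than 0.
- Zero-total-depth sites are excluded from the variant filter, not scored.
- Breakpoint refinement returns the discordant-implied interval with
  insert-sized uncertainty when the flanking median depth is zero, and
  rejects the cluster when coverage shows no edge at all.
- Rank ties break lexicographically on gene id (documented, deterministic).
- Insert-model estimation requires ≥ 100 proper pairs and otherwise raises,
  advising an explicit model.

## Known limitations

Only deletion-signature discordance is implemented (no inversions,
duplications, translocations, no split-read remapping or local assembly);
text SAM only; gene/mRNA/CDS are the only GFF3 features consulted; the
effect classifier handles biallelic substitutions and simple indels, not
complex replacements; in-silico PCR has no mismatch tolerance. The
candidate ranking encodes exactly the published-panel criterion
(dysfunctional-variant count); expression or annotation-quality evidence is
out of scope.
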