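"""The fixed-and-novel small-variant filter.

All plants in the mutant bulk are homozygous for the causal allele, so a
causal SNP/indel must be fixed in the bulk (within-bulk minor allele
frequency ~0) and never observed in fertile control cultivars.  Background
variants segregate in both and are rejected.
"""

from recessivemap.io_formats import VariantSite
from recessivemap.variant_filter import FilterParams, candidate_small_variants

sites = [
    # fixed in the bulk AND absent from the panel: the causal pattern
    VariantSite("chr1", 178_120, "C", "T", 0, 31, 0.0, False),
    # fixed in the bulk but common in the panel: an old cultivar allele
    VariantSite("chr1", 50_000, "A", "G", 1, 99, 0.45, True),
    # segregating in the bulk: cannot be causal for a homozygous bulk
    VariantSite("chr1", 90_000, "G", "A", 48, 52, 0.0, False),
    # too shallow to assert fixation
    VariantSite("chr1", 120_000, "T", "C", 0, 6, 0.0, False),
]

params = FilterParams(epsilon=0.02, min_site_depth=10, panel_max_frequency=0.0)
candidates = candidate_small_variants(sites, params)

print(f"{len(sites)} input sites -> {len(candidates)} candidate(s)")
for c in candidates:
    print(f"  {c.site.contig}:{c.site.pos}  {c.site.ref_allele}>{c.site.alt_allele}  "
          f"bulk_alt_fraction={c.bulk_alt_fraction:.3f}  "
          f"panel_frequency={c.site.panel_alt_frequency}")
print("only the bulk-fixed, panel-absent site survives; an empty result "
      "would point at a structural variant instead")
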