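"""Deletion calling from discordant pairs with breakpoint refinement.

Pairs straddling the deletion map with template length inflated by the
deletion size and lose the proper-pair flag; clustering them brackets the
event and soft-clipped reads stacking at the junctions give the exact
breakpoints.
"""

from recessivemap.coverage_saturation import build_depth, deduplicate
from recessivemap.sv_breakpoints import (
    call_deletions, cluster_discordant, estimate_insert_model, find_discordant_pairs,
)
from recessivemap.synthetic_data import SimulationParams, simulate_bundle

params = SimulationParams(seed=42)
bundle = simulate_bundle(params)
deduped = deduplicate(bundle.alignments)
track = build_depth(deduped, bundle.reference)

model = estimate_insert_model(deduped)
print(f"insert model from proper pairs: {model.mean:.1f} +- {model.sd:.1f} bp "
      f"(discordant beyond {model.max_concordant_tlen:.0f} bp)")

pairs = find_discordant_pairs(deduped, model)
print(f"deletion-signature discordant pairs: {len(pairs)}")
if pairs:
    tlens = [p.observed_tlen for p in pairs]
    print(f"  observed template lengths: {min(tlens):,}-{max(tlens):,} bp "
          f"(~ insert + deletion size)")

calls = call_deletions(deduped, track, model)
for c in calls:
    print(f"call: {c.contig}:{c.left_breakpoint:,}-{c.right_breakpoint:,}  "
          f"size={c.estimated_size:,} bp  support={c.support}  evidence={c.evidence}  "
          f"uncertainty=({c.left_uncertainty},{c.right_uncertainty}) bp")
print(f"truth: {params.deletion_interval}")
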