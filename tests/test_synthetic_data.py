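import io

import numpy as np
import pytest

from recessivemap.coverage_saturation import build_depth, deduplicate
from recessivemap.io_formats import write_sam
from recessivemap.synthetic_data import (
    SimulationParams,
    TruthRecord,
    make_reference,
    plant_deletion,
    plant_variants,
    simulate_bundle,
    simulate_paired_reads,
)

from conftest import small_params


class TestMakeReference:
    def test_deterministic_given_seed(self):
        p = SimulationParams(contig_length=100_000, deletion_interval=(40_001, 50_000), seed=7)
        (c1, g1), (c2, g2) = make_reference(p), make_reference(p)
        assert c1.sequence == c2.sequence
        assert g1 == g2

    def test_no_genes(self):
        p = SimulationParams(
            contig_length=50_000, n_genes=0, deletion_interval=None,
            n_deleted_genes=0, n_panel_dysfunctional_genes=0,
        )
        contig, genes = make_reference(p)
        assert genes == [] and contig.length == 50_000

    def test_base_composition_near_uniform(self):
        p = SimulationParams(contig_length=100_000, deletion_interval=(40_001, 50_000))
        contig, _ = make_reference(p)
        for base in "ACGT":
            assert contig.sequence.count(base) / contig.length == pytest.approx(0.25, abs=0.02)

    def test_genes_non_overlapping_and_deleted_genes_inside(self):
        p = SimulationParams()
        _, genes = make_reference(p)
        ordered = sorted(genes, key=lambda g: g.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end < b.start
        ds, de = p.deletion_interval
        inside = [g.gene_id for g in genes if ds <= g.start and g.end <= de]
        assert len(inside) == p.n_deleted_genes


class TestPlantDeletion:
    def test_length_arithmetic(self):
        seq = "A" * 100_000
        assert len(plant_deletion(seq, (40_001, 50_000))) == 90_000
        assert len(plant_deletion(seq, (1, 1))) == 99_999

    def test_junction_joins_flanks(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        mutant = plant_deletion(seq, (401, 500))
        assert mutant == seq[:400] + seq[500:]

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            plant_deletion("ACGT" * 10, (30, 50))


@pytest.fixture(scope="module")
def planted():
    p = small_params(n_snps=200, n_causal_fixed_sites=2)
    contig, genes = make_reference(p)
    return p, contig, genes, plant_variants(contig, genes, p)


class TestPlantVariants:
    def test_causal_sites_fixed_and_panel_absent(self, planted):
        p, _, _, (bulk, panel, truth) = planted
        panel_pos = {r["pos"] for r in panel}
        for pos in truth.causal_site_positions:
            rec = next(r for r in bulk if r["pos"] == pos)
            assert rec["ad"][0] == 0 and rec["ad"][1] > 0
            assert pos not in panel_pos

    def test_background_sites_segregate_in_panel(self, planted):
        p, _, _, (bulk, panel, truth) = planted
        causal = set(truth.causal_site_positions)
        background = [r for r in bulk if r["pos"] not in causal]
        panel_by_pos = {r["pos"]: r for r in panel}
        for rec in background:
            calls = panel_by_pos[rec["pos"]]["calls"]
            assert rec["alt"] in calls  # panel frequency > 0

    def test_allele_depths_track_planted_fractions(self, planted):
        # binomial sampling: mean realized alt fraction across many sites
        # should match the planted fraction with ~1/sqrt(n*d) error
        p, _, _, (bulk, _, truth) = planted
        causal = set(truth.causal_site_positions)
        diffs = [
            rec["ad"][1] / sum(rec["ad"]) - truth.per_site_bulk_alt_frequency[rec["pos"]]
            for rec in bulk if rec["pos"] not in causal
        ]
        assert abs(float(np.mean(diffs))) < 0.02

    def test_no_sites_inside_deletion(self, planted):
        p, _, _, (bulk, panel_records, truth) = planted
        ds, de = p.deletion_interval
        assert all(not ds <= r["pos"] <= de for r in bulk)

    def test_too_many_snps_rejected(self):
        p = small_params(contig_length=60_000, n_snps=60_000)
        contig, genes = make_reference(p)
        with pytest.raises(ValueError):
            plant_variants(contig, genes, p)

    def test_truth_absent_genes_match_containment(self, planted):
        p, _, genes, (_, _, truth) = planted
        ds, de = p.deletion_interval
        expected = sorted(g.gene_id for g in genes if ds <= g.start and g.end <= de)
        assert truth.absent_gene_ids == expected


class TestSimulatePairedReads:
    def test_same_seed_byte_identical_sam(self):
        p = small_params(contig_length=30_000, deletion_interval=(12_001, 17_000),
                         n_genes=3, n_deleted_genes=1, mean_depth=10)
        outs = []
        for _ in range(2):
            b = simulate_bundle(p)
            buf = io.StringIO()
            write_sam(b.alignments, buf, [b.reference])
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_no_deletion_all_pairs_proper(self):
        p = small_params(deletion_interval=None, n_deleted_genes=0,
                         n_panel_dysfunctional_genes=0, mean_depth=10)
        contig, _ = make_reference(p)
        records, _ = simulate_paired_reads(contig, contig.sequence, p)
        assert all(r.is_proper_pair for r in records)
        assert all(abs(r.tlen) >= 2 * p.read_length for r in records)

    def test_straddling_pairs_tlen_inflated_by_deletion(self, preset_bundle):
        p = preset_bundle.params
        d = p.deletion_interval[1] - p.deletion_interval[0] + 1
        straddlers = [abs(r.tlen) for r in preset_bundle.alignments
                      if not r.is_proper_pair and r.tlen > 0]
        assert len(straddlers) > 10
        expected = p.insert_mean + d
        tol = 3 * p.insert_sd / np.sqrt(len(straddlers)) + p.read_length
        assert np.mean(straddlers) == pytest.approx(expected, abs=tol)

    def test_depth_outside_deletion_near_target(self, preset_bundle, preset_track):
        p = preset_bundle.params
        ds, de = p.deletion_interval
        margin = int(p.insert_mean)
        outside = np.concatenate([
            preset_track.depth[2_000: ds - margin],
            preset_track.depth[de + margin: -2_000],
        ])
        assert float(outside.mean()) == pytest.approx(p.mean_depth, rel=0.15)

    def test_zero_depth_strictly_inside_deletion(self, preset_bundle):
        # includes duplicates and errors: nothing can create coverage there
        track = build_depth(preset_bundle.alignments, preset_bundle.reference)
        ds, de = preset_bundle.params.deletion_interval
        assert int(track.depth[ds - 1: de].max(initial=0)) == 0

    def test_insert_below_read_length_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(insert_mean=50, read_length=100)


class TestTruthRecord:
    def test_json_roundtrip(self, preset_bundle):
        truth = preset_bundle.truth
        again = TruthRecord.from_json(truth.to_json())
        assert again == truth

    def test_no_causal_site_gives_empty_candidates_downstream(self):
        from recessivemap.variant_filter import candidate_small_variants
        from conftest import sites_from_bundle

        p = small_params(n_causal_fixed_sites=0, n_snps=200, site_depth=100)
        b = simulate_bundle(p)
        assert candidate_small_variants(sites_from_bundle(b)) == []
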