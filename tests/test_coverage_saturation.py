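import numpy as np
import pytest

from recessivemap.coverage_saturation import (
    CoverageTrack,
    ScanParams,
    absent_regions,
    build_depth,
    deduplicate,
    gene_saturation,
    window_stats,
)
from recessivemap.io_formats import AlignmentRecord, Contig, GeneModel, VariantSite


def brute_force_depth(records, contig):
    """Independent oracle: per-read, per-base increment loop."""
    depth = [0] * contig.length
    for rec in records:
        if rec.is_unmapped or rec.rname != contig.name:
            continue
        ref = rec.pos - 1
        for n, op in rec.cigar_operations():
            if op in "MDN=X":
                if op in "MD=X":
                    for i in range(ref, ref + n):
                        depth[i] += 1
                ref += n
    return depth


def random_sam_instance(rng, contig_length=500, n_reads=200):
    """Random alignments with mixed CIGARs over a small contig."""
    records = []
    for i in range(int(rng.integers(1, n_reads + 1))):
        parts = []
        if rng.random() < 0.3:
            parts.append(f"{int(rng.integers(1, 10))}S")
        parts.append(f"{int(rng.integers(10, 40))}M")
        if rng.random() < 0.3:
            parts.append(f"{int(rng.integers(1, 5))}I")
            parts.append(f"{int(rng.integers(5, 20))}M")
        if rng.random() < 0.3:
            parts.append(f"{int(rng.integers(1, 5))}D")
            parts.append(f"{int(rng.integers(5, 20))}M")
        cigar = "".join(parts)
        span = AlignmentRecord("t", 0, "c", 1, 60, cigar, "*", 0, 0, "*").reference_span()
        pos = int(rng.integers(1, contig_length - span + 2))
        records.append(AlignmentRecord(f"r{i}", 0, "c", pos, 60, cigar, "*", 0, 0, "*"))
    return records


class TestDeduplicate:
    def test_identical_records_collapse(self):
        rec = AlignmentRecord("a", 99, "c", 10, 60, "10M", "=", 100, 200, "A" * 10)
        dup = AlignmentRecord("a.dup", 99, "c", 10, 60, "10M", "=", 100, 200, "A" * 10)
        assert deduplicate([rec, dup]) == [rec]

    def test_opposite_strands_both_kept(self):
        fwd = AlignmentRecord("a", 99, "c", 10, 60, "10M", "=", 100, 200, "A" * 10)
        rev = AlignmentRecord("b", 83, "c", 10, 60, "10M", "=", 100, -200, "A" * 10)
        assert len(deduplicate([fwd, rev])) == 2

    def test_unmapped_dropped(self):
        rec = AlignmentRecord("u", 4, "*", 0, 0, "*", "*", 0, 0, "*")
        assert deduplicate([rec]) == []

    def test_simulator_duplicates_removed_exactly(self, preset_bundle, preset_dedup):
        assert len(preset_dedup) == preset_bundle.truth.n_unique_records


class TestBuildDepth:
    def test_hand_enumerated_overlap(self):
        contig = Contig("c", 20)
        recs = [
            AlignmentRecord("a", 0, "c", 1, 60, "10M", "*", 0, 0, "*"),
            AlignmentRecord("b", 0, "c", 6, 60, "10M", "*", 0, 0, "*"),
        ]
        track = build_depth(recs, contig)
        assert track.depth.tolist() == [1] * 5 + [2] * 5 + [1] * 5 + [0] * 5

    def test_empty_input_all_zero(self):
        track = build_depth([], Contig("c", 30))
        assert track.depth.sum() == 0 and track.length == 30

    def test_depth_mass_conservation(self):
        rng = np.random.default_rng(5)
        contig = Contig("c", 500)
        records = random_sam_instance(rng)
        track = build_depth(records, contig)
        assert int(track.depth.sum()) == sum(r.reference_span() for r in records)

    def test_read_past_contig_end_names_record(self):
        contig = Contig("c", 10)
        rec = AlignmentRecord("runaway", 0, "c", 8, 60, "10M", "*", 0, 0, "*")
        with pytest.raises(ValueError, match="runaway"):
            build_depth([rec], contig)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        contig = Contig("c", 500)
        records = random_sam_instance(rng)
        track = build_depth(records, contig)
        assert track.depth.tolist() == brute_force_depth(records, contig)


class TestWindowStats:
    def test_cap_applied_before_averaging(self):
        track = CoverageTrack("c", np.full(100, 200))
        (w,) = window_stats(track, [], ScanParams(window_size=100))
        assert w.mean_capped_depth == 150.0
        assert w.saturation == 1.0

    def test_zero_window(self):
        track = CoverageTrack("c", np.zeros(100, dtype=int))
        (w,) = window_stats(track, [], ScanParams(window_size=100))
        assert w.mean_capped_depth == 0.0 and w.saturation == 0.0
        assert w.mean_alt_frequency is None

    def test_partial_coverage_fraction(self):
        depth = np.zeros(20, dtype=int)
        depth[:15] = 1
        (w,) = window_stats(CoverageTrack("c", depth), [], ScanParams(window_size=20))
        assert w.saturation == pytest.approx(0.75)

    def test_site_density_and_alt_frequency(self):
        track = CoverageTrack("c", np.full(100, 10))
        sites = [
            VariantSite("c", 10, "A", "G", 50, 50),
            VariantSite("c", 20, "A", "G", 0, 100),
            VariantSite("c", 150, "A", "G", 100, 0),
        ]
        w = window_stats(track, sites, ScanParams(window_size=100))[0]
        assert w.n_polymorphic_sites == 2
        assert w.mean_alt_frequency == pytest.approx(0.75)

    def test_last_window_reported_short(self):
        track = CoverageTrack("c", np.ones(250, dtype=int))
        wins = window_stats(track, [], ScanParams(window_size=100))
        assert [(w.start, w.end) for w in wins] == [(1, 100), (101, 200), (201, 250)]

    def test_saturation_conservation(self, preset_track):
        wins = window_stats(preset_track)
        total = sum(w.saturation * (w.end - w.start + 1) for w in wins)
        covered = int(np.count_nonzero(preset_track.depth >= 1))
        assert total == pytest.approx(covered)

    def test_adding_read_never_decreases_saturation(self):
        rng = np.random.default_rng(11)
        contig = Contig("c", 500)
        records = random_sam_instance(rng, n_reads=50)
        extra = AlignmentRecord("x", 0, "c", 250, 60, "40M", "*", 0, 0, "*")
        before = window_stats(build_depth(records, contig), [], ScanParams(window_size=100))
        after = window_stats(build_depth(records + [extra], contig), [], ScanParams(window_size=100))
        assert all(a.saturation >= b.saturation for a, b in zip(after, before))


class TestGeneSaturation:
    def test_fully_covered_gene(self):
        track = CoverageTrack("c", np.full(10_000, 30))
        gene = GeneModel("g", "c", 2_000, 4_000, "+", [(2_100, 2_400)])
        rep = gene_saturation(track, gene)
        assert rep.gene_saturation == 1.0 and not rep.absent
        assert rep.flank_saturation == 1.0

    def test_low_saturation_flagged_absent(self):
        depth = np.full(10_000, 30)
        depth[2_000 - 1: 4_000] = 0
        depth[2_010: 2_030] = 5  # 1% of the body covered
        track = CoverageTrack("c", depth)
        gene = GeneModel("g", "c", 2_000, 4_000, "+")
        rep = gene_saturation(track, gene)
        assert rep.gene_saturation == pytest.approx(0.01, abs=0.001)
        assert rep.absent

    def test_preset_absent_genes_match_truth(self, preset_bundle, preset_track):
        reports = {
            g.gene_id: gene_saturation(preset_track, g) for g in preset_bundle.genes
        }
        absent = sorted(gid for gid, r in reports.items() if r.absent)
        assert absent == preset_bundle.truth.absent_gene_ids
        for gid, rep in reports.items():
            if gid not in absent:
                assert rep.gene_saturation > 0.95


class TestAbsentRegions:
    def test_single_zero_run(self):
        depth = np.ones(3_000, dtype=int)
        depth[999:2_000] = 0  # 0-based [999, 2000) == 1-based 1000..2000
        regions = absent_regions(CoverageTrack("c", depth))
        assert regions == [("c", 1_000, 2_000)]

    def test_all_covered(self):
        assert absent_regions(CoverageTrack("c", np.ones(100, dtype=int))) == []

    def test_merge_across_short_covered_gap(self):
        depth = np.ones(1_000, dtype=int)
        depth[100:200] = 0
        depth[210:300] = 0
        merged = absent_regions(CoverageTrack("c", depth), merge_distance=100)
        assert merged == [("c", 101, 300)]
        split = absent_regions(CoverageTrack("c", depth), merge_distance=5)
        assert len(split) == 2
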