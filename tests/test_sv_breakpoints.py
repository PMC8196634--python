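import pytest

from recessivemap.coverage_saturation import build_depth, deduplicate
from recessivemap.io_formats import AlignmentRecord
from recessivemap.sv_breakpoints import (
    DiscordantPair,
    InsertModel,
    call_deletions,
    cluster_discordant,
    estimate_insert_model,
    find_discordant_pairs,
)
from recessivemap.synthetic_data import simulate_bundle

from conftest import small_params


def proper_pair(qname, pos, tlen, contig="c"):
    fwd = AlignmentRecord(qname, 99, contig, pos, 60, "100M", "=", pos + tlen - 100, tlen, "*")
    rev = AlignmentRecord(qname, 147, contig, pos + tlen - 100, 60, "100M", "=", pos, -tlen, "*")
    return [fwd, rev]


def discordant_pair(qname, pos, tlen, contig="c", mate_contig=None):
    mate_pos = pos + tlen - 100
    rnext = mate_contig or "="
    fwd = AlignmentRecord(qname, 97, contig, pos, 60, "100M", rnext, mate_pos, tlen, "*")
    rev = AlignmentRecord(
        qname, 145, mate_contig or contig, mate_pos, 60, "100M",
        "=" if mate_contig is None else contig, pos, -tlen, "*",
    )
    return [fwd, rev]


class TestEstimateInsertModel:
    def test_recovers_simulated_library(self, preset_dedup):
        model = estimate_insert_model(preset_dedup)
        assert model.mean == pytest.approx(300, abs=3)
        assert model.sd == pytest.approx(30, abs=5)

    def test_constant_tlen(self):
        records = [r for i in range(100) for r in proper_pair(f"q{i}", 1 + i, 300)]
        model = estimate_insert_model(records)
        assert (model.mean, model.sd) == (300.0, 0.0)

    def test_discordant_pairs_do_not_enter_estimate(self):
        records = [r for i in range(100) for r in proper_pair(f"q{i}", 1 + i, 300)]
        noisy = records + [r for i in range(50) for r in discordant_pair(f"d{i}", 1 + i, 10_000)]
        model = estimate_insert_model(noisy)
        assert (model.mean, model.sd) == (300.0, 0.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="explicit"):
            estimate_insert_model(proper_pair("q", 1, 300))


class TestFindDiscordantPairs:
    MODEL = InsertModel(mean=300, sd=30, k_sigma=5)

    def test_inflated_tlen_is_discordant(self):
        pairs = find_discordant_pairs(discordant_pair("d", 1000, 10_300), self.MODEL)
        assert len(pairs) == 1
        assert pairs[0].observed_tlen == 10_300
        assert pairs[0].left_read_end == 1_099
        assert pairs[0].right_read_start == 1_000 + 10_300 - 100

    def test_proper_pair_below_threshold_is_concordant(self):
        assert find_discordant_pairs(proper_pair("p", 1000, 449), self.MODEL) == []

    def test_improper_flag_alone_qualifies(self):
        pairs = find_discordant_pairs(discordant_pair("d", 1000, 400), self.MODEL)
        assert len(pairs) == 1

    def test_cross_contig_pairs_excluded(self):
        recs = discordant_pair("x", 1000, 10_000, mate_contig="c2")
        assert find_discordant_pairs(recs, self.MODEL) == []


class TestClusterDiscordant:
    def pairs_at(self, left, right, n, offset=0):
        return [
            DiscordantPair(f"q{offset + i}", "c", left + 7 * i, right + 7 * i, right - left)
            for i in range(n)
        ]

    def test_below_min_support_discarded(self):
        assert cluster_discordant(self.pairs_at(1000, 11_000, 2), max_gap=390) == []

    def test_single_event_single_cluster(self):
        clusters = cluster_discordant(self.pairs_at(1000, 11_000, 50), max_gap=390)
        assert len(clusters) == 1 and clusters[0].support == 50

    def test_two_distant_events_two_clusters(self):
        pairs = self.pairs_at(1000, 11_000, 10) + self.pairs_at(60_000, 75_000, 10, offset=50)
        clusters = cluster_discordant(pairs, max_gap=390)
        assert sorted(c.support for c in clusters) == [10, 10]

    def test_preset_straddlers_form_one_cluster(self, preset_dedup):
        model = estimate_insert_model(preset_dedup)
        pairs = find_discordant_pairs(preset_dedup, model)
        clusters = cluster_discordant(pairs, max_gap=model.mean + 3 * model.sd)
        assert len(clusters) == 1
        assert clusters[0].support == len(pairs)


class TestCallDeletions:
    def test_preset_breakpoints_exact_with_clips(self, preset_bundle, preset_dedup, preset_track):
        (call,) = call_deletions(preset_dedup, preset_track)
        assert (call.left_breakpoint, call.right_breakpoint) == preset_bundle.params.deletion_interval
        assert call.estimated_size == 10_000
        assert call.evidence == "clip"
        assert call.left_uncertainty == 0 and call.right_uncertainty == 0

    def test_supporting_pairs_flank_the_call(self, preset_dedup, preset_track):
        model = estimate_insert_model(preset_dedup)
        (call,) = call_deletions(preset_dedup, preset_track, model)
        pairs = find_discordant_pairs(preset_dedup, model)
        assert all(p.left_read_end < call.left_breakpoint for p in pairs)
        assert all(p.right_read_start > call.right_breakpoint for p in pairs)

    def test_deterministic(self, preset_dedup, preset_track):
        first = call_deletions(preset_dedup, preset_track)
        second = call_deletions(preset_dedup, preset_track)
        assert first == second

    def test_coverage_edge_resolution_without_clips(self):
        p = small_params(emit_junction_clips=False, seed=9)
        b = simulate_bundle(p)
        deduped = deduplicate(b.alignments)
        track = build_depth(deduped, b.reference)
        (call,) = call_deletions(deduped, track)
        ds, de = p.deletion_interval
        assert abs(call.left_breakpoint - ds) <= p.read_length
        assert abs(call.right_breakpoint - de) <= p.read_length
        assert call.evidence == "coverage"

    def test_no_deletion_no_calls(self):
        p = small_params(deletion_interval=None, n_deleted_genes=0,
                         n_panel_dysfunctional_genes=0, seed=3)
        b = simulate_bundle(p)
        deduped = deduplicate(b.alignments)
        track = build_depth(deduped, b.reference)
        assert call_deletions(deduped, track) == []

    def test_spurious_cluster_without_depth_drop_rejected(self, preset_track):
        # fabricate 3 discordant pairs over uniformly covered sequence
        records = [r for i in range(200) for r in proper_pair(f"p{i}", 1 + 40 * i, 300, "chr1")]
        fake = [r for i in range(3) for r in discordant_pair(f"f{i}", 2000 + 5 * i, 4_000, "chr1")]
        deduped = deduplicate(records + fake)
        from recessivemap.coverage_saturation import CoverageTrack
        import numpy as np

        flat = CoverageTrack("chr1", np.full(20_000, 30))
        model = InsertModel(mean=300, sd=30)
        assert call_deletions(deduped, flat, model) == []

    def test_support_grows_with_depth(self):
        supports = {}
        for depth in (15.0, 30.0):
            ss = []
            for seed in range(5):
                b = simulate_bundle(small_params(mean_depth=depth, seed=100 + seed))
                deduped = deduplicate(b.alignments)
                track = build_depth(deduped, b.reference)
                (call,) = call_deletions(deduped, track)
                ss.append(call.support)
            supports[depth] = sorted(ss)[len(ss) // 2]
        assert supports[30.0] >= 1.6 * supports[15.0]
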