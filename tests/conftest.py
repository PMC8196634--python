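import pytest

from recessivemap.coverage_saturation import build_depth, deduplicate
from recessivemap.io_formats import VariantSite
from recessivemap.synthetic_data import (
    SimulationParams,
    SimulatedBundle,
    simulate_bundle,
    write_bundle,
)


def sites_from_records(contig_name, bulk_records, panel_records) -> list[VariantSite]:
    """Join in-memory bulk and panel records into VariantSites (the same
    semantics parse_vcf_sites applies to the written files)."""
    panel = {}
    for rec in panel_records:
        calls = [c for c in rec["calls"] if c != "."]
        n_alt = sum(1 for c in calls if c == rec["alt"])
        panel[(rec["pos"], rec["ref"], rec["alt"])] = (
            n_alt / len(calls) if calls else 0.0
        )
    sites = []
    for rec in bulk_records:
        key = (rec["pos"], rec["ref"], rec["alt"])
        freq = panel.get(key)
        sites.append(
            VariantSite(
                contig=contig_name,
                pos=rec["pos"],
                ref_allele=rec["ref"],
                alt_allele=rec["alt"],
                bulk_ref_depth=rec["ad"][0],
                bulk_alt_depth=rec["ad"][1],
                panel_alt_frequency=freq if freq is not None else 0.0,
                panel_alt_observed=freq is not None,
            )
        )
    return sites


def sites_from_bundle(bundle: SimulatedBundle) -> list[VariantSite]:
    return sites_from_records(
        bundle.reference.name, bundle.bulk_records, bundle.panel_records
    )


def small_params(**overrides) -> SimulationParams:
    """A fast reduced-scale parameter set for multi-seed tests."""
    base = dict(
        contig_length=60_000,
        n_genes=6,
        deletion_interval=(26_001, 34_000),
        n_deleted_genes=2,
        n_panel_dysfunctional_genes=1,
        n_snps=60,
        mean_depth=30.0,
        seed=1,
    )
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture(scope="session")
def preset_bundle() -> SimulatedBundle:
    """The study preset: 200-kb contig, 10-kb deletion over 2 of 10 genes,
    30x, seed 42."""
    return simulate_bundle(SimulationParams())


@pytest.fixture(scope="session")
def preset_dedup(preset_bundle):
    return deduplicate(preset_bundle.alignments)


@pytest.fixture(scope="session")
def preset_track(preset_bundle, preset_dedup):
    return build_depth(preset_dedup, preset_bundle.reference)


@pytest.fixture(scope="session")
def preset_sites(preset_bundle):
    return sites_from_bundle(preset_bundle)


@pytest.fixture(scope="session")
def preset_bundle_dir(preset_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    write_bundle(preset_bundle, outdir)
    return outdir
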