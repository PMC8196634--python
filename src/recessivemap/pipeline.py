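"""End-to-end orchestration: dedup -> depth -> saturation scan -> variant
filter -> deletion calling -> candidate report, with a run manifest.

Outputs are deterministic: identical configuration and inputs yield
byte-identical TSV/BED files.  Every stage's parameters are echoed into
``manifest.json`` together with SHA-256 checksums of the inputs, so a run
can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .candidate_report import rank_candidates, write_report
from .coverage_saturation import (
    ScanParams,
    absent_regions,
    build_depth,
    deduplicate,
    gene_saturation,
    window_stats,
)
from .io_formats import (
    Contig,
    VariantSite,
    read_fasta,
    read_gff3_genes,
    read_panel_table,
    read_sam,
    parse_vcf_sites,
    write_bed,
)
from .sv_breakpoints import InsertModel, SvParams, call_deletions, estimate_insert_model
from .synthetic_data import SimulationParams, simulate_bundle, write_bundle
from .variant_filter import FilterParams, annotate_panel_effects, candidate_small_variants

__all__ = ["PipelineConfig", "run_all", "simulate"]


@dataclass
class PipelineConfig:
    sam: Path
    bulk_vcf: Path
    panel: Path
    gff3: Path
    fasta: Path
    outdir: Path
    scan: ScanParams = field(default_factory=ScanParams)
    filter: FilterParams = field(default_factory=FilterParams)
    sv: SvParams = field(default_factory=SvParams)
    insert_model: InsertModel | None = None

    def __post_init__(self) -> None:
        for name in ("sam", "bulk_vcf", "panel", "gff3", "fasta", "outdir"):
            setattr(self, name, Path(getattr(self, name)))

    def validate(self) -> None:
        missing = [
            str(p) for p in (self.sam, self.bulk_vcf, self.panel, self.gff3, self.fasta)
            if not p.exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _panel_variant_sites(panel_frame: pd.DataFrame) -> list[VariantSite]:
    sites = []
    for (contig, pos, ref, alt), row in panel_frame.iterrows():
        sites.append(
            VariantSite(
                contig=contig, pos=int(pos), ref_allele=ref, alt_allele=alt,
                bulk_ref_depth=0, bulk_alt_depth=0,
                panel_alt_frequency=float(row["alt_frequency"]),
                panel_alt_observed=True,
            )
        )
    return sites


def run_all(config: PipelineConfig, log=None) -> dict:
    """Execute every stage; returns a result dict with the key frames.

    Any stage failure aborts with the stage named; outputs written by
    earlier stages are preserved in ``outdir``.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage = "load_inputs"
    try:
        sequences = read_fasta(config.fasta)
        contigs = {name: Contig(name, len(seq), seq) for name, seq in sequences.items()}
        genes = read_gff3_genes(config.gff3)
        records = read_sam(config.sam)
        panel_frame = read_panel_table(config.panel)
        sites = parse_vcf_sites(config.bulk_vcf, panel_frame)
        log(f"[{stage}] {len(records)} alignments, {len(sites)} sites, "
            f"{len(genes)} genes ({time.perf_counter() - t0:.1f}s)")

        stage = "deduplicate"
        deduped = deduplicate(records)
        log(f"[{stage}] {len(records)} -> {len(deduped)} records")

        stage = "depth"
        tracks = {name: build_depth(deduped, c) for name, c in contigs.items()}

        stage = "saturation_scan"
        window_rows = []
        for name, track in tracks.items():
            for w in window_stats(track, sites, config.scan):
                window_rows.append(dataclasses.asdict(w))
        windows = pd.DataFrame(window_rows)
        windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)

        reports = []
        for g in genes:
            track = tracks.get(g.contig)
            if track is None:
                continue
            reports.append(gene_saturation(track, g, config.scan))
        pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
            outdir / "gene_saturation.tsv", sep="\t", index=False
        )
        regions = [iv for t in tracks.values() for iv in absent_regions(t, config.scan)]
        write_bed([(c, s, e, f"absent_{i + 1}") for i, (c, s, e) in enumerate(regions)],
                  outdir / "absent_regions.bed")
        n_absent = sum(r.absent for r in reports)
        log(f"[{stage}] {n_absent} absent gene(s), {len(regions)} uncovered region(s)")

        stage = "variant_filter"
        candidates_sv = candidate_small_variants(sites, config.filter)
        pd.DataFrame(
            [
                {
                    "contig": c.site.contig, "pos": c.site.pos,
                    "ref": c.site.ref_allele, "alt": c.site.alt_allele,
                    "bulk_alt_fraction": round(c.bulk_alt_fraction, 6),
                    "panel_frequency": c.site.panel_alt_frequency,
                }
                for c in candidates_sv
            ],
            columns=["contig", "pos", "ref", "alt", "bulk_alt_fraction", "panel_frequency"],
        ).to_csv(outdir / "candidate_variants.tsv", sep="\t", index=False)
        log(f"[{stage}] {len(candidates_sv)} fixed-and-novel site(s)")

        stage = "deletion_calling"
        insert_model = config.insert_model or estimate_insert_model(deduped)
        calls = []
        for name, track in tracks.items():
            recs = [r for r in deduped if r.rname == name]
            calls.extend(call_deletions(recs, track, insert_model, config.sv))
        pd.DataFrame(
            [
                {
                    "contig": c.contig, "start": c.left_breakpoint, "end": c.right_breakpoint,
                    "size": c.estimated_size, "support": c.support,
                    "left_uncertainty": c.left_uncertainty,
                    "right_uncertainty": c.right_uncertainty, "evidence": c.evidence,
                }
                for c in calls
            ],
            columns=["contig", "start", "end", "size", "support",
                     "left_uncertainty", "right_uncertainty", "evidence"],
        ).to_csv(outdir / "deletions.tsv", sep="\t", index=False)
        write_bed(
            [(c.contig, c.left_breakpoint, c.right_breakpoint, f"del_{i + 1}", c.support)
             for i, c in enumerate(calls)],
            outdir / "deletions.bed",
        )
        log(f"[{stage}] {len(calls)} deletion call(s)")

        stage = "candidate_report"
        panel_sites = _panel_variant_sites(panel_frame)
        effects = annotate_panel_effects(panel_sites, genes, sequences)
        ranked = rank_candidates(reports, calls, effects, genes)
        write_report(ranked, outdir / "candidates.tsv", genes, outdir / "candidates.bed")
        log(f"[{stage}] {len(ranked)} candidate gene(s)"
            + (f"; top: {ranked[0].gene_id}" if ranked else ""))

        stage = "manifest"
        manifest = {
            "version": __version__,
            "inputs": {
                name: {"path": str(getattr(config, name)),
                       "sha256": _sha256(getattr(config, name))}
                for name in ("sam", "bulk_vcf", "panel", "gff3", "fasta")
            },
            "params": {
                "scan": dataclasses.asdict(config.scan),
                "filter": dataclasses.asdict(config.filter),
                "sv": dataclasses.asdict(config.sv),
                "insert_model": (
                    dataclasses.asdict(config.insert_model) if config.insert_model else
                    {"mean": insert_model.mean, "sd": insert_model.sd,
                     "k_sigma": insert_model.k_sigma, "estimated": True}
                ),
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

        summary = [
            f"alignments: {len(records)} ({len(deduped)} after dedup)",
            f"polymorphic sites: {len(sites)}",
            f"absent genes: {n_absent}",
            f"fixed-and-novel small variants: {len(candidates_sv)}",
            f"deletion calls: " + "; ".join(
                f"{c.contig}:{c.left_breakpoint}-{c.right_breakpoint} "
                f"(size {c.estimated_size}, support {c.support}, {c.evidence})"
                for c in calls
            ) if calls else "deletion calls: none",
            "top candidate: " + (ranked[0].gene_id if ranked else "none"),
        ]
        (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
        log(f"[done] total {time.perf_counter() - t0:.1f}s")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "records": records,
        "deduplicated": deduped,
        "tracks": tracks,
        "windows": windows,
        "gene_reports": reports,
        "candidate_variants": candidates_sv,
        "deletion_calls": calls,
        "candidates": ranked,
        "genes": genes,
    }


def simulate(params: SimulationParams, outdir: str | Path) -> dict[str, Path]:
    """Generate the synthetic fixture bundle into ``outdir``."""
    bundle = simulate_bundle(params)
    return write_bundle(bundle, outdir)


def config_for_bundle(bundle_dir: str | Path, outdir: str | Path, **overrides) -> PipelineConfig:
    """PipelineConfig pointing at a written simulation bundle."""
    d = Path(bundle_dir)
    return PipelineConfig(
        sam=d / "bulk_alignments.sam",
        bulk_vcf=d / "bulk_sites.vcf",
        panel=d / "panel_alleles.tsv",
        gff3=d / "genes.gff3",
        fasta=d / "reference.fa",
        outdir=Path(outdir),
        **overrides,
    )
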