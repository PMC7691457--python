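"""End-to-end orchestration: QC → Fst/iHS → windows → regions →
classification → annotation, with flat-TSV/BED intermediates and a run
manifest so every stage is inspectable and re-runnable standalone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import fst as fst_mod
from . import ihs as ihs_mod
from . import signatures as sig
from . import vcf_qc
from . import windows as win
from .datatypes import HaplotypeBlock, PopulationMap
from .regions import RegionSet

log = logging.getLogger(__name__)


class ConfigError(Exception):
    pass


class DataError(Exception):
    pass


@dataclass
class PipelineConfig:
    """All paths, population roles and thresholds of one run.

    Threshold defaults are the scan's standard settings: 50-kb windows
    stepped 25 kb, <10-SNP windows discarded, top 1% outliers, 200-kb
    flanks, QC depth>=5 / MQ>=20 / spacing>=5 bp / missing<10%, EHH
    cutoff 0.05 with 200-kb gap cap and MAF floor 0.05, 100 iHS
    frequency bins, |ΔAF|>=0.8.
    """

    vcf: str = ""
    popmap: str = ""
    genes: Optional[str] = None
    qtls: Optional[str] = None
    outdir: str = "parasweep_out"
    domestic: List[str] = field(default_factory=lambda: ["DLW", "DU"])
    reference: str = "EWB"
    chrom_lengths: Optional[Dict[str, int]] = None

    window_size: int = 50_000
    window_step: int = 25_000
    min_snps: int = 10
    top_fraction: float = 0.01
    flank: int = 200_000
    min_depth: Optional[float] = 5.0
    min_mq: Optional[float] = 20.0
    min_spacing: Optional[int] = 5
    max_missing: Optional[float] = 0.10
    ehh_cutoff: float = 0.05
    max_gap: int = 200_000
    maf_min: float = 0.05
    ihs_bins: int = 100
    min_bin_count: int = 20
    keep_truncated: bool = False
    min_consistent: int = 2
    delta_af_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if len(self.domestic) != 2:
            raise ConfigError("exactly two domestic populations required")
        if self.reference in self.domestic:
            raise ConfigError("reference population cannot also be domestic")
        for name, lo, hi in (
            ("top_fraction", 0, 1), ("maf_min", 0, 0.5),
            ("ehh_cutoff", 0, 1), ("delta_af_threshold", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigError(f"{name}={v} outside ({lo}, {hi}]")
        if self.window_size <= 0 or self.window_step <= 0:
            raise ConfigError("window size/step must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known - {"sim", "sweeps"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in raw.items() if k in known})

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def track_pairs(self):
        d1, d2 = self.domestic
        return [(d1, self.reference), (d2, self.reference), (d1, d2)]


def _write_track(track: pd.DataFrame, path: Path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_inputs(config: PipelineConfig):
    try:
        haps, sites, popmap = vcf_qc.read_phased_vcf(config.vcf, config.popmap)
    except (OSError, ValueError) as e:
        raise DataError(f"stage qc: {e}") from e
    pops_needed = set(config.domestic) | {config.reference}
    if not pops_needed <= set(popmap.populations):
        raise DataError(
            f"population map lacks populations {sorted(pops_needed - set(popmap.populations))}"
        )
    return haps, sites, popmap


def stage_qc(config: PipelineConfig, haps, sites, outdir: Path):
    thr = vcf_qc.QcThresholds(
        min_depth=config.min_depth,
        min_mq=config.min_mq,
        min_spacing=config.min_spacing,
        max_missing=config.max_missing,
    )
    sites_f, haps_f, report = vcf_qc.apply_site_filters(sites, haps, thr)
    report.write_tsv(outdir / "filter_report.tsv")
    return haps_f, sites_f, report


def _chrom_lengths(config: PipelineConfig, haps) -> Dict[str, int]:
    if config.chrom_lengths:
        return {c: int(l) for c, l in config.chrom_lengths.items()}
    inferred = {c: int(b.positions.max()) for c, b in haps.items() if b.n_sites}
    log.info("chromosome lengths inferred from data: %s", inferred)
    return inferred


def stage_fst(config: PipelineConfig, haps, popmap, windows_df, outdir: Path):
    """Windowed Weir-Cockerham Fst tracks for the three population pairs."""
    tracks = {}
    for pop_a, pop_b in config.track_pairs():
        frames = []
        dumps = []
        for chrom in sorted(haps):
            block = haps[chrom]
            ga = vcf_qc.genotype_dosage(block, popmap.samples(pop_a))
            gb = vcf_qc.genotype_dosage(block, popmap.samples(pop_b))
            comp = fst_mod.wc_site_components(ga, gb, block.positions)
            wsub = windows_df[windows_df["chrom"] == chrom].reset_index(drop=True)
            frames.append(fst_mod.windowed_fst(comp, wsub, config.min_snps))
            dumps.append(comp.to_frame(chrom))
        label = sig.fst_label(pop_a, pop_b)
        tracks[label] = pd.concat(frames, ignore_index=True)
        pd.concat(dumps, ignore_index=True).to_csv(
            outdir / f"fst_sites_{pop_a}_{pop_b}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
    return tracks


def stage_ihs(config: PipelineConfig, haps, popmap, windows_df, outdir: Path):
    """Standardized |iHS| window tracks for the three populations."""
    tracks = {}
    pops = [*config.domestic, config.reference]
    for pop in pops:
        scans = []
        for chrom in sorted(haps):
            block = haps[chrom]
            rows = block.haplotype_rows(popmap.samples(pop))
            scans.append(
                ihs_mod.ihs_scan(
                    block, rows,
                    maf_min=config.maf_min,
                    cutoff=config.ehh_cutoff,
                    max_gap=config.max_gap,
                    keep_truncated=config.keep_truncated,
                )
            )
        scores = ihs_mod.standardize_ihs(
            pd.concat(scans, ignore_index=True), config.ihs_bins, config.min_bin_count
        )
        scores.to_csv(
            outdir / f"ihs_sites_{pop}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        frames = []
        for chrom in sorted(haps):
            wsub = windows_df[windows_df["chrom"] == chrom].reset_index(drop=True)
            frames.append(
                ihs_mod.windowed_abs_ihs(
                    scores[scores["chrom"] == chrom], wsub, config.min_snps
                )
            )
        tracks[sig.ihs_label(pop)] = pd.concat(frames, ignore_index=True)
    return tracks


def stage_regions(
    config: PipelineConfig, tracks: Dict[str, pd.DataFrame], chrom_lengths, outdir: Path
) -> Dict[str, RegionSet]:
    """Flag top-fraction outlier windows per track and build candidate
    regions (flank extension then merge)."""
    bundle = {}
    for label, track in tracks.items():
        flagged = win.flag_top_fraction(track, config.top_fraction)
        _write_track(flagged, outdir / f"windows_{label}.tsv")
        regions = win.build_candidate_regions(flagged, chrom_lengths, config.flank)
        regions.write_bed(outdir / f"regions_{label}.bed", name=label)
        bundle[label] = regions
    return bundle


def stage_classify(config: PipelineConfig, bundle, outdir: Path) -> sig.SignatureResult:
    result = sig.classify_all(bundle, config.domestic, config.reference)
    result.parallel.write_bed(outdir / "PS.bed", name="PS")
    for pop, rs in result.specific.items():
        rs.write_bed(outdir / f"{pop}.sp.bed", name=f"{pop}.sp")
    for pop, rs in result.artificial.items():
        rs.write_bed(outdir / f"artificial_{pop}.bed", name=f"artificial_{pop}")
    result.provenance.to_csv(outdir / "provenance.tsv", sep="\t", index=False)
    return result


def stage_annotate(
    config: PipelineConfig, result: sig.SignatureResult, sites: pd.DataFrame, outdir: Path
):
    """Gene overlap, QTL-consistency filtering and ΔAF scan per category."""
    gene_table = ann.read_gene_table(config.genes) if config.genes else None
    qtl_table = ann.read_qtl_table(config.qtls) if config.qtls else None
    categories = {"PS": result.parallel}
    categories.update({f"{p}.sp": r for p, r in result.specific.items()})
    outputs = {}
    for cat, regions in categories.items():
        if gene_table is not None:
            genes = ann.genes_in_regions(regions, gene_table)
            genes.to_csv(outdir / f"genes_{cat}.tsv", sep="\t", index=False)
            outputs[f"genes_{cat}"] = genes
        if qtl_table is not None:
            retained, per_region, tallies = ann.map_qtls(
                regions, qtl_table, config.min_consistent
            )
            retained.write_bed(outdir / f"qtl_retained_{cat}.bed", name=cat)
            per_region.to_csv(outdir / f"qtl_overlaps_{cat}.tsv", sep="\t", index=False)
            tallies.to_csv(outdir / f"qtl_tallies_{cat}.tsv", sep="\t", index=False)
            outputs[f"qtl_retained_{cat}"] = retained
        scan = ann.delta_af_scan(
            sites, regions, cat, config.domestic, config.reference,
            config.delta_af_threshold,
        )
        scan.to_csv(outdir / f"deltaaf_{cat}.tsv", sep="\t", index=False, float_format="%.10g")
        outputs[f"deltaaf_{cat}"] = scan
    return outputs


def run_pipeline(config: PipelineConfig) -> sig.SignatureResult:
    """Execute the full scan and write all intermediates plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    haps, sites, popmap = load_inputs(config)
    haps, sites, report = stage_qc(config, haps, sites, outdir)
    sites = vcf_qc.pop_allele_freqs(haps, popmap, sites)
    sites.to_csv(outdir / "sites_pass.tsv", sep="\t", index=False, float_format="%.10g")

    chrom_lengths = _chrom_lengths(config, haps)
    windows_df = win.make_windows(chrom_lengths, config.window_size, config.window_step)
    try:
        fst_tracks = stage_fst(config, haps, popmap, windows_df, outdir)
        ihs_tracks = stage_ihs(config, haps, popmap, windows_df, outdir)
        tracks = {**fst_tracks, **ihs_tracks}
        bundle = stage_regions(config, tracks, chrom_lengths, outdir)
        result = stage_classify(config, bundle, outdir)
        stage_annotate(config, result, sites, outdir)
    except (KeyError, ValueError) as e:
        raise DataError(str(e)) from e

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sites_input": report.n_input,
        "n_sites_pass": report.n_output,
        "row_counts": {
            p.name: sum(1 for _ in open(p)) for p in sorted(outdir.glob("*.tsv"))
        },
        "region_counts": {
            p.name: sum(1 for _ in open(p)) for p in sorted(outdir.glob("*.bed"))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
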