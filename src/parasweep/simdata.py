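"""Three-population phased cohort simulator with plantable hard sweeps.

The generator emulates the statistical structure a haplotype-based sweep
scan relies on, not genealogical history: founder haplotypes carry a
neutral-like 1/k frequency spectrum, sample haplotypes are recombinant
mosaics of founders (Li-Stephens-like), and per-population founder
weights perturbed by a Dirichlet concentration create baseline drift
(nonzero Fst) between the two domestic breeds (DLW, DU) and the wild
reference (EWB).  Hard sweeps are planted by copying one fixed sweep
haplotype onto a ``final_freq`` fraction of carriers, with exponentially
distributed arm lengths mimicking recombination escape.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import HaplotypeBlock, PopulationMap
from .vcf_qc import write_phased_vcf

QTL_CLASSES = ["Meat_and_Carcass", "Health", "Exterior", "Production", "Reproduction"]

_TRAITS = {
    "Meat_and_Carcass": ["intramuscular_fat", "loin_muscle_area", "backfat_thickness"],
    "Health": ["immune_response", "coping_behavior"],
    "Exterior": ["coat_color", "leg_conformation"],
    "Production": ["average_daily_gain", "feed_conversion"],
    "Reproduction": ["litter_size", "teat_number"],
}

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Simulation parameters; defaults give a 2x10 Mb, 78-diploid cohort
    (28 DLW / 27 DU / 23 EWB) at ~1 SNP per 500 bp."""

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_diploids_per_pop: Dict[str, int] = field(
        default_factory=lambda: {"DLW": 28, "DU": 27, "EWB": 23}
    )
    snp_density: float = 1 / 500
    n_founders: int = 30
    recomb_per_bp: float = 1e-5
    drift: Dict[str, float] = field(
        default_factory=lambda: {"DLW": 0.15, "DU": 0.15, "EWB": 0.15}
    )
    seed: int = 0

    def __post_init__(self):
        if len(set(self.chrom_lengths)) != len(self.chrom_lengths):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0 < self.snp_density < 1 / 6:
            raise ValueError("snp_density must be in (0, 1/6) to honor 5-bp spacing")
        if not 0 < self.recomb_per_bp < 1:
            raise ValueError("recomb_per_bp must be in (0,1)")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        missing = set(self.n_diploids_per_pop) - set(self.drift)
        if missing:
            raise ValueError(f"drift not specified for populations: {missing}")

    @property
    def populations(self) -> List[str]:
        return list(self.n_diploids_per_pop)


@dataclass
class SweepSpec:
    """One planted hard sweep."""

    chrom: str
    core_pos: int
    selected_pops: Tuple[str, ...]
    final_freq: float = 0.95
    mean_arm_bp: float = 300_000.0

    def __post_init__(self):
        if not self.selected_pops:
            raise ValueError("selected_pops must be non-empty")
        if not 0 < self.final_freq <= 1:
            raise ValueError("final_freq must be in (0, 1]")
        self.selected_pops = tuple(self.selected_pops)

    def category(self, domestic: Sequence[str] = ("DLW", "DU")) -> str:
        """PS when both domestic breeds are selected, else '<pop>.sp'."""
        sel = set(self.selected_pops)
        if set(domestic) <= sel:
            return "PS"
        if len(sel) == 1:
            return f"{next(iter(sel))}.sp"
        raise ValueError(f"cannot categorize selected_pops={self.selected_pops}")


def truth_set(
    sweeps: Sequence[SweepSpec],
    chrom_lengths: Dict[str, int],
    domestic: Sequence[str] = ("DLW", "DU"),
) -> List[Tuple[str, int, int, str]]:
    """Ground-truth intervals (1-based inclusive): core +/- mean arm length."""
    out = []
    for sw in sweeps:
        arm = int(sw.mean_arm_bp)
        out.append(
            (
                sw.chrom,
                max(1, sw.core_pos - arm),
                min(chrom_lengths[sw.chrom], sw.core_pos + arm),
                sw.category(domestic),
            )
        )
    return out


def _draw_positions(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    """Sorted unique positions with min spacing >= 5 bp and ~density SNPs/bp."""
    mean_gap = 1.0 / density
    p = 1.0 / (mean_gap - 5.0)
    n_draw = int(length * density * 1.3) + 100
    gaps = 5 + rng.geometric(p, size=n_draw)
    pos = np.cumsum(gaps)
    return pos[pos <= length].astype(np.int64)


def _founder_matrix(rng: np.random.Generator, n_founders: int, n_sites: int) -> np.ndarray:
    """Founder haplotypes with derived counts k drawn with P(k) ~ 1/k."""
    ks = np.arange(1, n_founders)
    w = (1.0 / ks) / (1.0 / ks).sum()
    k_per_site = rng.choice(ks, size=n_sites, p=w)
    order = np.argsort(rng.random((n_sites, n_founders)), axis=1)
    mask = (np.arange(n_founders)[None, :] < k_per_site[:, None]).astype(np.int8)
    mat = np.zeros((n_sites, n_founders), dtype=np.int8)
    np.put_along_axis(mat, order, mask, axis=1)
    return mat.T  # (n_founders, n_sites)


def simulate_haplotypes(
    config: SimConfig,
) -> Tuple[Dict[str, HaplotypeBlock], pd.DataFrame, PopulationMap]:
    """Simulate the neutral cohort: haplotype blocks per chromosome, a site
    table (QC fields + per-pop AFs) and the population map."""
    rng = np.random.default_rng(config.seed)
    sample_ids = []
    assignments = {}
    for pop, n in config.n_diploids_per_pop.items():
        for i in range(n):
            sid = f"{pop}_{i:03d}"
            sample_ids.append(sid)
            assignments[sid] = pop
    popmap = PopulationMap(assignments, config.populations)
    n_haps = 2 * len(sample_ids)

    # per-population founder weights: lower concentration -> more drift
    weights = {}
    for pop in config.populations:
        d = config.drift[pop]
        if math.isinf(d):
            weights[pop] = np.full(config.n_founders, 1.0 / config.n_founders)
        else:
            weights[pop] = rng.dirichlet(np.full(config.n_founders, d))

    haps: Dict[str, HaplotypeBlock] = {}
    site_frames = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        pos = _draw_positions(rng, length, config.snp_density)
        if len(pos) == 0:
            raise ValueError(
                f"{chrom}: zero sites drawn at density {config.snp_density}; "
                "increase snp_density or chromosome length"
            )
        n_sites = len(pos)
        founders = _founder_matrix(rng, config.n_founders, n_sites)
        p_switch = 1.0 - np.exp(-config.recomb_per_bp * np.diff(pos))

        alleles = np.empty((n_haps, n_sites), dtype=np.int8)
        row = 0
        for sid in sample_ids:
            w = weights[assignments[sid]]
            for _ in range(2):
                seg_id = np.concatenate(
                    [[0], np.cumsum(rng.random(n_sites - 1) < p_switch)]
                )
                founder_per_seg = rng.choice(config.n_founders, size=seg_id[-1] + 1, p=w)
                alleles[row] = founders[founder_per_seg[seg_id], np.arange(n_sites)]
                row += 1
        haps[chrom] = HaplotypeBlock(chrom, pos, alleles, sample_ids)

        ref_alt = _BASES[
            np.argsort(rng.random((n_sites, 4)), axis=1)[:, :2]
        ]  # two distinct bases per site
        anc_is_ref = rng.random(n_sites) < 0.8
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref_alt[:, 0],
                    "alt": ref_alt[:, 1],
                    "ancestral_allele": np.where(anc_is_ref, ref_alt[:, 0], ref_alt[:, 1]),
                    "mean_depth": np.round(np.clip(rng.normal(25, 3, n_sites), 5.5, None), 1),
                    "rms_mapping_quality": np.round(np.clip(rng.normal(55, 4, n_sites), 20.5, None), 1),
                    "missing_ratio": 0.0,
                    "aa_known": True,
                    "functional_class": "",
                    "gene_symbol": "",
                }
            )
        )
    site_table = pd.concat(site_frames, ignore_index=True)
    site_table = _refresh_afs(haps, popmap, site_table)
    return haps, site_table, popmap


def _refresh_afs(haps, popmap, site_table):
    from .vcf_qc import pop_allele_freqs

    return pop_allele_freqs(haps, popmap, site_table)


def plant_sweep(
    haps: Dict[str, HaplotypeBlock],
    site_table: pd.DataFrame,
    spec: SweepSpec,
    seed: int,
    popmap: PopulationMap | None = None,
) -> Tuple[Dict[str, HaplotypeBlock], pd.DataFrame]:
    """Plant one hard sweep; returns updated (haps, site_table).

    In each selected population a ``final_freq`` fraction of haplotypes
    has its segment around the core replaced by one fixed sweep haplotype
    (shared across selected populations — the parallel-selection pattern);
    each carrier's segment extends by independent Exponential(mean_arm_bp)
    lengths per side.  The core's derived allele is forced to 1 on the
    sweep haplotype and 0 on the background, so the selected populations'
    derived core frequency equals final_freq up to rounding.
    """
    rng = np.random.default_rng(seed)
    if spec.chrom not in haps:
        raise ValueError(f"chromosome {spec.chrom!r} not simulated")
    block = haps[spec.chrom]
    hit = np.flatnonzero(block.positions == spec.core_pos)
    if len(hit) == 0:
        nearest = int(block.positions[np.argmin(np.abs(block.positions - spec.core_pos))])
        raise ValueError(
            f"no simulated site at {spec.chrom}:{spec.core_pos}; nearest is {nearest}"
        )
    core = int(hit[0])
    if popmap is None:
        popmap = PopulationMap(
            {s: s.rsplit("_", 1)[0] for s in block.sample_ids}
        )

    alleles = block.alleles.copy()
    # one fixed sweep haplotype: background of a random template, core derived
    template_rows = block.haplotype_rows(popmap.samples(spec.selected_pops[0]))
    template = alleles[rng.choice(template_rows)].copy()
    template[core] = 1

    for pop in spec.selected_pops:
        rows = block.haplotype_rows(popmap.samples(pop))
        n_car = int(round(spec.final_freq * len(rows)))
        carriers = rng.choice(rows, size=n_car, replace=False)
        alleles[rows, core] = 0
        for r in carriers:
            left = rng.exponential(spec.mean_arm_bp)
            right = rng.exponential(spec.mean_arm_bp)
            lo = np.searchsorted(block.positions, spec.core_pos - left, side="left")
            hi = np.searchsorted(block.positions, spec.core_pos + right, side="right")
            alleles[r, lo:hi] = template[lo:hi]

    out = dict(haps)
    out[spec.chrom] = HaplotypeBlock(block.chrom, block.positions, alleles, block.sample_ids)
    site_table = _refresh_afs(out, popmap, site_table)
    return out, site_table


def make_gene_table(
    config: SimConfig,
    rng: np.random.Generator,
    gene_len: int = 20_000,
    gene_every: int = 50_000,
    frac_no_symbol: float = 0.1,
) -> pd.DataFrame:
    """Regularly spaced synthetic genes; a fraction lack a symbol to
    exercise the no-symbol exclusion downstream."""
    rows = []
    g = 0
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        start = 1 + int(rng.integers(0, gene_every // 2))
        while start + gene_len - 1 <= length:
            g += 1
            symbol = "" if rng.random() < frac_no_symbol else f"GENE{g:04d}"
            rows.append((chrom, start, start + gene_len - 1, f"ENSSSCG{g:08d}", symbol))
            start += gene_every
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "gene_symbol"])


def make_qtl_table(
    config: SimConfig,
    sweeps: Sequence[SweepSpec],
    rng: np.random.Generator,
    n_background_per_chrom: int = 30,
) -> pd.DataFrame:
    """Synthetic QTL table: random background QTLs (some >1 Mb, some with
    missing coordinates) plus trait-consistent clusters over each planted
    sweep so the QTL-retention rule is exercisable end to end."""
    rows = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        if length > 1_200_000:
            # one guaranteed over-length QTL per chromosome (dropped by the
            # 1-Mb rule downstream)
            start = int(rng.integers(1, length - 1_100_000))
            cls = QTL_CLASSES[int(rng.integers(len(QTL_CLASSES)))]
            rows.append((chrom, start, start + 1_100_000, _TRAITS[cls][0], cls))
        for _ in range(n_background_per_chrom):
            start = int(rng.integers(1, length))
            qlen = int(rng.lognormal(mean=11.5, sigma=1.2))  # ~100 kb median
            cls = QTL_CLASSES[int(rng.integers(len(QTL_CLASSES)))]
            trait = _TRAITS[cls][int(rng.integers(len(_TRAITS[cls])))]
            rows.append((chrom, start, min(length, start + qlen), trait, cls))
    for sw in sweeps:
        cls = QTL_CLASSES[int(rng.integers(len(QTL_CLASSES)))]
        trait = _TRAITS[cls][int(rng.integers(len(_TRAITS[cls])))]
        for _ in range(3):
            off = int(rng.integers(-100_000, 100_000))
            start = max(1, sw.core_pos + off - 200_000)
            rows.append((sw.chrom, start, start + 400_000, trait, cls))
    # two records with uncertain location, to exercise the drop rule
    rows.append((sorted(config.chrom_lengths)[0], None, None, "unmapped_trait", "Health"))
    rows.append((sorted(config.chrom_lengths)[0], None, None, "unmapped_trait2", "Production"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "trait_term", "qtl_class"])


def annotate_sites(
    site_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    rng: np.random.Generator,
    frac_nonsyn: float = 0.05,
) -> pd.DataFrame:
    """Mark a fraction of in-gene sites nonsynonymous, carrying the gene symbol."""
    out = site_table.copy()
    for gene in gene_table.itertuples():
        mask = (
            (out["chrom"] == gene.chrom)
            & (out["pos"] >= gene.start)
            & (out["pos"] <= gene.end)
        )
        idx = out.index[mask]
        if len(idx) == 0:
            continue
        chosen = idx[rng.random(len(idx)) < frac_nonsyn]
        out.loc[chosen, "functional_class"] = "nonsynonymous"
        out.loc[chosen, "gene_symbol"] = gene.gene_symbol
    return out


def export_bundle(
    haps: Dict[str, HaplotypeBlock],
    site_table: pd.DataFrame,
    config: SimConfig,
    sweeps: Sequence[SweepSpec],
    outdir,
    popmap: PopulationMap | None = None,
) -> Dict[str, Path]:
    """Write the full companion-file bundle.

    Produces: phased VCF (INFO AA/MQ, FORMAT DP), population map TSV,
    gene table TSV, QTL table TSV, truth BED of planted sweeps, and the
    annotated site table TSV.  Deterministic given the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 7])
    if popmap is None:
        sample_ids = next(iter(haps.values())).sample_ids
        popmap = PopulationMap({s: s.rsplit("_", 1)[0] for s in sample_ids})

    genes = make_gene_table(config, rng)
    site_table = annotate_sites(site_table, genes, rng)
    qtls = make_qtl_table(config, sweeps, rng)

    paths = {
        "vcf": outdir / "cohort.vcf",
        "popmap": outdir / "popmap.tsv",
        "genes": outdir / "genes.tsv",
        "qtls": outdir / "qtls.tsv",
        "truth": outdir / "truth.bed",
        "sites": outdir / "sites.tsv",
    }
    write_phased_vcf(haps, site_table, paths["vcf"], contig_lengths=config.chrom_lengths)
    popmap.write_tsv(paths["popmap"])
    genes.to_csv(paths["genes"], sep="\t", index=False)
    qtls.to_csv(paths["qtls"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        for chrom, s, e, cat in truth_set(sweeps, config.chrom_lengths):
            fh.write(f"{chrom}\t{s - 1}\t{e}\t{cat}\n")
    site_table.to_csv(paths["sites"], sep="\t", index=False)
    return paths


def snap_core(haps: Dict[str, HaplotypeBlock], spec: SweepSpec) -> SweepSpec:
    """Return a copy of ``spec`` with core_pos moved to the nearest
    simulated site on its chromosome."""
    block = haps[spec.chrom]
    nearest = int(block.positions[np.argmin(np.abs(block.positions - spec.core_pos))])
    return SweepSpec(
        chrom=spec.chrom,
        core_pos=nearest,
        selected_pops=spec.selected_pops,
        final_freq=spec.final_freq,
        mean_arm_bp=spec.mean_arm_bp,
    )


def simulate_bundle(
    config: SimConfig, sweeps: Sequence[SweepSpec], outdir, snap_cores: bool = True
) -> Dict[str, Path]:
    """Simulate, plant all sweeps, and export the bundle in one call.

    By default sweep cores are snapped to the nearest simulated site.
    """
    haps, sites, popmap = simulate_haplotypes(config)
    planted = []
    for i, sw in enumerate(sweeps):
        if snap_cores:
            sw = snap_core(haps, sw)
        haps, sites = plant_sweep(haps, sites, sw, seed=config.seed * 1000 + i, popmap=popmap)
        planted.append(sw)
    return export_bundle(haps, sites, config, planted, outdir, popmap=popmap)
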