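"""Phased-VCF ingestion and site-level quality control.

Reads a phased multi-population VCF plus a sample->population map into
per-chromosome :class:`HaplotypeBlock` matrices and a site table, applies
the site filters (mean depth >= 5, RMS mapping quality >= 20, adjacent-SNP
spacing >= 5 bp, sample missing ratio < 10%), and computes per-population
derived-allele frequencies.

Ancestral/derived polarity comes from the INFO AA tag when present; when
absent (or not matching REF/ALT) the alternate allele is taken as derived
and the site is flagged (``aa_known`` False) so haplotype-statistic
consumers know polarity is approximate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import HaplotypeBlock, PopulationMap

log = logging.getLogger(__name__)

ACGT = {"A", "C", "G", "T"}


@dataclass
class QcThresholds:
    """Site-filter thresholds; ``None`` disables a filter."""

    min_depth: float | None = 5.0
    min_mq: float | None = 20.0
    min_spacing: int | None = 5
    max_missing: float | None = 0.10


@dataclass
class FilterReport:
    """Removal counts per rule, in application order."""

    n_input: int = 0
    removed: Dict[str, int] = field(default_factory=dict)
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("output", self.n_output))
        return pd.DataFrame(rows, columns=["stage", "n_sites"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_phased_vcf(
    vcf_path, popmap_path
) -> Tuple[Dict[str, HaplotypeBlock], pd.DataFrame, PopulationMap]:
    """Load a phased VCF into haplotype blocks, a site table and a popmap.

    Only biallelic SNP records are retained (others are skipped and
    counted).  Unphased genotypes at retained sites and VCF samples
    missing from the population map are hard errors.
    """
    popmap = PopulationMap.read_tsv(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in popmap.assignments]
    if unmapped:
        raise ValueError(f"VCF samples absent from population map: {unmapped}")

    cols_by_chrom: Dict[str, list] = {}
    site_rows = []
    n_skipped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF not in ACGT
            or v.ALT[0] not in ACGT
        ):
            n_skipped += 1
            continue
        aa = v.INFO.get("AA")
        aa_known = aa in (v.REF, v.ALT[0])
        flip = aa_known and aa == v.ALT[0]
        ancestral = aa if aa_known else v.REF

        col = np.empty(2 * len(samples), dtype=np.int8)
        n_miss = 0
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                col[2 * i] = col[2 * i + 1] = -1
                n_miss += 1
                continue
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}; input must be phased"
                )
            if flip:
                a0, a1 = 1 - a0, 1 - a1
            col[2 * i] = a0
            col[2 * i + 1] = a1

        dp = v.format("DP")
        if dp is not None:
            dpv = dp.astype(float).ravel()
            dpv = dpv[dpv >= 0]
            mean_depth = float(dpv.mean()) if len(dpv) else np.nan
        else:
            mean_depth = np.nan
        mq = v.INFO.get("MQ")
        cols_by_chrom.setdefault(v.CHROM, []).append((v.POS, col))
        site_rows.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                v.ALT[0],
                ancestral,
                mean_depth,
                float(mq) if mq is not None else np.nan,
                n_miss / len(samples),
                aa_known,
            )
        )
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic-SNP records", n_skipped)

    haps: Dict[str, HaplotypeBlock] = {}
    for chrom, entries in cols_by_chrom.items():
        entries.sort(key=lambda e: e[0])
        positions = np.array([p for p, _ in entries], dtype=np.int64)
        alleles = np.column_stack([c for _, c in entries]).astype(np.int8)
        haps[chrom] = HaplotypeBlock(chrom, positions, alleles, samples)

    site_table = pd.DataFrame(
        site_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "ancestral_allele",
            "mean_depth", "rms_mapping_quality", "missing_ratio", "aa_known",
        ],
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    site_table["functional_class"] = ""
    site_table["gene_symbol"] = ""
    return haps, site_table, popmap


def apply_site_filters(
    site_table: pd.DataFrame,
    haps: Dict[str, HaplotypeBlock],
    thresholds: QcThresholds | None = None,
) -> Tuple[pd.DataFrame, Dict[str, HaplotypeBlock], FilterReport]:
    """Apply the site filters in order depth -> MQ -> missing -> spacing.

    A filter whose source column is entirely null is disabled with a
    warning (a joint VCF without DP cannot be depth-filtered).  The
    spacing rule runs last, on survivors, and removes BOTH members of any
    adjacent pair closer than the threshold — symmetric and idempotent.
    """
    t = thresholds or QcThresholds()
    report = FilterReport(n_input=len(site_table))
    keep = np.ones(len(site_table), dtype=bool)

    def enabled(threshold, col):
        if threshold is None:
            return False
        if site_table[col].isna().all():
            log.warning("column %s entirely null; filter disabled", col)
            return False
        return True

    if enabled(t.min_depth, "mean_depth"):
        bad = keep & (site_table["mean_depth"] < t.min_depth).fillna(False).to_numpy()
        report.removed["depth"] = int(bad.sum())
        keep &= ~bad
    else:
        report.removed["depth"] = 0
    if enabled(t.min_mq, "rms_mapping_quality"):
        bad = keep & (site_table["rms_mapping_quality"] < t.min_mq).fillna(False).to_numpy()
        report.removed["mq"] = int(bad.sum())
        keep &= ~bad
    else:
        report.removed["mq"] = 0
    if t.max_missing is not None:
        bad = keep & (site_table["missing_ratio"] >= t.max_missing).to_numpy()
        report.removed["missing"] = int(bad.sum())
        keep &= ~bad
    else:
        report.removed["missing"] = 0

    if t.min_spacing is not None:
        n_bad = 0
        for chrom in site_table["chrom"].unique():
            idx = np.flatnonzero((site_table["chrom"] == chrom).to_numpy() & keep)
            pos = site_table["pos"].to_numpy()[idx]
            gaps = np.diff(pos)
            close = gaps < t.min_spacing
            bad = np.zeros(len(idx), dtype=bool)
            bad[:-1] |= close
            bad[1:] |= close
            n_bad += int(bad.sum())
            keep[idx[bad]] = False
        report.removed["spacing"] = n_bad
    else:
        report.removed["spacing"] = 0

    report.n_output = int(keep.sum())
    if report.n_output == 0:
        log.warning("all sites removed by QC filters")

    out_sites = site_table[keep].reset_index(drop=True)
    out_haps: Dict[str, HaplotypeBlock] = {}
    for chrom, block in haps.items():
        cmask = keep[(site_table["chrom"] == chrom).to_numpy()]
        out_haps[chrom] = block.take_sites(cmask)
    return out_sites, out_haps, report


def pop_allele_freqs(
    haps: Dict[str, HaplotypeBlock], popmap: PopulationMap, site_table: pd.DataFrame
) -> pd.DataFrame:
    """Fill per-population derived-allele frequency columns (``af_<pop>``).

    AF = derived count / non-missing haplotype count per population; a
    population entirely missing at a site gets a null AF there.
    """
    out = site_table.copy()
    for pop in popmap.populations:
        vals = np.full(len(out), np.nan)
        for chrom, block in haps.items():
            rows = block.haplotype_rows(popmap.samples(pop))
            sub = block.alleles[rows]
            present = sub >= 0
            n_obs = present.sum(axis=0)
            n_der = np.logical_and(present, sub == 1).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                af = np.where(n_obs > 0, n_der / n_obs, np.nan)
            mask = (out["chrom"] == chrom).to_numpy()
            vals[mask] = af
        out[f"af_{pop}"] = vals
    return out


def genotype_dosage(block: HaplotypeBlock, samples) -> np.ndarray:
    """Diploid derived-allele dosage matrix (n_samples, n_sites); -1 missing."""
    rows = block.haplotype_rows(list(samples))
    h = block.alleles[rows]
    a, b = h[0::2].astype(np.int16), h[1::2].astype(np.int16)
    dos = a + b
    dos[(a < 0) | (b < 0)] = -1
    return dos


_GT_CACHE = {(-1, -1): ".|."}


def write_phased_vcf(
    haps: Dict[str, HaplotypeBlock],
    site_table: pd.DataFrame,
    path,
    contig_lengths: Dict[str, int] | None = None,
) -> None:
    """Write haplotype blocks + site table back out as a phased VCF 4.2.

    Emits INFO AA (always), INFO MQ and FORMAT DP when the corresponding
    site-table columns are non-null.  Derived coding is mapped back to
    REF/ALT via the ancestral allele.
    """
    sample_ids = next(iter(haps.values())).sample_ids
    sites = site_table.set_index(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in sorted(haps):
            length = (contig_lengths or {}).get(chrom, int(haps[chrom].positions.max()) if haps[chrom].n_sites else 0)
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for chrom in sorted(haps):
            block = haps[chrom]
            for j, pos in enumerate(block.positions):
                rec = sites.loc[(chrom, int(pos))]
                ref, alt, aa = rec["ref"], rec["alt"], rec["ancestral_allele"]
                flip = aa == alt  # derived is REF when the ALT is ancestral
                info = f"AA={aa}"
                mq = rec.get("rms_mapping_quality")
                if pd.notna(mq):
                    info += f";MQ={mq:g}"
                dp = rec.get("mean_depth")
                has_dp = pd.notna(dp)
                fmt = "GT:DP" if has_dp else "GT"
                dp_str = f":{int(round(dp))}" if has_dp else ""
                col = block.alleles[:, j]
                gts = []
                for i in range(len(sample_ids)):
                    a0, a1 = int(col[2 * i]), int(col[2 * i + 1])
                    key = (a0, a1)
                    gt = _GT_CACHE.get(key)
                    if gt is None:
                        gt = f"{a0}|{a1}"
                        _GT_CACHE[key] = gt
                    if a0 >= 0 and flip:
                        gt = f"{1 - a0}|{1 - a1}"
                    gts.append(gt + dp_str if a0 >= 0 or not has_dp else gt + ":.")
                fh.write(
                    f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(gts) + "\n"
                )
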