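"""Annotation of classified regions: gene overlap, QTL-consistency
filtering, and the ΔAF candidate-variant scan.

ΔAF contrasts per mode (domestic breeds D1, D2; wild reference R):

* PS:     (AF_D1 + AF_D2)/2 − AF_R
* D1.sp:  AF_D1 − (AF_D2 + AF_R)/2
* D2.sp:  AF_D2 − (AF_D1 + AF_R)/2

Candidates are nonsynonymous variants with a gene symbol inside the
mode's regions; those with |ΔAF| >= 0.8 pass.
"""

from __future__ import annotations

import logging
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .regions import RegionSet

log = logging.getLogger(__name__)

QTL_CLASSES = ["Meat_and_Carcass", "Health", "Exterior", "Production", "Reproduction"]
MAX_QTL_LENGTH = 1_000_000
MIN_CONSISTENT = 2
DELTA_AF_THRESHOLD = 0.8


def read_gene_table(path) -> pd.DataFrame:
    """Read a `chrom start end gene_id gene_symbol` TSV (1-based inclusive);
    malformed rows are skipped with a warning."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            fh.seek(0)
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                log.warning("gene table line %d malformed, skipped", ln)
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                log.warning("gene table line %d has non-integer coordinates, skipped", ln)
                continue
            symbol = parts[4] if len(parts) > 4 else ""
            rows.append((parts[0], start, end, parts[3], symbol))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "gene_symbol"])


def read_qtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, keep_default_na=True, na_values=[""]
    )
    need = {"chrom", "start", "end", "trait_term", "qtl_class"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns: {sorted(missing)}")
    return df


def genes_in_regions(regions: RegionSet, gene_table: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping each region by >= 1 bp (1-based inclusive),
    deduplicated per region."""
    rows = []
    for chrom, rs, re_ in regions:
        sub = gene_table[
            (gene_table["chrom"] == chrom)
            & (gene_table["start"] <= re_)
            & (gene_table["end"] >= rs)
        ].drop_duplicates(subset=["gene_id"])
        for g in sub.itertuples():
            rows.append((chrom, rs, re_, g.gene_id, g.gene_symbol))
    return pd.DataFrame(
        rows, columns=["region_chrom", "region_start", "region_end", "gene_id", "gene_symbol"]
    )


def map_qtls(
    regions: RegionSet,
    qtl_table: pd.DataFrame,
    min_consistent: int = MIN_CONSISTENT,
    max_length: int = MAX_QTL_LENGTH,
) -> Tuple[RegionSet, pd.DataFrame, pd.DataFrame]:
    """QTL-consistency filter over regions.

    QTLs with missing coordinates or longer than ``max_length`` bp are
    dropped first.  A region is retained iff some trait term occurs at
    least ``min_consistent`` times among its overlapping QTLs.  Returns
    (retained regions, per-region QTL table, class tallies).
    """
    q = qtl_table.copy()
    q = q[q["start"].notna() & q["end"].notna()]
    q = q[(q["end"] - q["start"] + 1) <= max_length]
    q["start"] = q["start"].astype(int)
    q["end"] = q["end"].astype(int)
    unknown = ~q["qtl_class"].isin(QTL_CLASSES)
    if unknown.any():
        log.warning("%d QTLs with unknown class kept as 'Other'", int(unknown.sum()))
        q.loc[unknown, "qtl_class"] = "Other"

    retained = []
    overlap_rows = []
    for chrom, rs, re_ in regions:
        hits = q[(q["chrom"] == chrom) & (q["start"] <= re_) & (q["end"] >= rs)]
        counts = hits["trait_term"].value_counts()
        keep = bool((counts >= min_consistent).any())
        if keep:
            retained.append((chrom, rs, re_))
            for h in hits.itertuples():
                overlap_rows.append(
                    (chrom, rs, re_, h.chrom, h.start, h.end, h.trait_term, h.qtl_class)
                )
    per_region = pd.DataFrame(
        overlap_rows,
        columns=[
            "region_chrom", "region_start", "region_end",
            "qtl_chrom", "qtl_start", "qtl_end", "trait_term", "qtl_class",
        ],
    )
    tallies = (
        per_region["qtl_class"].value_counts().rename_axis("qtl_class").reset_index(name="n_qtls")
        if len(per_region)
        else pd.DataFrame(columns=["qtl_class", "n_qtls"])
    )
    return RegionSet.from_records(retained), per_region, tallies


def delta_af(
    site_table: pd.DataFrame,
    mode: str,
    domestic: Sequence[str] = ("DLW", "DU"),
    reference: str = "EWB",
) -> pd.Series:
    """Signed ΔAF per site for one classification mode."""
    d1, d2 = domestic
    a1, a2, ar = (site_table[f"af_{p}"] for p in (d1, d2, reference))
    if mode == "PS":
        return (a1 + a2) / 2 - ar
    if mode == f"{d1}.sp":
        return a1 - (a2 + ar) / 2
    if mode == f"{d2}.sp":
        return a2 - (a1 + ar) / 2
    raise ValueError(f"unknown ΔAF mode {mode!r}")


def delta_af_scan(
    site_table: pd.DataFrame,
    regions: RegionSet,
    mode: str,
    domestic: Sequence[str] = ("DLW", "DU"),
    reference: str = "EWB",
    threshold: float = DELTA_AF_THRESHOLD,
) -> pd.DataFrame:
    """ΔAF over candidate variants of one mode's regions.

    Candidates are nonsynonymous sites with a non-empty gene symbol lying
    inside the regions; variants with any required AF missing are skipped
    (logged).  All candidates are reported with a ``passes`` flag
    (|ΔAF| >= threshold); ΔAF keeps its sign.
    """
    cand = site_table[
        (site_table["functional_class"] == "nonsynonymous")
        & (site_table["gene_symbol"].fillna("") != "")
    ].copy()
    if len(cand):
        in_region = cand.apply(
            lambda r: regions.contains(r["chrom"], int(r["pos"])), axis=1
        )
        cand = cand[in_region.to_numpy()]
    af_cols = [f"af_{p}" for p in (*domestic, reference)]
    has_af = cand[af_cols].notna().all(axis=1)
    if (~has_af).any():
        log.info("%d candidate variants skipped for missing AFs", int((~has_af).sum()))
    cand = cand[has_af]
    d = delta_af(cand, mode, domestic, reference) if len(cand) else pd.Series(dtype=float)
    out = pd.DataFrame(
        {
            "chrom": cand["chrom"],
            "pos": cand["pos"],
            "gene_symbol": cand["gene_symbol"],
            "mode": mode,
            "delta_af": np.round(d, 10),
            "passes": np.abs(d) >= threshold,
        }
    ).reset_index(drop=True)
    out["sift_score"] = np.nan  # reserved for externally joined predictions
    return out
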