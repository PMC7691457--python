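"""Sliding windows, empirical top-fraction outliers, and candidate regions.

The scan uses 50-kb windows stepped every 25 kb, discards windows with
fewer than 10 SNPs, ranks valid windows genome-wide per track, flags the
top 1% as outliers, extends each outlier window by 200 kb per side, and
merges the result into a normalized RegionSet.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
import pandas as pd

from .regions import RegionSet

WINDOW_SIZE = 50_000
WINDOW_STEP = 25_000
MIN_SNPS = 10
TOP_FRACTION = 0.01
FLANK = 200_000

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "score", "valid", "empirical_p", "outlier"]


def make_windows(
    chrom_lengths: Dict[str, int], size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> pd.DataFrame:
    """Sliding windows anchored at position 1 per chromosome.

    Starts run 1, 1+step, 1+2*step, ... while start <= chromosome length;
    the terminal window is truncated at the chromosome end.  Coordinates
    are 1-based inclusive.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        start = 1
        while start <= length:
            rows.append((chrom, start, min(start + size - 1, length)))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_snps(windows: pd.DataFrame, positions_by_chrom: Dict[str, np.ndarray]) -> pd.DataFrame:
    """Populate ``n_snps`` and the <min-SNP ``valid`` flag from site positions."""
    out = windows.copy()
    counts = np.zeros(len(out), dtype=int)
    for chrom, grp in out.groupby("chrom", sort=False):
        pos = np.asarray(positions_by_chrom.get(chrom, ()))
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="right")
        counts[grp.index] = hi - lo
    out["n_snps"] = counts
    out["valid"] = out["n_snps"] >= MIN_SNPS
    return out


def flag_top_fraction(track: pd.DataFrame, fraction: float = TOP_FRACTION) -> pd.DataFrame:
    """Empirical p-values by genome-wide ranking; flag the top fraction.

    Only valid windows are ranked.  empirical_p = rank/N with rank 1 the
    highest score; a window is an outlier iff rank <= ceil(fraction * N).
    Ties break by (score desc, chrom, start) so the outlier count is
    exactly ceil(fraction * N).
    """
    out = track.copy()
    out["empirical_p"] = np.nan
    out["outlier"] = False
    valid = out[out["valid"]]
    n = len(valid)
    if n == 0:
        raise ValueError("no valid windows to rank")
    order = valid.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    ranks = np.arange(1, n + 1)
    out.loc[order.index, "empirical_p"] = ranks / n
    k = math.ceil(fraction * n)
    out.loc[order.index[:k], "outlier"] = True
    return out


def build_candidate_regions(
    track: pd.DataFrame, chrom_lengths: Dict[str, int], flank: int = FLANK
) -> RegionSet:
    """Extend each outlier window by ``flank`` per side, clip to the
    chromosome, then merge overlapping/adjacent intervals."""
    recs = []
    for row in track[track.get("outlier", False) == True].itertuples():  # noqa: E712
        length = int(chrom_lengths[row.chrom])
        recs.append((row.chrom, max(1, row.start - flank), min(length, row.end + flank)))
    return RegionSet.from_records(recs)
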