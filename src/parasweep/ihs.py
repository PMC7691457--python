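"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

EHH at distance d from a core site is the probability that two randomly
drawn carrier haplotypes (same core allele) are identical over the whole
core-to-d stretch.  iHH is the trapezoidal integral of EHH against
physical distance, summed over both directions; the raw score is
ln(iHH_ancestral / iHH_derived), standardized within derived-allele
frequency bins so that extreme values mark unusually long haplotypes for
their frequency class.  Defaults (EHH cutoff 0.05, 200-kb gap cap, MAF
floor 0.05, 100 frequency bins) follow selscan.

The per-site walk is numba-compiled: a genome scan evaluates the walk
four times (two alleles x two directions) at every qualifying site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .datatypes import HaplotypeBlock

EHH_CUTOFF = 0.05
MAX_GAP = 200_000
MAF_MIN = 0.05
N_BINS = 100
MIN_BIN_COUNT = 20

# walk termination statuses
COMPLETE = 0        # EHH dropped below cutoff
TRUNC_GAP = 1       # inter-site gap exceeded max_gap
TRUNC_EDGE = 2      # ran off the chromosome end


@njit(cache=True)
def _ehh_walk(alleles, positions, carriers, core, direction, cutoff, max_gap):
    """Walk outward from ``core`` partitioning carriers by their
    core-to-site allele string; returns (distances, ehh values, status)."""
    n = carriers.shape[0]
    n_sites = positions.shape[0]
    dists = np.empty(n_sites + 1, np.float64)
    ehhs = np.empty(n_sites + 1, np.float64)
    dists[0] = 0.0
    ehhs[0] = 1.0
    cnt = 1
    labels = np.zeros(n, np.int64)
    keys = np.empty(n, np.int64)
    denom = n * (n - 1) / 2.0
    j = core
    status = TRUNC_EDGE
    while True:
        jn = j + direction
        if jn < 0 or jn >= n_sites:
            status = TRUNC_EDGE
            break
        gap = positions[jn] - positions[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            status = TRUNC_GAP
            break
        # refine the partition with the next site's alleles; missing (-1)
        # is treated as a distinct allele, breaking homozygosity
        for i in range(n):
            keys[i] = labels[i] * 4 + (alleles[carriers[i], jn] + 2)
        order = np.argsort(keys)
        pairs = 0.0
        lab = 0
        run = 1
        labels[order[0]] = 0
        for t in range(1, n):
            if keys[order[t]] == keys[order[t - 1]]:
                run += 1
            else:
                pairs += run * (run - 1) / 2.0
                lab += 1
                run = 1
            labels[order[t]] = lab
        pairs += run * (run - 1) / 2.0
        e = pairs / denom
        d = positions[jn] - positions[core]
        if d < 0:
            d = -d
        dists[cnt] = d
        ehhs[cnt] = e
        cnt += 1
        j = jn
        if e < cutoff:
            status = COMPLETE
            break
    return dists[:cnt], ehhs[:cnt], status


@dataclass
class EHHCurve:
    """EHH decay in both directions from a core site for one allele class."""

    core_index: int
    allele: int  # 0 = ancestral, 1 = derived
    left: np.ndarray   # (k, 2): distance from core (bp), ehh
    right: np.ndarray
    left_status: int
    right_status: int

    @property
    def truncated(self) -> bool:
        return self.left_status != COMPLETE or self.right_status != COMPLETE

    def ihh(self) -> float:
        """Trapezoidal integral of EHH vs distance, left + right."""
        total = 0.0
        for side in (self.left, self.right):
            if len(side) > 1:
                total += float(np.trapezoid(side[:, 1], side[:, 0]))
        return total


def ehh_curve(
    alleles: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    allele: int,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
) -> EHHCurve:
    """EHH curve (both directions) for carriers of ``allele`` at the core.

    ``alleles`` is the population's haplotype submatrix (n_haps, n_sites).
    Raises if fewer than 2 carriers exist.
    """
    alleles = np.ascontiguousarray(alleles, dtype=np.int8)
    positions = np.ascontiguousarray(positions, dtype=np.int64)
    carriers = np.flatnonzero(alleles[:, core_index] == allele).astype(np.int64)
    if len(carriers) < 2:
        raise ValueError(
            f"allele {allele} at core index {core_index} has "
            f"{len(carriers)} carrier(s); EHH undefined"
        )
    ld, le, ls = _ehh_walk(alleles, positions, carriers, core_index, -1, cutoff, max_gap)
    rd, re_, rs = _ehh_walk(alleles, positions, carriers, core_index, 1, cutoff, max_gap)
    return EHHCurve(
        core_index=core_index,
        allele=allele,
        left=np.column_stack([ld, le]),
        right=np.column_stack([rd, re_]),
        left_status=ls,
        right_status=rs,
    )


def site_ihs(
    alleles: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
) -> dict:
    """iHH for both allele classes and the raw score at one core site.

    Returns a dict with ``ihh_a``, ``ihh_d``, ``raw_ihs`` (NaN when either
    integral is zero or a class has <2 carriers) and ``truncated``.
    """
    try:
        curve_a = ehh_curve(alleles, positions, core_index, 0, cutoff, max_gap)
        curve_d = ehh_curve(alleles, positions, core_index, 1, cutoff, max_gap)
    except ValueError:
        return {"ihh_a": np.nan, "ihh_d": np.nan, "raw_ihs": np.nan, "truncated": False}
    ihh_a, ihh_d = curve_a.ihh(), curve_d.ihh()
    raw = np.log(ihh_a / ihh_d) if ihh_a > 0 and ihh_d > 0 else np.nan
    return {
        "ihh_a": ihh_a,
        "ihh_d": ihh_d,
        "raw_ihs": raw,
        "truncated": curve_a.truncated or curve_d.truncated,
    }


def ihs_scan(
    block: HaplotypeBlock,
    hap_rows: np.ndarray,
    maf_min: float = MAF_MIN,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
    keep_truncated: bool = False,
) -> pd.DataFrame:
    """Raw iHS at every qualifying site of one chromosome for one population.

    Sites outside [maf_min, 1 - maf_min] derived frequency are skipped;
    sites whose EHH walk hit a gap or the chromosome edge before the
    cutoff are dropped unless ``keep_truncated``.
    """
    sub = np.ascontiguousarray(block.alleles[hap_rows], dtype=np.int8)
    positions = np.ascontiguousarray(block.positions, dtype=np.int64)
    present = sub >= 0
    n_obs = present.sum(axis=0)
    n_der = np.logical_and(present, sub == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, n_der / n_obs, np.nan)

    rows = []
    for j in range(block.n_sites):
        f = freq[j]
        if not (maf_min <= f <= 1 - maf_min):
            continue
        res = site_ihs(sub, positions, j, cutoff, max_gap)
        if np.isnan(res["ihh_a"]) and np.isnan(res["ihh_d"]):
            continue  # a class had <2 carriers
        if res["truncated"] and not keep_truncated:
            continue
        rows.append(
            (block.chrom, int(positions[j]), f, res["ihh_a"], res["ihh_d"],
             res["raw_ihs"], res["truncated"])
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "derived_freq", "ihh_a", "ihh_d", "raw_ihs", "truncated"],
    )


def _merge_sparse_bins(bins: list, min_count: int) -> list:
    """Merge frequency bins with fewer than ``min_count`` sites into their
    nearest (smaller-count, tie -> left) neighbor until all meet the floor."""
    groups = [list(g) for g in bins]  # each group: list of (bin_id, count)
    def gcount(g):
        return sum(c for _, c in g)
    while len(groups) > 1:
        idx = next((i for i, g in enumerate(groups) if gcount(g) < min_count), None)
        if idx is None:
            break
        if idx == 0:
            nb = 1
        elif idx == len(groups) - 1:
            nb = idx - 1
        else:
            nb = idx - 1 if gcount(groups[idx - 1]) <= gcount(groups[idx + 1]) else idx + 1
        lo, hi = sorted((idx, nb))
        groups[lo] = groups[lo] + groups[hi]
        del groups[hi]
    return groups


def standardize_ihs(
    scores: pd.DataFrame, n_bins: int = N_BINS, min_bin_count: int = MIN_BIN_COUNT
) -> pd.DataFrame:
    """Standardize raw iHS within equal-width derived-frequency bins.

    Within each bin (after merging bins below ``min_bin_count`` with their
    nearest neighbor): std = (raw - bin mean) / bin sd, with the population
    (ddof=0) standard deviation.  A merged bin with zero sd yields null
    standardized scores.
    """
    out = scores.copy()
    out["std_ihs"] = np.nan
    ok = out["raw_ihs"].notna()
    if not ok.any():
        return out
    freq = out.loc[ok, "derived_freq"].to_numpy()
    bin_id = np.minimum((freq * n_bins).astype(int), n_bins - 1)
    occupied, counts = np.unique(bin_id, return_counts=True)
    groups = _merge_sparse_bins([[(b, c)] for b, c in zip(occupied, counts)], min_bin_count)
    group_of_bin = {b: gi for gi, g in enumerate(groups) for b, _ in g}
    gid = np.array([group_of_bin[b] for b in bin_id])
    raw = out.loc[ok, "raw_ihs"].to_numpy()
    std = np.full_like(raw, np.nan)
    for g in np.unique(gid):
        m = gid == g
        mu = raw[m].mean()
        sd = raw[m].std(ddof=0)
        if sd > 0:
            std[m] = (raw[m] - mu) / sd
    out.loc[ok, "std_ihs"] = std
    return out


def windowed_abs_ihs(
    scores: pd.DataFrame, windows: pd.DataFrame, min_snps: int = 10
) -> pd.DataFrame:
    """Mean |standardized iHS| per window; validity counts only sites with
    a defined standardized score."""
    scored = scores[scores["std_ihs"].notna()].sort_values("pos")
    pos = scored["pos"].to_numpy()
    absv = np.abs(scored["std_ihs"].to_numpy())
    cs = np.concatenate([[0.0], np.cumsum(absv)])
    lo = np.searchsorted(pos, windows["start"].to_numpy(), side="left")
    hi = np.searchsorted(pos, windows["end"].to_numpy(), side="right")
    out = windows.copy()
    out["n_snps"] = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out["score"] = np.where(hi > lo, (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1), np.nan)
    out["valid"] = out["n_snps"] >= min_snps
    return out
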