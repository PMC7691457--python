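"""Weir & Cockerham (1984) per-site variance components and windowed Fst.

For a biallelic site and two populations the estimator decomposes allele
variance into among-population (a), among-individual-within-population (b)
and within-individual (c) components.  The per-site ratio theta = a/(a+b+c)
is reported for inspection; windows use the ratio-of-sums convention
sum(a)/sum(a+b+c), the "weighted" Fst of VCFtools.

Genotypes are derived-allele dosages (0, 1, 2) with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

R_POPS = 2  # two-population comparison throughout


@dataclass
class FstSiteComponents:
    """Per-site a, b, c arrays plus theta; NaN components mark skipped sites."""

    positions: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom != 0, self.a / denom, np.nan)
        return t

    def to_frame(self, chrom: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": self.positions,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "theta": self.theta,
            }
        )


def _pop_summaries(geno: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site sample size, derived-allele frequency and heterozygote
    frequency for one population's dosage matrix (n_samples, n_sites)."""
    present = geno >= 0
    n = present.sum(axis=0).astype(float)
    dosage = np.where(present, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dosage / (2 * n), np.nan)
        h = np.where(n > 0, np.logical_and(present, geno == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def wc_site_components(
    geno_a: np.ndarray, geno_b: np.ndarray, positions: np.ndarray | None = None
) -> FstSiteComponents:
    """Weir & Cockerham variance components per site for a population pair.

    Parameters
    ----------
    geno_a, geno_b
        Dosage matrices (n_samples, n_sites), coded 0/1/2, -1 missing.
    positions
        Optional 1-based site positions carried through to the result.

    Sites where either population has zero non-missing genotypes are
    skipped (components NaN).  Sites monomorphic in the pooled pair get
    a = b = c = 0 and a null theta.
    """
    n1, p1, h1 = _pop_summaries(np.asarray(geno_a))
    n2, p2, h2 = _pop_summaries(np.asarray(geno_b))
    n_sites = len(n1)
    if positions is None:
        positions = np.arange(n_sites)

    r = float(R_POPS)
    skip = (n1 == 0) | (n2 == 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    mono = (pbar == 0) | (pbar == 1)
    for arr in (a, b, c):
        arr[mono] = 0.0
        arr[skip] = np.nan
    return FstSiteComponents(np.asarray(positions), a, b, c)


def windowed_fst(
    components: FstSiteComponents, windows: pd.DataFrame, min_snps: int = 10
) -> pd.DataFrame:
    """Ratio-of-sums Fst per window: sum(a) / sum(a+b+c) over member sites.

    ``windows`` must carry 1-based inclusive ``start``/``end`` columns for a
    single chromosome; the result adds ``n_snps``, ``score`` and ``valid``.
    Windows with fewer than ``min_snps`` contributing sites are invalid.
    Negative per-site components are retained (no clamping).
    """
    usable = ~np.isnan(components.a)
    pos = components.positions[usable]
    a = components.a[usable]
    tot = a + components.b[usable] + components.c[usable]

    # windows overlap, so prefix sums over sorted sites beat a groupby
    ca = np.concatenate([[0.0], np.cumsum(a)])
    ct = np.concatenate([[0.0], np.cumsum(tot)])
    lo = np.searchsorted(pos, windows["start"].to_numpy(), side="left")
    hi = np.searchsorted(pos, windows["end"].to_numpy(), side="right")

    out = windows.copy()
    out["n_snps"] = hi - lo
    sa = ca[hi] - ca[lo]
    st = ct[hi] - ct[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["score"] = np.where(st != 0, sa / st, np.nan)
    out["valid"] = (out["n_snps"] >= min_snps) & ~out["score"].isna()
    return out
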