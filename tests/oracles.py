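"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain scalar python against the
defining formulas — no shared code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components, scalar transcription
# ---------------------------------------------------------------------------

def wc_site_oracle(genotypes_by_pop):
    """a, b, c for one biallelic site from per-population diploid genotype
    lists (derived-allele dosages 0/1/2; missing entries excluded upstream).

    Returns (a, b, c) or None when a population has no genotypes.
    """
    r = len(genotypes_by_pop)
    ns, ps, hs = [], [], []
    for geno in genotypes_by_pop:
        geno = [g for g in geno if g >= 0]
        if not geno:
            return None
        n = len(geno)
        p = sum(geno) / (2 * n)
        h = sum(1 for g in geno if g == 1) / n
        ns.append(n); ps.append(p); hs.append(h)
    nbar = sum(ns) / r
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    if pbar in (0.0, 1.0):
        return (0.0, 0.0, 0.0)
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return (a, b, c)


# ---------------------------------------------------------------------------
# EHH / iHH by exhaustive haplotype-string comparison
# ---------------------------------------------------------------------------

def ehh_oracle_curve(hap_rows, positions, core, allele, direction, cutoff, max_gap):
    """EHH curve by comparing full core-to-site allele tuples pairwise.

    ``hap_rows`` is a list of per-haplotype allele lists.  Returns a list
    of (distance, ehh) points starting at (0, 1.0), mirroring the walk's
    stopping rules (cutoff reached / gap exceeded / chromosome edge).
    """
    carriers = [h for h in hap_rows if h[core] == allele]
    n = len(carriers)
    assert n >= 2
    npairs = n * (n - 1) // 2
    points = [(0, 1.0)]
    j = core
    while True:
        jn = j + direction
        if jn < 0 or jn >= len(positions):
            break
        if abs(positions[jn] - positions[j]) > max_gap:
            break
        strings = [tuple(h[min(core, jn): max(core, jn) + 1]) for h in carriers]
        identical = sum(1 for x, y in combinations(strings, 2) if x == y)
        e = identical / npairs
        points.append((abs(positions[jn] - positions[core]), e))
        j = jn
        if e < cutoff:
            break
    return points


def trapezoid_oracle(points):
    total = 0.0
    for (d1, e1), (d2, e2) in zip(points, points[1:]):
        total += (d2 - d1) * (e1 + e2) / 2.0
    return total


def ihh_oracle(hap_rows, positions, core, allele, cutoff=0.05, max_gap=200_000):
    left = ehh_oracle_curve(hap_rows, positions, core, allele, -1, cutoff, max_gap)
    right = ehh_oracle_curve(hap_rows, positions, core, allele, +1, cutoff, max_gap)
    return trapezoid_oracle(left) + trapezoid_oracle(right)


# ---------------------------------------------------------------------------
# Per-base boolean membership oracle for interval algebra
# ---------------------------------------------------------------------------

def mask_of(region_set, chrom, length):
    m = np.zeros(length + 2, dtype=bool)
    for s, e in region_set.intervals(chrom):
        m[s: e + 1] = True
    return m


def intervals_of(mask):
    """Recover sorted disjoint 1-based inclusive intervals from a mask."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return [(int(s), int(e)) for s, e in zip(starts, ends)]
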