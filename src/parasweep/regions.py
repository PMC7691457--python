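"""Genomic interval sets with exact coordinate-level algebra.

A :class:`RegionSet` holds, per chromosome, a sorted list of disjoint
1-based inclusive intervals and is closed under union, intersection and
subtraction.  Semantics follow bedtools: subtraction removes coordinates
(splitting intervals where needed) rather than dropping whole regions,
and normalization merges book-ended ("continuous") intervals.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np

Interval = Tuple[int, int]


def _normalize(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort, drop empties, and merge overlapping or adjacent intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e >= s)
    out: List[Interval] = []
    for s, e in ivs:
        # adjacent (gap of 0 bp on the 1-based inclusive scale) merges too
        if out and s <= out[-1][1] + 1:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


class RegionSet:
    """Normalized set of 1-based inclusive genomic intervals, per chromosome."""

    def __init__(self, intervals: Dict[str, Iterable[Interval]] | None = None):
        self._ivs: Dict[str, List[Interval]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                norm = _normalize(ivs)
                if norm:
                    self._ivs[chrom] = norm

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, int, int]]) -> "RegionSet":
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, s, e in records:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls(by_chrom)

    @classmethod
    def read_bed(cls, path) -> "RegionSet":
        """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
        recs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                recs.append((parts[0], int(parts[1]) + 1, int(parts[2])))
        return cls.from_records(recs)

    # -- inspection --------------------------------------------------------
    @property
    def chroms(self) -> List[str]:
        return sorted(self._ivs)

    def intervals(self, chrom: str) -> List[Interval]:
        return list(self._ivs.get(chrom, []))

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in sorted(self._ivs):
            for s, e in self._ivs[chrom]:
                yield chrom, s, e

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivs.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self._ivs == other._ivs

    def __repr__(self) -> str:
        n = len(self)
        return f"RegionSet({n} intervals on {len(self._ivs)} chromosome(s), {self.total_bp()} bp)"

    def is_empty(self) -> bool:
        return not self._ivs

    def total_bp(self) -> int:
        return sum(e - s + 1 for ivs in self._ivs.values() for s, e in ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self._ivs.get(chrom)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and ivs[i][1] >= pos

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return not self.intersect(RegionSet({chrom: [(start, end)]})).is_empty()

    # -- set algebra -------------------------------------------------------
    def union(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, List[Interval]] = {}
        for chrom in set(self._ivs) | set(other._ivs):
            out[chrom] = self._ivs.get(chrom, []) + other._ivs.get(chrom, [])
        return RegionSet(out)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, List[Interval]] = {}
        for chrom in set(self._ivs) & set(other._ivs):
            a, b = self._ivs[chrom], other._ivs[chrom]
            res: List[Interval] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s <= e:
                    res.append((s, e))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = res
        return RegionSet(out)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, List[Interval]] = {}
        for chrom, a in self._ivs.items():
            b = other._ivs.get(chrom, [])
            res: List[Interval] = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j][1] < cur:
                    j += 1
                k = j
                while k < len(b) and b[k][0] <= e:
                    bs, be = b[k]
                    if bs > cur:
                        res.append((cur, bs - 1))
                    cur = max(cur, be + 1)
                    if cur > e:
                        break
                    k += 1
                if cur <= e:
                    res.append((cur, e))
            if res:
                out[chrom] = res
        return RegionSet(out)

    # -- io ----------------------------------------------------------------
    def write_bed(self, path, name: str | None = None) -> None:
        """Write as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom, s, e in self:
                fields = [chrom, str(s - 1), str(e)]
                if name is not None:
                    fields.append(name)
                fh.write("\t".join(fields) + "\n")


def interval_op(a: RegionSet, b: RegionSet, op: str) -> RegionSet:
    """Apply a named set operation: ``union``, ``intersect`` or ``subtract``."""
    if op == "union":
        return a.union(b)
    if op == "intersect":
        return a.intersect(b)
    if op == "subtract":
        return a.subtract(b)
    raise ValueError(f"unknown interval op: {op!r}")
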