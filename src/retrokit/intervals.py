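"""Half-open, 0-based interval-set algebra on per-chromosome interval lists.

All public functions take and return ``dict[str, list[tuple[int, int]]]``
where each list is sorted, merged and non-overlapping. These are the
primitives behind accessibility masks and genome compartment bookkeeping.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Dict, Iterable, List, Tuple

Interval = Tuple[int, int]
IntervalDict = Dict[str, List[Interval]]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge_dict(d: IntervalDict) -> IntervalDict:
    return {c: merge_intervals(v) for c, v in d.items() if v}


def total_length(d: IntervalDict) -> int:
    return sum(e - s for ivs in d.values() for s, e in ivs)


def union(a: IntervalDict, b: IntervalDict) -> IntervalDict:
    out: IntervalDict = {}
    for chrom in set(a) | set(b):
        out[chrom] = merge_intervals(list(a.get(chrom, [])) + list(b.get(chrom, [])))
    return {c: v for c, v in out.items() if v}


def intersect(a: IntervalDict, b: IntervalDict) -> IntervalDict:
    out: IntervalDict = {}
    for chrom in set(a) & set(b):
        ia, ib = a[chrom], b[chrom]
        res: List[Interval] = []
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                res.append((s, e))
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
        if res:
            out[chrom] = res
    return out


def subtract(a: IntervalDict, b: IntervalDict) -> IntervalDict:
    out: IntervalDict = {}
    for chrom, ia in a.items():
        ib = b.get(chrom, [])
        res: List[Interval] = []
        for s, e in ia:
            cur = s
            for bs, be in ib:
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    res.append((cur, bs))
                cur = max(cur, be)
                if cur >= e:
                    break
            if cur < e:
                res.append((cur, e))
        if res:
            out[chrom] = res
    return out


class IntervalLookup:
    """O(log n) point-membership queries against a merged interval list."""

    def __init__(self, intervals: Iterable[Interval]):
        self._ivs = merge_intervals(intervals)
        self._starts = [s for s, _ in self._ivs]

    def __contains__(self, pos: int) -> bool:
        i = bisect_right(self._starts, pos) - 1
        return i >= 0 and pos < self._ivs[i][1]

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        i = bisect_right(self._starts, start) - 1
        if i >= 0 and start < self._ivs[i][1]:
            return True
        i += 1
        return i < len(self._ivs) and self._ivs[i][0] < end
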