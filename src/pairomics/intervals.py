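"""Genomic interval arithmetic on 0-based half-open intervals.

All functions operate on per-chromosome interval lists represented as
``(start, end)`` integer tuples with ``start < end``. Multi-chromosome
collections are handled by the callers (e.g. :mod:`pairomics.cna`), which
group by chromosome before delegating here.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def _validate(intervals: Iterable[Interval]) -> list[Interval]:
    out = []
    for start, end in intervals:
        if start >= end:
            raise ValueError(f"invalid interval [{start}, {end}): start >= end")
        out.append((int(start), int(end)))
    return out


def interval_union(intervals: Iterable[Interval]) -> list[Interval]:
    """Minimal disjoint sorted cover of a set of half-open intervals."""
    ivs = sorted(_validate(intervals))
    merged: list[Interval] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            last_start, last_end = merged[-1]
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def interval_subtract(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Exact set difference ``a \\ b`` as disjoint sorted intervals."""
    a_merged = interval_union(a)
    b_merged = interval_union(b)
    out: list[Interval] = []
    j = 0
    for start, end in a_merged:
        cur = start
        while j < len(b_merged) and b_merged[j][1] <= cur:
            j += 1
        k = j
        while k < len(b_merged) and b_merged[k][0] < end:
            bs, be = b_merged[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


def interval_intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Intersection of two interval sets as disjoint sorted intervals."""
    a_merged = interval_union(a)
    b_merged = interval_union(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a_merged) and j < len(b_merged):
        lo = max(a_merged[i][0], b_merged[j][0])
        hi = min(a_merged[i][1], b_merged[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a_merged[i][1] < b_merged[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(end - start for start, end in interval_union(intervals))


def overlap_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Total bp in the intersection of two interval sets."""
    a, b = list(a), list(b)
    if not a or not b:
        return 0
    return total_length(interval_intersect(a, b))


def overlap_fraction(interval: Interval, others: Sequence[Interval]) -> float:
    """Fraction of ``interval`` covered by the union of ``others``."""
    start, end = interval
    if start >= end:
        raise ValueError(f"invalid interval [{start}, {end})")
    if not others:
        return 0.0
    covered = total_length(interval_intersect([interval], others))
    return covered / (end - start)
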