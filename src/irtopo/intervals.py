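"""Half-open interval arithmetic on a single sequence.

All coordinates are 0-based half-open ``[start, end)``. Interval lists are
plain lists of ``(start, end)`` tuples; the functions here normalize them into
sorted, disjoint, non-adjacent form so that downstream base-pair accounting
(footprints, compartments, window overlaps) is unambiguous.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, disjoint, adjacent runs coalesced."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_bp(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two merged interval lists (linear sweep)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a − b for merged interval lists."""
    comp_b = complement(b, lo=min((s for s, _ in a), default=0),
                        hi=max((e for _, e in a), default=0))
    return intersect(a, comp_b)


def complement(intervals: Sequence[Interval], lo: int, hi: int) -> list[Interval]:
    """Complement of a merged interval list within ``[lo, hi)``."""
    out: list[Interval] = []
    cur = lo
    for s, e in intervals:
        s, e = max(s, lo), min(e, hi)
        if s >= e:
            continue
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        out.append((cur, hi))
    return out


def overlap_bp(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    return total_bp(intersect(a, b))


def gap_to(intervals: Sequence[Interval], start: int, end: int) -> int:
    """Minimum gap (bp) between ``[start, end)`` and any interval; 0 if touching/overlapping."""
    best = None
    for s, e in intervals:
        if e > start and s < end:
            return 0
        gap = s - end if s >= end else start - e
        best = gap if best is None else min(best, gap)
    return best if best is not None else 10 ** 18
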