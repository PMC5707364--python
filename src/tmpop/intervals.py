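"""Half-open interval arithmetic on plain ``(start, end)`` tuples.

All genomic intervals in this package are 0-based, half-open ``[start, end)``,
the BED convention.  Functions here accept iterables of such tuples and return
sorted, merged (non-overlapping) lists.  They are deliberately simple sweep
algorithms: the interval sets in this pipeline are small (thousands at most)
and clarity beats an external dependency.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or touching intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (each merged first)."""
    a = merge(a)
    b = merge(b)
    out: List[Interval] = []
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


def complement(intervals: Iterable[Interval], length: int) -> List[Interval]:
    """Complement of an interval set within ``[0, length)``."""
    out: List[Interval] = []
    prev = 0
    for s, e in merge(intervals):
        s = max(0, min(s, length))
        e = max(0, min(e, length))
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Set difference a \\ b."""
    a = merge(a)
    if not a:
        return []
    hi = a[-1][1]
    return intersect(a, complement(b, hi))


def overlap_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    return total_length(intersect(a, b))


def contains(intervals: Sequence[Interval], pos: int) -> bool:
    """Membership test for a sorted, merged interval list (binary search)."""
    import bisect

    idx = bisect.bisect_right([s for s, _ in intervals], pos) - 1
    return idx >= 0 and intervals[idx][0] <= pos < intervals[idx][1]
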