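"""Half-open interval arithmetic on (start, end) pairs.

All coordinates are 0-based, half-open (BED convention). Inputs may be any
iterable of (start, end) pairs; outputs are sorted, merged lists of tuples.
"""

from __future__ import annotations

from typing import Iterable


def _as_pairs(intervals: Iterable) -> list[tuple[int, int]]:
    out = []
    for iv in intervals:
        start, end = (iv.start, iv.end) if hasattr(iv, "start") else (iv[0], iv[1])
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        out.append((int(start), int(end)))
    return out


def merge(intervals: Iterable) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint half-open intervals.

    Abutting intervals ([0,5) and [5,9)) are coalesced.
    """
    pairs = sorted(_as_pairs(intervals))
    out: list[tuple[int, int]] = []
    for start, end in pairs:
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract(a: Iterable, b: Iterable) -> list[tuple[int, int]]:
    """Per-base set difference A \\ B as disjoint half-open intervals."""
    a_pairs, b_pairs = list(a), list(b)
    a_merged = merge(a_pairs) if a_pairs else []
    b_merged = merge(b_pairs) if b_pairs else []
    out: list[tuple[int, int]] = []
    for start, end in a_merged:
        cursor = start
        for bs, be in b_merged:
            if be <= cursor or bs >= end:
                continue
            if bs > cursor:
                out.append((cursor, bs))
            cursor = max(cursor, be)
            if cursor >= end:
                break
        if cursor < end:
            out.append((cursor, end))
    return out


def total_length(intervals: Iterable) -> int:
    """Summed length of the union of the intervals."""
    pairs = list(intervals)
    if not pairs:
        return 0
    return sum(end - start for start, end in merge(pairs))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the overlap of two half-open intervals (0 if disjoint)."""
    a0, a1 = (a.start, a.end) if hasattr(a, "start") else (a[0], a[1])
    b0, b1 = (b.start, b.end) if hasattr(b, "start") else (b[0], b[1])
    return max(0, min(a1, b1) - max(a0, b0))


def intersect_length(a: Iterable, b: Iterable) -> int:
    """Per-base size of the intersection of two interval sets."""
    a_pairs, b_pairs = list(a), list(b)
    if not a_pairs or not b_pairs:
        return 0
    diff = subtract(a_pairs, b_pairs)
    return total_length(a_pairs) - sum(e - s for s, e in diff)


def pad(intervals: Iterable, amount: int, lo: int, hi: int) -> list[tuple[int, int]]:
    """Extend each interval by `amount` on both sides, clipped to [lo, hi)."""
    out = []
    for start, end in _as_pairs(intervals):
        out.append((max(lo, start - amount), min(hi, end + amount)))
    return merge(out)
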