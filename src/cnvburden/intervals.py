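"""Genomic interval arithmetic in 1-based inclusive coordinates.

All callers' native output (PennCNV-style) is 1-based inclusive, so every
internal computation uses that convention: an interval (start, end) covers
``end - start + 1`` bases.  BED input is converted at the boundary by the IO
layer.  Functions here operate on plain integer pairs or ``(n, 2)`` numpy
arrays; higher-level containers live in :mod:`cnvburden.types`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "interval_length",
    "merge_intervals",
    "union_length",
    "covered_length",
    "overlap_length",
    "reciprocal_overlap",
]


def interval_length(start: int, end: int) -> int:
    """Number of bases covered by the inclusive interval [start, end]."""
    if end < start:
        raise ValueError(f"end < start for interval ({start}, {end})")
    return end - start + 1


def merge_intervals(intervals) -> np.ndarray:
    """Merge overlapping or abutting 1-based inclusive intervals.

    Parameters
    ----------
    intervals : array-like of shape (n, 2)
        Start/end pairs on a single chromosome, any order.

    Returns
    -------
    ndarray of shape (m, 2), sorted, pairwise disjoint and non-abutting.
    """
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("interval with end < start")
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        # abutting intervals (gap of 0 bases) merge: [1,50] + [51,100] -> [1,100]
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def union_length(intervals) -> int:
    """Total number of bases covered by the union of intervals (one chrom)."""
    merged = merge_intervals(intervals)
    if merged.size == 0:
        return 0
    return int(np.sum(merged[:, 1] - merged[:, 0] + 1))


def covered_length(start: int, end: int, intervals) -> int:
    """Bases of [start, end] covered by the union of ``intervals``.

    ``intervals`` need not be pre-merged or sorted.
    """
    merged = merge_intervals(intervals)
    if merged.size == 0:
        return 0
    lo = np.maximum(merged[:, 0], start)
    hi = np.minimum(merged[:, 1], end)
    lens = hi - lo + 1
    return int(np.sum(lens[lens > 0]))


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Bases shared by two inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len_a, overlap/len_b), the standard CNV matching measure."""
    ov = overlap_length(a_start, a_end, b_start, b_end)
    if ov == 0:
        return 0.0
    la = interval_length(a_start, a_end)
    lb = interval_length(b_start, b_end)
    return min(ov / la, ov / lb)
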