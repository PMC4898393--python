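"""Half-open interval arithmetic on numpy arrays.

All functions take ``(n, 2)`` integer arrays of ``[start, stop)`` rows on a
single chromosome.  Multi-chromosome sets are represented as
``dict[str, ndarray]`` by the callers.
"""
from __future__ import annotations

import numpy as np


def as_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, stop) pairs to a sorted (n, 2) array."""
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr.reshape(-1, 2).astype(np.int64)
    return arr[np.argsort(arr[:, 0], kind="stable")]


def merge_intervals(intervals, gap: int = 0) -> np.ndarray:
    """Merge overlapping intervals; intervals separated by <= gap also merge."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s - cur_e <= gap:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


def union_length(intervals) -> int:
    merged = merge_intervals(intervals)
    if len(merged) == 0:
        return 0
    return int((merged[:, 1] - merged[:, 0]).sum())


def _coverage_upto(x: np.ndarray, starts: np.ndarray, stops: np.ndarray,
                   cum: np.ndarray) -> np.ndarray:
    """Total covered bp of the merged set in [0, x)."""
    i = np.searchsorted(starts, x, side="right") - 1
    safe = np.maximum(i, 0)
    base = np.where(i >= 0, cum[safe], 0)
    extra = np.where(i >= 0,
                     np.clip(x - starts[safe], 0, stops[safe] - starts[safe]),
                     0)
    return base + extra


def _as_array_unsorted(intervals) -> np.ndarray:
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return arr.reshape(-1, 2).astype(np.int64)


def overlap_lengths(queries, subject) -> np.ndarray:
    """Per-query total intersection length (bp) with the subject interval set.

    Query order is preserved; queries need not be sorted.
    """
    q = _as_array_unsorted(queries)
    merged = merge_intervals(subject)
    if len(q) == 0:
        return np.zeros(0, dtype=np.int64)
    if len(merged) == 0:
        return np.zeros(len(q), dtype=np.int64)
    starts, stops = merged[:, 0], merged[:, 1]
    cum = np.concatenate([[0], np.cumsum(stops - starts)])[:-1]
    return (_coverage_upto(q[:, 1], starts, stops, cum)
            - _coverage_upto(q[:, 0], starts, stops, cum)).astype(np.int64)


def overlaps_any(queries, subject, min_overlap: int = 1) -> np.ndarray:
    """Boolean per query: does it intersect the subject set by >= min_overlap bp."""
    return overlap_lengths(queries, subject) >= min_overlap
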