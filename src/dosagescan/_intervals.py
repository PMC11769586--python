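"""Small interval utilities shared by the masking and simulation code.

All intervals are 0-based half-open ``(start, end)`` pairs in base
coordinates, the BED convention.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping intervals as a sorted, disjoint list."""
    if not intervals:
        return []
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def intervals_to_bool(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    """Boolean membership array of ``length``; True inside any interval."""
    arr = np.zeros(length, dtype=bool)
    for s, e in intervals:
        arr[max(0, s):min(length, e)] = True
    return arr


def bool_to_intervals(arr: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    if arr.size == 0:
        return []
    padded = np.concatenate(([False], arr.astype(bool), [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def clip_interval(start: int, end: int, length: int) -> tuple[int, int] | None:
    """Clip to [0, length); None if nothing remains."""
    s, e = max(0, int(start)), min(int(length), int(end))
    return (s, e) if s < e else None
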