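"""Minimal interval helpers for 1-based inclusive genomic intervals.

Only the two predicates the pipeline needs: pairwise ≥1 bp overlap against a
reference set, and grouping of mutually overlapping intervals. Interval sets
here are tiny (hundreds of DMRs), so a sorted sweep is plenty.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


def overlaps_any(
    chrom: str,
    start: int,
    end: int,
    reference: dict[str, np.ndarray],
) -> bool:
    """True if [start, end] (1-based inclusive) overlaps any reference interval.

    ``reference`` maps chrom -> (n, 2) array of sorted [start, end] rows, as
    built by :func:`build_interval_index`.
    """
    arr = reference.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    # candidate intervals with ref_start <= end; among them check ref_end >= start
    i = np.searchsorted(arr[:, 0], end, side="right")
    if i == 0:
        return False
    return bool(np.any(arr[:i, 1] >= start))


def build_interval_index(
    intervals: Iterable[tuple[str, int, int]],
) -> dict[str, np.ndarray]:
    """Index (chrom, start, end) triples by chromosome, sorted by start."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    return {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
        for c, v in by_chrom.items()
    }


def connected_groups(intervals: Sequence[tuple[str, int, int]]) -> list[list[int]]:
    """Group indices of intervals into connected components under ≥1 bp overlap.

    Coordinates are 1-based inclusive; intervals sharing a single base are
    connected. Returns groups of indices into ``intervals``.
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i][0], intervals[i][1]))
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_chrom: str | None = None
    cur_end = -1
    for i in order:
        chrom, start, end = intervals[i]
        if cur and chrom == cur_chrom and start <= cur_end:
            cur.append(i)
            cur_end = max(cur_end, end)
        else:
            if cur:
                groups.append(cur)
            cur = [i]
            cur_chrom = chrom
            cur_end = end
    if cur:
        groups.append(cur)
    return groups
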