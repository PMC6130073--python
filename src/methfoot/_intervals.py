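"""Sorted-interval algebra on a single chromosome.

Minimal set operations (merge, union, intersection, subtraction, overlap
length) on 0-based half-open intervals, backed by parallel numpy arrays of
starts and ends.  Used for annotation composition queries and NSR
construction, where the full weight of a genomic-ranges library is not
needed and boolean sweeps over merged endpoints are exact and fast.
"""

from __future__ import annotations

import numpy as np


class IntervalSet:
    """An immutable union of disjoint sorted intervals on one chromosome."""

    __slots__ = ("starts", "ends")

    def __init__(self, starts, ends, *, _merged: bool = False):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have equal length")
        if np.any(ends <= starts):
            raise ValueError("every interval needs end > start")
        if not _merged:
            starts, ends = _merge(starts, ends)
        self.starts = starts
        self.ends = ends

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(np.empty(0, np.int64), np.empty(0, np.int64), _merged=True)

    def __len__(self) -> int:
        return len(self.starts)

    def total_bp(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def overlap_bp(self, start: int, end: int) -> int:
        """Covered bp of [start, end) by this set."""
        if len(self.starts) == 0 or start >= end:
            return 0
        lo = np.clip(self.starts, start, end)
        hi = np.clip(self.ends, start, end)
        return int(np.sum(np.maximum(hi - lo, 0)))

    def contains_point(self, pos: int) -> bool:
        i = np.searchsorted(self.ends, pos, side="right")
        return i < len(self.starts) and self.starts[i] <= pos

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(
            np.concatenate([self.starts, other.starts]),
            np.concatenate([self.ends, other.ends]),
        )

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return self._boolean(other, keep=lambda a, b: a & b)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        return self._boolean(other, keep=lambda a, b: a & ~b)

    def complement(self, length: int) -> "IntervalSet":
        """Set difference [0, length) minus self."""
        whole = IntervalSet(np.array([0]), np.array([length]))
        return whole.subtract(self)

    def _boolean(self, other, keep) -> "IntervalSet":
        # Event sweep over all endpoints; inside-ness of each elementary
        # segment is decided by the `keep` predicate.
        pts = np.unique(
            np.concatenate([self.starts, self.ends, other.starts, other.ends])
        )
        if len(pts) < 2:
            return IntervalSet.empty()
        mids = pts[:-1]  # left endpoint of each elementary segment
        in_a = _covered(self, mids)
        in_b = _covered(other, mids)
        mask = keep(in_a, in_b)
        if not np.any(mask):
            return IntervalSet.empty()
        return IntervalSet(pts[:-1][mask], pts[1:][mask])

    def to_regions(self, chrom: str):
        from .types import GenomicRegion

        return [
            GenomicRegion(chrom, int(s), int(e))
            for s, e in zip(self.starts, self.ends)
        ]


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


def _covered(iset: IntervalSet, points: np.ndarray) -> np.ndarray:
    if len(iset.starts) == 0:
        return np.zeros(len(points), dtype=bool)
    idx = np.searchsorted(iset.ends, points, side="right")
    ok = idx < len(iset.starts)
    res = np.zeros(len(points), dtype=bool)
    res[ok] = iset.starts[idx[ok]] <= points[ok]
    return res
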