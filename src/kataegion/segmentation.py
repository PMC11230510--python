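"""Exact piecewise-constant fitting by penalized least squares.

Fits an ordered numeric series with segment-wise constant means, minimizing

    sum over segments of SSE(segment)  +  gamma * (n_segments - 1)

over all segmentations whose segments each contain at least ``kmin`` points.
The dynamic programme is exact (global optimum) and O(n^2); series here are
per-chromosome gap counts, so this is affordable and fully testable against
exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Segmentation", "exact_pcf", "pcf_adjusted_imd"]


@dataclass(frozen=True)
class Segmentation:
    """Result of an exact PCF fit.

    ``breakpoints`` are the 0-based start indices of segments 2..k (i.e. a
    breakpoint b means a new segment starts at index b); an empty tuple means
    a single segment. ``cost`` is the penalized objective value.
    """

    breakpoints: tuple[int, ...]
    segment_means: tuple[float, ...]
    cost: float
    gamma: float

    @property
    def n_segments(self) -> int:
        return len(self.segment_means)

    def segment_bounds(self, n: int) -> list[tuple[int, int]]:
        """Half-open index ranges [start, end) of each segment."""
        starts = (0,) + self.breakpoints
        ends = self.breakpoints + (n,)
        return list(zip(starts, ends))

    def fitted(self, n: int) -> np.ndarray:
        """Per-point fitted values (the mean of the containing segment)."""
        out = np.empty(n)
        for (s, e), m in zip(self.segment_bounds(n), self.segment_means):
            out[s:e] = m
        return out


def exact_pcf(series, gamma: float, kmin: int = 1) -> Segmentation:
    """Globally optimal penalized least-squares segmentation.

    Ties are broken toward fewer segments, then toward earliest breakpoints.

    Parameters
    ----------
    series:
        Finite numeric values, length >= kmin.
    gamma:
        Penalty per additional segment, >= 0.
    kmin:
        Minimum points per segment, >= 1.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains NaN/Inf")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    n = y.size
    if n < kmin:
        raise ValueError(f"series length {n} shorter than kmin={kmin}")

    # prefix sums for O(1) SSE of any window
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(i: int, j: int) -> float:
        # SSE of y[i:j]
        s = c1[j] - c1[i]
        q = c2[j] - c2[i]
        return max(q - s * s / (j - i), 0.0)

    INF = np.inf
    # best[j] = (cost, n_segments, start_of_last_segment) for prefix y[:j]
    best_cost = np.full(n + 1, INF)
    best_nseg = np.full(n + 1, 0, dtype=int)
    best_prev = np.full(n + 1, -1, dtype=int)
    best_cost[0] = -gamma  # cancels the +gamma of the first segment
    best_nseg[0] = 0

    sq = c2[1:]  # unused; keep prefix arrays referenced for clarity
    del sq

    for j in range(kmin, n + 1):
        # candidate starts i of the last segment: 0 <= i <= j - kmin, with
        # y[:i] itself segmentable (i == 0 or i >= kmin)
        i_arr = np.arange(0, j - kmin + 1)
        valid = (i_arr == 0) | (i_arr >= kmin)
        i_arr = i_arr[valid & np.isfinite(best_cost[i_arr])]
        if i_arr.size == 0:
            continue
        lens = j - i_arr
        s = c1[j] - c1[i_arr]
        q = c2[j] - c2[i_arr]
        seg_sse = np.maximum(q - s * s / lens, 0.0)
        costs = best_cost[i_arr] + seg_sse + gamma
        # tie-break: fewer segments, then earlier breakpoints (larger start of
        # last segment is NOT what we want — earliest breakpoints overall means
        # lexicographically smallest breakpoint tuple; with equal cost and
        # equal segment count, prefer the smallest last-segment start)
        order = np.lexsort((i_arr, best_nseg[i_arr], costs))
        k = order[0]
        best_cost[j] = costs[k]
        best_nseg[j] = best_nseg[i_arr[k]] + 1
        best_prev[j] = i_arr[k]

    if not np.isfinite(best_cost[n]):
        raise ValueError(f"no valid segmentation of length {n} with kmin={kmin}")

    bounds: list[int] = []
    j = n
    while j > 0:
        bounds.append(best_prev[j])
        j = best_prev[j]
    starts = bounds[::-1]  # first element is 0
    ends = starts[1:] + [n]
    means = tuple(float((c1[e] - c1[s]) / (e - s)) for s, e in zip(starts, ends))
    return Segmentation(
        breakpoints=tuple(starts[1:]),
        segment_means=means,
        cost=float(best_cost[n]),
        gamma=float(gamma),
    )


def pcf_adjusted_imd(positions, gamma: float = 25.0, kmin: int = 2) -> np.ndarray:
    """Smoothed inter-mutation distances for sorted positions on one chromosome.

    Computes the gaps between consecutive positions, segments log10(gap) with
    :func:`exact_pcf`, and returns per gap ``10 ** segment_mean`` — the
    locally averaged inter-mutation distance used for cluster thresholding.

    A single gap is returned unchanged. Duplicate positions are an error;
    callers de-duplicate upstream.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size < 2:
        raise ValueError("need >= 2 positions to form a gap")
    gaps = np.diff(pos)
    if np.any(gaps <= 0):
        bad = int(np.argmax(gaps <= 0))
        raise ValueError(
            f"positions must be strictly increasing; offending index {bad + 1}"
        )
    logg = np.log10(gaps.astype(float))
    if logg.size < max(kmin, 2):
        return gaps.astype(float)
    seg = exact_pcf(logg, gamma=gamma, kmin=kmin)
    return 10.0 ** seg.fitted(logg.size)
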