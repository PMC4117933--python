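"""Circular binary segmentation of standardized per-sample profiles.

Recursive changepoint detection: within a segment, find the arc (i, j) whose
two-sample t-like statistic against its complement is maximal; accept the
split if a within-segment permutation p-value falls below ``alpha``; recurse
on the resulting pieces.  The permutation stream is driven by an explicit
seed so segmentation is reproducible bit-for-bit.

Permutation testing stops early once enough exceedances have accumulated that
the p-value can no longer fall below ``alpha`` (this changes nothing about
the decision, only the cost of clear rejections).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np


@dataclass(frozen=True)
class Segment:
    """Half-open window-index interval with the mean standardized value."""

    start_window: int
    end_window: int
    mean: float

    @property
    def n_windows(self) -> int:
        return self.end_window - self.start_window


@dataclass
class SegmentList:
    """One sample's piecewise-constant segmentation, tiling [0, n_windows)."""

    sample_id: str
    segments: list[Segment]
    n_windows: int
    too_short: bool = False  # input shorter than 2*min_width: single segment

    @property
    def breakpoints(self) -> list[int]:
        """Interior breakpoints (window indices)."""
        return [s.start_window for s in self.segments[1:]]


@lru_cache(maxsize=128)
def _arc_indices(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All arcs [i, j) of length and complement length >= min_width."""
    i, j = np.triu_indices(n + 1, k=min_width)
    keep = (j - i) <= n - min_width
    return i[keep], j[keep]


def max_arc_statistic(
    x: np.ndarray, min_width: int = 2
) -> tuple[float, int, int]:
    """Maximal arc-vs-complement t statistic over all admissible arcs.

    Returns ``(t, i, j)`` for the best arc ``x[i:j)``.  A zero-variance split
    with distinct means scores +inf; a constant vector scores 0.  Ties break
    toward the smallest ``(i, j)`` in row-major order, deterministically.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    i, j = _arc_indices(n, min_width)
    if i.size == 0:
        return 0.0, 0, n
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    n1 = (j - i).astype(float)
    n2 = n - n1
    sum1 = S[j] - S[i]
    m1 = sum1 / n1
    m2 = (S[n] - sum1) / n2
    ss1 = Q[j] - Q[i]
    within = (ss1 - n1 * m1 * m1) + ((Q[n] - ss1) - n2 * m2 * m2)
    within = np.maximum(within, 0.0)
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(within / (n - 2) * (1.0 / n1 + 1.0 / n2))
        t = diff / denom
    scale = 1e-12 * (1.0 + float(np.abs(x).max()))
    t[denom == 0] = np.where(diff[denom == 0] > scale, np.inf, 0.0)
    k = int(np.argmax(t))
    return float(t[k]), int(i[k]), int(j[k])


def _permutation_accepts(
    seg: np.ndarray,
    t_obs: float,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test of the observed maximal statistic within one segment."""
    if not t_obs > 0:
        return False
    # Once this many permuted maxima reach t_obs, p >= alpha is certain.
    limit = math.ceil(alpha * (n_perm + 1))
    exceed = 0
    for _ in range(n_perm):
        t_p, _, _ = max_arc_statistic(rng.permutation(seg), min_width)
        if t_p >= t_obs:
            exceed += 1
            if exceed >= limit:
                return False
    return (1 + exceed) / (1 + n_perm) < alpha


def segment_profile(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
    sample_id: str = "",
) -> SegmentList:
    """Segment one standardized profile into piecewise-constant regions.

    Parameters follow common CBS practice: ``alpha`` is the per-split
    significance level, ``n_perm`` the number of label permutations, and
    ``min_width`` the minimum arm width of a split.  Vectors shorter than
    ``2*min_width`` return a single segment flagged ``too_short``.
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("profile contains NaN; drop masked windows first")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = x.size
    if n < 2 * min_width:
        return SegmentList(sample_id, [Segment(0, n, float(x.mean()))], n, True)

    rng = np.random.default_rng(seed)
    breakpoints: list[int] = []

    def recurse(a: int, b: int) -> None:
        seg = x[a:b]
        if seg.size < 2 * min_width:
            return
        t_obs, i, j = max_arc_statistic(seg, min_width)
        if not _permutation_accepts(seg, t_obs, alpha, n_perm, min_width, rng):
            return
        cuts = [c for c in (i, j) if 0 < c < seg.size]
        for c in cuts:
            breakpoints.append(a + c)
        bounds = [a] + [a + c for c in cuts] + [b]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            recurse(lo, hi)

    recurse(0, n)
    bps = sorted(set(breakpoints))
    bounds = [0] + bps + [n]
    segments = [
        Segment(lo, hi, float(x[lo:hi].mean()))
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]
    return SegmentList(sample_id, segments, n)


def segment_sample(
    x_row: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
    sample_id: str = "",
) -> SegmentList:
    """Segment a sample row that may contain masked (NaN) windows.

    Masked windows never reach the segmentation statistic: the profile is
    compressed to its unmasked windows, segmented, and breakpoints are mapped
    back to original window indices.  For bookkeeping, masked windows are
    absorbed into the enclosing segment's span; segment means are computed
    over unmasked member windows only.
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no unmasked windows")
    dense = segment_profile(
        np.asarray(x_row, dtype=float)[idx],
        alpha=alpha,
        n_perm=n_perm,
        min_width=min_width,
        seed=seed,
        sample_id=sample_id,
    )
    n = mask.size
    bps = [int(idx[b]) for b in dense.breakpoints]
    bounds = [0] + bps + [n]
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        member = idx[(idx >= lo) & (idx < hi)]
        segments.append(Segment(lo, hi, float(np.asarray(x_row)[member].mean())))
    return SegmentList(sample_id, segments, n, dense.too_short)


def segments_to_frame(seglists: list[SegmentList], grid) -> "pd.DataFrame":
    """Serialize segment lists as a table (1-based inclusive bp coordinates)."""
    import pandas as pd

    rows = []
    for sl in seglists:
        for s in sl.segments:
            span_start = grid.region_start + s.start_window * grid.window_size
            span_end = min(
                grid.region_start + s.end_window * grid.window_size, grid.region_end
            )
            rows.append(
                {
                    "sample_id": sl.sample_id,
                    "contig": grid.contig,
                    "start": span_start + 1,
                    "end": span_end,
                    "n_windows": s.n_windows,
                    "mean": s.mean,
                }
            )
    return pd.DataFrame(rows)
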