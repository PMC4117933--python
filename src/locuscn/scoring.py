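"""Per-sample segmentation scores over the target gene.

The gene's score (SS) summarizes the sample's standardized read-depth shift
over the gene interval, extracted from the segmentation with merge and
boundary rules:

1. gene inside a single segment -> that segment's mean;
2. gene split into segments whose signs all agree with the direction of the
   dominant (|mean| >= tau) class -> length-weighted average over all of them
   (small same-sign segments merge freely; weights are the bp lengths of the
   segments clipped to the gene);
3. exactly one opposite-sign segment, sitting at a gene boundary with clipped
   length below half a window (default): its z-score (mean standardized ratio
   over its windows) arbitrates — same sign as the majority: length-weighted
   average over the OTHER segments; otherwise zero;
4. anything else -> score 0, i.e. the population average at the locus.

In the pooled multi-population run a stricter rule applies: any split of the
gene yields score zero, regardless of the segment means.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval
from .segment import Segment, SegmentList
from .windows import WindowGrid


class Rule(str, enum.Enum):
    SINGLE_SEGMENT = "single_segment"
    SAME_SIGN_MERGE = "same_sign_merge"
    BOUNDARY_ZSCORE_RESCUE = "boundary_zscore_rescue"
    ZERO_DEFAULT = "zero_default"


@dataclass
class ScoreParams:
    """Merge threshold tau and the boundary-segment length threshold.

    ``merge_threshold`` (default 0.35) separates gain/loss segments from
    neutral ones; ``boundary_len_bp`` defaults to half the window size.
    """

    window_size: int
    merge_threshold: float = 0.35
    boundary_len_bp: int | None = None

    def __post_init__(self) -> None:
        if self.merge_threshold <= 0:
            raise ValueError("merge_threshold must be positive")
        if self.boundary_len_bp is None:
            self.boundary_len_bp = self.window_size // 2
        if self.boundary_len_bp <= 0:
            raise ValueError("boundary_len_bp must be positive")


@dataclass
class GeneScore:
    sample_id: str
    score: float
    rule: Rule


def _clipped(
    seglist: SegmentList, gene: GenomicInterval, grid: WindowGrid
) -> list[tuple[Segment, int]]:
    """Segments overlapping the gene (genomic order) with clipped bp lengths."""
    out = []
    for seg in sorted(seglist.segments, key=lambda s: s.start_window):
        span = GenomicInterval(
            grid.contig,
            grid.region_start + seg.start_window * grid.window_size,
            min(grid.region_start + seg.end_window * grid.window_size,
                grid.region_end),
        )
        ov = span.overlap(gene)
        if ov > 0:
            out.append((seg, ov))
    return out


def _weighted(sub: list[tuple[Segment, int]]) -> float:
    w = np.array([length for _, length in sub], dtype=float)
    m = np.array([seg.mean for seg, _ in sub])
    return float((w * m).sum() / w.sum())


def gene_score(
    seglist: SegmentList,
    gene: GenomicInterval,
    x_row: np.ndarray,
    grid: WindowGrid,
    params: ScoreParams,
) -> GeneScore:
    """Segmentation score of the gene for one sample (see module docstring)."""
    overlapping = _clipped(seglist, gene, grid)
    if not overlapping:
        raise ValueError(f"gene {gene.to_region()} does not overlap the grid")
    sid = seglist.sample_id

    if len(overlapping) == 1:
        return GeneScore(sid, overlapping[0][0].mean, Rule.SINGLE_SEGMENT)

    tau = params.merge_threshold
    means = np.array([seg.mean for seg, _ in overlapping])
    gain = means >= tau
    loss = means <= -tau

    # Majority class from the non-neutral segments; if both classes occur,
    # the more frequent one wins, with no unique majority -> score zero.
    n_gain, n_loss = int(gain.sum()), int(loss.sum())
    if n_gain > n_loss:
        majority = 1.0
    elif n_loss > n_gain:
        majority = -1.0
    elif n_gain == n_loss == 0:
        # All neutral: merge if the signs agree, else no clear direction.
        signs = np.sign(means[means != 0])
        if signs.size == 0 or (signs == signs[0]).all():
            return GeneScore(sid, _weighted(overlapping), Rule.SAME_SIGN_MERGE)
        return GeneScore(sid, 0.0, Rule.ZERO_DEFAULT)
    else:
        return GeneScore(sid, 0.0, Rule.ZERO_DEFAULT)

    discordant = np.flatnonzero(np.sign(means) == -majority)
    if discordant.size == 0:
        return GeneScore(sid, _weighted(overlapping), Rule.SAME_SIGN_MERGE)

    if discordant.size == 1:
        k = int(discordant[0])
        seg, clip_len = overlapping[k]
        at_boundary = k == 0 or k == len(overlapping) - 1
        if at_boundary and clip_len < params.boundary_len_bp:
            gene_windows = grid.windows_overlapping(gene)
            member = [
                j
                for j in range(seg.start_window, seg.end_window)
                if j in gene_windows
            ]
            vals = np.asarray(x_row, dtype=float)[member] if member else np.array([])
            vals = vals[~np.isnan(vals)]
            z = float(vals.mean()) if vals.size else 0.0
            if np.sign(z) == majority:
                others = [ov for i, ov in enumerate(overlapping) if i != k]
                return GeneScore(sid, _weighted(others), Rule.BOUNDARY_ZSCORE_RESCUE)
        return GeneScore(sid, 0.0, Rule.ZERO_DEFAULT)

    return GeneScore(sid, 0.0, Rule.ZERO_DEFAULT)


def pooled_gene_score(
    seglist: SegmentList, gene: GenomicInterval, grid: WindowGrid
) -> GeneScore:
    """Pooled-run score: segment mean if the gene sits in one segment, else 0.

    The split rule is structural — two segments with identical means still
    yield zero — because in the pooled run a split gene signals that the
    sample straddles distinct CN regions relative to the pooled average.
    """
    overlapping = _clipped(seglist, gene, grid)
    if not overlapping:
        raise ValueError(f"gene {gene.to_region()} does not overlap the grid")
    if len(overlapping) == 1:
        return GeneScore(seglist.sample_id, overlapping[0][0].mean,
                         Rule.SINGLE_SEGMENT)
    return GeneScore(seglist.sample_id, 0.0, Rule.ZERO_DEFAULT)
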