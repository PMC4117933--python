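"""Discovery of polymorphic regions from all samples' segmentations.

The union of every sample's breakpoints partitions the analysis region into
sub-regions; within one sample each sub-region is covered by exactly one
segment, so the per-sample value of a sub-region is that segment's mean with
no re-averaging error.  Cross-sample standard deviations (and a percentile
ladder) over sub-regions localize copy-number variable blocks: windows where
samples disagree strongly about their segment mean are exactly the windows
where copy number varies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .segment import SegmentList
from .windows import WindowGrid

PERCENTILE_LEVELS = (1, 5, 25, 50, 75, 95, 99)


@dataclass
class SubRegionProfile:
    """Sub-regions (window-index half-open) with cross-sample statistics."""

    grid: WindowGrid
    subregions: list[tuple[int, int]]
    values: np.ndarray  # (n_samples, n_subregions) covering-segment means
    sample_ids: list[str]
    sd: np.ndarray
    percentiles: pd.DataFrame  # columns p1, p5, ... per sub-region

    def to_frame(self) -> pd.DataFrame:
        g = self.grid
        rows = []
        for k, (lo, hi) in enumerate(self.subregions):
            start = g.region_start + lo * g.window_size
            end = min(g.region_start + hi * g.window_size, g.region_end)
            rows.append({"contig": g.contig, "start": start + 1, "end": end,
                         "start_window": lo, "end_window": hi, "sd": self.sd[k]})
        out = pd.DataFrame(rows)
        return pd.concat([out, self.percentiles.reset_index(drop=True)], axis=1)


@dataclass
class PolymorphicRegions:
    """High-SD runs and the (possibly absent) run overlapping the gene."""

    runs: list[GenomicInterval]
    gene_region: GenomicInterval | None

    @property
    def found(self) -> bool:
        return self.gene_region is not None


def derive_subregions(seglists: list[SegmentList]) -> list[tuple[int, int]]:
    """Sub-regions delimited by the union of all samples' breakpoints."""
    if not seglists:
        raise ValueError("no segment lists")
    n = seglists[0].n_windows
    if any(sl.n_windows != n for sl in seglists):
        raise ValueError("segment lists tile inconsistent grids")
    cuts = {0, n}
    for sl in seglists:
        cuts.update(sl.breakpoints)
    bounds = sorted(cuts)
    return list(zip(bounds[:-1], bounds[1:]))


def subregion_stats(
    seglists: list[SegmentList],
    subregions: list[tuple[int, int]],
    grid: WindowGrid,
    levels: tuple[int, ...] = PERCENTILE_LEVELS,
) -> SubRegionProfile:
    """Cross-sample SD and percentiles of covering-segment means per sub-region."""
    if len(seglists) < 2:
        raise ValueError("need at least 2 samples for cross-sample statistics")
    values = np.empty((len(seglists), len(subregions)))
    for s, sl in enumerate(seglists):
        starts = np.array([seg.start_window for seg in sl.segments])
        means = np.array([seg.mean for seg in sl.segments])
        # Sub-region boundaries are a superset of this sample's breakpoints,
        # so each sub-region lies inside exactly one segment.
        pos = np.searchsorted(starts, [lo for lo, _ in subregions], side="right") - 1
        values[s] = means[pos]
    sd = values.std(axis=0, ddof=1)
    pct = np.percentile(values, levels, axis=0)  # linear interpolation
    percentiles = pd.DataFrame(
        {f"p{lv}": pct[i] for i, lv in enumerate(levels)}
    )
    return SubRegionProfile(
        grid, list(subregions), values, [sl.sample_id for sl in seglists], sd,
        percentiles,
    )


def identify_polymorphic_region(
    profile: SubRegionProfile,
    gene: GenomicInterval,
    sd_threshold: float = 0.5,
    max_bridge_bp: int | None = None,
) -> PolymorphicRegions:
    """Locate the CN-variable region containing the gene.

    Maximal runs of sub-regions with SD >= ``sd_threshold`` are formed; runs
    separated by a low-SD gap shorter than ``max_bridge_bp`` (default: five
    window widths) are merged, making the visual "merge across a shallow SD
    dip" step reproducible.  The run overlapping the gene is returned along
    with every run; absence of an overlapping run is reported explicitly, not
    raised.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    g = profile.grid
    if max_bridge_bp is None:
        max_bridge_bp = 5 * g.window_size

    def span(lo_w: int, hi_w: int) -> GenomicInterval:
        return GenomicInterval(
            g.contig,
            g.region_start + lo_w * g.window_size,
            min(g.region_start + hi_w * g.window_size, g.region_end),
        )

    hot = profile.sd >= sd_threshold
    raw: list[list[int]] = []
    for k, flag in enumerate(hot):
        if flag:
            if raw and raw[-1][1] == k:
                raw[-1][1] = k + 1
            else:
                raw.append([k, k + 1])
    # Merge runs across short internal low-SD gaps.
    merged: list[list[int]] = []
    for lo, hi in raw:
        if merged:
            gap = span(profile.subregions[merged[-1][1] - 1][1],
                       profile.subregions[lo][0])
            if gap.length < max_bridge_bp:
                merged[-1][1] = hi
                continue
        merged.append([lo, hi])
    runs = [
        span(profile.subregions[lo][0], profile.subregions[hi - 1][1])
        for lo, hi in merged
    ]
    gene_region = next((r for r in runs if r.overlap(gene) > 0), None)
    return PolymorphicRegions(runs, gene_region)


def regions_to_bed(regions: list[GenomicInterval]) -> str:
    """BED text (0-based half-open) for a list of intervals."""
    return "".join(f"{r.contig}\t{r.start}\t{r.end}\n" for r in regions)
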