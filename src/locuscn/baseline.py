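"""Naive single-sample read-depth CN caller, for contrast.

Calls ``CN = round(2 * gene read density / regional median window density)``
using only the sample's own counts — no cross-sample reference.  In regions
whose counts are systematically depressed by multi-mapping losses this
estimator is biased downward by the mappability factor, which is exactly the
failure mode the cross-sample-standardized pipeline is built to avoid.
"""
from __future__ import annotations

import numpy as np

from .intervals import GenomicInterval
from .windows import CountMatrix


def naive_ratio_calls(counts: CountMatrix, gene: GenomicInterval) -> np.ndarray:
    """Per-sample ratio-to-2 CN estimates (round half away from zero)."""
    grid = counts.grid
    gene_windows = np.array(list(grid.windows_overlapping(gene)))
    if gene_windows.size == 0:
        raise ValueError(f"gene {gene.to_region()} does not overlap the grid")
    widths = grid.widths.astype(float)
    gene_bp = widths[gene_windows].sum()
    dens_gene = counts.counts[:, gene_windows].sum(axis=1) / gene_bp
    dens_med = np.median(counts.counts / widths[None, :], axis=1)
    if (dens_med == 0).any():
        raise ValueError("a sample has zero median window density")
    ratio = dens_gene / dens_med
    return np.floor(2.0 * ratio + 0.5).astype(int)
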