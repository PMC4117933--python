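"""Window grids and per-window read counting.

The analysis region is tiled with fixed-width, non-overlapping windows (the
last window may be short).  A read is assigned to the window containing its
leftmost aligned position, which keeps per-window counts additive and
unambiguous.  Counting defaults to ``min_mapq=0`` because at segmentally
duplicated loci the bulk of reads map with MAPQ 0 (multiple equally good
alignments) and filtering them would remove the copy-number signal itself.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-width tiling of an analysis region (0-based half-open)."""

    contig: str
    region_start: int
    region_end: int
    window_size: int

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.region_end <= self.region_start:
            raise ValueError("empty analysis region")

    @classmethod
    def from_region(cls, region: str, window_size: int) -> "WindowGrid":
        iv = GenomicInterval.from_region(region)
        return cls(iv.contig, iv.start, iv.end, window_size)

    @property
    def n_windows(self) -> int:
        return math.ceil((self.region_end - self.region_start) / self.window_size)

    @property
    def starts(self) -> np.ndarray:
        """0-based start position of every window."""
        return self.region_start + self.window_size * np.arange(self.n_windows)

    @property
    def widths(self) -> np.ndarray:
        """Width in bp of every window (last one may be short)."""
        s = self.starts
        return np.minimum(s + self.window_size, self.region_end) - s

    def window_span(self, j: int) -> GenomicInterval:
        s = self.region_start + j * self.window_size
        return GenomicInterval(self.contig, s, min(s + self.window_size, self.region_end))

    def window_of(self, pos: int) -> int:
        """Window index containing 0-based position ``pos`` (-1 if outside)."""
        if pos < self.region_start or pos >= self.region_end:
            return -1
        return (pos - self.region_start) // self.window_size

    def windows_overlapping(self, iv: GenomicInterval) -> range:
        """Range of window indices overlapping ``iv`` (empty if disjoint)."""
        if iv.contig != self.contig:
            return range(0)
        lo = max(iv.start, self.region_start)
        hi = min(iv.end, self.region_end)
        if hi <= lo:
            return range(0)
        j0 = (lo - self.region_start) // self.window_size
        j1 = (hi - 1 - self.region_start) // self.window_size + 1
        return range(j0, j1)

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.region_start, self.region_end)


@dataclass
class CountMatrix:
    """Samples x windows read counts over a :class:`WindowGrid`."""

    grid: WindowGrid
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_windows), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), self.grid.n_windows):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.grid.n_windows} windows"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def totals(self) -> np.ndarray:
        """Per-sample total read count over the region."""
        return self.counts.sum(axis=1)

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing}")
        rows = [index[s] for s in sample_ids]
        return CountMatrix(self.grid, list(sample_ids), self.counts[rows].copy())

    # -- TSV interchange ---------------------------------------------------
    # Header comment line carries the grid; the column header row holds the
    # 1-based window start positions; one row per sample, sample_id first.

    def to_tsv(self, path: str | os.PathLike) -> None:
        g = self.grid
        with open(path, "w") as fh:
            fh.write(
                f"# contig={g.contig}\tregion_start={g.region_start}"
                f"\tregion_end={g.region_end}\twindow_size={g.window_size}\n"
            )
            starts = g.starts + 1
            fh.write("sample_id\t" + "\t".join(str(s) for s in starts) + "\n")
            for sid, row in zip(self.sample_ids, self.counts):
                fh.write(sid + "\t" + "\t".join(str(int(c)) for c in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CountMatrix":
        with open(path) as fh:
            header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing grid header line")
        meta = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        grid = WindowGrid(
            meta["contig"],
            int(meta["region_start"]),
            int(meta["region_end"]),
            int(meta["window_size"]),
        )
        df = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
        counts = df.to_numpy(dtype=np.int64)
        return cls(grid, [str(s) for s in df.index], counts)


def count_reads_in_windows(
    alignments: Mapping[str, str | os.PathLike],
    grid: WindowGrid,
    min_mapq: int = 0,
) -> CountMatrix:
    """Count reads per window for each sample from indexed BAM files.

    Parameters
    ----------
    alignments
        Mapping of sample id to the path of a coordinate-sorted, indexed BAM
        restricted to (or at least covering) the analysis region.
    grid
        Window tiling of the analysis region.
    min_mapq
        Minimum mapping quality; reads below it are skipped.  The default of 0
        keeps multi-mapping (MAPQ 0) reads, which dominate at paralogous loci.

    A read is counted in the window containing its leftmost aligned position.
    Unmapped, secondary and duplicate-flagged reads are excluded.
    """
    import pysam

    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    sample_ids = list(alignments)
    counts = np.zeros((len(sample_ids), grid.n_windows), dtype=np.int64)
    for row, sid in enumerate(sample_ids):
        path = str(alignments[sid])
        with pysam.AlignmentFile(path, "rb") as bam:
            if not bam.has_index():
                raise FileNotFoundError(f"{path}: BAM index is missing")
            if grid.contig not in bam.references:
                raise ValueError(
                    f"{path}: contig {grid.contig!r} absent from BAM header"
                )
            for read in bam.fetch(grid.contig, grid.region_start, grid.region_end):
                if read.is_unmapped or read.is_secondary or read.is_duplicate:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                j = grid.window_of(read.reference_start)
                if j >= 0:
                    counts[row, j] += 1
    return CountMatrix(grid, sample_ids, counts)
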