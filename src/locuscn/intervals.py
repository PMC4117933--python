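"""Genomic interval handling.

Region strings follow the samtools convention ("chr:start-end", 1-based,
inclusive); internally every interval is 0-based half-open.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

_REGION_RE = re.compile(r"^(?P<contig>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


@dataclass(frozen=True)
class GenomicInterval:
    """A contiguous genomic interval (0-based, half-open)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: {self.contig}:{self.start}-{self.end}")

    @classmethod
    def from_region(cls, region: str) -> "GenomicInterval":
        """Parse a 1-based inclusive region string such as 'chr17:34623842-34625730'."""
        m = _REGION_RE.match(region.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {region!r}")
        start = int(m.group("start").replace(",", ""))
        end = int(m.group("end").replace(",", ""))
        if start < 1 or end < start:
            raise ValueError(f"invalid coordinates in region string {region!r}")
        return cls(m.group("contig"), start - 1, end)

    def to_region(self) -> str:
        """Render as a 1-based inclusive region string."""
        return f"{self.contig}:{self.start + 1}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 if disjoint or on different contigs)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )
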