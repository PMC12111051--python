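"""Shared genomic-interval data model.

All coordinates are 0-based half-open (BED-native) throughout the package;
GTF input is converted on ingest. Using a single convention everywhere
eliminates off-by-one drift between the motif, annotation and state layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class NarrowPeak(GenomicInterval):
    """ENCODE narrowPeak / broadPeak record.

    ``summit_offset`` is relative to ``start``; -1 means absent (broadPeak,
    or narrowPeak rows without a called summit).
    """

    signal_value: float = 0.0
    p_value: float = -1.0  # -log10
    q_value: float = -1.0  # -log10
    summit_offset: int = -1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.summit_offset != -1 and not (0 <= self.summit_offset < self.width):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of width {self.width}"
            )

    @property
    def summit(self) -> Optional[int]:
        """Absolute summit coordinate, or None if no summit was called."""
        if self.summit_offset < 0:
            return None
        return self.start + self.summit_offset


@dataclass
class GeneModel:
    """A gene body with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")

    @property
    def tss(self) -> int:
        """TSS coordinate: ``start`` on +, ``end - 1`` on - (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


def build_trees(intervals: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    """Index intervals per chromosome for ≥1 bp overlap queries."""
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees

def overlaps_any(
    chrom: str, start: int, end: int, trees: Dict[str, IntervalTree]
) -> bool:
    """True iff [start, end) overlaps any indexed interval by ≥1 bp."""
    tree = trees.get(chrom)
    if tree is None:
        return False
    return bool(tree.overlap(start, end))
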