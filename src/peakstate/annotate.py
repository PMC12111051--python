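"""Nearest-TSS annotation of peaks and distance binning.

Each peak is assigned the gene whose TSS is closest to the peak's reference
point (summit when called, otherwise midpoint), searching only within the
peak's chromosome. Distances are binned on absolute distance with half-open
edges; the defaults split peaks into <5 kb, 5-50 kb and >=50 kb from the
TSS, with the <5 kb bin subdivided at 0.5 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GeneModel, GenomicInterval, NarrowPeak


def _fmt_bp(bp: int) -> str:
    if bp % 1000 == 0:
        return f"{bp // 1000}kb"
    return f"{bp / 1000:g}kb"


@dataclass(frozen=True)
class DistanceBins:
    """Half-open absolute-distance bins partitioning [0, inf).

    ``edges`` are the primary cut points; ``sub_edges`` subdivide the first
    primary bin (fractions for sub-bins are reported relative to their
    parent bin, i.e. "the share of <5 kb peaks that lie within 0.5 kb").
    """

    edges: Tuple[int, ...] = (5_000, 50_000)
    sub_edges: Tuple[int, ...] = (500,)

    def __post_init__(self) -> None:
        if list(self.edges) != sorted(set(self.edges)) or any(e <= 0 for e in self.edges):
            raise ValueError("bin edges must be positive and strictly increasing")
        if self.sub_edges and (
            list(self.sub_edges) != sorted(set(self.sub_edges))
            or self.sub_edges[-1] >= self.edges[0]
        ):
            raise ValueError("sub-bin edges must increase and stay below the first edge")

    @property
    def labels(self) -> List[str]:
        labs = [f"<{_fmt_bp(self.edges[0])}"]
        for lo, hi in zip(self.edges, self.edges[1:]):
            labs.append(f"{_fmt_bp(lo)}-{_fmt_bp(hi)}")
        labs.append(f">={_fmt_bp(self.edges[-1])}")
        return labs

    @property
    def sub_labels(self) -> List[str]:
        if not self.sub_edges:
            return []
        cuts = (0,) + tuple(self.sub_edges) + (self.edges[0],)
        labs = [f"<{_fmt_bp(cuts[1])}"]
        for lo, hi in zip(cuts[1:], cuts[2:]):
            labs.append(f"{_fmt_bp(lo)}-{_fmt_bp(hi)}")
        return labs

    def bin_label(self, distance: int) -> str:
        idx = int(np.searchsorted(self.edges, distance, side="right"))
        return self.labels[idx]

    def sub_label(self, distance: int) -> Optional[str]:
        if not self.sub_edges or distance >= self.edges[0]:
            return None
        cuts = tuple(self.sub_edges)
        idx = int(np.searchsorted(cuts, distance, side="right"))
        return self.sub_labels[idx]


@dataclass
class PeakAnnotation:
    """A peak's nearest-gene assignment.

    ``signed_distance_bp`` is negative when the peak lies upstream of the
    TSS relative to the gene's strand; bins use the absolute distance.
    Peaks on chromosomes without genes carry ``gene_id=None`` and are
    flagged ``annotated=False``.
    """

    peak_name: str
    gene_id: Optional[str]
    distance_bp: Optional[int]
    signed_distance_bp: Optional[int]
    bin_label: Optional[str]
    annotated: bool = True


def peak_reference_point(p: GenomicInterval) -> int:
    """Summit if available, else the floor midpoint."""
    if isinstance(p, NarrowPeak) and p.summit is not None:
        return p.summit
    return (p.start + p.end) // 2


def annotate_nearest_tss(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    bins: DistanceBins = DistanceBins(),
) -> List[PeakAnnotation]:
    """Assign each peak to the nearest same-chromosome TSS.

    Ties on distance are broken by the lexicographically smallest gene_id;
    peaks on chromosomes with no genes are flagged unannotated rather than
    rejected.
    """
    by_chrom: Dict[str, Tuple[np.ndarray, List[GeneModel]]] = {}
    for g in sorted(genes, key=lambda g: (g.tss, g.gene_id)):
        by_chrom.setdefault(g.chrom, (None, []))[1].append(g)
    by_chrom = {
        c: (np.array([g.tss for g in gl], dtype=np.int64), gl)
        for c, (_, gl) in by_chrom.items()
    }

    out = []
    for p in peaks:
        entry = by_chrom.get(p.chrom)
        if entry is None:
            out.append(PeakAnnotation(p.name, None, None, None, None, annotated=False))
            continue
        tss_arr, gene_list = entry
        ref = peak_reference_point(p)
        dists = np.abs(tss_arr - ref)
        dmin = int(dists.min())
        candidates = [gene_list[i] for i in np.flatnonzero(dists == dmin)]
        best = min(candidates, key=lambda g: g.gene_id)
        signed = ref - best.tss if best.strand == "+" else best.tss - ref
        out.append(PeakAnnotation(p.name, best.gene_id, dmin, signed,
                                  bins.bin_label(dmin)))
    return out


@dataclass
class BinCounts:
    """Primary and sub-bin counts with fractions (as percentages)."""

    total_annotated: int
    primary_counts: Dict[str, int]
    primary_pct: Dict[str, float]
    sub_counts: Dict[str, int]
    sub_pct_of_parent: Dict[str, float]


def bin_distances(
    annotations: Sequence[PeakAnnotation], bins: DistanceBins = DistanceBins()
) -> BinCounts:
    """Count annotated peaks per distance bin.

    Primary percentages are of all annotated peaks; sub-bin percentages are
    of their parent (first primary) bin, mirroring "the share of <5 kb
    peaks that fall within 0.5 kb of the TSS".
    """
    from .io import round_percent

    dists = [a.distance_bp for a in annotations if a.annotated]
    primary = {lab: 0 for lab in bins.labels}
    sub = {lab: 0 for lab in bins.sub_labels}
    for d in dists:
        primary[bins.bin_label(d)] += 1
        s = bins.sub_label(d)
        if s is not None:
            sub[s] += 1
    total = len(dists)
    parent = primary[bins.labels[0]] if bins.labels else 0
    primary_pct = {
        lab: (round_percent(n, total) if total else 0.0) for lab, n in primary.items()
    }
    sub_pct = {
        lab: (round_percent(n, parent) if parent else 0.0) for lab, n in sub.items()
    }
    return BinCounts(total, primary, primary_pct, sub, sub_pct)
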