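"""Five-state chromatin classification of genes from mark/ATAC overlap.

A gene's regulatory state is called from the presence of four histone
post-translational modifications (H3K4me1, H3K4me3, H3K27me3, H3K27ac) and
ATAC accessibility over its evaluation windows:

=============  =======  =======  ========  =======  ====
state          H3K4me1  H3K4me3  H3K27me3  H3K27ac  ATAC
=============  =======  =======  ========  =======  ====
Active           +/or     +/or      -         +       +
Primed           +/or     +/or      -         -       +
Poised           +/or     +/or      +         -       +
Repressed         -        -        +         -       -
Closed           +/-      +/-       -        +/-      -
=============  =======  =======  ========  =======  ====

For Active/Primed/Poised, either K4 mark (or both) satisfies the K4
requirement. Rules are evaluated hierarchically in the order above, first
match wins; flag vectors matching no row are Unclassified and keep their
full flag vector for audit. Presence means >=1 bp overlap between the
mark's peak set and the gene's window: H3K27me3 is tested against the
unextended gene body, every other track against the union of the TSS
window (TSS +/- 2 kb) and the extended gene body (body +/- 5 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .intervals import GeneModel, GenomicInterval, build_trees

MARK_NAMES = ("H3K4me1", "H3K4me3", "H3K27me3", "H3K27ac", "ATAC")

#: Which window(s) each track is tested against. "gene_body" is the
#: unextended gene body; "union" is tss_window ∪ gene_window.
DEFAULT_WINDOW_POLICY: Dict[str, str] = {
    "H3K4me1": "union",
    "H3K4me3": "union",
    "H3K27me3": "gene_body",
    "H3K27ac": "union",
    "ATAC": "union",
}
WINDOW_CHOICES = ("tss_only", "gene_only", "union", "gene_body")


class ConfigurationError(ValueError):
    """A required mark track was not supplied."""


class GeneState(str, Enum):
    ACTIVE = "Active"
    PRIMED = "Primed"
    POISED = "Poised"
    REPRESSED = "Repressed"
    CLOSED = "Closed"
    UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class MarkPresence:
    """Overlap flags for one gene, in Table order."""

    k4me1: bool
    k4me3: bool
    k27me3: bool
    k27ac: bool
    atac: bool

    def as_tuple(self) -> Tuple[bool, bool, bool, bool, bool]:
        return (self.k4me1, self.k4me3, self.k27me3, self.k27ac, self.atac)


@dataclass(frozen=True)
class EvaluationWindows:
    """Per-gene evaluation windows, clamped to chromosome bounds."""

    chrom: str
    tss_window: Tuple[int, int]
    gene_window: Tuple[int, int]
    k27me3_window: Tuple[int, int]


def build_windows(
    g: GeneModel,
    tss_flank: int = 2_000,
    gene_flank: int = 5_000,
    chrom_length: Optional[int] = None,
) -> EvaluationWindows:
    """TSS +/- tss_flank, gene body +/- gene_flank, and the bare gene body."""
    if tss_flank < 0 or gene_flank < 0:
        raise ValueError("flanks must be >= 0")

    def clamp(lo: int, hi: int) -> Tuple[int, int]:
        lo = max(0, lo)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi

    tss = g.tss
    return EvaluationWindows(
        chrom=g.chrom,
        tss_window=clamp(tss - tss_flank, tss + tss_flank),
        gene_window=clamp(g.start - gene_flank, g.end + gene_flank),
        k27me3_window=(g.start, g.end),
    )


def _window_hit(tree: Optional[IntervalTree], lo: int, hi: int) -> bool:
    return tree is not None and lo < hi and bool(tree.overlap(lo, hi))


def mark_presence(
    g: GeneModel,
    marks: Mapping[str, Mapping[str, IntervalTree]],
    windows: EvaluationWindows,
    window_policy: Optional[Mapping[str, str]] = None,
) -> MarkPresence:
    """Overlap-test the five tracks against the gene's windows.

    ``marks`` maps track name -> per-chromosome interval trees (see
    :func:`peakstate.intervals.build_trees`); an empty track is legal but a
    missing one is a configuration error.
    """
    policy = dict(DEFAULT_WINDOW_POLICY)
    if window_policy:
        policy.update(window_policy)
    missing = [m for m in MARK_NAMES if m not in marks]
    if missing:
        raise ConfigurationError(f"mark track(s) not supplied: {missing}")

    flags = []
    for mark in MARK_NAMES:
        mode = policy[mark]
        if mode not in WINDOW_CHOICES:
            raise ConfigurationError(f"unknown window policy {mode!r} for {mark}")
        tree = marks[mark].get(windows.chrom)
        if mode == "tss_only":
            hit = _window_hit(tree, *windows.tss_window)
        elif mode == "gene_only":
            hit = _window_hit(tree, *windows.gene_window)
        elif mode == "gene_body":
            hit = _window_hit(tree, *windows.k27me3_window)
        else:  # union
            hit = _window_hit(tree, *windows.tss_window) or _window_hit(
                tree, *windows.gene_window
            )
        flags.append(hit)
    return MarkPresence(*flags)


def classify_state(m: MarkPresence) -> GeneState:
    """Hierarchical first-match-wins state call (see module docstring)."""
    k4 = m.k4me1 or m.k4me3
    if k4 and not m.k27me3 and m.k27ac and m.atac:
        return GeneState.ACTIVE
    if k4 and not m.k27me3 and not m.k27ac and m.atac:
        return GeneState.PRIMED
    if k4 and m.k27me3 and not m.k27ac and m.atac:
        return GeneState.POISED
    if not m.k4me1 and not m.k4me3 and m.k27me3 and not m.k27ac and not m.atac:
        return GeneState.REPRESSED
    if not m.k27me3 and not m.atac:
        return GeneState.CLOSED
    return GeneState.UNCLASSIFIED


def state_truth_table() -> Dict[Tuple[bool, bool, bool, bool, bool], GeneState]:
    """The total map from all 32 flag vectors to states (audit aid)."""
    return {
        flags: classify_state(MarkPresence(*flags))
        for flags in product((False, True), repeat=5)
    }


def apply_overrides(
    states: Dict[str, GeneState], overrides: Mapping[str, GeneState]
) -> Dict[str, GeneState]:
    """Apply a user-supplied manual-curation table of gene_id -> state.

    Automatic calls are never silently reassigned; overrides make any
    manual re-classification explicit and reproducible.
    """
    out = dict(states)
    for gene_id, state in overrides.items():
        if gene_id in out:
            out[gene_id] = state
    return out
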