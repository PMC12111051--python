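"""Degenerate-consensus motif scanning and hierarchical peak classification.

PAX-family transcription factors bind DNA through two independent domains:
the Paired Domain (PD), recognized here by the degenerate 6-mer
``TYMYSS`` (= T[T/C][C/A][C/T][G/C][G/C]) or the 7-mer ``GTCAYGG``, and the
Homeodomain (HD), whose major site is a TAAT/ATTA palindromic pair separated
by a 2-3 bp spacer (``TAATN{2,3}ATTA``). Peaks are classified hierarchically
by motif content: PDHD (both domains represented), PD, HD, or NONE.

Patterns are written in IUPAC one-letter code with at most one bounded gap
``N{a,b}`` (b <= 5), compile to a finite set of fixed-length words, and are
scanned on both strands with regular expressions. An ``N`` in the subject
sequence never satisfies a motif position, including gap positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml

from .genome import GenomeSequence
from .intervals import GenomicInterval, NarrowPeak, build_trees, overlaps_any

logger = logging.getLogger(__name__)

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT: Dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_BASE_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MAX_GAP = 5
_GAP_RE = re.compile(r"N\{(\d+),(\d+)\}")


class PatternError(ValueError):
    """An invalid motif pattern (bad IUPAC code or gap syntax)."""


class MotifClass(str, Enum):
    PD = "PD"
    HD = "HD"
    PDHD = "PDHD"
    NONE = "None"


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate consensus assigned to a binding-domain class."""

    label: str
    domain_class: str  # "PD" or "HD"
    pattern: str

    def __post_init__(self) -> None:
        if self.domain_class not in ("PD", "HD"):
            raise PatternError(f"{self.label}: domain_class must be PD or HD")


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence within a scanned sequence (forward coordinates)."""

    pattern_label: str
    domain_class: str
    offset: int
    strand: str
    matched_word: str


def revcomp(seq: str) -> str:
    return seq.translate(_BASE_COMPLEMENT)[::-1]


def _iupac_revcomp(word: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(word))


def expand_gap(pattern: str) -> List[str]:
    """Expand one bounded ``N{a,b}`` gap into fixed-length IUPAC words."""
    gaps = list(_GAP_RE.finditer(pattern))
    if re.search(r"N\{[^}]*$|N\{(?!\d+,\d+\})", pattern):
        raise PatternError(f"{pattern!r}: gap must be bounded as N{{a,b}}")
    if len(gaps) > 1:
        raise PatternError(f"{pattern!r}: at most one N{{a,b}} gap allowed")
    if not gaps:
        words = [pattern]
    else:
        m = gaps[0]
        a, b = int(m.group(1)), int(m.group(2))
        if a > b or b > MAX_GAP:
            raise PatternError(
                f"{pattern!r}: gap bounds must satisfy a <= b <= {MAX_GAP}"
            )
        words = [pattern[: m.start()] + "N" * k + pattern[m.end():]
                 for k in range(a, b + 1)]
    for w in words:
        bad = sorted(set(w) - set(IUPAC))
        if bad:
            raise PatternError(f"{pattern!r}: invalid IUPAC code(s) {bad}")
    return words


def _word_regex(word: str) -> str:
    # Character classes list explicit bases only, so subject N never matches.
    parts = []
    for code in word:
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


class CompiledPattern:
    """A pattern compiled to overlapping-match regexes for both strands."""

    def __init__(self, pattern: MotifPattern):
        self.pattern = pattern
        self.words = expand_gap(pattern.pattern)
        self.lengths = sorted({len(w) for w in self.words})
        fwd = "|".join(_word_regex(w) for w in self.words)
        rev = "|".join(_word_regex(_iupac_revcomp(w)) for w in self.words)
        # Zero-width lookahead so overlapping occurrences are all reported.
        self._fwd = re.compile(f"(?=({fwd}))")
        self._rev = re.compile(f"(?=({rev}))")

    def finditer(
        self, seq: str, strands: Sequence[str] = ("+", "-")
    ) -> Iterable[MotifMatch]:
        p = self.pattern
        if "+" in strands:
            for m in self._fwd.finditer(seq):
                yield MotifMatch(p.label, p.domain_class, m.start(), "+", m.group(1))
        if "-" in strands:
            for m in self._rev.finditer(seq):
                yield MotifMatch(p.label, p.domain_class, m.start(), "-", m.group(1))

    def matches_word(self, word: str) -> bool:
        """Exact membership: is ``word`` a forward-strand realization?"""
        return any(
            len(word) == len(w)
            and all(s in IUPAC[c] for s, c in zip(word, w))
            for w in self.words
        )


def compile_pattern(pattern: MotifPattern) -> CompiledPattern:
    return CompiledPattern(pattern)


def default_patterns() -> List[MotifPattern]:
    """The shipped pattern set.

    Only the major HD site is included: the minor HD variants reported in
    the binding-site literature lack a printed consensus here, so they are
    supplied per-run via a pattern config file when needed.
    """
    return [
        MotifPattern("PD_core", "PD", "TYMYSS"),
        MotifPattern("PD_GTCAYGG", "PD", "GTCAYGG"),
        MotifPattern("HD_major", "HD", "TAATN{2,3}ATTA"),
    ]


def load_patterns(path: str) -> List[MotifPattern]:
    """Load patterns from YAML (list of mappings) or TSV (label/class/pattern)."""
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
    else:
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if line.strip():
                    entries.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    pats = [MotifPattern(e["label"], e["domain_class"], e["pattern"]) for e in entries]
    labels = [p.label for p in pats]
    if len(set(labels)) != len(labels):
        raise PatternError(f"{path}: duplicate pattern labels")
    return pats


def scan_peak(
    seq: str,
    patterns: Sequence[CompiledPattern],
    strands: Sequence[str] = ("+", "-"),
) -> List[MotifMatch]:
    """All motif occurrences in ``seq``, deduplicated and sorted.

    Matches are deduplicated to (pattern label, offset, strand) keys —
    e.g. the two spacer lengths of the HD site at one offset count once —
    and sorted by offset then strand. Classification depends only on
    presence, so deduplication can never change a peak's class.
    """
    seq = seq.upper()
    seen = {}
    for cp in patterns:
        for match in cp.finditer(seq, strands):
            key = (match.pattern_label, match.offset, match.strand)
            seen.setdefault(key, match)
    return sorted(seen.values(), key=lambda m: (m.offset, m.strand, m.pattern_label))


def classify_motifs(matches: Iterable[MotifMatch]) -> MotifClass:
    """Hierarchical four-way classification from domain-class presence."""
    classes = {m.domain_class for m in matches}
    if "PD" in classes and "HD" in classes:
        return MotifClass.PDHD
    if "PD" in classes:
        return MotifClass.PD
    if "HD" in classes:
        return MotifClass.HD
    return MotifClass.NONE


def extend_peaks(
    peaks: Sequence[NarrowPeak],
    flank: int = 150,
    genome: Optional[GenomeSequence] = None,
) -> List[NarrowPeak]:
    """Extend each peak by ±``flank`` bp, clamped to chromosome bounds.

    The ±150 bp default captures the full mono-nucleosome of sequence
    context around a narrow TF peak. Names are preserved one-to-one and
    summit offsets are re-based so the absolute summit is unchanged.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for p in peaks:
        start = max(0, p.start - flank)
        end = p.end + flank
        if genome is not None and p.chrom in genome:
            end = min(end, genome.chrom_length(p.chrom))
        summit = p.summit
        summit_offset = -1
        if summit is not None and start <= summit < end:
            summit_offset = summit - start
        out.append(NarrowPeak(p.chrom, start, end, p.name, p.score, p.strand,
                              p.signal_value, p.p_value, p.q_value, summit_offset))
    return out


def filter_blacklist(
    peaks: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval],
) -> Tuple[List[GenomicInterval], List[GenomicInterval]]:
    """Partition peaks into (kept, removed) by ≥1 bp blacklist overlap.

    Intervals are half-open, so abutment is not overlap. Input order is
    preserved in both outputs.
    """
    trees = build_trees(blacklist)
    kept, removed = [], []
    for p in peaks:
        (removed if overlaps_any(p.chrom, p.start, p.end, trees) else kept).append(p)
    return kept, removed
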