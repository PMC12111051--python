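"""Genome sequence container with FASTA I/O and interval extraction."""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterator, Mapping

from pyfaidx import Fasta

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class GenomeSequence:
    """Uppercase DNA sequences keyed by chromosome name.

    Out-of-bounds extraction is clamped (with a logged warning) rather than
    rejected: downstream peak extension can legitimately overrun chromosome
    ends. Bases outside {A,C,G,T} are retained as-is; the motif scanner
    never matches N against a non-N motif position.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        """Read a FASTA file (first whitespace-delimited header token = name)."""
        if os.path.getsize(path) == 0 or not open(path).read(1024).strip():
            logger.warning("empty FASTA file %s: empty genome", path)
            return cls({})
        # pyfaidx builds/uses a .fai index and rejects duplicate headers.
        fa = Fasta(path, as_raw=True, duplicate_action="first")
        names = list(fa.keys())
        with open(path) as fh:
            headers = [ln[1:].split()[0] for ln in fh if ln.startswith(">")]
        dups = {h for h in headers if headers.count(h) > 1}
        if dups:
            raise ValueError(f"duplicate FASTA headers: {sorted(dups)}")
        return cls({name: str(fa[name][:]) for name in names})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def extract(self, iv: GenomicInterval) -> str:
        """Forward-strand sequence of ``iv``, clamped to chromosome bounds.

        Strand handling is deliberately left to the motif scanner, which
        scans both orientations itself.
        """
        if iv.chrom not in self._seqs:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome")
        seq = self._seqs[iv.chrom]
        lo, hi = max(0, iv.start), min(len(seq), iv.end)
        if (lo, hi) != (iv.start, iv.end):
            logger.warning(
                "interval %s:%d-%d clamped to %d-%d (chrom length %d)",
                iv.chrom, iv.start, iv.end, lo, hi, len(seq),
            )
        return seq[lo:hi]

    def to_fasta(self, path: str, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def extract_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    return genome.extract(iv)


def read_fasta(path: str) -> GenomeSequence:
    return GenomeSequence.from_fasta(path)
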