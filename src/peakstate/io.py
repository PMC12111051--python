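"""Readers and writers for BED-family peak files, gene models and tables.

BED/narrowPeak/broadPeak records are split line-by-line so that malformed
records can be reported with their line number; GTF ingest goes through
gffutils and FASTA through pyfaidx (see :mod:`peakstate.genome`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Dict, Iterable, List, Optional, Sequence, Union

import gffutils
import pandas as pd

from .intervals import GenomicInterval, GeneModel, NarrowPeak

logger = logging.getLogger(__name__)

INTERVAL_FORMATS = ("bed", "narrowPeak", "broadPeak")
_SKIP_PREFIXES = ("#", "track", "browser")


class ParseError(ValueError):
    """A malformed record, reported with its file and line number."""


def _parse_bed_fields(fields: Sequence[str], path: str, lineno: int, fmt: str):
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:{lineno}: need chrom/start/end integers: {exc}")
    if start >= end or start < 0:
        raise ParseError(f"{path}:{lineno}: invalid coordinates start={start} end={end}")
    name = fields[3] if len(fields) > 3 else "."
    score: Optional[float] = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else "."
    if fmt == "bed":
        return GenomicInterval(chrom, start, end, name, score, strand)
    # narrowPeak = BED6+4, broadPeak = BED6+3
    try:
        signal = float(fields[6]) if len(fields) > 6 else 0.0
        pval = float(fields[7]) if len(fields) > 7 else -1.0
        qval = float(fields[8]) if len(fields) > 8 else -1.0
        summit = int(fields[9]) if fmt == "narrowPeak" and len(fields) > 9 else -1
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad {fmt} statistics column: {exc}")
    try:
        return NarrowPeak(chrom, start, end, name, score, strand,
                          signal, pval, qval, summit)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}")


def read_intervals(
    path: str, format: str = "bed"
) -> List[Union[GenomicInterval, NarrowPeak]]:
    """Read a BED3/6, narrowPeak or broadPeak file, preserving input order.

    Track, browser and comment lines are skipped. Malformed lines raise
    :class:`ParseError` naming the line number.
    """
    if format not in INTERVAL_FORMATS:
        raise ValueError(f"unknown interval format {format!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            records.append(_parse_bed_fields(line.split("\t"), path, lineno, format))
    return records


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write BED6 (plus narrowPeak columns when the records carry them)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name, score, iv.strand]
            if isinstance(iv, NarrowPeak):
                cols += [f"{iv.signal_value:g}", f"{iv.p_value:g}",
                         f"{iv.q_value:g}", str(iv.summit_offset)]
            fh.write("\t".join(cols) + "\n")


def _genes_from_gtf(path: str) -> List[GeneModel]:
    db = gffutils.create_db(
        path, ":memory:", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ParseError(f"{path}: gene at {feat.seqid}:{feat.start} lacks strand")
        gene_id = feat.attributes["gene_id"][0]
        # GTF is 1-based inclusive; internal coordinates are 0-based half-open.
        genes.append(GeneModel(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return genes


def _genes_from_bed(path: str) -> List[GeneModel]:
    genes = []
    for iv in read_intervals(path, "bed"):
        if iv.strand not in ("+", "-"):
            raise ParseError(f"{path}: gene {iv.name} lacks strand")
        genes.append(GeneModel(iv.name, iv.chrom, iv.start, iv.end, iv.strand))
    return genes


def read_gene_models(path: str, format: str = "gtf") -> List[GeneModel]:
    """Read gene models from GTF (type ``gene``) or BED6/BED12 (one row/gene)."""
    if format == "gtf":
        genes = _genes_from_gtf(path)
    elif format in ("bed6", "bed12", "bed"):
        genes = _genes_from_bed(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    seen: Dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = sorted(gid for gid, n in seen.items() if n > 1)
    if dups:
        raise ParseError(f"{path}: duplicate gene_id(s): {dups}")
    return genes


def round_percent(count: Union[int, float], total: Union[int, float]) -> float:
    """count/total as a percentage, one decimal, round-half-to-even."""
    if total == 0:
        raise ZeroDivisionError("cannot compute a percentage of zero records")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def _to_record(rec) -> Dict:
    if is_dataclass(rec):
        return asdict(rec)
    if isinstance(rec, dict):
        return dict(rec)
    raise TypeError(f"cannot serialize record of type {type(rec)}")


def write_table(
    records: Sequence, path: str, format: str = "tsv",
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write records sharing a schema as TSV or JSON.

    Column order follows the first record (or ``columns`` for an empty
    list, giving a header-only file); columns named ``*_pct`` or
    ``*percent*`` are written with one decimal place.
    """
    rows = [_to_record(r) for r in records]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2, default=str)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown table format {format!r}")
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        if col.endswith("_pct") or "percent" in col:
            df[col] = df[col].map(lambda v: f"{v:.1f}")
    df.to_csv(path, sep="\t", index=False)
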