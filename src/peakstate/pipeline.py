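"""End-to-end orchestration: peaks + genome + annotation -> classified tables.

Stage order: extend peaks (±150 bp) -> blacklist-filter the extended
windows -> extract sequence -> motif scan/classify -> nearest-TSS
annotation -> per-gene mark presence and state call -> join -> summarize.
The effective configuration is serialized into the output directory so a
run can be reproduced from its own outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import annotate, io, motifs, report, states
from .annotate import DistanceBins
from .genome import GenomeSequence, read_fasta
from .intervals import GeneModel, NarrowPeak, build_trees
from .motifs import MotifClass
from .report import ClassifiedPeak, SummaryReport
from .states import ConfigurationError, GeneState

logger = logging.getLogger(__name__)

PER_PEAK_SCHEMA = "peakstate.per_peak.v1"
PER_GENE_SCHEMA = "peakstate.per_gene.v1"


@dataclass
class RunConfig:
    peaks: str = ""
    genome: str = ""
    genes: str = ""
    marks: Dict[str, str] = field(default_factory=dict)  # mark name -> BED path
    blacklist: Optional[str] = None
    patterns: Optional[str] = None
    state_overrides: Optional[str] = None
    outdir: str = "peakstate_out"
    flank: int = 150
    tss_flank: int = 2_000
    gene_flank: int = 5_000
    bin_edges: Tuple[int, ...] = (5_000, 50_000)
    sub_bin_edges: Tuple[int, ...] = (500,)
    strand: str = "both"  # both|forward
    gene_format: str = "gtf"
    window_policy: Dict[str, str] = field(default_factory=dict)
    nonactive_includes_unclassified: bool = True
    plots: bool = False

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["bin_edges"] = list(self.bin_edges)
        d["sub_bin_edges"] = list(self.sub_bin_edges)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("bin_edges", "sub_bin_edges"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _validate_inputs(cfg: RunConfig) -> None:
    """Fail on missing inputs before any computation starts."""
    missing = []
    for label, path in [("peaks", cfg.peaks), ("genome", cfg.genome),
                        ("genes", cfg.genes)]:
        if not path or not os.path.exists(path):
            missing.append(f"{label}: {path!r}")
    for mark in states.MARK_NAMES:
        path = cfg.marks.get(mark)
        if not path or not os.path.exists(path):
            missing.append(f"{mark}: {path!r}")
    for label, path in [("blacklist", cfg.blacklist), ("patterns", cfg.patterns),
                        ("state_overrides", cfg.state_overrides)]:
        if path and not os.path.exists(path):
            missing.append(f"{label}: {path!r}")
    if missing:
        raise ConfigurationError("missing input file(s): " + "; ".join(missing))


def _load_overrides(path: str) -> Dict[str, GeneState]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["gene_id"]): GeneState(r["state"]) for _, r in df.iterrows()
    }


def run_classify(cfg: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline; returns the in-memory results and writes
    per-peak/per-gene tables plus the summary report to ``cfg.outdir``."""
    _validate_inputs(cfg)
    os.makedirs(cfg.outdir, exist_ok=True)
    strands = ("+", "-") if cfg.strand == "both" else ("+",)

    logger.info("reading inputs")
    genome = read_fasta(cfg.genome)
    peaks = [p for p in io.read_intervals(cfg.peaks, "narrowPeak")]
    genes = io.read_gene_models(cfg.genes, cfg.gene_format)
    pattern_set = (motifs.load_patterns(cfg.patterns) if cfg.patterns
                   else motifs.default_patterns())
    compiled = [motifs.compile_pattern(p) for p in pattern_set]

    logger.info("extending %d peaks by ±%d bp", len(peaks), cfg.flank)
    extended = motifs.extend_peaks(peaks, cfg.flank, genome)

    removed_names: set = set()
    if cfg.blacklist:
        blacklist = io.read_intervals(cfg.blacklist, "bed")
        kept_ext, removed_ext = motifs.filter_blacklist(extended, blacklist)
        removed_names = {p.name for p in removed_ext}
        logger.info("blacklist filtering removed %d peak(s)", len(removed_ext))
    else:
        kept_ext = extended
    kept = [p for p in peaks if p.name not in removed_names]

    logger.info("scanning %d peaks for motifs", len(kept))
    motif_class: Dict[str, MotifClass] = {}
    for ext in kept_ext:
        seq = genome.extract(ext)
        matches = motifs.scan_peak(seq, compiled, strands)
        motif_class[ext.name] = motifs.classify_motifs(matches)

    logger.info("annotating nearest TSS")
    bins = DistanceBins(cfg.bin_edges, cfg.sub_bin_edges)
    annotations = annotate.annotate_nearest_tss(kept, genes, bins)
    bin_counts = annotate.bin_distances(annotations, bins)

    logger.info("classifying gene states")
    gene_by_id = {g.gene_id: g for g in genes}
    associated = sorted({a.gene_id for a in annotations if a.annotated})
    mark_trees = {
        mark: build_trees(io.read_intervals(path, "bed"))
        for mark, path in cfg.marks.items()
    }
    flags_by_gene: Dict[str, states.MarkPresence] = {}
    state_by_gene: Dict[str, GeneState] = {}
    for gid in associated:
        g = gene_by_id[gid]
        win = states.build_windows(g, cfg.tss_flank, cfg.gene_flank,
                                   genome.chrom_length(g.chrom) if g.chrom in genome
                                   else None)
        flags = states.mark_presence(g, mark_trees, win, cfg.window_policy)
        flags_by_gene[gid] = flags
        state_by_gene[gid] = states.classify_state(flags)
    if cfg.state_overrides:
        state_by_gene = states.apply_overrides(
            state_by_gene, _load_overrides(cfg.state_overrides))

    classified: List[ClassifiedPeak] = []
    for p, a in zip(kept, annotations):
        classified.append(ClassifiedPeak(
            name=p.name, chrom=p.chrom, start=p.start, end=p.end,
            motif_class=motif_class[p.name],
            gene_id=a.gene_id, distance_bp=a.distance_bp, bin_label=a.bin_label,
            state=state_by_gene.get(a.gene_id) if a.annotated else None,
        ))

    summary = report.summarize(
        classified, bin_counts,
        nonactive_includes_unclassified=cfg.nonactive_includes_unclassified,
    )
    _write_outputs(cfg, classified, flags_by_gene, state_by_gene, summary)
    return {
        "classified": classified,
        "summary": summary,
        "states": state_by_gene,
        "flags": flags_by_gene,
        "bin_counts": bin_counts,
        "n_blacklisted": len(removed_names),
    }


def _write_outputs(cfg, classified, flags_by_gene, state_by_gene, summary) -> None:
    per_peak = [{
        "schema": PER_PEAK_SCHEMA, "name": c.name, "chrom": c.chrom,
        "start": c.start, "end": c.end, "motif_class": c.motif_class.value,
        "gene_id": c.gene_id if c.gene_id is not None else "",
        "distance_bp": c.distance_bp if c.distance_bp is not None else -1,
        "bin_label": c.bin_label or "",
        "state": c.state.value if c.state is not None else "",
    } for c in classified]
    io.write_table(per_peak, os.path.join(cfg.outdir, "per_peak.tsv"))

    per_gene = [{
        "schema": PER_GENE_SCHEMA, "gene_id": gid,
        "k4me1": flags.k4me1, "k4me3": flags.k4me3, "k27me3": flags.k27me3,
        "k27ac": flags.k27ac, "atac": flags.atac,
        "state": state_by_gene[gid].value,
    } for gid, flags in sorted(flags_by_gene.items())]
    io.write_table(per_gene, os.path.join(cfg.outdir, "per_gene.tsv"))

    report.render_report(summary, cfg.outdir, peaks=classified, plots=cfg.plots)
    cfg.to_yaml(os.path.join(cfg.outdir, "config.yaml"))


class SchemaError(ValueError):
    """A per-peak table with an unrecognized schema version."""


def load_per_peak(path: str) -> List[ClassifiedPeak]:
    """Read a per_peak.tsv back into classified-peak records."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if "schema" not in df.columns or not (df["schema"] == PER_PEAK_SCHEMA).all():
        found = sorted(set(df.get("schema", ["<none>"])))
        raise SchemaError(f"{path}: expected schema {PER_PEAK_SCHEMA}, found {found}")
    out = []
    for _, r in df.iterrows():
        annotated = r["gene_id"] != ""
        out.append(ClassifiedPeak(
            name=str(r["name"]), chrom=str(r["chrom"]),
            start=int(r["start"]), end=int(r["end"]),
            motif_class=MotifClass(r["motif_class"]),
            gene_id=str(r["gene_id"]) if annotated else None,
            distance_bp=int(r["distance_bp"]) if annotated else None,
            bin_label=str(r["bin_label"]) if annotated else None,
            state=GeneState(r["state"]) if r["state"] else None,
        ))
    return out


def run_report(per_peak_path: str, outdir: str,
               nonactive_includes_unclassified: bool = True) -> SummaryReport:
    """Recompute all summaries from a per-peak table without re-scanning."""
    classified = load_per_peak(per_peak_path)
    bins = DistanceBins()
    anns = [
        annotate.PeakAnnotation(c.name, c.gene_id, c.distance_bp, c.distance_bp,
                                c.bin_label, annotated=c.gene_id is not None)
        for c in classified
    ]
    bin_counts = annotate.bin_distances(anns, bins)
    summary = report.summarize(
        classified, bin_counts,
        nonactive_includes_unclassified=nonactive_includes_unclassified,
    )
    os.makedirs(outdir, exist_ok=True)
    report.render_report(summary, outdir, peaks=classified)
    return summary
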