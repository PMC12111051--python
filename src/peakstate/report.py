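"""Count/percentage summaries and motif x state cross-tabulations.

Percentages are count/total x 100, rounded to one decimal with
round-half-to-even. The "Non-Active" aggregate is every state other than
Active; by default this includes Unclassified (reported separately as
well), with a toggle to exclude Unclassified and reproduce accountings in
which unassignable genes were manually resolved first.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .annotate import BinCounts
from .io import round_percent, write_table
from .motifs import MotifClass
from .states import GeneState

SCHEMA_VERSION = "peakstate.summary.v1"

MOTIF_ORDER = [MotifClass.PD, MotifClass.HD, MotifClass.PDHD, MotifClass.NONE]
STATE_ORDER = [
    GeneState.ACTIVE, GeneState.PRIMED, GeneState.POISED,
    GeneState.REPRESSED, GeneState.CLOSED, GeneState.UNCLASSIFIED,
]


@dataclass
class ClassifiedPeak:
    """The fully joined per-peak record behind every summary table.

    Unannotated peaks (no gene on the chromosome) carry ``gene_id=None``
    and ``state=None``; they are excluded from state percentages and
    counted separately — never silently dropped.
    """

    name: str
    chrom: str
    start: int
    end: int
    motif_class: MotifClass
    gene_id: Optional[str]
    distance_bp: Optional[int]
    bin_label: Optional[str]
    state: Optional[GeneState]


@dataclass
class SummaryReport:
    total_peaks: int
    n_unannotated: int
    motif_counts: Dict[str, int]
    motif_pct: Dict[str, float]
    state_counts: Dict[str, int]
    state_pct: Dict[str, float]
    active_count: int
    active_pct: float
    nonactive_count: int
    nonactive_pct: float
    hd_containing_count: int
    hd_containing_pct: float
    nonactive_by_motif: Dict[str, int]
    nonactive_nonpd_count: int
    nonactive_nonpd_pct: float
    unclassified_count: int
    unclassified_pct: float
    nonactive_includes_unclassified: bool
    distance_bins: Optional[BinCounts] = None


def summarize(
    peaks: Sequence[ClassifiedPeak],
    distance_bins: Optional[BinCounts] = None,
    nonactive_includes_unclassified: bool = True,
) -> SummaryReport:
    """Aggregate per-peak records into the count/percentage report.

    The HD-containing aggregate counts peaks whose class is HD or PDHD
    (an HD site alone, or coupled with a PD site). State percentages are
    over state-classified peaks; motif percentages over all peaks.
    """
    if not peaks:
        raise ValueError("cannot summarize an empty peak list")
    total = len(peaks)

    motif_counts = {mc.value: 0 for mc in MOTIF_ORDER}
    for p in peaks:
        motif_counts[p.motif_class.value] += 1
    motif_pct = {k: round_percent(v, total) for k, v in motif_counts.items()}

    with_state = [p for p in peaks if p.state is not None]
    n_unannot = total - len(with_state)
    n_state = len(with_state)
    state_counts = {s.value: 0 for s in STATE_ORDER}
    for p in with_state:
        state_counts[p.state.value] += 1
    state_pct = {
        k: (round_percent(v, n_state) if n_state else 0.0)
        for k, v in state_counts.items()
    }

    active = [p for p in with_state if p.state is GeneState.ACTIVE]
    nonactive = [p for p in with_state if p.state is not GeneState.ACTIVE]
    if not nonactive_includes_unclassified:
        nonactive = [p for p in nonactive if p.state is not GeneState.UNCLASSIFIED]
    n_active, n_nonactive = len(active), len(nonactive)

    hd_containing = motif_counts[MotifClass.HD.value] + motif_counts[MotifClass.PDHD.value]
    nonactive_by_motif = {mc.value: 0 for mc in MOTIF_ORDER}
    for p in nonactive:
        nonactive_by_motif[p.motif_class.value] += 1
    nonactive_nonpd = n_nonactive - nonactive_by_motif[MotifClass.PD.value]

    return SummaryReport(
        total_peaks=total,
        n_unannotated=n_unannot,
        motif_counts=motif_counts,
        motif_pct=motif_pct,
        state_counts=state_counts,
        state_pct=state_pct,
        active_count=n_active,
        active_pct=round_percent(n_active, n_state) if n_state else 0.0,
        nonactive_count=n_nonactive,
        nonactive_pct=round_percent(n_nonactive, n_state) if n_state else 0.0,
        hd_containing_count=hd_containing,
        hd_containing_pct=round_percent(hd_containing, total),
        nonactive_by_motif=nonactive_by_motif,
        nonactive_nonpd_count=nonactive_nonpd,
        nonactive_nonpd_pct=(
            round_percent(nonactive_nonpd, n_nonactive) if n_nonactive else 0.0
        ),
        unclassified_count=state_counts[GeneState.UNCLASSIFIED.value],
        unclassified_pct=(
            round_percent(state_counts[GeneState.UNCLASSIFIED.value], n_state)
            if n_state else 0.0
        ),
        nonactive_includes_unclassified=nonactive_includes_unclassified,
        distance_bins=distance_bins,
    )


def crosstab_motif_state(peaks: Sequence[ClassifiedPeak]) -> pd.DataFrame:
    """Motif class x gene state count matrix with row/column margins.

    Unannotated peaks appear in an explicit "(unannotated)" column so the
    grand total still equals the number of input peaks.
    """
    if not peaks:
        raise ValueError("cannot cross-tabulate an empty peak list")
    rows = [mc.value for mc in MOTIF_ORDER]
    cols = [s.value for s in STATE_ORDER] + ["(unannotated)"]
    tab = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for p in peaks:
        col = p.state.value if p.state is not None else "(unannotated)"
        tab.loc[p.motif_class.value, col] += 1
    tab["total"] = tab.sum(axis=1)
    tab.loc["total"] = tab.sum(axis=0)
    return tab


def crosstab_row_percentages(tab: pd.DataFrame) -> pd.DataFrame:
    """Row percentages of a crosstab (each motif row sums to ~100)."""
    body = tab.drop(index="total").drop(columns="total")
    totals = tab.drop(index="total")["total"]
    out = body.copy().astype(float)
    for row in body.index:
        t = int(totals[row])
        out.loc[row] = [round_percent(int(v), t) if t else 0.0 for v in body.loc[row]]
    return out


def _report_dict(report: SummaryReport) -> Dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "total_peaks": report.total_peaks,
        "n_unannotated": report.n_unannotated,
        "motif_counts": report.motif_counts,
        "motif_pct": report.motif_pct,
        "state_counts": report.state_counts,
        "state_pct": report.state_pct,
        "active_count": report.active_count,
        "active_pct": report.active_pct,
        "nonactive_count": report.nonactive_count,
        "nonactive_pct": report.nonactive_pct,
        "hd_containing_count": report.hd_containing_count,
        "hd_containing_pct": report.hd_containing_pct,
        "nonactive_by_motif": report.nonactive_by_motif,
        "nonactive_nonpd_count": report.nonactive_nonpd_count,
        "nonactive_nonpd_pct": report.nonactive_nonpd_pct,
        "unclassified_count": report.unclassified_count,
        "unclassified_pct": report.unclassified_pct,
        "nonactive_includes_unclassified": report.nonactive_includes_unclassified,
    }
    if report.distance_bins is not None:
        b = report.distance_bins
        d["distance_bins"] = {
            "total_annotated": b.total_annotated,
            "primary_counts": b.primary_counts,
            "primary_pct": b.primary_pct,
            "sub_counts": b.sub_counts,
            "sub_pct_of_parent": b.sub_pct_of_parent,
        }
    return d


def render_report(
    report: SummaryReport,
    outdir: str,
    peaks: Optional[Sequence[ClassifiedPeak]] = None,
    plots: bool = False,
) -> List[str]:
    """Write the deterministic report file set; bar charts only on request."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    path = os.path.join(outdir, "summary.json")
    with open(path, "w") as fh:
        json.dump(_report_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(path)

    motif_rows = [
        {"motif_class": k, "count": report.motif_counts[k], "pct": report.motif_pct[k]}
        for k in report.motif_counts
    ]
    path = os.path.join(outdir, "motif_counts.tsv")
    write_table(motif_rows, path)
    written.append(path)

    state_rows = [
        {"state": k, "count": report.state_counts[k], "pct": report.state_pct[k]}
        for k in report.state_counts
    ]
    path = os.path.join(outdir, "state_counts.tsv")
    write_table(state_rows, path)
    written.append(path)

    if peaks is not None:
        tab = crosstab_motif_state(peaks)
        path = os.path.join(outdir, "crosstab.tsv")
        tab.to_csv(path, sep="\t", index_label="motif_class")
        written.append(path)

    if report.distance_bins is not None:
        b = report.distance_bins
        rows = [
            {"bin": lab, "count": b.primary_counts[lab], "pct": b.primary_pct[lab]}
            for lab in b.primary_counts
        ] + [
            {"bin": lab, "count": b.sub_counts[lab], "pct": b.sub_pct_of_parent[lab]}
            for lab in b.sub_counts
        ]
        path = os.path.join(outdir, "distance_bins.tsv")
        write_table(rows, path)
        written.append(path)

    if plots:
        written += _render_plots(report, outdir)
    return written


def _render_plots(report: SummaryReport, outdir: str) -> List[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for stem, counts in (
        ("motif_counts", report.motif_counts),
        ("state_counts", report.state_counts),
    ):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(list(counts), list(counts.values()), color="0.4")
        ax.set_ylabel("peaks")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        path = os.path.join(outdir, f"{stem}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
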