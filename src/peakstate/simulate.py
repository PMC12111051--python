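"""Self-contained synthetic datasets with known ground truth.

The generator emulates the data the classification pipeline consumes: a
small multi-chromosome genome, gene models with TSSs, TF peaks carrying
planted PD/HD/PDHD/no-motif sequences at controlled fractions placed at
controlled distances from their target TSS, and histone/ATAC interval sets
constructed to realize each chromatin state exactly. In motif-scrubbed
mode the background provably contains no chance motif hit, so a pipeline
run must recover the planted truth with zero discrepancies.

A single global seed drives independent per-stage substreams (genome,
genes, peaks, states, decoys), so e.g. changing the peak count does not
perturb the genome.

What this does *not* emulate: read-level noise, realistic peak shapes or
signal values, overlapping genes, repeat content, or chromatin-state
ambiguity — planted marks sit strictly inside or outside their windows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .annotate import DistanceBins
from .genome import GenomeSequence
from .intervals import GeneModel, GenomicInterval, NarrowPeak
from .io import write_bed
from .motifs import (
    IUPAC, CompiledPattern, MotifClass, MotifPattern, compile_pattern,
    classify_motifs, default_patterns, expand_gap, scan_peak, _iupac_revcomp,
)
from .states import (
    GeneState, MarkPresence, MARK_NAMES, build_windows, classify_state,
    state_truth_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = {b: i for i, b in enumerate("ACGT")}

GUARD = 10  # bp kept clear between extended peak windows


class ScrubError(RuntimeError):
    """Motif scrubbing failed to converge (pattern set too dense for the
    background); retry with more scrub iterations or sparser patterns."""


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Study-like defaults: peak and gene counts, class/state/distance
    mixtures and genome scale mirror the source study's printed
    proportions at desk scale (see docs/methods.md for the rationale
    behind each default)."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 4_800_000
    n_genes: int = 760
    n_isolated_genes: int = 40
    gene_length: Tuple[int, int] = (2_000, 5_000)
    n_peaks: int = 837
    peak_width: Tuple[int, int] = (150, 300)
    flank: int = 150
    gc: float = 0.41
    scrub_motifs: bool = True
    scrub_max_iter: int = 60
    n_decoy_peaks: int = 0
    motif_class_fractions: Dict[str, float] = field(
        default_factory=lambda: {"PD": 0.817, "HD": 0.005, "PDHD": 0.162, "None": 0.016}
    )
    state_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "Active": 0.85, "Primed": 0.04, "Poised": 0.03,
            "Repressed": 0.02, "Closed": 0.03, "Unclassified": 0.03,
        }
    )
    #: (lo, hi, weight): distance of the peak reference point from its
    #: target TSS is drawn uniformly from [lo, hi) with probability weight.
    distance_profile: Tuple[Tuple[int, int, float], ...] = (
        (0, 500, 0.55),
        (500, 5_000, 0.06),
        (5_000, 50_000, 0.259),
        (50_000, 60_000, 0.131),
    )

    def __post_init__(self) -> None:
        for name, fracs in (
            ("motif_class_fractions", self.motif_class_fractions.values()),
            ("state_fractions", self.state_fractions.values()),
            ("distance_profile", [w for _, _, w in self.distance_profile]),
        ):
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if not (0 <= self.n_isolated_genes <= self.n_genes):
            raise ValueError("need 0 <= n_isolated_genes <= n_genes")

    @property
    def base_probs(self) -> np.ndarray:
        g = self.gc
        return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gene_length" in raw:
            raw["gene_length"] = tuple(raw["gene_length"])
        if "peak_width" in raw:
            raw["peak_width"] = tuple(raw["peak_width"])
        if "distance_profile" in raw:
            raw["distance_profile"] = tuple(tuple(e) for e in raw["distance_profile"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["gene_length"] = list(self.gene_length)
        d["peak_width"] = list(self.peak_width)
        d["distance_profile"] = [list(e) for e in self.distance_profile]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted truth: per-peak motif class / nearest gene / distance, and
    per-gene state with the realized flag vector."""

    peaks: pd.DataFrame
    genes: pd.DataFrame


# ---------------------------------------------------------------------------
# vectorized motif machinery on encoded arrays

def _pattern_words(patterns: Sequence[MotifPattern]) -> List[str]:
    """All fixed-length IUPAC words realized by the patterns, both strands."""
    words = []
    for p in patterns:
        for w in expand_gap(p.pattern):
            words.append(w)
            words.append(_iupac_revcomp(w))
    return sorted(set(words))


def _word_masks(word: str) -> List[np.ndarray]:
    masks = []
    for code in word:
        m = np.zeros(4, dtype=bool)
        for b in IUPAC[code]:
            m[_ENCODE[b]] = True
        masks.append(m)
    return masks


def _match_starts(arr: np.ndarray, masks: List[np.ndarray]) -> np.ndarray:
    """Boolean array of word match-start positions in the encoded array."""
    L = len(masks)
    n = arr.size
    if n < L:
        return np.zeros(0, dtype=bool)
    acc = masks[0][arr[: n - L + 1]]
    for i in range(1, L):
        acc &= masks[i][arr[i : n - L + 1 + i]]
    return acc


def _match_cover(arr: np.ndarray, word_masks: List[List[np.ndarray]]) -> np.ndarray:
    """Positions covered by any match of any word (for scrub resampling)."""
    n = arr.size
    diff = np.zeros(n + 1, dtype=np.int32)
    for masks in word_masks:
        starts = np.flatnonzero(_match_starts(arr, masks))
        if starts.size:
            L = len(masks)
            np.add.at(diff, starts, 1)
            np.add.at(diff, starts + L, -1)
    return np.cumsum(diff[:-1]) > 0


def _scrub(
    arr: np.ndarray,
    word_masks: List[List[np.ndarray]],
    rng: np.random.Generator,
    probs: np.ndarray,
    frozen: Optional[np.ndarray] = None,
    max_iter: int = 60,
) -> None:
    """Resample matching windows in place until no word matches remain.

    ``frozen`` positions (planted motifs) are never resampled; a match
    whose every position is frozen is unremovable and raises ScrubError.
    """
    for _ in range(max_iter):
        cover = _match_cover(arr, word_masks)
        if not cover.any():
            return
        if frozen is not None:
            cover &= ~frozen
            if not cover.any():
                raise ScrubError("match lies entirely within frozen positions")
        idx = np.flatnonzero(cover)
        arr[idx] = rng.choice(4, size=idx.size, p=probs)
    raise ScrubError(
        f"scrubbing did not converge in {max_iter} iterations; "
        "increase scrub_max_iter or reduce pattern density"
    )


def _realize_word(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """Sample one concrete DNA realization of a degenerate pattern."""
    words = expand_gap(pattern.pattern)
    word = words[int(rng.integers(len(words)))]
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in word)


def _encode_word(word: str) -> np.ndarray:
    return np.array([_ENCODE[b] for b in word], dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


# ---------------------------------------------------------------------------
# generator stages

def make_background_genome(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    patterns: Optional[Sequence[MotifPattern]] = None,
) -> Dict[str, np.ndarray]:
    """I.i.d. background at the configured GC, optionally motif-scrubbed.

    Returns mutable encoded arrays (A,C,G,T = 0..3) keyed by chromosome;
    use :func:`arrays_to_genome` for the string container.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[0])
    if patterns is None:
        patterns = default_patterns()
    word_masks = [_word_masks(w) for w in _pattern_words(patterns)]
    chroms: Dict[str, np.ndarray] = {}
    for i in range(cfg.n_chroms):
        arr = rng.choice(4, size=cfg.chrom_length, p=cfg.base_probs).astype(np.uint8)
        if cfg.scrub_motifs:
            _scrub(arr, word_masks, rng, cfg.base_probs, max_iter=cfg.scrub_max_iter)
        chroms[f"chr{i + 1}"] = arr
    return chroms


def arrays_to_genome(chroms: Mapping[str, np.ndarray]) -> GenomeSequence:
    return GenomeSequence({c: _decode(a) for c, a in chroms.items()})


DENSE_PITCH = 16_000   # TSS pitch of the dense gene tier (bp)
ISO_PITCH = 130_000    # TSS pitch of the isolated tier (hosts distal peaks)
_BUFFER = 300_000      # gap between the two tiers
_MARGIN_LO = 70_000    # chromosome-start margin
_MARGIN_HI = 191_000   # chromosome-end margin (blacklist + distal headroom)


def place_genes(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> List[GeneModel]:
    """Gene models on fixed TSS anchors, in two spacing tiers per chromosome.

    A dense tier (18 kb pitch) receives promoter-proximal peaks; an
    isolated tier (130 kb pitch) receives distal peaks, whose nearest-TSS
    assignment needs more than twice the maximum peak-to-TSS distance of
    clearance. The dense pitch also guarantees that one gene's planted
    marks can never fall inside a neighbour's evaluation windows (gene
    bodies ≤5 kb, windows extend 5 kb).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[1])
    if cfg.gene_length[1] > DENSE_PITCH // 3:
        raise ValueError(f"max gene length must be <= {DENSE_PITCH // 3} bp")
    n_dense = cfg.n_genes - cfg.n_isolated_genes
    per_dense = [n_dense // cfg.n_chroms] * cfg.n_chroms
    per_iso = [cfg.n_isolated_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(n_dense % cfg.n_chroms):
        per_dense[i] += 1
    for i in range(cfg.n_isolated_genes % cfg.n_chroms):
        per_iso[i] += 1

    genes = []
    gidx = 0

    def add(anchor: int, chrom: str) -> None:
        nonlocal gidx
        length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = anchor, anchor + length
        else:
            start, end = anchor + 1 - length, anchor + 1
        genes.append(GeneModel(f"g{gidx:04d}", chrom, start, end, strand))
        gidx += 1

    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        nd, ni = per_dense[c], per_iso[c]
        needed = _MARGIN_LO + nd * DENSE_PITCH + _BUFFER + ni * ISO_PITCH + _MARGIN_HI
        if needed > cfg.chrom_length:
            raise ValueError(
                f"chrom_length {cfg.chrom_length} too short for {nd} dense + "
                f"{ni} isolated genes (need >= {needed} bp)"
            )
        for j in range(nd):
            add(_MARGIN_LO + int((j + 0.5) * DENSE_PITCH), chrom)
        iso_lo = _MARGIN_LO + nd * DENSE_PITCH + _BUFFER
        for j in range(ni):
            add(iso_lo + int((j + 0.5) * ISO_PITCH), chrom)
    return genes


def _nearest_is(
    ref: int, tss_arr: np.ndarray, target_idx: int, d: int
) -> bool:
    """True iff the target TSS is the strict unique nearest at distance d."""
    dists = np.abs(tss_arr - ref)
    dmin = dists.min()
    return dmin == d and int((dists == dmin).sum()) == 1 and dists[target_idx] == dmin


class _Occupancy:
    """Per-chromosome record of reserved (extended + guard) peak windows."""

    def __init__(self) -> None:
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {}

    def free(self, chrom: str, lo: int, hi: int) -> bool:
        return all(not (lo < e and s < hi) for s, e in self._by_chrom.get(chrom, ()))

    def reserve(self, chrom: str, lo: int, hi: int) -> None:
        self._by_chrom.setdefault(chrom, []).append((lo, hi))


def _blacklist_intervals(cfg: SimulationConfig) -> List[GenomicInterval]:
    out = []
    L = cfg.chrom_length
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        out.append(GenomicInterval(chrom, L - 50_000, L - 45_000, f"bl_{chrom}_1"))
        out.append(GenomicInterval(chrom, L - 40_000, L - 35_000, f"bl_{chrom}_2"))
    return out


def plant_peaks(
    cfg: SimulationConfig,
    chroms: Dict[str, np.ndarray],
    genes: Sequence[GeneModel],
    rng: Optional[np.random.Generator] = None,
    patterns: Optional[Sequence[MotifPattern]] = None,
) -> Tuple[List[NarrowPeak], pd.DataFrame]:
    """Plant TF peaks with known motif class, nearest gene and distance.

    Each peak's summit sits exactly at its drawn distance from the target
    TSS, motif words are written into the sequence centred on the summit
    (PDHD peaks carry a PD word and an HD word 4 bp apart), and extended
    windows never overlap each other or the blacklist. On a scrubbed
    background a verification pass re-scans every peak and locally
    re-scrubs junction artefacts, so the realized class always equals the
    intended class.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[2])
    if patterns is None:
        patterns = default_patterns()
    compiled = [compile_pattern(p) for p in patterns]
    pd_patterns = [p for p in patterns if p.domain_class == "PD"]
    hd_patterns = [p for p in patterns if p.domain_class == "HD"]
    if not pd_patterns or not hd_patterns:
        raise ValueError("pattern set must contain at least one PD and one HD pattern")

    bins = DistanceBins()
    class_labels = list(cfg.motif_class_fractions)
    class_probs = np.array([cfg.motif_class_fractions[c] for c in class_labels])
    prof = cfg.distance_profile
    prof_probs = np.array([w for _, _, w in prof])

    by_chrom_tss: Dict[str, Tuple[np.ndarray, List[int]]] = {}
    for i, g in enumerate(genes):
        by_chrom_tss.setdefault(g.chrom, ([], []))[0].append(g.tss)
        by_chrom_tss[g.chrom][1].append(i)
    by_chrom_tss = {
        c: (np.array(t, dtype=np.int64), idx) for c, (t, idx) in by_chrom_tss.items()
    }

    # Nearest-neighbour TSS distance per gene: a gene can host a peak at
    # distance d only when every other TSS is farther than d from the
    # peak, for which nn > 2*d is sufficient. Pre-filtering genes per
    # distance bin avoids burning placement attempts on hopeless draws.
    nn_dist = {}
    for c, (tss_arr, idxs) in by_chrom_tss.items():
        for i, gi in enumerate(idxs):
            others = np.abs(tss_arr - tss_arr[i])
            others = others[others > 0]
            nn_dist[gi] = int(others.min()) if others.size else cfg.chrom_length
    pools = [
        [genes[i] for i in range(len(genes)) if nn_dist[i] > 2 * hi]
        for _, hi, _ in prof
    ]
    for (lo_d, hi_d, _), pool in zip(prof, pools):
        if not pool:
            raise RuntimeError(
                f"no gene isolated enough to host peaks {lo_d}-{hi_d} bp from a TSS"
            )

    occ = _Occupancy()
    L = cfg.chrom_length
    zone_lo, zone_hi = 1_000, L - 51_000
    peaks: List[NarrowPeak] = []
    truth_rows = []
    planted_spans: List[List[Tuple[int, int]]] = []

    for i in range(cfg.n_peaks):
        mclass = class_labels[int(rng.choice(len(class_labels), p=class_probs))]
        bin_i = int(rng.choice(len(prof), p=prof_probs))
        lo_d, hi_d, _ = prof[bin_i]
        pool = pools[bin_i]
        placed = False
        for attempt in range(800):
            g = pool[int(rng.integers(len(pool)))]
            tss_arr, _ = by_chrom_tss[g.chrom]
            d = int(rng.integers(lo_d, hi_d))
            side = 1 if (d == 0 or rng.random() < 0.5) else -1
            ref = g.tss + side * d
            w = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
            start = ref - w // 2
            end = start + w
            res_lo, res_hi = start - cfg.flank - GUARD, end + cfg.flank + GUARD
            if res_lo < zone_lo or res_hi > zone_hi:
                continue
            tloc = int(np.flatnonzero(tss_arr == g.tss)[0])
            if not _nearest_is(ref, tss_arr, tloc, d):
                continue
            if not occ.free(g.chrom, res_lo, res_hi):
                continue
            occ.reserve(g.chrom, res_lo, res_hi)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place peak {i} after 800 attempts; "
                "genome too small for the requested peak count"
            )

        spans: List[Tuple[int, int]] = []
        arr = chroms[g.chrom]
        if mclass in ("PD", "PDHD"):
            word = _realize_word(
                pd_patterns[int(rng.integers(len(pd_patterns)))], rng)
            mstart = ref - len(word) // 2
            arr[mstart : mstart + len(word)] = _encode_word(word)
            spans.append((mstart, mstart + len(word)))
        if mclass in ("HD", "PDHD"):
            word = _realize_word(
                hd_patterns[int(rng.integers(len(hd_patterns)))], rng)
            if mclass == "HD":
                mstart = ref - len(word) // 2
            else:
                mstart = spans[-1][1] + 4
            arr[mstart : mstart + len(word)] = _encode_word(word)
            spans.append((mstart, mstart + len(word)))

        name = f"pk{i:05d}"
        peaks.append(NarrowPeak(g.chrom, start, end, name, None, ".",
                                10.0, 5.0, 3.0, ref - start))
        planted_spans.append(spans)
        truth_rows.append({
            "name": name, "chrom": g.chrom, "start": start, "end": end,
            "summit": ref, "motif_class": mclass, "gene_id": g.gene_id,
            "distance_bp": d, "bin_label": bins.bin_label(d),
            "planted": ";".join(f"{s}-{e}" for s, e in spans),
            "blacklisted": False,
        })

    if cfg.scrub_motifs:
        _verify_and_fix(cfg, chroms, peaks, planted_spans, truth_rows,
                        compiled, patterns, rng)
    return peaks, pd.DataFrame(truth_rows)


def _verify_and_fix(
    cfg: SimulationConfig,
    chroms: Dict[str, np.ndarray],
    peaks: List[NarrowPeak],
    planted_spans: List[List[Tuple[int, int]]],
    truth_rows: List[dict],
    compiled: List[CompiledPattern],
    patterns: Sequence[MotifPattern],
    rng: np.random.Generator,
) -> None:
    """Re-scan every peak; locally re-scrub junction-created cross-class
    matches (a planted word's boundary with background can by chance
    complete a word of the other domain class)."""
    forbidden = {
        "PD": [p for p in patterns if p.domain_class == "HD"],
        "HD": [p for p in patterns if p.domain_class == "PD"],
        "PDHD": [],
        "None": list(patterns),
    }
    for i, (peak, spans, row) in enumerate(zip(peaks, planted_spans, truth_rows)):
        intended = row["motif_class"]
        arr = chroms[peak.chrom]
        ws = max(0, peak.start - cfg.flank)
        we = min(arr.size, peak.end + cfg.flank)
        window = arr[ws:we]

        def realized() -> str:
            return classify_motifs(scan_peak(_decode(window), compiled)).value

        if realized() == intended:
            continue
        bad = forbidden[intended]
        if not bad:
            raise ScrubError(
                f"peak {peak.name}: planted {intended} but scanned {realized()}"
            )
        frozen = np.zeros(we - ws, dtype=bool)
        for s, e in spans:
            frozen[s - ws : e - ws] = True
        masks = [_word_masks(w) for w in _pattern_words(bad)]
        _scrub(window, masks, rng, cfg.base_probs, frozen=frozen,
               max_iter=cfg.scrub_max_iter)
        if realized() != intended:
            raise ScrubError(
                f"peak {peak.name}: could not realize class {intended}"
            )


def plant_states(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, List[GenomicInterval]], pd.DataFrame]:
    """Mark/ATAC interval sets realizing a target state for every gene.

    For each gene a flag vector is drawn uniformly from the vectors the
    classifier maps to the target state (inverting the rule table, which
    also yields Unclassified targets from the 14 off-table vectors), and
    present marks are placed strictly inside the relevant window: H3K27me3
    in the unextended gene body, all other tracks inside the TSS window.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[3])
    table = state_truth_table()
    vectors_by_state: Dict[str, List[Tuple[bool, ...]]] = {}
    for vec, state in table.items():
        vectors_by_state.setdefault(state.value, []).append(vec)
    for state in vectors_by_state:
        vectors_by_state[state].sort()

    state_labels = list(cfg.state_fractions)
    state_probs = np.array([cfg.state_fractions[s] for s in state_labels])

    marks: Dict[str, List[GenomicInterval]] = {m: [] for m in MARK_NAMES}
    rows = []
    for g in genes:
        state = state_labels[int(rng.choice(len(state_labels), p=state_probs))]
        vecs = vectors_by_state[state]
        vec = vecs[int(rng.integers(len(vecs)))]
        body_mid = (g.start + g.end) // 2
        body_w = min(400, g.end - g.start - 2)
        for mark, flag in zip(MARK_NAMES, vec):
            if not flag:
                continue
            if mark == "H3K27me3":
                lo = body_mid - body_w // 2
                iv = GenomicInterval(g.chrom, lo, lo + body_w, f"{mark}_{g.gene_id}")
            else:
                iv = GenomicInterval(g.chrom, g.tss - 200, g.tss + 200,
                                     f"{mark}_{g.gene_id}")
            marks[mark].append(iv)
        rows.append({
            "gene_id": g.gene_id, "state": state,
            "k4me1": vec[0], "k4me3": vec[1], "k27me3": vec[2],
            "k27ac": vec[3], "atac": vec[4],
        })
    return marks, pd.DataFrame(rows)


def _plant_decoys(
    cfg: SimulationConfig, rng: np.random.Generator
) -> Tuple[List[NarrowPeak], List[dict]]:
    """Peaks inside blacklist regions; the pipeline must drop them."""
    decoys, rows = [], []
    bl = _blacklist_intervals(cfg)
    for j in range(cfg.n_decoy_peaks):
        region = bl[int(rng.integers(len(bl)))]
        w = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
        start = int(rng.integers(region.start, region.end - w))
        name = f"decoy{j:03d}"
        decoys.append(NarrowPeak(region.chrom, start, start + w, name, None, ".",
                                 10.0, 5.0, 3.0, w // 2))
        rows.append({
            "name": name, "chrom": region.chrom, "start": start, "end": start + w,
            "summit": start + w // 2, "motif_class": "None", "gene_id": "",
            "distance_bp": -1, "bin_label": "", "planted": "",
            "blacklisted": True,
        })
    return decoys, rows


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            fh.write("\t".join([
                g.chrom, "peakstate_sim", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")


def simulate(cfg: SimulationConfig, outdir: str) -> GroundTruth:
    """Run all stages and emit the full fixture file set.

    Writes genome.fa, genes.gtf, peaks.narrowPeak, one BED per mark track,
    blacklist.bed, ground-truth tables and the effective config.
    """
    os.makedirs(outdir, exist_ok=True)
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    chroms = make_background_genome(cfg, np.random.default_rng(streams[0]))
    genes = place_genes(cfg, np.random.default_rng(streams[1]))
    peaks, peak_truth = plant_peaks(
        cfg, chroms, genes, np.random.default_rng(streams[2]))
    marks, gene_truth = plant_states(cfg, genes, np.random.default_rng(streams[3]))
    decoys, decoy_rows = _plant_decoys(cfg, np.random.default_rng(streams[4]))

    genome = arrays_to_genome(chroms)
    genome.to_fasta(os.path.join(outdir, "genome.fa"))
    write_gtf(genes, os.path.join(outdir, "genes.gtf"))
    write_bed(peaks + decoys, os.path.join(outdir, "peaks.narrowPeak"))
    for mark in MARK_NAMES:
        write_bed(marks[mark], os.path.join(outdir, f"{mark}.bed"))
    write_bed(_blacklist_intervals(cfg), os.path.join(outdir, "blacklist.bed"))

    # join per-gene state onto per-peak truth
    peak_truth = pd.concat(
        [peak_truth, pd.DataFrame(decoy_rows)], ignore_index=True
    ) if decoy_rows else peak_truth
    state_map = dict(zip(gene_truth["gene_id"], gene_truth["state"]))
    peak_truth["gene_state"] = peak_truth["gene_id"].map(state_map).fillna("")
    peak_truth.to_csv(os.path.join(outdir, "ground_truth_peaks.tsv"),
                      sep="\t", index=False)
    gene_truth.to_csv(os.path.join(outdir, "ground_truth_genes.tsv"),
                      sep="\t", index=False)
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    return GroundTruth(peaks=peak_truth, genes=gene_truth)
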