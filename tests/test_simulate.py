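"""Synthetic-data generator: determinism, scrubbing, planted recovery."""

import numpy as np
import pytest
from scipy import stats

from peakstate.genome import read_fasta
from peakstate.intervals import build_trees
from peakstate.motifs import classify_motifs, default_patterns, scan_peak
from peakstate.simulate import (
    ScrubError, SimulationConfig, _match_starts, _pattern_words, _scrub,
    _word_masks, arrays_to_genome, make_background_genome, place_genes,
    plant_peaks, plant_states, simulate,
)
from peakstate.states import (
    MARK_NAMES, build_windows, classify_state, mark_presence,
)

SMALL = dict(n_chroms=2, chrom_length=2_000_000, n_genes=60,
             n_isolated_genes=4, n_peaks=100)


def test_fraction_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(motif_class_fractions={"PD": 0.5, "HD": 0.4,
                                                "PDHD": 0.0, "None": 0.0})


def test_genome_deterministic_per_seed(tmp_path):
    cfg = SimulationConfig(seed=5, n_chroms=1, chrom_length=50_000,
                           n_genes=2, n_isolated_genes=0, scrub_motifs=False)
    g1 = arrays_to_genome(make_background_genome(cfg))
    g2 = arrays_to_genome(make_background_genome(cfg))
    assert g1["chr1"] == g2["chr1"]
    g3 = arrays_to_genome(make_background_genome(
        SimulationConfig(seed=6, n_chroms=1, chrom_length=50_000,
                         n_genes=2, n_isolated_genes=0, scrub_motifs=False)))
    assert g1["chr1"] != g3["chr1"]


def test_scrubbed_genome_has_zero_matches(compiled_defaults):
    cfg = SimulationConfig(seed=7, n_chroms=1, chrom_length=120_000,
                           n_genes=2, n_isolated_genes=0)
    genome = arrays_to_genome(make_background_genome(cfg))
    assert scan_peak(genome["chr1"], compiled_defaults) == []


def test_gc_within_binomial_interval():
    cfg = SimulationConfig(seed=8, n_chroms=1, chrom_length=100_000,
                           n_genes=2, n_isolated_genes=0, gc=0.5,
                           scrub_motifs=False)
    seq = arrays_to_genome(make_background_genome(cfg))["chr1"]
    n_gc = seq.count("G") + seq.count("C")
    # 99% binomial interval around p = 0.5 at n = 100 000
    lo, hi = stats.binom.interval(0.99, 100_000, 0.5)
    assert lo <= n_gc <= hi


def test_scrub_unremovable_match_raises():
    word_masks = [_word_masks(w) for w in _pattern_words(default_patterns())]
    arr = np.array([_b for _b in [2, 3, 1, 0, 1, 2, 2]], dtype=np.uint8)  # GTCACGG
    frozen = np.ones(arr.size, dtype=bool)
    with pytest.raises(ScrubError):
        _scrub(arr, word_masks, np.random.default_rng(0),
               np.full(4, 0.25), frozen=frozen, max_iter=5)


def test_vectorized_matcher_agrees_with_scanner(compiled_defaults):
    rng = np.random.default_rng(123)
    arr = rng.integers(0, 4, size=5_000).astype(np.uint8)
    seq = arrays_to_genome({"c": arr})["c"]
    regex_offsets = {m.offset for m in scan_peak(seq, compiled_defaults)}
    vec_offsets = set()
    for w in _pattern_words(default_patterns()):
        vec_offsets |= set(np.flatnonzero(_match_starts(arr, _word_masks(w))))
    assert vec_offsets == regex_offsets


def test_gene_layout_tiers_and_determinism():
    cfg = SimulationConfig(seed=9, **SMALL)
    genes = place_genes(cfg)
    assert len(genes) == cfg.n_genes
    assert len({g.gene_id for g in genes}) == cfg.n_genes
    assert genes == place_genes(cfg)
    # isolated genes really are isolated
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    nn = {}
    for g in genes:
        others = [abs(t - g.tss) for t in by_chrom[g.chrom] if t != g.tss]
        nn[g.gene_id] = min(others)
    assert sum(1 for v in nn.values() if v >= 120_000) >= cfg.n_isolated_genes


def test_chrom_too_short_raises():
    with pytest.raises(ValueError, match="too short"):
        place_genes(SimulationConfig(n_chroms=1, chrom_length=300_000,
                                     n_genes=50, n_isolated_genes=2))


@pytest.mark.parametrize("fractions,expected", [
    ({"PD": 1.0, "HD": 0.0, "PDHD": 0.0, "None": 0.0}, "PD"),
    ({"PD": 0.0, "HD": 0.0, "PDHD": 0.0, "None": 1.0}, "None"),
])
def test_pure_class_simulations_recover_exactly(
        compiled_defaults, fractions, expected):
    cfg = SimulationConfig(seed=13, motif_class_fractions=fractions,
                           n_peaks=40, **{k: v for k, v in SMALL.items()
                                          if k != "n_peaks"})
    chroms = make_background_genome(cfg)
    genes = place_genes(cfg)
    peaks, truth = plant_peaks(cfg, chroms, genes)
    genome = arrays_to_genome(chroms)
    for pk in peaks:
        seq = genome["{}".format(pk.chrom)][pk.start - cfg.flank:pk.end + cfg.flank]
        assert classify_motifs(scan_peak(seq, compiled_defaults)).value == expected
    assert set(truth.motif_class) == {expected}


def test_planted_states_recovered_for_all_genes():
    # balanced mixture so every target state is exercised at 60 genes
    cfg = SimulationConfig(seed=17, state_fractions={
        "Active": 0.17, "Primed": 0.17, "Poised": 0.17,
        "Repressed": 0.17, "Closed": 0.16, "Unclassified": 0.16,
    }, **SMALL)
    genes = place_genes(cfg)
    marks, truth = plant_states(cfg, genes)
    trees = {m: build_trees(marks[m]) for m in MARK_NAMES}
    truth = truth.set_index("gene_id")
    for g in genes:
        w = build_windows(g, chrom_length=cfg.chrom_length)
        state = classify_state(mark_presence(g, trees, w))
        assert state.value == truth.loc[g.gene_id, "state"]
    # every target state should occur at this size
    assert set(truth.state) == {"Active", "Primed", "Poised", "Repressed",
                                "Closed", "Unclassified"}


def test_distance_profile_fidelity():
    """Empirical bin fractions at n=2000 match the configured mixture
    within 3 binomial standard errors."""
    cfg = SimulationConfig(seed=19, n_peaks=2_000)
    genes = place_genes(cfg)
    # skip sequence work: distances only need placement, not planting
    cfg2 = SimulationConfig(seed=19, n_peaks=2_000, scrub_motifs=False)
    chroms = {f"chr{i+1}": np.zeros(cfg.chrom_length, dtype=np.uint8)
              for i in range(cfg.n_chroms)}
    _, truth = plant_peaks(cfg2, chroms, genes)
    n = len(truth)
    for lo, hi, wgt in cfg.distance_profile:
        got = ((truth.distance_bp >= lo) & (truth.distance_bp < hi)).mean()
        se = np.sqrt(wgt * (1 - wgt) / n)
        assert abs(got - wgt) <= 3 * se, (lo, hi, got, wgt)


def test_simulate_writes_consistent_files(small_sim, compiled_defaults):
    cfg, outdir, truth = small_sim
    genome = read_fasta(str(outdir / "genome.fa"))
    assert set(genome) == {f"chr{i+1}" for i in range(cfg.n_chroms)}
    assert all(genome.lengths[c] == cfg.chrom_length for c in genome)
    n_regular = (~truth.peaks.blacklisted).sum()
    assert n_regular == cfg.n_peaks
    assert truth.peaks.blacklisted.sum() == cfg.n_decoy_peaks
    # planted motif classes are readable straight off the emitted FASTA
    sample = truth.peaks[~truth.peaks.blacklisted].head(20)
    for _, row in sample.iterrows():
        seq = genome[row.chrom][row.start - cfg.flank:row.end + cfg.flank]
        assert classify_motifs(scan_peak(seq, compiled_defaults)).value == \
            row.motif_class


def test_simulate_byte_identical_reruns(tmp_path, small_sim):
    cfg, outdir, _ = small_sim
    rerun = tmp_path / "rerun"
    simulate(cfg, str(rerun))
    for f in ["genome.fa", "genes.gtf", "peaks.narrowPeak", "blacklist.bed",
              "ground_truth_peaks.tsv", "ATAC.bed"]:
        assert (rerun / f).read_bytes() == (outdir / f).read_bytes(), f
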