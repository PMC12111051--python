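import pytest

from peakstate.motifs import compile_pattern, default_patterns
from peakstate.simulate import SimulationConfig, simulate
from peakstate.states import MARK_NAMES


@pytest.fixture(scope="session")
def compiled_defaults():
    return [compile_pattern(p) for p in default_patterns()]


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small seeded simulation shared by I/O, pipeline and CLI tests."""
    cfg = SimulationConfig(
        seed=11, n_chroms=2, chrom_length=2_000_000,
        n_genes=60, n_isolated_genes=4, n_peaks=150, n_decoy_peaks=3,
    )
    outdir = tmp_path_factory.mktemp("sim")
    truth = simulate(cfg, str(outdir))
    return cfg, outdir, truth


def sim_run_config(outdir, resdir):
    """RunConfig pointing at a simulation output directory."""
    from peakstate.pipeline import RunConfig

    return RunConfig(
        peaks=str(outdir / "peaks.narrowPeak"),
        genome=str(outdir / "genome.fa"),
        genes=str(outdir / "genes.gtf"),
        marks={m: str(outdir / f"{m}.bed") for m in MARK_NAMES},
        blacklist=str(outdir / "blacklist.bed"),
        outdir=str(resdir),
    )
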