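import pytest

from svlr.ml_filters import train_bundle_from_simulation
from svlr.pipeline import RunConfig, call_variants
from svlr.synthetic_data import SimulationSpec, simulate_to_files

SMALL_NSV = {"DEL": 6, "INS": 6, "DUP": 5, "INV": 5, "TRA": 3}


@pytest.fixture(scope="session")
def small_clean_sim(tmp_path_factory):
    """Small noise-free sample: 300 kb, 25 SVs, 30x, exact CIGARs."""
    spec = SimulationSpec(ref_length=300_000, second_contig_length=120_000,
                          n_sv=dict(SMALL_NSV), noise_rate=0.0,
                          platform_noise_scale=0.0, seed=3)
    outdir = tmp_path_factory.mktemp("clean_sim")
    bam, fasta, truth = simulate_to_files(spec, str(outdir))
    return bam, fasta, truth


@pytest.fixture(scope="session")
def small_noisy_sim(tmp_path_factory):
    """Small noisy sample: 300 kb, 25 SVs, 30x, noise_rate 0.1."""
    spec = SimulationSpec(ref_length=300_000, second_contig_length=120_000,
                          n_sv=dict(SMALL_NSV), noise_rate=0.1, seed=5)
    outdir = tmp_path_factory.mktemp("noisy_sim")
    bam, fasta, truth = simulate_to_files(spec, str(outdir))
    return bam, fasta, truth


@pytest.fixture(scope="session")
def full_noisy_sim(tmp_path_factory):
    """The reference study conditions: 1 Mb, 100 SVs across all five types,
    30x coverage, noise_rate 0.1."""
    spec = SimulationSpec(seed=11)
    outdir = tmp_path_factory.mktemp("full_sim")
    bam, fasta, truth = simulate_to_files(spec, str(outdir))
    return bam, fasta, truth


@pytest.fixture(scope="session")
def trained_bundle():
    """RF+CNN filter bundle trained on two seeded synthetic genomes."""
    return train_bundle_from_simulation(seed=7)


@pytest.fixture(scope="session")
def sensitive_calls(full_noisy_sim):
    bam, _, truth = full_noisy_sim
    calls, _ = call_variants(bam, RunConfig(mode="sensitive", genotype=False))
    return calls, truth


@pytest.fixture(scope="session")
def general_calls(full_noisy_sim, trained_bundle):
    bam, _, truth = full_noisy_sim
    calls, _ = call_variants(
        bam, RunConfig(mode="general", genotype=False, bundle=trained_bundle))
    return calls, truth
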