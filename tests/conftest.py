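import pytest

from sbscreen.config import ScreenConfig
from sbscreen.synthetic import simulate_genome, simulate_insertions


@pytest.fixture(scope="session")
def default_screen():
    """One default-parameter screen (40 primary + 30 met, 5/5/4 planted drivers)."""
    cfg = ScreenConfig(seed=1)
    sequences, genes, ta_index = simulate_genome(cfg)
    table, truth = simulate_insertions(cfg, genes, ta_index)
    return cfg, sequences, genes, ta_index, table, truth


@pytest.fixture(scope="session")
def small_screen_config():
    """A read-level-tractable screen used for FASTQ round trips and CLI runs."""
    return ScreenConfig(
        seed=7,
        n_chromosomes=3,
        chrom_length=60_000,
        n_genes=40,
        gene_length_range=(1_000, 2_000),
        n_primary_samples=4,
        n_met_samples=3,
        background_insertions_per_sample=80,
        clonal_count_mean=80.0,
        subclonal_count_mean=5.0,
    )


@pytest.fixture(scope="session")
def small_screen(small_screen_config):
    cfg = small_screen_config
    sequences, genes, ta_index = simulate_genome(cfg)
    table, truth = simulate_insertions(cfg, genes, ta_index)
    return cfg, sequences, genes, ta_index, table, truth
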