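import numpy as np
import pytest

from triomics import simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_trio():
    """1200-feature trio (100 per category) at the standard conditions."""
    cfg = simulate.SimulationConfig(
        seed=7, n_features_per_class={c: 100 for c in simulate.CATEGORIES}
    )
    matrix, truth = simulate.simulate_trio_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_methylome():
    """Two 150-kb chromosomes with 3 planted DMR bins per category."""
    cfg = simulate.SimulationConfig(
        seed=5, n_chromosomes=2, chrom_length_bp=150_000,
        n_dmrs_per_class={c: 3 for c in simulate.CATEGORIES},
    )
    genome = simulate.simulate_genome(cfg)
    cx, design, truth = simulate.simulate_methylome(cfg, genome["seqs"])
    return cfg, genome, cx, design, truth
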