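import numpy as np
import pytest

from scmtl.synthetic import SimConfig, simulate_citeseq


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim():
    """3 well-separated types, 2 batches, ~600 cells — shared across tests."""
    cfg = SimConfig(
        cells_per_type=(250, 200, 150),
        n_genes=120,
        n_proteins=8,
        n_batches=2,
        nb_dispersion=8.0,
        batch_effect_scale=0.1,
        protein_noise_sd=0.3,
        marker_fold=8.0,
        seed=0,
    )
    datasets, truth = simulate_citeseq(cfg)
    return cfg, datasets, truth
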