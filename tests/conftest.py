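import numpy as np
import pytest

from promvar.simulate import SimulationConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_experiment():
    """A modest simulated experiment shared across read-only tests."""
    cfg = SimulationConfig(
        n_genes=40, seed=7, causal_fraction=0.2, fixed_effect=1.0,
        barcodes_per_oligo=40, dna_mean=50, n_replicates=6,
    )
    return simulate_experiment(cfg)
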