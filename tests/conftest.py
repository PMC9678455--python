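import numpy as np
import pytest

from pnbayes import (
    ChainSettings,
    SimulationCondition,
    TruthParameters,
    generate_dataset,
)


@pytest.fixture
def small_dataset():
    """30 subjects: 10 independent controls + 4 clusters of 5."""
    condition = SimulationCondition(c=4, m=5, rho=0.1, n_control=10)
    return generate_dataset(condition, TruthParameters(rho=0.1), seed=42)


@pytest.fixture
def tiny_settings():
    """Very short chains for plumbing tests (not for inference quality)."""
    return ChainSettings(n_iter=600, n_burn=200, thin=2, n_chains=2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
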