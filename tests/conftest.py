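import numpy as np
import pytest

from termarrest import (
    SimulationConfig,
    build_transcriptome,
    plant_modifications,
    simulate_pileups,
)


@pytest.fixture
def small_config():
    return SimulationConfig(n_transcripts=4, seed=11)


@pytest.fixture
def small_transcriptome(small_config):
    return build_transcriptome(small_config)


@pytest.fixture
def m6a_experiment():
    """One seeded simulate->pileup run with only m6A sites planted."""
    cfg = SimulationConfig(n_transcripts=10, seed=7)
    tx = build_transcriptome(cfg)
    truth = plant_modifications(tx, {"m6A": 10}, arrest_prob_treated=0.5, seed=7)
    treated, control = simulate_pileups(tx, truth, cfg)
    return cfg, tx, truth, treated, control


@pytest.fixture
def rng():
    return np.random.default_rng(123)
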