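import warnings

import numpy as np
import pytest

from premirscan.simulate import SimulationConfig

# SVC(probability=True) deprecation chatter from sklearn 1.9 is irrelevant here
warnings.filterwarnings("ignore", message="The `probability` parameter")


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale study conditions for fast unit tests."""
    return SimulationConfig(
        seed=1, n_positives=60, n_negatives=60, n_contigs=2,
        contig_length_range=(8_000, 12_000), planted_hairpins=3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
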