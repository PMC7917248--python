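import numpy as np
import pytest

from tridta.model_core import ModelConfig
from tridta.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Small-width config so model tests run in milliseconds."""
    return ModelConfig(
        mlp_widths=[1024, 32, 16, 32],
        cnn_filters=[8, 8, 8],
        cnn_kernel_lengths=[3, 5, 7],
        shared_dim=16,
        fc_widths=[32, 32, 16],
        dropout_rates=[0.1, 0.1],
        prot_max_len=100,
        batch_size=16,
        learning_rate=1e-3,
        epochs=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """8 drugs x 5 proteins synthetic dataset with both label classes."""
    return generate_dataset(SyntheticSpec(n_drugs=8, n_proteins=5, seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
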