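import numpy as np
import pytest

from miaug import SyntheticSpec, generate_dataset
from miaug.model import scaled_down_config


@pytest.fixture(scope="session")
def bench_dataset():
    """Desk-scale benchmark dataset: 5 subjects x 20 epochs/class, 8 ch x 128 samples."""
    return generate_dataset(SyntheticSpec(n_channels=8, n_samples=128, seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny dataset for contract tests: 2 subjects x 6 epochs/class."""
    return generate_dataset(
        SyntheticSpec(n_subjects=2, epochs_per_class_per_subject=6, n_channels=8, n_samples=128, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_model_config():
    return scaled_down_config(max_epochs=5, seed=0)
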