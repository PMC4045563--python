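import numpy as np
import pytest

from mfractal import ClassifierConfig, evaluate_loocv, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130627)


@pytest.fixture(scope="session")
def texture_dataset():
    """Default two-class texture dataset, 20 images per class."""
    return generate_dataset(n_per_class=20, seed=0)


@pytest.fixture(scope="session")
def texture_report(texture_dataset):
    return evaluate_loocv(texture_dataset, ClassifierConfig())
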