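import numpy as np
import pytest

from kdaloc import synthetic
from kdaloc.dataset import LabeledDataset


@pytest.fixture
def small_dataset():
    """N=12, C=3 random dataset for scatter-matrix oracles."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((12, 4))
    y = np.array([0] * 5 + [1] * 4 + [2] * 3)
    return LabeledDataset(X, y)


@pytest.fixture
def rings():
    return synthetic.make_rings(seed=1)


@pytest.fixture
def blobs():
    return synthetic.make_blobs(n_classes=3, n_per_class=10, dim=2, separation=8.0, noise_sd=0.8, seed=7)
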