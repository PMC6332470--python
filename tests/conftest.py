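import numpy as np
import pytest

from adsnn import ASNParams, normalized_params
from adsnn.toydata import make_blobs
from adsnn.training import TrainConfig, train_mlp


@pytest.fixture(scope="session")
def default_params() -> ASNParams:
    """Default neuron constants with the spike height normalized (f(1)=1)."""
    return normalized_params(ASNParams())


@pytest.fixture(scope="session")
def blobs():
    """The standard desk-scale task: 3 well-separated Gaussian classes in 4-D."""
    return make_blobs(n=240, d=4, K=3, separation=6.0, seed=1)


@pytest.fixture(scope="session")
def trained_spec(blobs):
    """A [4-20-20-3] analog network trained on the blobs task (with BN)."""
    return train_mlp(blobs, TrainConfig(seed=1))
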