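import numpy as np
import pytest

from neurodup import Activation, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_params(rng, k0_max: int = 20) -> ModelParams:
    """A random parameter draw over the model's full domain."""
    return ModelParams(
        b=rng.uniform(0.1, 2.0),
        c=rng.uniform(0.0, 1.0),
        c_hat=rng.uniform(0.0, 1.0),
        epsilon=rng.uniform(0.0, 1.0),
        K0=int(rng.integers(1, k0_max + 1)),
    )


def random_activation(rng) -> Activation:
    return Activation(float(rng.random()), float(rng.random()))
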