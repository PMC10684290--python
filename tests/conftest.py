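import numpy as np
import pytest

from cdmenet.density import DensityMap
from cdmenet.network import NetworkConfig, PredictorOutputs, build_network


@pytest.fixture(scope="session")
def tiny_cfg() -> NetworkConfig:
    return NetworkConfig(width_scale=1 / 16)


@pytest.fixture()
def tiny_net(tiny_cfg):
    return build_network(tiny_cfg, seed=0)


def outputs_from(level_probs, density=None, divisor=8) -> PredictorOutputs:
    """Wrap raw arrays into PredictorOutputs for loss/pseudo-label tests."""
    probs = np.asarray(level_probs, dtype=float)
    if density is None:
        density = np.zeros(probs.shape[1:])
    return PredictorOutputs(
        density=DensityMap(np.asarray(density, dtype=float), divisor),
        level_probs=probs,
    )
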