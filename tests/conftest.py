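import numpy as np
import pytest

from vesselseg.model import NetworkSpec, build_network
from vesselseg.synthetic import SynthConfig, generate_dataset, generate_sample


@pytest.fixture(scope="session")
def small_synth_cfg():
    return SynthConfig(height=128, width=128, seed=0)


@pytest.fixture(scope="session")
def synth_sample(small_synth_cfg):
    """One small, fixed synthetic image/label/FOV triple."""
    return generate_sample(small_synth_cfg, seed=42)


@pytest.fixture(scope="session")
def synth_dataset(small_synth_cfg):
    """Four small synthetic samples with derived seeds."""
    return generate_dataset(4, small_synth_cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_spec():
    return NetworkSpec(
        growth_rate=4, layers_per_block=1, n_blocks_down=1, initial_channels=4
    )


@pytest.fixture()
def tiny_model(tiny_spec):
    return build_network(tiny_spec, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
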