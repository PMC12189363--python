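import numpy as np
import pytest

from cardioseg import NetworkConfig, build_model
from cardioseg.phantom import PhantomParams, generate_cohort
from cardioseg.preprocess import preprocess_pair


@pytest.fixture(scope="session")
def phantom_pairs():
    """~70 preprocessed 64x64 phantom (image, mask) pairs."""
    params = PhantomParams.for_size(64, seed=3)
    pairs = []
    for case in generate_cohort(8, params):
        for img, mask in zip(case.slices, case.masks):
            pairs.append(preprocess_pair(img, mask, 64))
    return pairs


@pytest.fixture()
def tiny_cfg():
    """A small network configuration for fast structural tests."""
    return NetworkConfig(encoder_variant="plain", plain_width=8,
                         decoder_channels=(32, 16, 8, 8, 8))


@pytest.fixture()
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
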