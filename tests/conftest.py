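import math

import numpy as np
import pytest

from vortexdiff.digits import generate_corpus
from vortexdiff.pipeline import SceneConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scene():
    """A miniature but physically consistent scene for fast unit tests:
    64x64 grid at 10 um pitch (640 um field), w0 = 100 um so the largest
    matched Gaussian (w0 sqrt 5) still captures >= 99%, network side 32."""
    return SceneConfig(
        grid_side=64,
        pitch=10e-6,
        waist_w0=100e-6,
        z_leg=2e-3,
        correlation_length=25e-6,
        net_side=32,
        grit_label="tiny",
        diffuser_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_corpus():
    return generate_corpus(2, seed=11)  # 20 glyphs


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scene, tiny_corpus):
    return simulate_dataset(tiny_scene, tiny_corpus, "vortex", split_seed=3)
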