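import numpy as np
import pytest

import hsifm as h
from hsifm.pipeline import run_benchmark


@pytest.fixture(scope="session")
def lib():
    return h.make_endmembers(96, seed=7)


@pytest.fixture(scope="session")
def cube_and_mask(lib):
    scene = h.SceneSpec(height_px=48, width_px=48, seed=3, n_fm=2)
    return h.synth_cube(scene, lib)


@pytest.fixture(scope="session")
def tiny_model():
    return h.build_discriminator(seed=0)


@pytest.fixture(scope="session")
def benchmark():
    """The full desk-scale benchmark: 4 clean training scenes + 4
    contaminated evaluation scenes, both channels trained 30 epochs,
    fp32 and fp16 pipelines evaluated. Shared across acceptance tests."""
    return run_benchmark(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
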