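import numpy as np
import pytest

import neuroseg as ns


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default geometry, no noise, seed 0."""
    return ns.make_phantom(ns.default_spec(seed=0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default geometry, noise_sigma 0.05, seed 0."""
    return ns.make_phantom(ns.default_spec(seed=0, noise_sigma=0.05))


@pytest.fixture(scope="session")
def batch10_results():
    """The surrogate benchmark batch: seeds 0-9, noise_sigma 0.05, with the
    full pipeline already run. Shared across acceptance tests."""
    out = []
    for seed in range(10):
        img, gt = ns.make_phantom(ns.default_spec(seed=seed, noise_sigma=0.05))
        out.append((img, gt, ns.segment_gm_wm(img)))
    return out


@pytest.fixture(scope="session")
def noiseless_result(noiseless_phantom):
    img, _ = noiseless_phantom
    return ns.segment_gm_wm(img)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
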