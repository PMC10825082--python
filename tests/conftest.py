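import numpy as np
import pytest

from bjtvd.denoise import TVDConfig, tvd_admm
from bjtvd.simulate import generate_dataset, generate_trace


@pytest.fixture(scope="session")
def class1_trace():
    """One noisy Class 1 trace with a fixed seed."""
    return generate_trace(1, rng_seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """30 noisy traces per class, fixed seed, with TVD(lam=1) reconstructions."""
    traces = generate_dataset(30, rng_seed=7)
    cfg = TVDConfig(lam=1.0)
    for t in traces:
        t.reconstructed = tvd_admm(t.log_g, cfg).reconstructed
    return traces


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
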