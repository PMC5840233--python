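import numpy as np
import pytest

import dareservoir as da


@pytest.fixture(scope="session")
def lif():
    return da.LIFParams()


@pytest.fixture(scope="session")
def syn():
    return da.SynapseParams()


@pytest.fixture(scope="session")
def small_target():
    return da.make_one_hot_target(0, 1, da.BumpSpec())


@pytest.fixture(scope="session")
def trained_driven_small(small_target):
    """2 x 100 x 1 driven network, RLS-trained on a single bump target."""
    driven = da.build_driven(100, 2, 1, weight_scale=300.0, seed=1, alpha=1.0)
    driven, history = da.train_driven(driven, [small_target], n_epochs=8)
    return driven, history


@pytest.fixture(scope="session")
def small_auto(trained_driven_small):
    driven, _ = trained_driven_small
    return da.derive_auto(driven, b_max=0.15, seed=2, u_r=20.0)


@pytest.fixture(scope="session")
def fixed_spike_input():
    rng = np.random.default_rng(3)
    return (rng.random((2, 300)) < 0.3).astype(np.uint8)


@pytest.fixture(scope="session")
def tiny_clip():
    spec = next(iter(da.default_class_specs((64, 64), n_frames=40).values()))
    return da.generate_clip(spec)
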