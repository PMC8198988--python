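import numpy as np
import pytest

import gatcda as g


@pytest.fixture(scope="session")
def toy():
    """Hand-computed 3x3x3x3 worked example."""
    return g.worked_toy()


@pytest.fixture(scope="session")
def small_dataset():
    """Small coupled synthetic corpus for fast end-to-end tests."""
    cfg = g.SynthConfig(
        nc=40, nd=12, n_mirna=20, n_mrna=30, density_cd=0.08, seed=3
    )
    return g.generate(cfg)


@pytest.fixture()
def quick_params():
    """Estimator settings sized for unit tests, not benchmark quality."""
    return dict(epochs=30, embed_dim=8, n_heads=2, random_state=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
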