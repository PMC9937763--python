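import numpy as np
import pytest

from dqloc import phantom as ph


@pytest.fixture(scope="session")
def noiseless_cfg():
    return ph.PhantomConfig(speckle_sigma=0.0, seed=42)


@pytest.fixture(scope="session")
def speckled_cfg():
    return ph.PhantomConfig(speckle_sigma=0.15, seed=42)


@pytest.fixture(scope="session")
def noiseless_scan(noiseless_cfg):
    """One clean phantom with a 50-px chord plus its annotation."""
    return ph.generate_bscan(noiseless_cfg, 50, np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_dataset(speckled_cfg):
    """Three 4-frame speckled patients: 12 (scan, annotation) pairs."""
    cfg = ph.PhantomConfig(speckle_sigma=0.15, seed=7, n_frames_per_patient=4)
    return ph.generate_dataset(cfg, 3, seed=7)
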