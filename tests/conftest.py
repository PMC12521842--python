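import numpy as np
import pytest

from pcgkit.synthio import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(fs=4000.0, duration_s=5.0, heart_rate_bpm=60.0,
                     snr_db=20.0, seed=1)


@pytest.fixture(scope="session")
def as_recording(sim_cfg):
    """One aortic-stenosis recording at 20 dB SNR (seed 1)."""
    return simulate_recording("AS", sim_cfg)


@pytest.fixture(scope="session")
def nhf_recording(sim_cfg):
    return simulate_recording("NHF", sim_cfg)


@pytest.fixture(scope="session")
def small_label_set():
    """Balanced two-cluster classification fixture (well separated)."""
    rng = np.random.default_rng(42)
    n = 40
    X = np.vstack([rng.normal(0.0, 0.5, (n, 3)),
                   rng.normal(3.0, 0.5, (n, 3))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y
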