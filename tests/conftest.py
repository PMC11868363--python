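import numpy as np
import pytest

import usirhf as u


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse two-gauge phantom on a 96x96 grid (fast recon problems)."""
    spec = u.SlitPhantomSpec(gauge_freqs_lp_cm=(0.5, 1.0), fov_mm=280.0)
    return spec, u.make_slit_phantom(spec, (96, 96))


@pytest.fixture(scope="session")
def default_phantom():
    spec = u.SlitPhantomSpec()
    return spec, u.make_slit_phantom(spec, (320, 320))


@pytest.fixture(scope="session")
def experiment_report():
    """One full three-arm phantom experiment, shared across tests."""
    return u.run_phantom_experiment(u.ExperimentConfig(seed=1))


def nrmse(a, b):
    a = np.abs(np.asarray(a, dtype=complex))
    b = np.abs(np.asarray(b, dtype=complex))
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
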