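"""Shared fixtures: small, seeded, session-scoped simulations."""

import numpy as np
import pytest

from cardiochron import simulate as sim


@pytest.fixture(scope="session")
def mouse_params():
    return sim.mouse_ecg_params()


@pytest.fixture(scope="session")
def nmr_params():
    return sim.nmr_ecg_params()


@pytest.fixture(scope="session")
def mouse_clean_60s(mouse_params):
    """60-s clean mouse recording + ground truth (seed 101)."""
    return sim.simulate_ecg(mouse_params, duration=60.0, noise_sd=0.0, seed=101)


@pytest.fixture(scope="session")
def mouse_noisy_60s(mouse_params):
    """60-s mouse recording at SNR 20 dB (seed 101; same beat times as the
    clean fixture because noise uses an independent substream)."""
    noise = sim.noise_for_snr(mouse_params, 20.0)
    return sim.simulate_ecg(mouse_params, duration=60.0, noise_sd=noise, seed=101)


@pytest.fixture(scope="session")
def nmr_clean_60s(nmr_params):
    return sim.simulate_ecg(nmr_params, duration=60.0, noise_sd=0.0, seed=202)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
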