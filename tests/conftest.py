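import numpy as np
import pytest
from hypothesis import settings

import rfus

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_protocol() -> rfus.StimulusProtocol:
    return rfus.make_protocol()


@pytest.fixture(scope="session")
def epoch_grid() -> np.ndarray:
    """Within-trial time axis of the default epoching: 77 samples at 0.4 s."""
    return np.arange(-37, 40) * 0.4 + 0.2


@pytest.fixture(scope="session")
def short_protocol() -> rfus.StimulusProtocol:
    """Three-trial protocol for fast image-pipeline tests (137.4 s)."""
    return rfus.make_protocol(n_trials=3)


def make_trials(protocol, amplitude=0.20, noise_sd=0.10, seed=0):
    """Epoch matrix from the single-pixel fast path, in percent units."""
    truth = rfus.GroundTruth(
        hrf_params_true=rfus.wt_hrf().scaled(amplitude / rfus.wt_hrf().amplitude),
        vessel_mask=np.ones((1, 1), bool),
        noise_sd=noise_sd,
        rng_seed=seed,
    )
    times, traces, _ = rfus.simulate_roi_series(protocol, truth)
    return rfus.epoch_trials(100.0 * (traces[0] - 1.0), times, protocol)


@pytest.fixture(scope="session")
def calibrated_epochs(default_protocol):
    """50 noisy trials at the calibrated default (20% amplitude, 10% noise)."""
    return make_trials(default_protocol, amplitude=0.20, noise_sd=0.10, seed=0)
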