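import numpy as np
import pytest

import fnirs_skill as fsk

FS = 5.0


@pytest.fixture(scope="session")
def small_layout():
    return fsk.make_layout(n_long=6, n_short=2)


@pytest.fixture(scope="session")
def block_stim():
    # six 15-s task blocks, onsets 80 s apart: short enough that each
    # response fits inside the -2..60 s HRF support
    return fsk.StimDesign(
        onsets=40.0 + 80.0 * np.arange(6),
        durations=np.full(6, 15.0),
        rest_duration=30.0,
    )


@pytest.fixture(scope="session")
def clean_conc(small_layout, block_stim):
    """Noiseless, nuisance-free concentration recording (amplitude 1 μM)."""
    truth = fsk.SimulationTruth(
        hrf_amplitude=1.0,
        superficial_gain=0.0,
        physio=(),
        superficial_slow_sd=0.0,
        drift_slope_sd=0.0,
        noise_sd=0.0,
        seed=0,
    )
    rec, comps = fsk.simulate_hemodynamics(
        truth, block_stim, small_layout, duration=520.0, fs=FS
    )
    return rec, comps


@pytest.fixture(scope="session")
def noisy_conc(small_layout, block_stim):
    """Default-world recording: task + superficial + physio + drift + noise."""
    truth = fsk.SimulationTruth(hrf_amplitude=1.0, seed=7)
    rec, comps = fsk.simulate_hemodynamics(
        truth, block_stim, small_layout, duration=520.0, fs=FS
    )
    return rec, comps
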