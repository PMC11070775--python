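import numpy as np
import pytest

from retistim import CellSpec, MovieSpec, StimulusEvent, StimulusLog, make_stimulus_ladder


@pytest.fixture
def quiet_spec():
    """Small zero-noise, zero-bleach movie spec with one centred soma."""
    return MovieSpec(
        height_px=32, width_px=32, um_per_px=4.0, duration_s=20.0,
        baseline_f0=1000.0, noise_sd=0.0, bleach_a1=0.0, bleach_a2=0.0,
        cells=[CellSpec((64.0, 64.0), 8.0, 1.0)], spot_fwhm_um=60.0,
        resp_peak_dff=0.5, seed=0,
    )


@pytest.fixture
def single_pulse():
    return StimulusLog([StimulusEvent(10.0, 100.0, 100.0)])


@pytest.fixture
def ladder():
    return make_stimulus_ladder([10, 15, 35, 50, 100], n_reps=1, start_s=10.0)
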