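import numpy as np
import pytest

from oddwave import preprocessing as pp
from oddwave import synthetic as syn
from oddwave import presets


#: short FIR for tests where the kernel length is irrelevant to the property
FAST_FILTER = pp.FilterSpec(transition_hz=2.0)


@pytest.fixture(scope="session")
def small_schedule():
    return syn.build_schedule(40, 20, 2, seed=3)


@pytest.fixture(scope="session")
def clean_control_truth():
    """Noiseless control ERP kernels without oscillatory bursts."""
    return presets.make_truth("control", noise_sd_uv=0.0, include_bursts=False)


@pytest.fixture(scope="session")
def clean_epochs(small_schedule, clean_control_truth):
    """Filtered, epoched, rejection-masked noiseless oddball session."""
    rec = syn.simulate_oddball_recording(small_schedule, clean_control_truth)
    filtered = pp.filter_recording(rec, FAST_FILTER)
    return pp.reject_artifacts(pp.extract_epochs(filtered))


def make_epochset(data, fs=3000.0, t0=-0.1, conditions=("deviant",)):
    """EpochSet around a raw (trials, channels, samples) array, no rejection."""
    out_e, out_r = {}, {}
    for cond in conditions:
        out_e[cond] = np.asarray(data, float)
        out_r[cond] = np.zeros(data.shape[:2], dtype=bool)
    times = np.arange(data.shape[2]) / fs + t0
    names = tuple(f"ch{i+1}" for i in range(data.shape[1]))
    return pp.EpochSet(epochs=out_e, rejected=out_r, times_s=times, fs_hz=fs,
                       channel_names=names)
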