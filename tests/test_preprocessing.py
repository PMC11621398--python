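"""Filter design, zero-phase application, epoching, delta-criterion rejection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as ss

from oddwave import preprocessing as pp
from oddwave import synthetic as syn

from conftest import FAST_FILTER, make_epochset

FS = 3000.0


class TestFilterDesign:
    def test_tap_count_matches_printed_length_within_convention_slack(self):
        taps = pp.design_bandpass(pp.FilterSpec(), FS)
        assert abs(len(taps) - 54330) / 54330 < 0.002
        assert len(taps) % 2 == 1

    def test_taps_are_palindromic_linear_phase(self):
        taps = pp.design_bandpass(FAST_FILTER, FS)
        assert np.max(np.abs(taps - taps[::-1])) < 1e-12

    def test_frequency_response_passband_and_stopband(self):
        # DFT of the taps as the oracle for the measured response
        taps = pp.design_bandpass(pp.FilterSpec(), FS)
        w, h = ss.freqz(taps, worN=np.array([10.0, 50.0]), fs=FS)
        gain_db = 20.0 * np.log10(np.abs(h))
        assert abs(gain_db[0]) <= 0.1          # 10 Hz: unity within 0.1 dB
        assert gain_db[1] <= -50.0             # 50 Hz: in the stopband

    def test_invalid_band_edges_raise(self):
        with pytest.raises(ValueError):
            pp.design_bandpass(pp.FilterSpec(low_hz=50, high_hz=45), FS)


class TestZeroPhase:
    def test_unit_tap_is_identity(self):
        x = np.random.default_rng(0).normal(size=500)
        assert np.array_equal(pp.apply_zero_phase(np.ones(1), x), x)

    def test_dc_is_removed_by_bandpass(self):
        # needs the full-length kernel: only there does the stopband reach DC
        taps = pp.design_bandpass(pp.FilterSpec(), FS)
        y = pp.apply_zero_phase(taps, np.full(60000, 7.0))
        assert np.max(np.abs(y)) < 0.05

    def test_in_band_sinusoid_keeps_phase_and_amplitude(self):
        taps = pp.design_bandpass(FAST_FILTER, FS)
        t = np.arange(30000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = pp.apply_zero_phase(taps, x)
        mid = slice(5000, 25000)
        # cross-correlation peak at lag zero -> no group delay
        lags = ss.correlation_lags(len(x[mid]), len(y[mid]))
        assert lags[np.argmax(ss.correlate(x[mid], y[mid]))] == 0
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)

    def test_white_noise_transfer_matches_amplitude_response(self):
        taps = pp.design_bandpass(pp.FilterSpec(transition_hz=5.0), FS)
        rng = np.random.default_rng(1)
        x = rng.normal(size=300000)
        y = pp.apply_zero_phase(taps, x)
        f, pxx = ss.welch(x, fs=FS, nperseg=4096)
        _, pyy = ss.welch(y, fs=FS, nperseg=4096)
        _, h = ss.freqz(taps, worN=f, fs=FS)
        band = (f > 5) & (f < 40)
        ratio = pyy[band] / pxx[band]
        assert np.allclose(ratio, np.abs(h[band]) ** 2, rtol=0.2)

    def test_signal_shorter_than_kernel_raises(self):
        taps = pp.design_bandpass(FAST_FILTER, FS)
        with pytest.raises(ValueError, match="longer"):
            pp.apply_zero_phase(taps, np.zeros(100))


def _recording(data, schedule=None):
    names = tuple(f"ch{i+1}" for i in range(data.shape[0]))
    return syn.RawRecording(data=data, fs_hz=FS, channel_names=names,
                            schedule=schedule)


class TestEpoching:
    def test_constant_signal_epochs_to_zero(self, small_schedule):
        n = int((small_schedule.onsets_s[-1] + 1) * FS)
        rec = _recording(np.full((2, n), 5.0), small_schedule)
        ep = pp.extract_epochs(rec)
        for cond in ep.conditions:
            assert np.allclose(ep.epochs[cond], 0.0, atol=1e-12)

    def test_out_of_bounds_event_is_dropped(self):
        sched = syn.StimulusSchedule(
            onsets_s=np.array([0.05, 2.0, 3.0]), blocks=np.ones(3, int),
            conditions=np.array(["deviant"] * 3, object))
        rec = _recording(np.zeros((1, int(4 * FS))), sched)
        ep = pp.extract_epochs(rec)
        assert ep.n_dropped_out_of_bounds == 1
        assert ep.epochs["deviant"].shape[0] == 2

    def test_epoch_average_recovers_known_kernel(self, clean_epochs,
                                                clean_control_truth):
        avg = clean_epochs.epochs["deviant"].mean(axis=0)[0]
        expected = syn.erp_kernel(clean_epochs.times_s,
                                  clean_control_truth.components["deviant"])
        sel = clean_epochs.times_s > 0.01
        assert np.max(np.abs(avg[sel] - expected[sel])) < 0.5

    @given(st.floats(-200, 200))
    @settings(max_examples=25, deadline=None)
    def test_baseline_invariance_under_dc_offsets(self, offset):
        sched = syn.StimulusSchedule(
            onsets_s=np.array([1.0, 3.0]), blocks=np.ones(2, int),
            conditions=np.array(["deviant", "deviant"], object))
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, int(5 * FS)))
        ep0 = pp.extract_epochs(_recording(x, sched))
        ep1 = pp.extract_epochs(_recording(x + offset, sched))
        assert np.allclose(ep0.epochs["deviant"], ep1.epochs["deviant"], atol=1e-9)

    def test_empty_schedule_raises(self):
        rec = _recording(np.zeros((1, 10000)))
        with pytest.raises(ValueError, match="events"):
            pp.extract_epochs(rec)


class TestRejection:
    def test_all_zero_epochs_have_no_rejections(self):
        ep = pp.reject_artifacts(make_epochset(np.zeros((5, 3, 2400))))
        assert not ep.rejected["deviant"].any()

    def test_range_exactly_at_threshold_is_retained(self):
        data = np.zeros((4, 1, 2400))
        data[0, 0, 1000] = 250.0
        data[0, 0, 1100] = -250.0      # range exactly 500 -> retained (strict >)
        data[1, 0, 1000] = 251.0
        data[1, 0, 1100] = -250.0      # range 501 -> rejected
        ep = pp.reject_artifacts(make_epochset(data))
        assert not ep.rejected["deviant"][0, 0]
        assert ep.rejected["deviant"][1, 0]
        assert not ep.rejected["deviant"][2:, 0].any()

    def test_rejection_is_idempotent(self):
        rng = np.random.default_rng(3)
        data = rng.normal(scale=300, size=(10, 2, 2400))
        once = pp.reject_artifacts(make_epochset(data))
        twice = pp.reject_artifacts(once)
        for cond in once.conditions:
            assert np.array_equal(once.rejected[cond], twice.rejected[cond])

    def test_channel_dropped_when_rejection_fraction_exceeds_threshold(self):
        data = np.zeros((10, 2, 2400))
        data[:4, 1, 100] = 1000.0      # 40% of channel 2 epochs are artifacts
        ep = pp.reject_artifacts(make_epochset(data))
        assert ep.qc["dropped_channels"] == ["ch2"]
        assert ep.rejected["deviant"][:, 1].all()
        assert not ep.rejected["deviant"][:, 0].any()


def test_filter_then_epoch_preserves_in_band_amplitude(small_schedule):
    t = np.arange(int((small_schedule.onsets_s[-1] + 1) * FS)) / FS
    x = 10.0 * np.sin(2 * np.pi * 10.0 * t)
    rec = _recording(x[None, :], small_schedule)
    filtered = pp.filter_recording(rec, FAST_FILTER)
    ep = pp.extract_epochs(filtered)
    assert np.max(ep.epochs["standard"]) == pytest.approx(10.0, rel=0.01)
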