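"""Event-related spectral perturbation (ERSP) and band-wise maxima.

Per retained trial, a Hann-tapered sliding window of 400 samples is Fourier
transformed with a pad ratio of 64 (zero-padding to 25,600 points at 3 kHz,
i.e. 0.1171875 Hz bin spacing), converted to one-sided power spectral density
(µV²/Hz), averaged across trials, and expressed in absolute decibels,
dB = 10·log10(µV²/Hz) — no baseline term appears in the dB definition, so the
default is absolute power; a pre-stimulus-baseline-subtracted variant is
available via ``baseline_window_s``. For each frequency band (delta 1–4,
theta 4–8, alpha 8–12, beta 12–30, gamma 30–45 Hz) and the whole 1–45 Hz
range, the maximum ERSP and its frequency and latency are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}
BETA_SUBBANDS: dict[str, tuple[float, float]] = {
    "beta_low": (12.0, 15.0),
    "beta_mid": (15.0, 18.0),
    "beta_high": (18.0, 30.0),
}
WHOLE_RANGE: tuple[float, float] = (1.0, 45.0)

FLOOR_DB = -100.0


@dataclass
class ERSPMap:
    """Trial-averaged time-frequency power, dB re 1 µV²/Hz.

    ``power_db`` has shape (channels, freqs, times); ``times_s`` are window
    centres on the epoch time axis; frequency spacing is
    fs / (window_samples × pad_ratio).
    """

    power_db: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...]
    window_samples: int = 400
    pad_ratio: int = 64

    @property
    def df_hz(self) -> float:
        return self.fs_hz / (self.window_samples * self.pad_ratio)

    def linear_power(self) -> np.ndarray:
        return 10.0 ** (self.power_db / 10.0)


def _hann_periodic(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def stft_frame_density(frame: np.ndarray, fs_hz: float, pad_ratio: int,
                       freq_bins: np.ndarray | None = None) -> np.ndarray:
    """One-sided PSD (µV²/Hz) of a single tapered, zero-padded frame.

    Reference path used as the per-frame definition: identical to
    ``np.fft.rfft(taper * frame, n=len(frame) * pad_ratio)`` with density
    normalisation 2/(fs·Σw²) (no doubling at DC/Nyquist).
    """
    n = len(frame)
    win = _hann_periodic(n)
    nfft = n * pad_ratio
    spec = np.fft.rfft(win * frame, n=nfft)
    power = (np.abs(spec) ** 2) * (2.0 / (fs_hz * np.sum(win**2)))
    power[0] /= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    if freq_bins is not None:
        power = power[freq_bins]
    return power


def compute_ersp(
    epochs: EpochSet,
    condition: str,
    window_samples: int = 400,
    pad_ratio: int = 64,
    n_times: int = 200,
    fmin_hz: float = 0.0,
    fmax_hz: float = 45.0,
    channels: list[int] | None = None,
    baseline_window_s: tuple[float, float] | None = None,
    floor_db: float = FLOOR_DB,
) -> ERSPMap:
    """Sliding-window ERSP averaged over retained trials, per channel.

    Window start positions are spread evenly to yield ``n_times`` output
    frames; each frame is Hann-tapered and zero-padded by ``pad_ratio``.
    Only bins with fmin < f ≤ fmax are computed (the zero-padded DFT at a bin
    equals the dot product with the corresponding complex exponential, so the
    restriction is exact, not an approximation). Power is floored at
    ``floor_db`` before conversion to dB. With ``baseline_window_s`` the mean
    pre-stimulus log-power per frequency is subtracted (relative ERSP).
    """
    if condition not in epochs.epochs:
        raise ValueError(f"no epochs for condition {condition!r}")
    data = epochs.epochs[condition]
    n_trials, n_channels, n_samp = data.shape
    if n_samp < window_samples:
        raise ValueError("epoch shorter than the analysis window")
    fs = epochs.fs_hz
    ch_idx = list(range(n_channels)) if channels is None else list(channels)

    starts = np.unique(np.round(np.linspace(0, n_samp - window_samples, n_times)).astype(int))
    times_s = epochs.times_s[starts] + (window_samples / 2.0) / fs

    nfft = window_samples * pad_ratio
    all_freqs = np.arange(nfft // 2 + 1) * (fs / nfft)
    bins = np.flatnonzero((all_freqs > fmin_hz) & (all_freqs <= fmax_hz + 1e-12))
    freqs = all_freqs[bins]
    win = _hann_periodic(window_samples)
    # zero-padded DFT restricted to the analysis bins, as a matrix product
    dft = np.exp(
        -2j * np.pi * np.outer(np.arange(window_samples), bins) / nfft
    ) * win[:, None]
    scale = 2.0 / (fs * np.sum(win**2))

    keep = ~epochs.rejected[condition]
    power = np.zeros((len(ch_idx), len(freqs), len(starts)))
    for out_c, ch in enumerate(ch_idx):
        trials = np.flatnonzero(keep[:, ch])
        if len(trials) == 0:
            power[out_c] = 10.0 ** (floor_db / 10.0)
            continue
        frames = np.stack(
            [data[trials, ch, s: s + window_samples] for s in starts], axis=2
        )  # (n_keep, window, n_frames)
        acc = np.zeros((len(freqs), len(starts)))
        for tr in range(frames.shape[0]):
            spec = dft.T @ frames[tr]                  # (freqs, n_frames)
            acc += (spec.real**2 + spec.imag**2)
        power[out_c] = acc * (scale / len(trials))
        if bins[0] == 0:
            power[out_c, 0] /= 2.0
    power = np.maximum(power, 10.0 ** (floor_db / 10.0))
    power_db = 10.0 * np.log10(power)
    if baseline_window_s is not None:
        base = (times_s >= baseline_window_s[0]) & (times_s < baseline_window_s[1])
        if not base.any():
            raise ValueError("baseline window contains no ERSP frames")
        power_db = power_db - power_db[:, :, base].mean(axis=2, keepdims=True)
    return ERSPMap(
        power_db=power_db, freqs_hz=freqs, times_s=times_s, fs_hz=fs,
        channel_names=tuple(epochs.channel_names[i] for i in ch_idx),
        window_samples=window_samples, pad_ratio=pad_ratio,
    )


def _band_mask(freqs: np.ndarray, band: tuple[float, float], fmax: float) -> np.ndarray:
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
    if hi >= fmax - 1e-9:    # top band includes its upper edge
        mask |= np.abs(freqs - hi) < 1e-9
        mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return mask


def band_max(ersp: ERSPMap, band: tuple[float, float], channel: int = 0) -> dict:
    """Maximum ERSP within a band with its frequency and latency.

    Ties break to the lowest frequency, then the earliest time.
    """
    mask = _band_mask(ersp.freqs_hz, band, float(ersp.freqs_hz[-1]))
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the frequency axis")
    sub = ersp.power_db[channel][mask]               # (freqs_in_band, times)
    flat = int(np.argmax(sub))
    fi, ti = np.unravel_index(flat, sub.shape)
    return {
        "max_ersp_db": float(sub[fi, ti]),
        "frequency_hz": float(ersp.freqs_hz[mask][fi]),
        "latency_ms": float(ersp.times_s[ti] * 1000.0),
    }


def band_max_table(
    ersp: ERSPMap,
    bands: dict[str, tuple[float, float]] | None = None,
    include_whole_range: bool = True,
) -> pd.DataFrame:
    """Tidy per-(channel, band) summary of maximum ERSP, frequency, latency."""
    bands = dict(bands if bands is not None else BANDS)
    if include_whole_range:
        bands["whole_range"] = WHOLE_RANGE
    rows = []
    for ch_i, ch in enumerate(ersp.channel_names):
        for name, band in bands.items():
            entry = band_max(ersp, band, channel=ch_i)
            rows.append({"channel": ch, "band": name, **entry})
    return pd.DataFrame(rows)
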