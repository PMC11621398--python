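"""Resting-state spectral analysis: Welch PSD with bad-epoch exclusion.

Continuous (filtered) recordings are segmented into 2-s epochs with 50 %
overlap; segments whose peak-to-peak range exceeds the delta criterion
(500 µV, per channel) are excluded; the remaining segments are Hamming-tapered
and their one-sided periodograms averaged (Welch's method, density
normalisation including the taper power), restricted to 1–45 Hz and expressed
in dB re 1 µV²/Hz. Band power defaults to the mean *linear* density over the
band's bins converted to dB afterwards (a physical power average); averaging
in dB is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import RawRecording
from .timefreq import BANDS


@dataclass
class PSDSpectrum:
    """Welch power spectral density per channel.

    ``density`` is linear µV²/Hz, shape (channels, freqs); ``db`` converts.
    ``n_segments_used`` counts retained segments per channel;
    ``n_segments_total`` is the pre-rejection segment count.
    """

    density: np.ndarray
    freqs_hz: np.ndarray
    channel_names: tuple[str, ...]
    segment_s: float
    overlap_fraction: float
    n_segments_used: np.ndarray
    n_segments_total: int

    @property
    def db(self) -> np.ndarray:
        return 10.0 * np.log10(self.density)


def _hamming_periodic(n: int) -> np.ndarray:
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(n) / n)


def welch_psd(
    rec: RawRecording | np.ndarray,
    fs_hz: float | None = None,
    segment_s: float = 2.0,
    overlap: float = 0.5,
    delta_uv: float = 500.0,
    fmin_hz: float = 1.0,
    fmax_hz: float = 45.0,
) -> PSDSpectrum:
    """Welch PSD of a continuous recording with delta-criterion segment rejection.

    For a T-second recording, ``floor((T - segment_s)/step) + 1`` segments are
    formed (step = segment_s·(1 − overlap)); a segment is excluded for a
    channel when its range strictly exceeds ``delta_uv`` on that channel.
    Raises if every segment of any channel is rejected.
    """
    if isinstance(rec, RawRecording):
        data, fs, ch_names = rec.data, rec.fs_hz, rec.channel_names
    else:
        data = np.atleast_2d(np.asarray(rec, float))
        if fs_hz is None:
            raise ValueError("fs_hz required for array input")
        fs, ch_names = fs_hz, tuple(f"ch{i+1}" for i in range(data.shape[0]))
    nper = int(round(segment_s * fs))
    step = int(round(nper * (1.0 - overlap)))
    n_channels, n_samp = data.shape
    if n_samp < nper:
        raise ValueError("recording shorter than one segment")
    starts = np.arange(0, n_samp - nper + 1, step)

    win = _hamming_periodic(nper)
    scale = 2.0 / (fs * np.sum(win**2))
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    keep_f = (freqs >= fmin_hz - 1e-9) & (freqs <= fmax_hz + 1e-9)

    density = np.zeros((n_channels, int(keep_f.sum())))
    used = np.zeros(n_channels, dtype=int)
    for ch in range(n_channels):
        segs = np.stack([data[ch, s: s + nper] for s in starts])
        ptp = segs.max(axis=1) - segs.min(axis=1)
        good = ptp <= delta_uv
        if not good.any():
            raise ValueError(
                f"all {len(starts)} segments rejected on channel {ch_names[ch]} "
                f"(delta criterion {delta_uv} µV)"
            )
        spec = np.fft.rfft(segs[good] * win, axis=1)
        pxx = (np.abs(spec) ** 2) * scale
        pxx[:, 0] /= 2.0
        if nper % 2 == 0:
            pxx[:, -1] /= 2.0
        density[ch] = pxx[:, keep_f].mean(axis=0)
        used[ch] = int(good.sum())
    return PSDSpectrum(
        density=density, freqs_hz=freqs[keep_f], channel_names=ch_names,
        segment_s=segment_s, overlap_fraction=overlap,
        n_segments_used=used, n_segments_total=len(starts),
    )


def band_power(psd: PSDSpectrum, band: tuple[float, float],
               mode: str = "mean_linear") -> np.ndarray:
    """Band power in dB per channel.

    ``mean_linear`` (default): mean linear density over the band's bins, then
    dB. ``mean_db``: mean of per-bin dB values.
    """
    lo, hi = band
    sel = (psd.freqs_hz >= lo - 1e-9) & (psd.freqs_hz <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins")
    if mode == "mean_linear":
        return 10.0 * np.log10(psd.density[:, sel].mean(axis=1))
    if mode == "mean_db":
        return (10.0 * np.log10(psd.density[:, sel])).mean(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def band_integrated_power(psd: PSDSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Integrated linear power (µV²) over a band: Σ density · Δf per channel.

    Rectangular bin integration, so a sinusoid's full mainlobe power is
    accounted to the bins it occupies (a pure A-amplitude tone at a bin centre
    integrates to A²/2).
    """
    lo, hi = band
    sel = (psd.freqs_hz >= lo - 1e-9) & (psd.freqs_hz <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins")
    df = float(psd.freqs_hz[1] - psd.freqs_hz[0])
    return psd.density[:, sel].sum(axis=1) * df


def band_power_table(
    psd: PSDSpectrum,
    bands: dict[str, tuple[float, float]] | None = None,
    mode: str = "mean_linear",
) -> pd.DataFrame:
    """Tidy per-(channel, band) resting band power in dB."""
    bands = bands if bands is not None else BANDS
    rows = []
    for name, band in bands.items():
        vals = band_power(psd, band, mode=mode)
        for ch, v in zip(psd.channel_names, vals):
            rows.append({"channel": ch, "band": name, "db": float(v)})
    return pd.DataFrame(rows)
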