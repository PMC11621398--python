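"""ERP difference curves and windowed component scoring.

Components are scored on the deviant-minus-standard difference curve (the
frequent standard habituates and rarely shows pronounced deflections) inside
predefined windows — P1 20–70, N1 35–120, P2 60–260, N2 100–320,
P3 130–600 ms — as the windowed global extremum of the appropriate polarity,
ties to the earliest sample. Because windows overlap, a latency inversion is
possible on noisy traces; a deterministic ordering rule re-searches each
window from the previous component's latency onward so that
P1 ≤ N1 ≤ P2 ≤ N2 ≤ P3. Peak-to-peak amplitudes (P1N1, N1P2, P2N2, N2P3) are
signed positive-minus-negative differences, so canonical morphology yields
positive values; an absolute-value variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

#: (window_start_ms, window_end_ms, polarity) — windows half-open [start, end)
DEFAULT_WINDOWS: dict[str, tuple[float, float, int]] = {
    "P1": (20.0, 70.0, +1),
    "N1": (35.0, 120.0, -1),
    "P2": (60.0, 260.0, +1),
    "N2": (100.0, 320.0, -1),
    "P3": (130.0, 600.0, +1),
}

COMPONENT_ORDER = ("P1", "N1", "P2", "N2", "P3")
PEAK_TO_PEAK_PAIRS = (("P1", "N1"), ("N1", "P2"), ("P2", "N2"), ("N2", "P3"))


def average_erp(epochs: EpochSet, condition: str) -> np.ndarray:
    """Per-channel mean trace over retained trials; shape (channels, samples).

    Channels with zero retained trials yield NaN rows; raises if no channel
    retains any trial.
    """
    if condition not in epochs.epochs:
        raise ValueError(f"no epochs for condition {condition!r}")
    data = epochs.epochs[condition]
    keep = ~epochs.rejected[condition]            # (trials, channels)
    counts = keep.sum(axis=0)
    if not counts.any():
        raise ValueError(f"zero retained epochs for condition {condition!r}")
    w = keep.astype(float)[:, :, None]
    with np.errstate(invalid="ignore"):
        avg = (data * w).sum(axis=0) / counts[:, None]
    return avg


def grand_average(subject_averages: list[np.ndarray]) -> np.ndarray:
    """Unweighted mean of per-subject average traces (equal subject weight
    regardless of trial counts)."""
    if not subject_averages:
        raise ValueError("no subject averages")
    return np.mean(np.stack(subject_averages), axis=0)


def difference_wave(deviant_avg: np.ndarray, standard_avg: np.ndarray) -> np.ndarray:
    """Pointwise deviant − standard."""
    deviant_avg = np.asarray(deviant_avg, float)
    standard_avg = np.asarray(standard_avg, float)
    if deviant_avg.shape != standard_avg.shape:
        raise ValueError("deviant and standard traces differ in shape")
    return deviant_avg - standard_avg


def pick_components(
    trace: np.ndarray,
    times_s: np.ndarray,
    windows: dict[str, tuple[float, float, int]] = DEFAULT_WINDOWS,
    enforce_order: bool = True,
    absolute_peak_to_peak: bool = False,
) -> dict:
    """Score one trace: per-component latency/amplitude plus peak-to-peaks.

    Positive components take the windowed maximum, negative the minimum; ties
    break to the earliest sample. With ``enforce_order`` each component is
    searched from the previous component's latency onward. Returns
    ``{"P1": {"latency_ms", "amplitude_uv"}, ..., "P1N1": value, ...}``.
    """
    trace = np.asarray(trace, float)
    t_ms = np.asarray(times_s, float) * 1000.0
    res: dict = {}
    prev_lat = -np.inf
    for name in COMPONENT_ORDER:
        if name not in windows:
            continue
        lo, hi, pol = windows[name]
        start = max(lo, prev_lat) if enforce_order else lo
        sel = (t_ms >= start) & (t_ms < hi)
        if not sel.any():
            raise ValueError(f"window for {name} [{start}, {hi}) ms outside trace")
        seg = trace[sel]
        idx = int(np.argmax(seg)) if pol > 0 else int(np.argmin(seg))
        lat = float(t_ms[sel][idx])
        res[name] = {"latency_ms": lat, "amplitude_uv": float(seg[idx])}
        if enforce_order:
            prev_lat = lat
    for a, b in PEAK_TO_PEAK_PAIRS:
        if a in res and b in res:
            pos, neg = (a, b) if windows[a][2] > 0 else (b, a)
            val = res[pos]["amplitude_uv"] - res[neg]["amplitude_uv"]
            res[a + b] = abs(val) if absolute_peak_to_peak else val
    return res


def component_table(
    epochs_by_subject: dict[str, EpochSet],
    group_by_subject: dict[str, str] | None = None,
    windows: dict = DEFAULT_WINDOWS,
    deviant: str = "deviant",
    standard: str = "standard",
) -> pd.DataFrame:
    """Tidy per-(subject, channel) component scores from difference curves.

    Columns: subject, group, channel, component, latency_ms, amplitude_uv,
    plus one row per peak-to-peak pair (component = e.g. "P1N1",
    amplitude_uv = the peak-to-peak value, latency NaN).
    """
    rows = []
    for subject, ep in epochs_by_subject.items():
        group = (group_by_subject or {}).get(subject, "")
        diff = difference_wave(average_erp(ep, deviant), average_erp(ep, standard))
        for ch_i, ch in enumerate(ep.channel_names):
            if np.isnan(diff[ch_i]).all():
                continue
            scores = pick_components(diff[ch_i], ep.times_s, windows)
            for name in COMPONENT_ORDER:
                if name in scores:
                    rows.append({"subject": subject, "group": group, "channel": ch,
                                 "component": name,
                                 "latency_ms": scores[name]["latency_ms"],
                                 "amplitude_uv": scores[name]["amplitude_uv"]})
            for a, b in PEAK_TO_PEAK_PAIRS:
                key = a + b
                if key in scores:
                    rows.append({"subject": subject, "group": group, "channel": ch,
                                 "component": key, "latency_ms": np.nan,
                                 "amplitude_uv": scores[key]})
    return pd.DataFrame(rows)
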