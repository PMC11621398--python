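"""File interfaces: EDF recordings, BIDS-style events TSV, sidecars, containers.

Recordings are exchanged as European Data Format (EDF) files — one file per
session, channel labels row-major R1C1…R3C3 with the front-row centre
electrode doubling as the frontocentral "FC" site — plus a tab-separated
events file (onset, duration, trial_type, block) and a JSON sidecar carrying
the generative ground truth for synthetic sessions. The EDF writer here
implements the fixed-layout EDF header + 16-bit data records directly;
reading goes through ``mne.io.read_raw_edf``, which also serves as an
independent check of the writer. EDF quantises to 16 bits over the physical
range, so round-trips are exact only to that resolution.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .synthetic import GroundTruth, RawRecording, StimulusSchedule


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> bytes:
    for fmt in (f"%.{p}g" for p in range(7, 0, -1)):
        s = fmt % value
        if len(s) <= width:
            return _ascii(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path, rec: RawRecording, record_duration_s: float = 1.0) -> Path:
    """Write a recording to EDF (16-bit); the final partial record is zero-padded."""
    path = Path(path)
    data = rec.data
    n_signals = data.shape[0]
    spr = int(round(rec.fs_hz * record_duration_s))   # samples per record
    n_records = int(np.ceil(data.shape[1] / spr))
    padded = np.zeros((n_signals, n_records * spr))
    padded[:, : data.shape[1]] = data

    phys_min = np.floor(padded.min(axis=1))
    phys_max = np.ceil(padded.max(axis=1))
    same = phys_max <= phys_min
    phys_min[same] -= 1.0
    phys_max[same] += 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header_bytes = 256 * (1 + n_signals)
    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii("X X X X", 80))                       # patient id
        f.write(_ascii("Startdate X X X X", 80))             # recording id
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(header_bytes, 8))
        f.write(_ascii("", 44))
        f.write(_ascii(n_records, 8))
        f.write(_num(record_duration_s, 8))
        f.write(_ascii(n_signals, 4))
        for name in rec.channel_names:
            f.write(_ascii(name, 16))
        for _ in range(n_signals):
            f.write(_ascii("", 80))                          # transducer
        for _ in range(n_signals):
            f.write(_ascii("uV", 8))
        for v in phys_min:
            f.write(_num(v, 8))
        for v in phys_max:
            f.write(_num(v, 8))
        for _ in range(n_signals):
            f.write(_ascii(dig_min, 8))
        for _ in range(n_signals):
            f.write(_ascii(dig_max, 8))
        for _ in range(n_signals):
            f.write(_ascii("", 80))                          # prefiltering
        for _ in range(n_signals):
            f.write(_ascii(spr, 8))
        for _ in range(n_signals):
            f.write(_ascii("", 32))
        for r in range(n_records):
            f.write(digital[:, r * spr: (r + 1) * spr].tobytes())
    return path


def read_edf(path, n_samples: int | None = None) -> RawRecording:
    """Read an EDF recording into microvolts via mne."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6                              # volts -> µV
    if n_samples is not None:
        data = data[:, :n_samples]
    return RawRecording(
        data=data, fs_hz=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names), schedule=None, truth=None,
    )


# ---------------------------------------------------------------------------
# events, ground truth, drinking, epochs
# ---------------------------------------------------------------------------

def write_events_tsv(path, schedule: StimulusSchedule) -> Path:
    path = Path(path)
    df = schedule.to_frame().rename(columns={"onset_s": "onset", "condition": "trial_type"})
    df["duration"] = schedule.tone_params[synthetic.STANDARD]["duration_s"]
    df[["onset", "duration", "trial_type", "block"]].to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path, isi_s: float = 1.0) -> StimulusSchedule:
    df = pd.read_csv(path, sep="\t")
    return StimulusSchedule(
        onsets_s=df["onset"].to_numpy(float),
        blocks=df.get("block", pd.Series(np.ones(len(df)))).to_numpy(int),
        conditions=df["trial_type"].to_numpy(object),
        isi_s=isi_s,
    )


def _truth_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _truth_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _truth_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_truth_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_truth_json(path, truth: GroundTruth) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_truth_to_jsonable(truth), indent=1))
    return path


def write_drinking_csv(path, profile) -> Path:
    path = Path(path)
    profile.intake.to_csv(path, index=False)
    return path


def read_drinking_csv(path, calendar=None):
    from .consumption import DrinkingProfile, infer_calendar

    intake = pd.read_csv(path)
    if calendar is None:
        calendar = infer_calendar(intake)
    return DrinkingProfile(intake=intake, calendar=tuple(calendar))


def write_epochs(path, epochs) -> Path:
    """Single-file container for an EpochSet: npz arrays + JSON metadata."""
    path = Path(path)
    meta = {
        "fs_hz": epochs.fs_hz,
        "channel_names": list(epochs.channel_names),
        "baseline_window_s": list(epochs.baseline_window_s),
        "conditions": epochs.conditions,
        "n_dropped_out_of_bounds": epochs.n_dropped_out_of_bounds,
        "qc": epochs.qc,
    }
    arrays = {"times_s": epochs.times_s, "_meta": np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)}
    for cond in epochs.conditions:
        arrays[f"epochs_{cond}"] = epochs.epochs[cond]
        arrays[f"rejected_{cond}"] = epochs.rejected[cond]
    np.savez_compressed(path, **arrays)
    return path


def read_epochs(path):
    from .preprocessing import EpochSet

    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        epochs = {c: z[f"epochs_{c}"] for c in meta["conditions"]}
        rejected = {c: z[f"rejected_{c}"] for c in meta["conditions"]}
        return EpochSet(
            epochs=epochs, rejected=rejected, times_s=z["times_s"],
            fs_hz=meta["fs_hz"], channel_names=tuple(meta["channel_names"]),
            baseline_window_s=tuple(meta["baseline_window_s"]),
            n_dropped_out_of_bounds=meta["n_dropped_out_of_bounds"],
            qc=meta["qc"],
        )
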