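"""Pipeline configuration: one structured mapping, YAML round-trippable.

Every analysis choice that the methods leave open is a field here with its
default equal to the package's documented decision (filter transition width,
delta criterion, channel-drop fraction, ERSP baseline mode, band aggregation,
Sidak family scope). Simulation defaults are the full paradigm: 1344
standards / 276 deviants in 6 blocks at 1.05 s SOA on a 9-channel 3 kHz
array.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    presets: tuple[str, ...] = ("control", "dependent")
    n_subjects: int = 10

    # stimulus schedule
    n_standards: int = 1344
    n_deviants: int = 276
    n_blocks: int = 6
    isi_s: float = 1.0
    block_gap_s: float = 30.0

    # simulation
    n_channels: int = 9
    noise_sd_uv: float = 30.0
    background_level_uv2_hz: float = 20.0
    artifact_count: int = 5
    resting_duration_s: float = 300.0

    # filtering
    filter_low_hz: float = 0.1
    filter_high_hz: float = 45.0
    filter_beta: float = 5.65
    filter_transition_hz: float = 0.2

    # epoching / artifact rejection
    epoch_window_s: tuple[float, float] = (-0.1, 0.7)
    baseline_window_s: tuple[float, float] = (-0.1, 0.0)
    delta_uv: float = 500.0
    channel_drop_fraction: float = 0.3

    # ERSP
    ersp_window_samples: int = 400
    ersp_pad_ratio: int = 64
    ersp_n_times: int = 200
    ersp_baseline: bool = False       # absolute dB by default
    ersp_channels: tuple[str, ...] = ("FC",)

    # resting PSD
    psd_segment_s: float = 2.0
    psd_overlap: float = 0.5
    band_aggregation: str = "mean_linear"   # or "mean_db"

    # statistics
    sidak_scope: str = "per_metric"         # correlation-family scope

    # drinking simulation
    drinking_bl_means: tuple[float, float, float] = (1.02, 1.25, 1.16)
    drinking_ade_increments: tuple[float, float, float] = (0.56, 0.24, 0.43)
    drinking_noise_sd: float = 0.25
    drinking_between_sd: float = 0.30

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)
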