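"""Condition presets for the synthetic generator.

Four cohorts are shipped: alcohol-naive controls, alcohol-dependent rats in
abstinence, and dependent rats after an acute dose of psilocybin or of the
mGluR2/3 agonist LY379268. Effect *directions* follow the reported group
contrasts — dependent animals show reduced P1N1/N1P2 peak-to-peak amplitudes
with earlier N1/P2 peaks, enhanced P2N2, reduced and later-peaking
delta-through-beta event-related oscillations but increased gamma, a shift of
event-related beta activity toward the high-beta range, and resting-state
spectra dominated by high-beta (>18 Hz) power where controls are dominated by
low beta (12–15 Hz). Effect *magnitudes* are this package's configuration,
not reported values; the drug presets move the dependent phenotype part-way
back toward control. Standards are rendered at a fraction of the deviant
response (habituation to the frequent tone).
"""

from __future__ import annotations

import numpy as np

from .synthetic import (
    ArtifactSpec,
    BandLevel,
    DEVIANT,
    ErpComponent,
    GroundTruth,
    OscBurst,
    STANDARD,
)

PRESET_NAMES = ("control", "dependent", "dependent+psilocybin", "dependent+LY")

#: fraction of the deviant response carried by the frequent standard tone
STANDARD_ATTENUATION = 0.25


def _components(p1, n1, p2, n2, p3):
    names = ("P1", "N1", "P2", "N2", "P3")
    pols = (+1, -1, +1, -1, +1)
    return {
        name: ErpComponent(latency_ms=lat, amplitude_uv=amp, width_ms=w, polarity=pol)
        for name, (lat, amp, w), pol in zip(names, (p1, n1, p2, n2, p3), pols)
    }


# (latency_ms, amplitude_uV, FWHM_ms) per component
_ERP = {
    "control": _components((45, 20, 24), (90, 40, 28), (165, 30, 50),
                           (250, 20, 60), (380, 18, 90)),
    "dependent": _components((42, 12, 24), (80, 24, 28), (150, 24, 50),
                             (245, 30, 60), (375, 8, 90)),
    "dependent+psilocybin": _components((44, 16, 24), (86, 32, 28), (158, 27, 50),
                                        (248, 25, 60), (378, 13, 90)),
    "dependent+LY": _components((43, 15, 24), (84, 30, 28), (156, 26, 50),
                                (247, 26, 60), (377, 12, 90)),
}

# (center_hz, onset_ms, duration_ms, amplitude_uV) per band; dependent rats:
# delta–beta reduced and later, beta centred high (22 Hz vs 13.5 Hz), gamma
# increased and earlier.
_ERO = {
    "control": [
        OscBurst(2.5, 50, 500, 45.0), OscBurst(6.0, 80, 350, 36.0),
        OscBurst(10.0, 100, 300, 30.0), OscBurst(13.5, 120, 250, 40.0),
        OscBurst(38.0, 150, 150, 8.0),
    ],
    "dependent": [
        OscBurst(2.5, 120, 500, 30.0), OscBurst(6.0, 150, 350, 24.0),
        OscBurst(10.0, 170, 300, 18.0), OscBurst(22.0, 190, 250, 38.0),
        OscBurst(38.0, 100, 150, 15.0),
    ],
    "dependent+psilocybin": [
        OscBurst(2.5, 80, 500, 38.0), OscBurst(6.0, 110, 350, 30.0),
        OscBurst(10.0, 130, 300, 24.0), OscBurst(17.0, 150, 250, 36.0),
        OscBurst(38.0, 130, 150, 11.0),
    ],
    "dependent+LY": [
        OscBurst(2.5, 90, 500, 36.0), OscBurst(6.0, 120, 350, 28.0),
        OscBurst(10.0, 140, 300, 23.0), OscBurst(18.0, 160, 250, 35.0),
        OscBurst(38.0, 130, 150, 12.0),
    ],
}

# resting-state flat-density components (µV²/Hz); dependent: high-beta
# dominance and elevated gamma.
_RESTING = {
    "control": (
        BandLevel("delta", 1, 4, 5.0), BandLevel("theta", 4, 8, 4.0),
        BandLevel("alpha", 8, 12, 3.0), BandLevel("beta_low", 12, 15, 3.0),
        BandLevel("beta_mid", 15, 18, 1.5), BandLevel("beta_high", 18, 30, 0.8),
        BandLevel("gamma", 30, 45, 0.5),
    ),
    "dependent": (
        BandLevel("delta", 1, 4, 4.0), BandLevel("theta", 4, 8, 3.2),
        BandLevel("alpha", 8, 12, 2.5), BandLevel("beta_low", 12, 15, 1.0),
        BandLevel("beta_mid", 15, 18, 1.8), BandLevel("beta_high", 18, 30, 3.5),
        BandLevel("gamma", 30, 45, 1.2),
    ),
    "dependent+psilocybin": (
        BandLevel("delta", 1, 4, 4.5), BandLevel("theta", 4, 8, 3.6),
        BandLevel("alpha", 8, 12, 2.8), BandLevel("beta_low", 12, 15, 2.0),
        BandLevel("beta_mid", 15, 18, 1.6), BandLevel("beta_high", 18, 30, 2.0),
        BandLevel("gamma", 30, 45, 0.8),
    ),
    "dependent+LY": (
        BandLevel("delta", 1, 4, 4.4), BandLevel("theta", 4, 8, 3.5),
        BandLevel("alpha", 8, 12, 2.7), BandLevel("beta_low", 12, 15, 1.8),
        BandLevel("beta_mid", 15, 18, 1.7), BandLevel("beta_high", 18, 30, 2.2),
        BandLevel("gamma", 30, 45, 0.9),
    ),
}


def make_truth(
    preset: str,
    seed: int = 0,
    noise_sd_uv: float = 30.0,
    background_level_uv2_hz: float = 20.0,
    artifact_spec: ArtifactSpec | None = None,
    include_bursts: bool = True,
) -> GroundTruth:
    """GroundTruth for one of the shipped cohort presets."""
    if preset not in PRESET_NAMES:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESET_NAMES}")
    dev = _ERP[preset]
    std = {
        name: ErpComponent(c.latency_ms, c.amplitude_uv * STANDARD_ATTENUATION,
                           c.width_ms, c.polarity)
        for name, c in dev.items()
    }
    bursts_dev = list(_ERO[preset]) if include_bursts else []
    bursts_std = [
        OscBurst(b.center_hz, b.onset_ms, b.duration_ms,
                 b.amplitude_uv * STANDARD_ATTENUATION)
        for b in bursts_dev
    ]
    return GroundTruth(
        components={DEVIANT: dev, STANDARD: std},
        ero_bursts={DEVIANT: bursts_dev, STANDARD: bursts_std},
        resting_profile=_RESTING[preset],
        one_over_f_alpha=1.0,
        background_level_uv2_hz=background_level_uv2_hz,
        noise_sd_uv=noise_sd_uv,
        artifact_spec=artifact_spec or ArtifactSpec(count=0),
        seed=seed,
    )


def subject_truth(truth: GroundTruth, rng: np.random.Generator,
                  amp_jitter: float = 0.15, latency_jitter_ms: float = 5.0) -> GroundTruth:
    """Per-animal variant of a preset: multiplicative amplitude jitter
    (lognormal, sigma ``amp_jitter``) and additive latency jitter, applied
    consistently across conditions so the standard stays an attenuated copy."""
    scale = {name: float(rng.lognormal(0.0, amp_jitter)) for name in ("P1", "N1", "P2", "N2", "P3")}
    shift = {name: float(rng.normal(0.0, latency_jitter_ms)) for name in scale}
    comps = {
        cond: {
            name: ErpComponent(c.latency_ms + shift[name], c.amplitude_uv * scale[name],
                               c.width_ms, c.polarity)
            for name, c in by_name.items()
        }
        for cond, by_name in truth.components.items()
    }
    from dataclasses import replace
    return replace(truth, components=comps, seed=int(rng.integers(2**31)))


def simulate_feature_table(
    n_per_group: int = 10,
    effect_in_sd: float = 1.0,
    n_channels: int = 9,
    subject_sd: float = 0.8,
    channel_sd: float = 1.8,
    control_mean: float = 60.0,
    within_group_sd: float = 9.0,
    seed: int = 0,
) -> "pd.DataFrame":
    """Subject x channel table of a neural marker (canonically P1N1, µV) under
    the dependent-vs-control contrast.

    The generative model separates animal-level variability from single-channel
    measurement noise: value = group mean + subject offset + channel noise, with
    ``subject_sd`` and ``channel_sd`` expressed as fractions of the within-group
    SD of *subject-level* means (so that SD is ``within_group_sd`` by
    construction: subject_sd² + channel_sd²/n_channels = 1). The dependent
    group mean is shifted down by ``effect_in_sd`` of that SD.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    s = within_group_sd
    rows = []
    for group, mean in (("control", control_mean),
                        ("dependent", control_mean - effect_in_sd * s)):
        for subj in range(n_per_group):
            offset = rng.normal(0.0, subject_sd * s)
            vals = mean + offset + rng.normal(0.0, channel_sd * s, size=n_channels)
            for ch in range(n_channels):
                rows.append({"group": group, "subject": f"{group}{subj:02d}",
                             "channel": f"ch{ch + 1}", "value": vals[ch]})
    return pd.DataFrame(rows)
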