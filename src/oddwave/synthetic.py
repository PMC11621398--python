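"""Ground-truth-annotated synthetic ECoG and drinking data.

Everything downstream of this module is exercised against recordings whose
generative parameters are known exactly: a two-tone auditory oddball session
(frequent standards, rare deviants, deviants never adjacent), stimulus-locked
ERP deflections modelled as Gaussian-windowed monophasic kernels, band-limited
event-locked oscillatory bursts, stationary resting oscillations on a 1/f^a
background, occasional high-amplitude artifacts, and four-bottle drinking
trajectories exhibiting an alcohol-deprivation effect.

The electrode layout emulates a 3 x 3 epidural prefrontal array sampled at
3 kHz; channels share a common background-noise source (default fraction 0.7)
plus independent per-channel noise, and carry identical evoked kernels, so
channels are near-exchangeable, matching the absence of a channel effect in
the analyses this generator feeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consumption import DEFAULT_CALENDAR, SOLUTIONS, DrinkingProfile, Phase

FS_HZ = 3000.0
N_ROWS = 3
N_COLS = 3
CHANNEL_NAMES = tuple(f"R{r}C{c}" for r in range(1, N_ROWS + 1) for c in range(1, N_COLS + 1))
FC_CHANNEL = "R1C2"  # frontocentral alias: front-row centre electrode

STANDARD = "standard"
DEVIANT = "deviant"

#: tone parameters per condition (duration s, carrier Hz, level dB SPL, ramp s).
#: Tones exist only as event labels; no acoustic waveform is synthesised.
TONE_PARAMS = {
    STANDARD: {"duration_s": 0.050, "freq_hz": 1000.0, "level_db": 70.0, "ramp_s": 0.005},
    DEVIANT: {"duration_s": 0.050, "freq_hz": 2000.0, "level_db": 80.0, "ramp_s": 0.005},
}


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered oddball event list: (onset_s, block, condition) per tone."""

    onsets_s: np.ndarray          # float seconds, strictly increasing
    blocks: np.ndarray            # int, 1..n_blocks
    conditions: np.ndarray        # object array of {standard, deviant}
    isi_s: float = 1.0
    tone_params: dict = field(default_factory=lambda: dict(TONE_PARAMS))

    def __len__(self) -> int:
        return len(self.onsets_s)

    @property
    def soa_s(self) -> float:
        """Stimulus-onset asynchrony: inter-stimulus interval + tone duration."""
        return self.isi_s + self.tone_params[STANDARD]["duration_s"]

    def n_condition(self, condition: str) -> int:
        return int(np.sum(self.conditions == condition))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets_s, "block": self.blocks, "condition": self.conditions}
        )


def _split_counts(total: int, n_blocks: int) -> list[int]:
    # remainder assigned deterministically to the earliest blocks
    base, rem = divmod(total, n_blocks)
    return [base + (1 if b < rem else 0) for b in range(n_blocks)]


def _place_deviants(n_events: int, n_dev: int, forbid_first: bool, rng) -> np.ndarray:
    """Uniform draw of deviant positions with no two adjacent.

    Classic stars-and-bars bijection: choosing k non-adjacent positions out of
    n is choosing k unordered slots out of n - k + 1 and spreading them.
    When ``forbid_first`` the first event must be a standard (the previous
    block ended on a deviant).
    """
    n_avail = n_events - (1 if forbid_first else 0)
    if n_dev == 0:
        return np.zeros(0, dtype=int)
    if n_avail - n_dev + 1 < n_dev:
        raise ValueError(
            f"cannot place {n_dev} non-adjacent deviants among {n_events} events"
        )
    slots = np.sort(rng.choice(n_avail - n_dev + 1, size=n_dev, replace=False))
    pos = slots + np.arange(n_dev)
    return pos + (1 if forbid_first else 0)


def build_schedule(
    n_standards: int = 1344,
    n_deviants: int = 276,
    n_blocks: int = 6,
    isi_s: float = 1.0,
    seed: int = 0,
    block_gap_s: float = 30.0,
) -> StimulusSchedule:
    """Randomised oddball schedule with deviants never adjacent.

    Counts are split across blocks (remainders to early blocks); within each
    block deviant positions are drawn uniformly under the adjacency
    constraint, reproducibly from ``seed``. Onsets advance by one SOA
    (``isi_s`` + tone duration) per tone plus ``block_gap_s`` between blocks.
    """
    if n_standards < 0 or n_deviants < 0 or n_blocks < 1:
        raise ValueError("counts must be non-negative and n_blocks >= 1")
    if n_standards < n_deviants - 1:
        raise ValueError(
            f"{n_deviants} deviants cannot be separated by {n_standards} standards"
        )
    rng = np.random.default_rng(seed)
    std_per_block = _split_counts(n_standards, n_blocks)
    dev_per_block = _split_counts(n_deviants, n_blocks)

    soa = isi_s + TONE_PARAMS[STANDARD]["duration_s"]
    onsets, blocks, conds = [], [], []
    t = 0.0
    prev_ended_deviant = False
    for b in range(n_blocks):
        n_b = std_per_block[b] + dev_per_block[b]
        pos = _place_deviants(n_b, dev_per_block[b], prev_ended_deviant, rng)
        cond_b = np.full(n_b, STANDARD, dtype=object)
        cond_b[pos] = DEVIANT
        onsets.extend(t + soa * np.arange(n_b))
        blocks.extend([b + 1] * n_b)
        conds.extend(cond_b)
        t += soa * n_b + block_gap_s
        prev_ended_deviant = n_b > 0 and cond_b[-1] == DEVIANT
    return StimulusSchedule(
        onsets_s=np.asarray(onsets), blocks=np.asarray(blocks, dtype=int),
        conditions=np.asarray(conds, dtype=object), isi_s=isi_s,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErpComponent:
    """One monophasic deflection: Gaussian kernel parameterised by the three
    quantities the analysis measures (latency, amplitude, width)."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float       # full width at half maximum of the Gaussian kernel
    polarity: int         # +1 or -1

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("width must be positive")
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be non-negative")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class OscBurst:
    """Event-locked band-limited burst: Hann-windowed sinusoid."""

    center_hz: float
    onset_ms: float
    duration_ms: float
    amplitude_uv: float

    def __post_init__(self):
        if self.duration_ms <= 0 or self.amplitude_uv < 0:
            raise ValueError("burst duration must be > 0 and amplitude >= 0")


@dataclass(frozen=True)
class BandLevel:
    """Stationary resting oscillation: flat spectral density `level_uv2_hz`
    (µV²/Hz) between f_lo and f_hi."""

    name: str
    f_lo_hz: float
    f_hi_hz: float
    level_uv2_hz: float


@dataclass(frozen=True)
class ArtifactSpec:
    """High-amplitude movement-like transients injected into the recording."""

    count: int = 0
    amplitude_uv: float = 600.0
    duration_ms: float = 50.0
    times_s: tuple[float, ...] | None = None  # explicit placements (else random)


@dataclass(frozen=True)
class GroundTruth:
    """Complete generative parameter set carried alongside each simulation."""

    components: dict            # condition -> {name: ErpComponent}
    ero_bursts: dict = field(default_factory=dict)   # condition -> [OscBurst]
    resting_profile: tuple = ()                       # tuple[BandLevel]
    resting_sinusoids: tuple = ()                     # tuple[(freq_hz, amplitude_uv)]
    one_over_f_alpha: float = 1.0
    background_level_uv2_hz: float = 0.0              # 1/f density at 1 Hz
    noise_sd_uv: float = 0.0                          # broadband noise SD per channel
    shared_noise_fraction: float = 0.7                # variance fraction common to channels
    artifact_spec: ArtifactSpec = ArtifactSpec()
    seed: int = 0

    def __post_init__(self):
        for band in self.resting_profile:
            if not (band.f_lo_hz <= (band.f_lo_hz + band.f_hi_hz) / 2 <= band.f_hi_hz):
                raise ValueError("band centre outside band")
        if not 0.0 <= self.shared_noise_fraction <= 1.0:
            raise ValueError("shared_noise_fraction in [0, 1]")


@dataclass
class RawRecording:
    """Multi-channel raw ECoG: channels x samples in microvolts."""

    data: np.ndarray
    fs_hz: float = FS_HZ
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    schedule: StimulusSchedule | None = None   # None for resting recordings
    truth: GroundTruth | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, name: str) -> int:
        if name == "FC":
            name = FC_CHANNEL
        return self.channel_names.index(name)


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def erp_kernel(times_s: np.ndarray, components: dict) -> np.ndarray:
    """Noiseless single-trial evoked waveform at `times_s` (s, 0 = onset)."""
    out = np.zeros_like(times_s, dtype=float)
    for comp in components.values():
        sigma_s = comp.width_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += (
            comp.polarity * comp.amplitude_uv
            * np.exp(-0.5 * ((times_s - comp.latency_ms / 1000.0) / sigma_s) ** 2)
        )
    return out


def burst_waveform(times_s: np.ndarray, bursts) -> np.ndarray:
    """Event-locked oscillatory bursts: Hann-enveloped, phase-locked sinusoids."""
    out = np.zeros_like(times_s, dtype=float)
    for b in bursts:
        t0, dur = b.onset_ms / 1000.0, b.duration_ms / 1000.0
        inside = (times_s >= t0) & (times_s < t0 + dur)
        tt = times_s[inside] - t0
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * tt / dur))
        out[inside] += b.amplitude_uv * env * np.sin(2.0 * np.pi * b.center_hz * tt)
    return out


def one_over_f_noise(n_samples: int, fs_hz: float, alpha: float, rng,
                     f_min_hz: float = 0.1) -> np.ndarray:
    """Unit-variance noise with power spectral density ∝ 1/f^alpha.

    Spectral shaping of white Gaussian noise; the shaping is flattened below
    ``f_min_hz`` so the variance stays finite for alpha >= 1.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_min_hz) ** (-alpha / 2.0)
    shape[0] = 0.0
    spec = np.fft.rfft(rng.standard_normal(n_samples)) * shape
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def noise_sd_for_snr(truth: GroundTruth, condition: str, snr: float,
                     window_s: tuple[float, float] = (0.0, 0.7)) -> float:
    """Broadband noise SD giving the requested single-trial SNR.

    Trial SNR is defined as the RMS of the condition's noiseless evoked
    waveform over ``window_s`` divided by the per-channel noise SD.
    """
    t = np.arange(window_s[0], window_s[1], 1.0 / FS_HZ)
    wave = erp_kernel(t, truth.components[condition])
    wave = wave + burst_waveform(t, truth.ero_bursts.get(condition, ()))
    rms = float(np.sqrt(np.mean(wave**2)))
    if snr <= 0:
        raise ValueError("snr must be positive")
    return rms / snr


def _channel_noise(n_channels: int, n_samples: int, truth: GroundTruth,
                   rng) -> np.ndarray:
    """Shared + independent 1/f^alpha noise, per-channel SD = noise_sd_uv."""
    if truth.noise_sd_uv == 0:
        return np.zeros((n_channels, n_samples))
    shared = one_over_f_noise(n_samples, FS_HZ, truth.one_over_f_alpha, rng)
    out = np.empty((n_channels, n_samples))
    w_shared = np.sqrt(truth.shared_noise_fraction)
    w_indep = np.sqrt(1.0 - truth.shared_noise_fraction)
    for ch in range(n_channels):
        indep = one_over_f_noise(n_samples, FS_HZ, truth.one_over_f_alpha, rng)
        out[ch] = truth.noise_sd_uv * (w_shared * shared + w_indep * indep)
    return out


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_oddball_recording(
    schedule: StimulusSchedule,
    truth: GroundTruth,
    tail_s: float = 1.0,
    channel_names: tuple[str, ...] = CHANNEL_NAMES,
) -> RawRecording:
    """Render an oddball session: evoked kernels + bursts + noise + artifacts.

    Every event adds its condition's component kernels and oscillatory bursts
    at the event onset, identically on all channels; background noise follows
    the truth's 1/f^alpha model with a shared-source fraction across channels.
    Artifacts are square-envelope transients of the specified amplitude.
    """
    missing = {str(c) for c in np.unique(schedule.conditions)} - set(truth.components)
    if missing:
        raise ValueError(f"ground truth lacks components for conditions: {sorted(missing)}")
    rng = np.random.default_rng(truth.seed)
    n_samples = int(np.ceil((schedule.onsets_s[-1] + tail_s) * FS_HZ))
    n_channels = len(channel_names)

    # one evoked template per condition, stamped at each event onset
    templ_t = np.arange(-0.2, 0.9, 1.0 / FS_HZ)
    data = _channel_noise(n_channels, n_samples, truth, rng)
    for cond in np.unique(schedule.conditions):
        wave = erp_kernel(templ_t, truth.components[cond])
        wave = wave + burst_waveform(templ_t, truth.ero_bursts.get(cond, ()))
        if not np.any(wave):
            continue
        evoked = np.zeros(n_samples)
        off = int(round(templ_t[0] * FS_HZ))
        for onset in schedule.onsets_s[schedule.conditions == cond]:
            start = int(np.floor(onset * FS_HZ)) + off
            lo, hi = max(start, 0), min(start + len(wave), n_samples)
            evoked[lo:hi] += wave[lo - start: hi - start]
        data += evoked[None, :]

    spec = truth.artifact_spec
    if spec.count > 0:
        if spec.times_s is not None:
            times = np.asarray(spec.times_s[: spec.count], dtype=float)
        else:
            times = rng.uniform(0.5, n_samples / FS_HZ - 0.5, size=spec.count)
        width = int(round(spec.duration_ms / 1000.0 * FS_HZ))
        for t0 in times:
            start = int(np.floor(t0 * FS_HZ))
            data[:, start: start + width] += spec.amplitude_uv
    return RawRecording(data=data, fs_hz=FS_HZ, channel_names=channel_names,
                        schedule=schedule, truth=truth)


def simulate_resting(
    truth: GroundTruth,
    duration_s: float = 300.0,
    channel_names: tuple[str, ...] = CHANNEL_NAMES,
) -> RawRecording:
    """Stationary resting-state recording (no events).

    The spectrum is synthesised in the frequency domain: a 1/f^alpha
    background at ``background_level_uv2_hz`` (density at 1 Hz) plus flat
    band-limited components at each BandLevel's density, with independent
    random phases per channel except for deterministic ``resting_sinusoids``
    which are rendered in the time domain (useful for analytic checks).
    """
    if duration_s < 4.0:
        raise ValueError("resting simulation needs duration >= 4 s")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration_s * FS_HZ))
    freqs = np.fft.rfftfreq(n, d=1.0 / FS_HZ)
    density = np.zeros_like(freqs)
    if truth.background_level_uv2_hz > 0:
        nz = freqs > 0
        density[nz] += truth.background_level_uv2_hz * np.maximum(freqs[nz], 0.1) ** (
            -truth.one_over_f_alpha
        )
    for band in truth.resting_profile:
        density[(freqs >= band.f_lo_hz) & (freqs < band.f_hi_hz)] += band.level_uv2_hz

    n_channels = len(channel_names)
    data = np.zeros((n_channels, n))
    if np.any(density > 0):
        # E|X_k|^2 = S_k * fs * n / 2 makes the one-sided periodogram match S
        amp = np.sqrt(density * FS_HZ * n / 2.0)
        for ch in range(n_channels):
            z = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
            z /= np.sqrt(2.0)
            spec = amp * z
            spec[0] = 0.0
            data[ch] = np.fft.irfft(spec, n=n)
    t = np.arange(n) / FS_HZ
    for f_hz, a_uv in truth.resting_sinusoids:
        data += a_uv * np.sin(2.0 * np.pi * f_hz * t)[None, :]
    return RawRecording(data=data, fs_hz=FS_HZ, channel_names=channel_names,
                        schedule=None, truth=truth)


def simulate_drinking(
    n_rats: int = 10,
    calendar: tuple[Phase, ...] = DEFAULT_CALENDAR,
    bl_means: tuple[float, float, float] = (1.02, 1.25, 1.16),
    ade_increments: tuple[float, float, float] = (0.56, 0.24, 0.43),
    noise_sd: float = 0.25,
    between_sd: float = 0.30,
    seed: int = 0,
) -> DrinkingProfile:
    """Four-bottle drinking trajectories with an alcohol-deprivation effect.

    Daily intakes (g EtOH/kg) per solution are drawn around ``bl_means``
    during drinking phases (per-animal offsets with SD ``between_sd``, daily
    noise SD ``noise_sd``, clipped at zero); the first day of renewed access
    after each deprivation is elevated by ``ade_increments``. Deprivation
    days are exact zeros. Defaults reproduce the cohort-mean baselines
    1.02/1.25/1.16 (total 3.43) and post-deprivation intakes 1.58/1.49/1.59
    (total 4.66) in expectation.
    """
    if min(bl_means) < 0 or min(ade_increments) < 0:
        raise ValueError("means and increments must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for rat in range(n_rats):
        animal = f"rat{rat + 1:02d}"
        offset = rng.normal(0.0, between_sd, size=len(SOLUTIONS)) if between_sd > 0 else np.zeros(3)
        day = 0
        prev_kind = None
        for kind, n_days in calendar:
            for d in range(n_days):
                for i, sol in enumerate(SOLUTIONS):
                    if kind == "deprivation":
                        g = 0.0
                    else:
                        g = bl_means[i] + offset[i]
                        if d == 0 and prev_kind == "deprivation":
                            g += ade_increments[i]
                        if noise_sd > 0:
                            g += rng.normal(0.0, noise_sd)
                        g = max(g, 0.0)
                    rows.append({"animal": animal, "day": day, "solution": sol,
                                 "g_per_kg": g})
                day += 1
            prev_kind = kind
    return DrinkingProfile(intake=pd.DataFrame(rows), calendar=tuple(calendar))
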