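# Methods

This note documents the models, numerical conventions and open design
choices behind `oddwave`. It is the place to look when a default looks
arbitrary: if a rule is not stated in the standard description of the
paradigm, the decision and its rationale are recorded here.

## Signal model of the synthetic generator

The generator exists so that every analysis stage can be tested against a
known ground truth. It is a *phenomenological* model of epidural prefrontal
ECoG, not a biophysical one: no volume conduction, no cortical sources, no
acoustic waveforms (tones are event labels only).

**Stimulus schedule.** Standards and deviants are split across blocks
(remainders to the earliest blocks); within each block, deviant positions
are drawn uniformly from all arrangements with no two deviants adjacent,
via the stars-and-bars bijection (choosing k non-adjacent slots out of n is
choosing k out of n − k + 1). If the previous block ended on a deviant, the
next block may not start with one, so the constraint holds across the whole
session. Onsets advance by one SOA = ISI + tone duration (1.05 s by
default); inter-block breaks default to 30 s. The canonical composition is
1344 standards / 276 deviants in 6 blocks. The often-quoted 87 %/13 % split
is inconsistent with those counts (which imply 83 %/17 %); the counts are
taken as authoritative and the generator is parameterised by counts. Block
duration is likewise derived from counts rather than fixed at 5 min.

**Evoked components.** Each ERP component is a Gaussian-windowed monophasic
deflection parameterised by exactly the three quantities the scoring stage
measures: latency (peak time), amplitude (peak µV), width (FWHM ms), plus a
polarity. A Gaussian is the least-structured smooth kernel with those
parameters. Preset latencies/widths are chosen so neighbouring kernels
cross-talk below ~1 % at each other's peaks and so the narrowest kernel
(FWHM 24 ms) loses < 1 % peak amplitude to the 45 Hz low-pass — this is what
makes the "noiseless recovery exact to one sample and < 1 % in amplitude"
property attainable, and it is a design constraint of the generator, not a
tuned afterthought.

**Event-related oscillations.** Per condition, Hann-enveloped sinusoidal
bursts (centre frequency, onset, duration, single-trial amplitude),
phase-locked to stimulus onset. Burst amplitudes in the presets (18–45 µV)
are deliberately larger than the averaged ERP components: the band-wise
ERSP maximum is only an informative outcome when event-locked oscillatory
power exceeds both the 1/f background and the spectral skirt of the ERP
transient in that band, and single-trial oscillations exceeding
trial-averaged ERP amplitudes is the typical regime in real recordings.
With weak bursts the beta-band maximum degenerates to the band's low edge
(the ERP skirt) for every cohort and carries no group information.

**Background noise.** 1/f^α noise (α = 1 default) made by spectral shaping
of white Gaussian noise, flattened below 0.1 Hz to keep variance finite. A
fraction of the noise variance (default 0.7) comes from a source shared by
all 9 channels, the rest is channel-independent; evoked kernels are
identical across channels. Channels are therefore near-exchangeable, which
matches the absence of channel effects in the analyses this feeds.

**Trial SNR.** Defined as (RMS of the condition's noiseless evoked waveform
over 0–700 ms) / (broadband noise SD per channel);
`noise_sd_for_snr` inverts it.

**Artifacts.** Square-envelope transients (default 600 µV, 50 ms) at random
or explicitly specified times — the latter lets tests construct fixtures in
which exactly k known epochs violate the rejection criterion.

**Resting state.** Synthesised directly in the frequency domain: each
channel's one-sided spectrum gets complex-Gaussian bins with
E|X_k|² = S(f_k)·fs·N/2, where S is a 1/f^α background plus flat band-limited
components (µV²/Hz) per named band; deterministic sinusoids can be added in
the time domain for analytic checks (a 1 µV tone integrates to 0.5 µV²).

**Cohort presets.** Four presets (control, dependent, dependent+psilocybin,
dependent+LY) encode group-effect *directions*: dependent rats have reduced
P1N1/N1P2 with earlier N1/P2, enhanced P2N2, unchanged N2P3, reduced and
later delta–beta bursts but increased and earlier gamma, an event-related
beta centre shifted from 13.5 Hz (control) to 22 Hz, and resting spectra
dominated by high-beta (18–30 Hz) density where controls are dominated by
low beta (12–15 Hz). The drug presets sit part-way back toward control.
All magnitudes are this package's configuration, chosen to be detectable at
cohort sizes around n = 10; they are not measured values. Per-animal
variation: lognormal amplitude jitter (σ = 0.15) and Gaussian latency jitter
(σ = 5 ms), applied consistently across conditions.

**Drinking trajectories.** Daily intake per solution is Gaussian around the
per-animal baseline mean (between-animal SD 0.30, daily SD 0.25 g/kg,
clipped at zero); deprivation days are exact zeros; the first day of renewed
access is elevated by the ADE increment. Default means (1.02/1.25/1.16) and
increments (0.56/0.24/0.43 g/kg) reproduce cohort-mean baselines totalling
3.43 and post-deprivation intakes totalling 4.66 g/kg/day in expectation.
The default calendar is an initial 8-week drinking phase followed by 4–6-week
phases alternating with 2–3-week deprivations (8 drinking phases, ~61 weeks).

What the generator does **not** emulate: non-stationarity and drifting
electrode impedance, correlated trial-to-trial latency jitter, induced
(non-phase-locked) oscillations, realistic artifact morphology, circadian
drinking structure, body-weight change. Passing tests therefore demonstrate
correctness of the *analysis machinery* under the stated statistical
structure, not robustness to every property of real recordings.

## Preprocessing conventions

* **Filter.** Kaiser-window FIR bandpass, β = 5.65. The transition width is
  not part of the standard description; it is fixed at 0.2 Hz (twice the low
  cutoff), which reproduces the conventional ~54,330-tap length at 3 kHz to
  within 0.04 % under `scipy.signal.kaiserord`'s order estimate
  (A = β/0.1102 + 8.7 ≈ 60 dB). Tap counts are convention-dependent across
  implementations, so equality is never asserted — a 0.2 % band is.
  Length is forced odd (exact linear phase, integer group delay).
* **Phase.** Zero-phase application: the symmetric kernel is applied once by
  convolution with reflection padding and group-delay compensation. ERP
  latencies are the measurand; they must not be shifted. (Filtering twice,
  forward–backward, would square the amplitude response instead.)
* **Time convention.** Stimulus onset = 0; windows half-open [start, end);
  sample index = floor(t·fs). Epochs −100…700 ms, baseline −100…0 ms,
  per-trial per-channel baseline mean subtracted.
* **Rejection.** An epoch is rejected per (trial, channel) iff its
  peak-to-peak range **strictly** exceeds 500 µV (a range of exactly 500 is
  retained). Whether rejection should span all channels of a trial is
  config-exposed in principle; the per-(trial, channel) rule is the default
  because channels are analysed separately. A channel is dropped entirely
  when > 30 % of its epochs are rejected (threshold config-exposed; no
  standard value exists). All counts land in a QC report — there is no
  visual-inspection step anywhere in the pipeline.

## ERP scoring

Components are windowed *global* extrema (argmax for positive, argmin for
negative, ties to the earliest sample), not local-peak detections: global
extrema are deterministic on monotone segments and match the
"attribute the peak to a predefined interval" convention. Because windows
overlap (N1 35–120 vs P2 60–260 ms), inversions are possible on noisy
traces; the ordering rule re-searches each window from the previous
component's latency onward, guaranteeing P1 ≤ N1 ≤ P2 ≤ N2 ≤ P3 — a
deterministic stand-in for confirmatory visual inspection. Peak-to-peak
amplitudes are signed (positive-component amplitude minus
negative-component amplitude), so canonical morphology gives positive
values; an absolute-value flag exists. Scoring runs on difference curves by
default (standards habituate and carry little structure); per-condition
scoring is available. Grand averages weight subjects equally regardless of
retained-trial counts.

## ERSP

Per retained trial: Hann-tapered (periodic window) 400-sample frames,
zero-padded ×64 (nfft = 25,600; 0.1171875 Hz bins), one-sided density
2|X|²/(fs·Σw²), averaged across trials, floored at −100 dB (so zero signals
are representable), then 10·log₁₀(µV²/Hz). Frame starts are spread evenly to
give ~200 output frames per epoch; frame time = window centre. Only bins up
to 45 Hz are evaluated — the zero-padded DFT at a bin equals a dot product
with that bin's complex exponential, so the restriction is exact and is what
makes the pad-64 transform affordable (tests verify 1e-12 agreement with a
full `np.fft.rfft` of the padded frame). The dB value is *absolute* density:
the defining formula has no baseline term. Toolbox ERSP implementations
often divide by a pre-stimulus baseline; that variant is available via
`baseline_window_s` but is off by default, and the choice is flagged as
genuinely ambiguous. Band maxima break ties toward the lowest frequency,
then the earliest frame; the gamma band is 30–45 Hz (the filter's passband
edge), and the top band includes its upper edge so the five bands partition
1–45 Hz exactly (whole-range maximum ≡ max of band maxima).

## Resting-state PSD

Welch's method written out explicitly: 2-s segments, 50 % overlap
(for a T-second recording, floor((T−2)/1)+1 segments), per-channel
δ-criterion segment exclusion (error if nothing survives), periodic Hamming
taper, density normalisation including taper power, mean over retained
segments, restricted to 1–45 Hz. The explicit form exists because segment
rejection cannot be expressed through a monolithic Welch call; equality with
`scipy.signal.welch` on clean data is asserted in tests at 1e-10. Band power
is the mean *linear* density over the band's bins converted to dB (a
physical power average); mean-of-dB is available but is not the default
(Jensen's inequality makes it systematically lower). For integrated power,
rectangular bin integration (Σ density·Δf) is used so that a tone's full
mainlobe is accounted to the bins it occupies.

## Statistics

* **rmANOVA** (two within factors, balanced): direct sums-of-squares
  decomposition with each effect tested against its subject-by-effect
  stratum. Greenhouse–Geisser ε per effect from orthonormal contrasts
  (Kronecker contrasts for the interaction); Mauchly's test where the
  contrast covariance is estimable (it is singular by construction when
  subjects ≤ contrast dimension — e.g. 9 channels need > 9 subjects — in
  which case W is NaN and no correction is auto-selected). Both corrected
  and uncorrected p are always reported; `p_report` uses GG when Mauchly
  rejects at 0.05.
* **Between-subjects ANOVA**: statsmodels OLS + type-II `anova_lm`
  (equivalent to the textbook decomposition on balanced layouts, which the
  tests verify exactly).
* **Sidak**: p' = 1 − (1 − p)^m, clipped to [0, 1].
* **Spearman**: Pearson on midranks. p-values: t approximation for n ≥ 10,
  exact permutation (all n! pairings, vectorised) below — cohorts of ~10
  animals sit exactly at the boundary where the approximation starts being
  defensible. Strength labels at |ρ| ≥ 0.1/0.4/0.7/0.9.
* **Partial Spearman**: first-order partial correlation on midranks,
  ρ_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), p from t with n − 3 df;
  rank-degenerate controls (|r| = 1) are an error.
* Neural markers are averaged over channels *before* correlating with
  drinking metrics (done in the statistics layer, not upstream). Sidak
  families for correlation matrices default to one family per drinking
  metric; global and no adjustment are options, since the appropriate scope
  is not standardised.
* Degenerate paired t-test inputs: identical samples return t = 0, p = 1;
  constant non-zero differences are an error.

## Drinking metrics

BL = mean over the final 7 calendar days of each drinking phase, then an
unweighted mean over phases (all cycles, not only the last one — matching
"means over the whole experimental period"). ADE = first-day intake of each
post-deprivation phase, averaged over cycles. Relapse intensity = per-cycle
ADE minus the *preceding* phase's BL, averaged over cycles. Totals are sums
over the three solutions, exact by construction. Phases come from the
attached calendar, or are inferred from all-zero days for externally
recorded profiles. A drinking phase shorter than the baseline window is an
error naming the phase. Intakes are g EtOH per kg body weight; synthetic
profiles use constant weight.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks run at desk scale, chosen as this package's own
test-design sizes: the noisy ERP-recovery check uses 300 deviants +
600 standards at trial SNR 0.25 through the full-length filter; the
detection-power check runs 200 cohort simulations (n = 10/group, 9 channels)
at a 1-SD P1N1 reduction generated at the marker level (subject offsets
0.8·SD, channel noise 1.8·SD, so subject-level means have exactly unit SD);
the beta-directionality check simulates, per seed, 10 animals per cohort
(12-deviant single-channel sessions, 2 Hz filter transition) through the
real filter → epoch → ERSP → band-max path and compares group means,
200 seeds. Short-transition (wider, therefore shorter) filters appear only
where kernel length is irrelevant to the property under test; anything
asserting stopband behaviour at DC or the printed tap count uses the
full-length design.

## Known limitations

* The rmANOVA path requires complete balanced layouts; unbalanced designs
  must go through the between-subjects path or be completed upstream.
* ERSP is plain short-time FFT: no wavelets, no multitaper, no inter-trial
  phase coherence.
* The EDF writer covers the plain-EDF subset used here (identical rates,
  16-bit, no annotations); it is validated by round-tripping through mne.
* Exact Spearman permutation p-values are enumerated (n! pairings) and are
  practical only for n ≤ 9 — precisely the regime they are needed in.
* No spectral parameterisation (periodic/aperiodic decomposition) of
  resting spectra; band powers only.
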