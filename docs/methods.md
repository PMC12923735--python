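# Methods

This note documents the models, algorithms and numerical choices behind
`lfpkit`, in the spirit of the methods documentation that mature
analysis toolkits ship alongside their code. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and data model

The toolkit analyses three kinds of in vivo recordings from a single
animal preparation:

1. **field potentials (LFP)** — multi-channel continuous voltage,
   acquired at 40 kHz, low-pass filtered at 250 Hz and down-sampled to
   1 kHz for oscillation analysis, stored and processed as sequential
   5-minute segments;
2. **spike-band traces** — the same electrodes at full 40 kHz
   bandwidth, from which single units are extracted and classified;
3. **fiber photometry** — paired 470 nm (calcium-sensitive GCaMP) and
   410 nm (isosbestic) fluorescence with behavioural event tags.

The central container, `ContinuousSignal`, carries the sample matrix,
sampling rate and an explicit channel-contiguity graph. The contiguity
graph exists because the epileptiform criterion requires events on
*more than 4 contiguous channels* of a 4×2 microwire array; the
detector refuses to guess electrode layout, so geometry is part of the
data, defaulting to a linear chain for synthetic recordings.

## Spectral analysis

PSDs are Welch averages of Hann-windowed, mean-removed segments with
1024 one-sided frequency values (window length `2*(1024-1)` samples)
and 25% overlap, matching the acquisition-software configuration the
analyses assume. The density is variance-normalised (one-sided,
units²/Hz) so its integral equals the signal variance; proprietary
acquisition software uses an undocumented absolute scale, but all
claims downstream are comparative (ratios between bands or
conditions), which this normalisation preserves. Band power integrates
the density trapezoidally with the band edges interpolated onto the
frequency grid; this makes band power exactly additive over adjacent
disjoint bands. PSDs of long recordings are computed per 5-minute
segment and averaged (`psd_per_segment`), with the whole-recording
variant also available; for stationary signals the two agree.

Band presets: theta 3–8 Hz (PSD summaries), theta 4–12 Hz (filtering /
PAC phase), low gamma 30–50 Hz, high gamma 50–90 Hz, wide gamma
30–80 Hz (filtering / PAC amplitude), ripple 140–200 Hz, fast ripple
200–500 Hz. Both theta presets ship because spectral summaries and
band-limited filtering conventionally use different edges; the PAC
phase band defaults to 4–12 Hz and is configurable.

## Filtering

All band-limited filtering is 4th-order Butterworth applied
forward–backward (`sosfiltfilt`): zero phase, so event timing and
phase estimates are unshifted, with a monotone passband and better
than 20 dB attenuation one octave outside the band. The order is
configurable; 4 is the common default for neural band isolation.

## Phase–amplitude coupling

The modulation index is the mean-vector-length statistic

    MIn = | n⁻¹ Σₜ Aₜ e^{iθₜ} | ,

with θₜ the instantaneous phase of the low (theta) band and Aₜ the
instantaneous amplitude envelope of the high (gamma) band, both from
the analytic signal (Hilbert transform) of the zero-phase band-passed
trace — the standard extraction for this family of coupling measures.
A 1-s edge margin is trimmed to discard filter/Hilbert transients, and
a minimum of 10 low-band cycles is documented for a stable estimate.

Raw MIn carries the signal's amplitude scale (it is homogeneous of
degree 1 in Aₜ); `MIn_normalized = MIn / mean(Aₜ) ∈ [0, 1]` is
reported alongside for cross-condition comparisons. The comodulogram
scans a band-pair grid of normalised indices; the default grids place
bin edges on odd frequencies so the canonical 6 Hz / 40 Hz pair falls
at cell centres rather than edges. A surrogate null for visualisation
circularly shifts the amplitude series by ≥ 1 s uniform offsets
(200 surrogates, seeded), preserving both marginal autocorrelations.

The synthetic LFP generator produces the exact generative counterpart:
gamma amplitude `gamma_amp·(1 + m·cos(θ−φ))/(1+m)` with coupling depth
`m ∈ [0,1]`, over a 1/f^β background synthesised by spectral shaping of
white noise (exact exponent control). Recovery tests verify that the
measured normalised index increases strictly with `m` and that the
comodulogram peak localises to the true pair for `m ≥ 0.5`.

## Event detection

**Epileptiform discharges.** Criteria are conjunctive, applied to the
analytic-signal energy envelope of the > 100 Hz high-passed trace:

* envelope above baseline mean + 4 SD (threshold multiplier
  configurable);
* duration ≤ 4 s;
* detected on ≥ 5 channels ("more than 4") forming a connected set
  under the electrode geometry;
* duration ≥ 0.1 s (default, configurable) — this operationalises the
  requirement that a discharge carry a sustained burst of
  high-frequency activity; without it, millisecond common-mode noise
  excursions that happen to span the array would count as discharges.

Baseline statistics are estimated on the envelope with a robust
(median/MAD) first pass followed by two mean/SD passes over
sub-threshold samples; a purely moment-based first pass lets a long
high-amplitude discharge inflate its own detection threshold.
Sharp-wave-ripple-type events (> 200 Hz dominant frequency) detected
during freely-moving epochs are counted as epileptiform. Detection
uses dual thresholds (hysteresis): cores above the main threshold are
extended outward to a lower edge threshold (default 2 SD) so the
onset/offset ramps are included in the event extent.

**Ripples (140–200 Hz) and fast ripples (200–500 Hz).** Band-pass →
analytic-signal envelope → Gaussian smoothing (σ = 4 ms) → dual
threshold at mean + 3 SD (edge 2 SD) → minimum *core* duration (20 ms
ripple / 10 ms fast ripple) → merge events closer than 10 ms. The
minimum duration applies to the supra-threshold core rather than the
edge-extended run: envelope excursions of band-limited noise regularly
exceed the edge threshold for tens of milliseconds, but sustained
cores are rare, so this choice controls the false-positive rate
without touching sensitivity. On twenty seeded 60-s noise-only runs
at the default threshold the detector produced a mean of 1.0 false
events/min (max 4/min in a single run).

Per event the toolkit reports peak envelope amplitude and the
intra-event oscillation frequency, computed as the reciprocal of the
median inter-peak interval of the band-limited trace with parabolic
(sub-sample) refinement of each peak time — at 1 kHz a 160 Hz carrier
has only ~6 samples per cycle, and integer-sample peak spacing would
quantise the estimate by ±20 Hz, so the sub-sample refinement is what
makes the ±5 Hz accuracy contract attainable. Because "ripple
frequency" can mean either occurrence rate or intra-event frequency,
summaries report both (`event_rate_per_min` and `intra_freq_hz`).

Ripple statistics exclude epochs overlapping epileptiform events by
default (`exclude_overlapping`), so physiological ripple summaries are
not contaminated by pathological discharges; the exclusion is a
separate composable step and can be skipped.

Fast-ripple analysis requires `fs > 1 kHz` (the 200–500 Hz band must
sit below Nyquist); synthetic fast-ripple fixtures therefore use
2 kHz. How > 250 Hz content survives a 250 Hz acquisition low-pass in
the original recordings is an upstream acquisition question the
toolkit cannot resolve; it simply enforces the Nyquist requirement.

## Spike units

Candidates are negative threshold crossings at 3 noise SD, with the
noise SD estimated as MAD/0.6745 so the spikes themselves do not
inflate it. Each crossing is trough-aligned (window −0.5…+1.5 ms) with
a 1 ms dead time. At 3 SD, iid Gaussian noise alone produces
crossings at rate `fs·Φ(−3)(1−Φ(−3))` thinned by the dead time
(≈ 50/s at 40 kHz) — an inherent property of the threshold, verified
against that closed form in the tests. Separating these
near-threshold events from unit spikes is the job of spike sorting,
which is out of scope (the bespoke content here is thresholding, QC
and classification, not cluster cutting); the single-template
assignment in `build_units` therefore applies a deterministic
two-cluster split on trough depth per channel, keeping the deeper
cluster when the cluster means separate by more than 3 pooled
within-cluster SDs and leaving unimodal channels intact. Externally
sorted units can be supplied directly.

QC: the absolute-refractory rule is operationalised as a violation
fraction — a unit is excluded when more than 0.5% of its ISIs are
shorter than 1 ms (boundary inclusive), since "autocorrelation < 1 ms"
is not an executable criterion verbatim. Detections coincident within
0.5 ms on ≥ 6 of 8 channels are invalidated as cross-channel
artifacts (defaults; no published values exist for these).

Features of the mean waveform: trough-to-peak time, width of the
trough at half depth (linear interpolation between samples),
peak-valley ratio, trough-to-peak slope, plus the firing rate. FS/RS
classification fits a 2-component full-covariance Gaussian mixture
(k-means++ initialisation, seeded, hence deterministic) on
standardised (log rate, peak-valley ratio, half-height width); the
component with the narrower mean waveform is FS. Responsibilities
within 0.1 of 0.5 are flagged low-confidence. A singular fit falls
back to diagonal covariance.

The spike generator draws renewal trains (Gamma-ISI with hard dead
time; shape 1 = Poisson-with-dead-time, matching the
absolute-refractory semantics) and injects biphasic Gaussian-lobe
templates whose generative parameters (trough-to-peak, half-width,
peak-valley ratio) are recoverable from the template to within one
sample. The default synthetic populations are FS 20 Hz / 0.3 ms
trough-to-peak / 0.2 ms half-width / ratio 0.35 and RS 2 Hz / 0.8 ms /
0.5 ms / 0.55, with template amplitude 8 noise SD — a clearly
separated pair representing the canonical narrow-fast vs broad-slow
dichotomy. `gen_units` additionally builds sorted units directly
(renewal train + noisy waveform draws, 5% multiplicative per-unit
parameter jitter) for population-level work where a 40-channel
continuous trace would be waste.

## Photometry

ΔF/F is computed per event tag as `(F − F0)/F0` with `F0` the mean of
the same channel over the two minutes immediately preceding the tag;
tags closer than 120 s to the recording start, or whose peri-event
window (default −2…+5 s) overruns the recording, are skipped with a
warning and counted. The per-tag local baseline is what the defining
formula implies, and it absorbs slow photobleaching without any global
detrend. ΔF/F is exactly invariant to detector gain.

The 410 nm isosbestic channel is processed identically and serves as
the movement/bleaching control. `isosbestic_check` reports the
per-event correlation between the channels' ΔF/F and, when the 410
channel is informative, a motion-corrected trace (470 ΔF/F minus the
least-squares linear transform of 410 ΔF/F fitted on pre-event
baseline samples) with the variance fraction it explains. Because the
original correction procedure is not documented, the raw per-channel
ΔF/F is always the primary output and the regression-corrected trace
is clearly labelled, never silently substituted.

AUC integrates ΔF/F trapezoidally over a stated window (default
0…+5 s post-event; whether the reference analyses span −2…+5 s is not
recorded, so the window is configurable). Endpoints are interpolated
onto the sample grid, making AUC exactly additive over adjacent
windows; a 0.1 × 3 s rectangle integrates to exactly 0.3 ΔF/F·s on
its aligned window, with the usual half-sample trapezoid closure at a
sampled step edge.

The photometry generator emulates exponential photobleaching,
difference-of-exponential calcium transients (default 0.2 s rise, 1 s
decay) on the 470 channel only, band-limited motion shared by both
channels in proportion to their baselines, and white measurement
noise.

## Pipeline and reproducibility

`run_pipeline` executes simulate → spectral → PAC → events → spikes →
photometry from one JSON config; unknown keys are rejected before any
computation. All randomness flows from a single master seed through a
documented derivation (`SeedSequence([seed, crc32(stage_name)])`), so
each stage is independently reproducible and a rerun with the same
config and seed yields an identical report. Two demo configurations
ship: "WT" (strong theta-gamma coupling, no pathological events) and
"KI" (weak coupling plus injected epileptiform discharges and a fast
ripple), emulating the healthy vs late-stage disease contrast.
`compare_conditions` reports descriptive ratios/differences only —
group inferential statistics are out of scope, and ratios with a zero
denominator are reported as absent, never infinite.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the analyses
assume: 1/f background with controllable exponent, theta-locked gamma
with exact coupling depth, Tukey-enveloped oscillation bursts (chosen
over hard-edged bursts to avoid ringing that would confound detector
onset tests), renewal spike trains with refractory dead time,
template-shaped waveforms in Gaussian noise, and shared-motion
two-channel photometry. They do not model non-stationary behavioural
state changes, electrode drift, spike waveform overlap on a shared
channel, correlated (non-Gaussian) noise bursts, or hemodynamic
contamination of photometry. Passing recovery tests therefore
demonstrates correctness of the implementations under the stated
assumptions, not robustness to every pathology of real recordings;
thresholds exposed as parameters should be recalibrated on real data.

Recording-level noise amplitudes are calibration choices (no
signal-to-noise figures are published for the original recordings):
LFP noise SD 0.5 against theta amplitude 1.0 and gamma amplitude 0.4,
spike templates at 8 noise SD, photometry SNR set per test (amplitude
recovery is validated at SNR 10, the contract's boundary).

## Problem sizes

Validation uses 60–120 s synthetic recordings (1–2 kHz LFP; 40 kHz
spike band), 20 injected events per 60 s run for detector metrics
(10 seeds), 5 seeds per coupling depth for PAC recovery, and 40 units
per seed (10 seeds) for classifier accuracy — sizes at which every
ground-truth quantity is estimated with comfortable margin while the
whole suite runs in well under a minute per module.
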