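"""Seeded generators for LFP, spike-band and photometry recordings.

Every generator takes an explicit integer seed and builds its own
``numpy.random.Generator`` (PCG64); no global RNG state is touched, so
identical specs and seeds reproduce identical samples on any platform.

The LFP generator emulates the statistical structure the downstream
analyses assume: a 1/f^beta background, a theta rhythm, gamma whose
amplitude is modulated by theta phase with controllable depth ``m``

    gamma(t) = gamma_amp * (1 + m*cos(theta_phase(t) - phi)) / (1 + m)
               * cos(2*pi*gamma_hz*t)

and optional injected interval events (epileptiform bursts, ripples,
fast ripples) as raised-cosine (Tukey) enveloped carrier bursts on a
chosen channel subset.  Ground truth for every injected event (and for
the true coupled band pair) is returned alongside the signal so
detector sensitivity and precision can be measured exactly.

The spike-band generator draws renewal spike trains with a hard
absolute refractory period and places parameterised biphasic waveform
templates into Gaussian noise of known SD; the photometry generator
produces a 470 nm calcium-sensitive channel (bleaching baseline +
transients + motion) and a 410 nm isosbestic channel that shares the
bleaching and motion terms but carries no calcium transients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .events import OscEvent
from .signal import ContinuousSignal, ValidationError, linear_geometry

_KIND_BANDS = {
    "ripple": (140.0, 200.0),
    "fast_ripple": (200.0, 500.0),
    "epileptiform": (100.0, float("inf")),
}


@dataclass
class EventSpec:
    """An interval event to inject: Tukey-enveloped carrier burst."""

    kind: str
    t_on: float
    duration_s: float
    carrier_hz: float
    amplitude: float  # multiples of the background SD
    channels: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.kind not in _KIND_BANDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        lo, hi = _KIND_BANDS[self.kind]
        if not (lo <= self.carrier_hz <= hi):
            raise ValidationError(
                f"{self.kind} carrier {self.carrier_hz} Hz outside "
                f"[{lo}, {hi}] Hz"
            )
        if self.duration_s <= 0:
            raise ValidationError("event duration must be > 0")


@dataclass
class LfpSpec:
    fs: float = 1000.0
    duration_s: float = 60.0
    theta_hz: float = 6.0
    theta_amp: float = 1.0
    gamma_hz: float = 40.0
    gamma_amp: float = 0.4
    coupling_depth: float = 0.0  # m in [0, 1]
    coupling_phase: float = 0.0  # phi, radians
    noise_exponent: float = 1.0  # beta of the 1/f^beta background
    noise_sd: float = 0.5
    n_channels: int = 8
    shared_fraction: float = 0.7
    events: list[EventSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.coupling_depth <= 1:
            raise ValidationError("coupling_depth must be in [0, 1]")
        if not 0 <= self.shared_fraction <= 1:
            raise ValidationError("shared_fraction must be in [0, 1]")
        fmax = max(self.theta_hz, self.gamma_hz,
                   *(e.carrier_hz for e in self.events), 0.0)
        if self.fs <= 2 * fmax:
            raise ValidationError(
                f"fs {self.fs} Hz cannot represent {fmax} Hz content"
            )
        for e in self.events:
            if e.t_on < 0 or e.t_on + e.duration_s > self.duration_s:
                raise ValidationError(
                    f"event at {e.t_on}s/{e.duration_s}s outside recording "
                    f"of {self.duration_s}s"
                )
            if any(c < 0 or c >= self.n_channels for c in e.channels):
                raise ValidationError("event channel index out of range")


def one_over_f_noise(n: int, fs: float, beta: float, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """1/f^beta background by spectral shaping of white noise.

    White Gaussian noise is transformed to the frequency domain, each
    positive-frequency bin scaled by f^(-beta/2) (the DC bin zeroed),
    transformed back and rescaled to the requested standard deviation.
    """
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n)
    shaped *= sd / shaped.std()
    return shaped


def _tukey_burst(n_samples: int, fs: float, carrier_hz: float,
                 amplitude: float, alpha: float = 0.25) -> np.ndarray:
    t = np.arange(n_samples) / fs
    env = sps.windows.tukey(n_samples, alpha=alpha)
    return amplitude * env * np.sin(2 * np.pi * carrier_hz * t)


def gen_lfp(spec: LfpSpec, seed: int) -> tuple[ContinuousSignal, dict]:
    """Generate a multi-channel LFP with known ground truth.

    Returns the signal and a truth dict with keys ``events`` (one
    :class:`OscEvent` per injected event), ``low_hz``/``high_hz`` (the
    truly coupled frequency pair), ``coupling_depth`` and
    ``coupling_phase``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    theta_phase = 2 * np.pi * spec.theta_hz * t
    theta = spec.theta_amp * np.cos(theta_phase)
    m = spec.coupling_depth
    gamma_env = spec.gamma_amp * (
        1 + m * np.cos(theta_phase - spec.coupling_phase)) / (1 + m)
    gamma = gamma_env * np.cos(2 * np.pi * spec.gamma_hz * t)
    common_osc = theta + gamma

    shared_noise = one_over_f_noise(n, spec.fs, spec.noise_exponent,
                                    spec.noise_sd, rng)
    sf = spec.shared_fraction
    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        own = one_over_f_noise(n, spec.fs, spec.noise_exponent,
                               spec.noise_sd, rng)
        noise = math.sqrt(sf) * shared_noise + math.sqrt(1 - sf) * own
        data[ch] = common_osc + noise

    background_sd = spec.noise_sd if spec.noise_sd > 0 else 1.0
    channel_ids = [f"ch{i}" for i in range(spec.n_channels)]
    truth_events = []
    for ev in spec.events:
        i0 = int(round(ev.t_on * spec.fs))
        n_ev = int(round(ev.duration_s * spec.fs))
        burst = _tukey_burst(n_ev, spec.fs, ev.carrier_hz,
                             ev.amplitude * background_sd)
        for ch in ev.channels:
            data[ch, i0:i0 + n_ev] += burst
        truth_events.append(OscEvent(
            ev.kind, ev.t_on, ev.t_on + ev.duration_s,
            frozenset(channel_ids[c] for c in ev.channels),
            peak_amplitude=ev.amplitude * background_sd,
            intra_freq_hz=ev.carrier_hz,
        ))

    sig = ContinuousSignal(data, spec.fs, channel_ids,
                           geometry=linear_geometry(channel_ids),
                           units="uV")
    truth = {
        "events": truth_events,
        "low_hz": spec.theta_hz,
        "high_hz": spec.gamma_hz,
        "coupling_depth": m,
        "coupling_phase": spec.coupling_phase,
    }
    return sig, truth


# ---------------------------------------------------------------------------
# spike-band generation
# ---------------------------------------------------------------------------

@dataclass
class SpikeClassSpec:
    """Waveform/rate parameters for one unit class (e.g. FS or RS)."""

    name: str
    rate_hz: float
    trough_to_peak_ms: float
    half_width_ms: float
    peak_valley_ratio: float
    amplitude_sd_multiple: float = 8.0
    n_units: int = 1

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValidationError("rate must be > 0")


#: default populations: narrow fast-spiking vs broad regular-spiking
FS_DEFAULT = SpikeClassSpec("FS", rate_hz=20.0, trough_to_peak_ms=0.3,
                            half_width_ms=0.2, peak_valley_ratio=0.35)
RS_DEFAULT = SpikeClassSpec("RS", rate_hz=2.0, trough_to_peak_ms=0.8,
                            half_width_ms=0.5, peak_valley_ratio=0.55)


@dataclass
class SpikePopSpec:
    fs: float = 40000.0
    duration_s: float = 30.0
    classes: list[SpikeClassSpec] = field(default_factory=lambda: [
        SpikeClassSpec(**vars(FS_DEFAULT)), SpikeClassSpec(**vars(RS_DEFAULT))])
    refractory_ms: float = 1.5
    noise_sd: float = 1.0
    gamma_shape: float = 1.0  # renewal-ISI shape; 1 = Poisson with dead time

    def __post_init__(self) -> None:
        if self.refractory_ms < 0:
            raise ValidationError("refractory must be >= 0")
        for c in self.classes:
            if self.refractory_ms * 1e-3 >= 1.0 / c.rate_hz:
                raise ValidationError(
                    f"class {c.name}: refractory {self.refractory_ms} ms "
                    f">= mean ISI at {c.rate_hz} Hz (unrealizable rate)"
                )


#: waveform extraction window around the trough, in ms
WAVEFORM_WINDOW_MS = (-0.5, 1.5)


def spike_template(fs: float, trough_to_peak_ms: float, half_width_ms: float,
                   peak_valley_ratio: float, depth: float = 1.0) -> np.ndarray:
    """Biphasic extracellular waveform template on the standard window.

    A negative Gaussian trough at t=0 whose full width at half depth is
    ``half_width_ms``, followed by a positive Gaussian peak at
    ``trough_to_peak_ms`` with amplitude ``peak_valley_ratio * depth``.
    The two lobes are far enough apart (relative to their widths, for
    physiological parameters) that the generative parameters can be read
    back off the template to within one sample.
    """
    pre_ms, post_ms = WAVEFORM_WINDOW_MS
    t = np.arange(int(round(pre_ms * 1e-3 * fs)),
                  int(round(post_ms * 1e-3 * fs))) / fs * 1e3  # ms
    sigma_t = half_width_ms / (2 * math.sqrt(2 * math.log(2)))
    sigma_p = 1.4 * sigma_t
    w = -depth * np.exp(-0.5 * (t / sigma_t) ** 2)
    w += peak_valley_ratio * depth * np.exp(
        -0.5 * ((t - trough_to_peak_ms) / sigma_p) ** 2)
    return w


def renewal_train(rate_hz: float, duration_s: float, refractory_s: float,
                  rng: np.random.Generator, shape: float = 1.0) -> np.ndarray:
    """Renewal spike train with a hard dead time.

    ISIs are refractory + Gamma(shape, scale) with the scale chosen so the
    mean rate equals ``rate_hz``; shape 1 gives Poisson-with-dead-time.
    """
    mean_isi = 1.0 / rate_hz
    free = mean_isi - refractory_s
    if free <= 0:
        raise ValidationError("refractory >= mean ISI")
    times = []
    t = float(rng.exponential(mean_isi))
    while t < duration_s:
        times.append(t)
        t += refractory_s + float(rng.gamma(shape, free / shape))
    return np.asarray(times)


def gen_spikes(spec: SpikePopSpec, seed: int
               ) -> tuple[ContinuousSignal, list[dict]]:
    """Generate spike-band traces (one channel per unit) plus ground truth.

    Returns the 40 kHz (by default) multi-channel signal and a truth list
    with one dict per unit: ``unit_id``, ``channel``, ``label`` (class
    name), ``timestamps`` and the clean ``template``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs))
    units = []
    for cls in spec.classes:
        for k in range(cls.n_units):
            units.append((cls, k))
    data = np.empty((len(units), n))
    truth = []
    for ui, (cls, k) in enumerate(units):
        data[ui] = rng.standard_normal(n) * spec.noise_sd
        train = renewal_train(cls.rate_hz, spec.duration_s,
                              spec.refractory_ms * 1e-3, rng,
                              spec.gamma_shape)
        tmpl = spike_template(spec.fs, cls.trough_to_peak_ms,
                              cls.half_width_ms, cls.peak_valley_ratio,
                              depth=cls.amplitude_sd_multiple * spec.noise_sd)
        pre = int(round(-WAVEFORM_WINDOW_MS[0] * 1e-3 * spec.fs))
        kept = []
        for ts in train:
            i_tr = int(round(ts * spec.fs))
            i0 = i_tr - pre
            if i0 < 0 or i0 + len(tmpl) > n:
                continue
            data[ui, i0:i0 + len(tmpl)] += tmpl
            kept.append(i_tr / spec.fs)
        truth.append({
            "unit_id": f"u{ui}",
            "channel": f"ch{ui}",
            "label": cls.name,
            "timestamps": np.asarray(kept),
            "template": tmpl,
            "rate_hz": cls.rate_hz,
            "trough_to_peak_ms": cls.trough_to_peak_ms,
            "half_width_ms": cls.half_width_ms,
            "peak_valley_ratio": cls.peak_valley_ratio,
        })
    channel_ids = [f"ch{i}" for i in range(len(units))]
    sig = ContinuousSignal(data, spec.fs, channel_ids,
                           geometry=linear_geometry(channel_ids),
                           units="uV")
    return sig, truth


def gen_units(spec: SpikePopSpec, seed: int, param_jitter: float = 0.05,
              max_waveforms: int = 200):
    """Generate sorted spike units directly (no continuous trace).

    For population-level work (e.g. FS/RS classifier validation) the
    continuous spike-band trace is unnecessary; this draws, per unit, a
    renewal spike train and a set of noisy waveforms around the class
    template.  Per-unit waveform/rate parameters are jittered by a
    multiplicative N(1, ``param_jitter``) factor so units within a
    class are not identical clones.

    Returns ``(units, labels)`` where ``units`` is a list of
    :class:`~lfpkit.spikes.SpikeUnit` and ``labels`` the true class
    names, index-aligned.
    """
    from .spikes import SpikeUnit

    rng = np.random.default_rng(seed)
    units, labels = [], []
    ui = 0
    for cls in spec.classes:
        for _ in range(cls.n_units):
            j = lambda v: v * float(rng.normal(1.0, param_jitter))
            rate = max(j(cls.rate_hz), 0.1)
            train = renewal_train(rate, spec.duration_s,
                                  spec.refractory_ms * 1e-3, rng,
                                  spec.gamma_shape)
            if len(train) < 2:
                continue
            tmpl = spike_template(
                spec.fs, j(cls.trough_to_peak_ms), j(cls.half_width_ms),
                j(cls.peak_valley_ratio),
                depth=cls.amplitude_sd_multiple * spec.noise_sd)
            n_wf = min(len(train), max_waveforms)
            wfs = tmpl[None, :] + rng.standard_normal(
                (n_wf, len(tmpl))) * spec.noise_sd
            units.append(SpikeUnit(
                unit_id=f"u{ui}", timestamps=train, waveforms=wfs,
                fs=spec.fs, recording_duration_s=spec.duration_s))
            labels.append(cls.name)
            ui += 1
    return units, labels


# ---------------------------------------------------------------------------
# photometry generation
# ---------------------------------------------------------------------------

@dataclass
class TransientSpec:
    t_s: float
    amplitude_frac: float  # peak amplitude as a fraction of F0
    rise_s: float = 0.2
    decay_s: float = 1.0


@dataclass
class PhotoSpec:
    fs: float = 30.0
    duration_s: float = 300.0
    f0_470: float = 100.0
    f0_410: float = 80.0
    bleach_tau_s: float = math.inf  # inf = no photobleaching
    transients: list[TransientSpec] = field(default_factory=list)
    motion_amp: float = 0.0  # shared additive artifact amplitude (F units)
    noise_sd: float = 0.0  # per-channel measurement noise (F units)
    event_tags: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.f0_470 <= 0 or self.f0_410 <= 0:
            raise ValidationError("baseline fluorescence must be > 0")
        for tag in self.event_tags:
            if tag < 120.0:
                raise ValidationError(
                    f"event tag at {tag}s: needs a full 2-min baseline "
                    "before the tag"
                )
            if tag > self.duration_s:
                raise ValidationError("event tag beyond recording end")


def _transient_kernel(t: np.ndarray, t_on: float, rise_s: float,
                      decay_s: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalised to unit peak."""
    dt = t - t_on
    k = np.where(dt > 0,
                 np.exp(-np.maximum(dt, 0) / decay_s)
                 - np.exp(-np.maximum(dt, 0) / rise_s),
                 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_photometry(spec: PhotoSpec, seed: int):
    """Two-channel fiber-photometry recording plus transient ground truth.

    The 470 nm channel carries bleaching baseline + calcium transients +
    motion; the 410 nm isosbestic channel carries the same bleaching
    shape and the same motion artifact (scaled to its own baseline) but
    is calcium-insensitive, so it carries no transients.
    """
    from .photometry import PhotometryRecording

    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    if math.isinf(spec.bleach_tau_s):
        bleach = np.ones(n)
    else:
        bleach = np.exp(-t / spec.bleach_tau_s)
    f470 = spec.f0_470 * bleach
    f410 = spec.f0_410 * bleach
    if spec.motion_amp > 0:
        # smooth band-limited motion, identical in both channels up to
        # the per-channel baseline scale
        raw = rng.standard_normal(n)
        sos = sps.butter(2, min(2.0, 0.45 * spec.fs), fs=spec.fs,
                         output="sos")
        motion = sps.sosfiltfilt(sos, raw)
        motion *= spec.motion_amp / motion.std()
        f470 = f470 + motion
        f410 = f410 + motion * (spec.f0_410 / spec.f0_470)
    for tr in spec.transients:
        f470 = f470 + spec.f0_470 * tr.amplitude_frac * _transient_kernel(
            t, tr.t_s, tr.rise_s, tr.decay_s)
    if spec.noise_sd > 0:
        f470 = f470 + rng.standard_normal(n) * spec.noise_sd
        f410 = f410 + rng.standard_normal(n) * spec.noise_sd
    rec = PhotometryRecording(F470=f470, F410=f410, fs=spec.fs,
                              event_tags=list(spec.event_tags))
    truth = [{"t_s": tr.t_s, "amplitude_frac": tr.amplitude_frac,
              "rise_s": tr.rise_s, "decay_s": tr.decay_s}
             for tr in spec.transients]
    return rec, truth
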