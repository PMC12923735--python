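"""Detection of epileptiform discharges, ripples and fast ripples.

Three event families are handled:

* **epileptiform discharges** — abnormal high-energy transients.  The
  criteria are conjunctive: envelope energy above ``sd_mult`` (default 4)
  baseline standard deviations after high-pass filtering above
  ``hf_cut_hz`` (default 100 Hz), duration at most ``max_duration_s``
  (default 4 s), and simultaneous appearance on at least
  ``min_channels_contig`` (default 5, i.e. *more than 4*) channels that
  are contiguous under the recording's electrode geometry;
* **ripples** — physiological 140-200 Hz oscillations;
* **fast ripples** — pathological 200-500 Hz oscillations.

Band events (ripple / fast ripple) are detected per channel from the
Gaussian-smoothed analytic-signal envelope of the band-passed trace;
the paper trail for ripple statistics distinguishes the *occurrence
rate* (events/min, ``EventSummary.event_rate``) from the *intra-event
oscillation frequency* (Hz, ``OscEvent.intra_freq_hz``); both are
computed because either reading of "ripple frequency" is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .signal import (BandDef, ContinuousSignal, FAST_RIPPLE, RIPPLE,
                     ValidationError, bandpass, highpass)


class ConfigurationError(ValueError):
    pass


@dataclass
class OscEvent:
    """A detected (or injected) interval event.

    ``peak_amplitude`` is the maximum of the band-limited envelope inside
    the event, in signal units; ``intra_freq_hz`` is the dominant
    oscillation frequency within the event.
    """

    kind: str  # epileptiform | ripple | fast_ripple
    t_on: float
    t_off: float
    channels: frozenset[str] = field(default_factory=frozenset)
    peak_amplitude: float = float("nan")
    intra_freq_hz: float = float("nan")
    segment_index: int | None = None

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValidationError(
                f"event t_off {self.t_off} <= t_on {self.t_on}"
            )
        self.channels = frozenset(self.channels)

    @property
    def duration_s(self) -> float:
        return self.t_off - self.t_on

    def overlaps(self, other: "OscEvent") -> bool:
        return self.t_on < other.t_off and other.t_on < self.t_off


@dataclass
class EventSummary:
    n_events: int
    event_rate_per_min: float
    mean_intra_freq_hz: float | None
    mean_peak_amplitude: float | None
    mean_duration_s: float | None
    per_segment_counts: list[int]
    per_segment_rates_per_min: list[float]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _threshold_runs(env: np.ndarray, core_thr: float,
                    edge_thr: float) -> list[tuple[int, int, int]]:
    """Dual-threshold (hysteresis) detection.

    Event cores are runs above ``core_thr``; each core is extended
    outward to the surrounding run above the lower ``edge_thr``, which
    recovers the full extent of an event whose onset/offset ramps sit
    below the core threshold.  Edge runs containing no core are
    discarded.  Returns (start, stop, longest_core_samples) triples;
    the core length lets callers demand a sustained supra-threshold
    oscillation rather than a brief excursion whose edge extension
    happens to be long.
    """
    cores = _runs_above(env > core_thr)
    if not cores:
        return []
    edges = _runs_above(env > edge_thr)
    out = []
    ci = 0
    for a, b in edges:
        longest = 0
        while ci < len(cores) and cores[ci][1] <= b:
            if cores[ci][0] >= a:
                longest = max(longest, cores[ci][1] - cores[ci][0])
            ci += 1
        if longest:
            out.append((a, b, longest))
    return out


def _merge_intervals(iv: list[tuple[float, float]],
                     gap: float) -> list[tuple[float, float]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for a, b in iv[1:]:
        if a - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def _largest_contiguous(channels: set[str],
                        adjacency: dict[str, set[str]]) -> int:
    """Size of the largest connected channel subset under the geometry."""
    remaining = set(channels)
    best = 0
    while remaining:
        stack = [remaining.pop()]
        size = 0
        while stack:
            c = stack.pop()
            size += 1
            for nb in adjacency.get(c, ()):
                if nb in remaining:
                    remaining.discard(nb)
                    stack.append(nb)
        best = max(best, size)
    return best


def _intra_event_frequency(band_trace: np.ndarray, fs: float) -> float:
    """Dominant oscillation frequency from sub-sample-refined peak times.

    Peaks of the band-limited trace are located with parabolic
    interpolation around each sample maximum, then the median inter-peak
    interval gives the frequency.  The sub-sample refinement avoids the
    coarse quantisation that integer-sample peak spacing would impose at
    carrier periods of only a few samples.
    """
    peaks, _ = sps.find_peaks(band_trace)
    if len(peaks) < 2:
        return float("nan")
    refined = []
    for p in peaks:
        if 0 < p < len(band_trace) - 1:
            y0, y1, y2 = band_trace[p - 1:p + 2]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            refined.append(p + float(np.clip(delta, -0.5, 0.5)))
        else:
            refined.append(float(p))
    intervals = np.diff(refined)
    med = float(np.median(intervals))
    return fs / med if med > 0 else float("nan")


def _envelope(x: np.ndarray, fs: float, smooth_sigma_ms: float) -> np.ndarray:
    env = np.abs(sps.hilbert(x))
    if smooth_sigma_ms > 0:
        env = gaussian_filter1d(env, smooth_sigma_ms * 1e-3 * fs)
    return env


# ---------------------------------------------------------------------------
# epileptiform detection
# ---------------------------------------------------------------------------

def detect_epileptiform(
    signal: ContinuousSignal,
    sd_mult: float = 4.0,
    min_channels_contig: int = 5,
    max_duration_s: float = 4.0,
    min_duration_s: float = 0.1,
    hf_cut_hz: float = 100.0,
    baseline: tuple[float, float] | None = None,
    smooth_sigma_ms: float = 4.0,
    merge_gap_s: float = 0.05,
    edge_sd_mult: float = 2.0,
    label_swr_above_hz: float = 200.0,
) -> list[OscEvent]:
    """Detect epileptiform discharges under conjunctive criteria.

    Per channel the trace is high-pass filtered above ``hf_cut_hz`` and its
    analytic-signal energy envelope is thresholded at baseline mean +
    ``sd_mult`` baseline SD (the baseline statistics are computed on the
    envelope over event-free samples, with a second pass that excludes
    the first pass's supra-threshold runs).  Each supra-threshold core
    is extended outward to the surrounding run above a lower edge
    threshold (``edge_sd_mult`` SD) so the full onset/offset ramps are
    captured.  Supra-threshold runs are
    merged across channels when they overlap in time; a merged event is
    kept only if its channel set contains at least ``min_channels_contig``
    channels that are contiguous under the recording geometry AND its
    duration lies within [``min_duration_s``, ``max_duration_s``] — the
    lower bound operationalises the requirement that a discharge carry
    a sustained burst of high-frequency activity rather than a
    millisecond noise excursion.

    Sharp-wave-ripple-type events (dominant intra-event frequency above
    ``label_swr_above_hz``) are labeled epileptiform like the rest; in
    freely-moving recordings such events are counted as pathological.
    """
    if not signal.geometry:
        raise ConfigurationError(
            "epileptiform detection needs channel geometry (contiguity)"
        )
    if signal.n_channels < min_channels_contig:
        raise ConfigurationError(
            f"{signal.n_channels} channels present but "
            f"{min_channels_contig} contiguous channels required"
        )
    hp = highpass(signal, hf_cut_hz)
    adjacency = signal.neighbors()
    fs = signal.fs

    per_channel_runs: dict[str, list[tuple[float, float]]] = {}
    envs: dict[str, np.ndarray] = {}
    for ci, cid in enumerate(signal.channel_ids):
        env = _envelope(hp.data[ci], fs, smooth_sigma_ms)
        envs[cid] = env
        if baseline is not None:
            b0 = int(round((baseline[0] - signal.t0) * fs))
            b1 = int(round((baseline[1] - signal.t0) * fs))
            base = env[b0:b1]
        else:
            base = env
        # two-pass baseline: a robust (median/MAD) first estimate so that
        # the events themselves cannot inflate it, then mean/SD over the
        # sub-threshold (event-free) samples
        mu = float(np.median(base))
        sd = float(np.median(np.abs(base - mu)) / 0.6745)
        for _ in range(2):
            thr = mu + sd_mult * sd
            quiet = base[base <= thr]
            if quiet.size < 10:
                break
            mu, sd = float(np.mean(quiet)), float(np.std(quiet))
        thr = mu + sd_mult * sd
        edge = mu + min(edge_sd_mult, sd_mult) * sd
        runs = _threshold_runs(env, thr, edge)
        iv = [(signal.t0 + a / fs, signal.t0 + b / fs) for a, b, _ in runs]
        per_channel_runs[cid] = _merge_intervals(iv, merge_gap_s)

    # merge across channels: overlapping intervals form one candidate event
    tagged = [(a, b, cid) for cid, ivs in per_channel_runs.items()
              for a, b in ivs]
    tagged.sort()
    events: list[OscEvent] = []
    cluster: list[tuple[float, float, str]] = []

    def flush(cluster: list[tuple[float, float, str]]) -> None:
        if not cluster:
            return
        t_on = min(a for a, _, _ in cluster)
        t_off = max(b for _, b, _ in cluster)
        chans = {cid for _, _, cid in cluster}
        if _largest_contiguous(chans, adjacency) < min_channels_contig:
            return
        if not (min_duration_s <= t_off - t_on <= max_duration_s):
            return
        i0 = int(round((t_on - signal.t0) * fs))
        i1 = int(round((t_off - signal.t0) * fs))
        peak = max(float(envs[c][i0:i1].max()) for c in chans)
        ref = max(chans, key=lambda c: float(envs[c][i0:i1].max()))
        ref_i = signal.channel_ids.index(ref)
        freq = _intra_event_frequency(hp.data[ref_i, i0:i1], fs)
        events.append(OscEvent("epileptiform", t_on, t_off,
                               frozenset(chans), peak, freq))

    for a, b, cid in tagged:
        if cluster and a <= max(x[1] for x in cluster):
            cluster.append((a, b, cid))
        else:
            flush(cluster)
            cluster = [(a, b, cid)]
    flush(cluster)
    events.sort(key=lambda e: e.t_on)
    return events


# ---------------------------------------------------------------------------
# band-limited (ripple / fast ripple) detection
# ---------------------------------------------------------------------------

#: per-kind presets: (band, minimum duration in ms)
BAND_EVENT_PRESETS: dict[str, tuple[BandDef, float]] = {
    "ripple": (RIPPLE, 20.0),
    "fast_ripple": (FAST_RIPPLE, 10.0),
}


def detect_band_events(
    signal: ContinuousSignal,
    band: BandDef,
    channel: int | str = 0,
    envelope_sd_mult: float = 3.0,
    min_duration_ms: float = 20.0,
    merge_gap_ms: float = 10.0,
    smooth_sigma_ms: float = 4.0,
    edge_sd_mult: float = 2.0,
    kind: str | None = None,
) -> list[OscEvent]:
    """Detect transient band-limited oscillation events on one channel.

    Pipeline: zero-phase band-pass -> analytic-signal envelope ->
    Gaussian smoothing (sigma ``smooth_sigma_ms``) -> threshold at
    envelope mean + ``envelope_sd_mult`` envelope SD with hysteresis
    down to ``edge_sd_mult`` SD for the onset/offset ramps -> keep
    events whose supra-threshold core lasts at least
    ``min_duration_ms`` (the core, not the edge extension, must be
    sustained), merging events separated by less than ``merge_gap_ms``.
    """
    band.check_nyquist(signal.fs)
    if kind is None:
        kind = band.name if band.name in BAND_EVENT_PRESETS else "band_event"
    bp = bandpass(signal, band)
    ci = (signal.channel_ids.index(channel)
          if isinstance(channel, str) else channel)
    trace = bp.data[ci]
    fs = signal.fs
    env = _envelope(trace, fs, smooth_sigma_ms)
    mu, sd = float(np.mean(env)), float(np.std(env))
    thr = mu + envelope_sd_mult * sd
    edge = mu + min(edge_sd_mult, envelope_sd_mult) * sd
    min_core = min_duration_ms * 1e-3 * fs
    runs = [(a, b) for a, b, core in _threshold_runs(env, thr, edge)
            if core >= min_core]
    iv = [(signal.t0 + a / fs, signal.t0 + b / fs) for a, b in runs]
    iv = _merge_intervals(iv, merge_gap_ms * 1e-3)
    cid = signal.channel_ids[ci]
    events = []
    for a, b in iv:
        i0 = int(round((a - signal.t0) * fs))
        i1 = int(round((b - signal.t0) * fs))
        events.append(OscEvent(
            kind, a, b, frozenset({cid}),
            peak_amplitude=float(env[i0:i1].max()),
            intra_freq_hz=_intra_event_frequency(trace[i0:i1], fs),
        ))
    return events


def detect_ripples(signal: ContinuousSignal, channel: int | str = 0,
                   **kw) -> list[OscEvent]:
    band, min_dur = BAND_EVENT_PRESETS["ripple"]
    kw.setdefault("min_duration_ms", min_dur)
    return detect_band_events(signal, band, channel, kind="ripple", **kw)


def detect_fast_ripples(signal: ContinuousSignal, channel: int | str = 0,
                        **kw) -> list[OscEvent]:
    band, min_dur = BAND_EVENT_PRESETS["fast_ripple"]
    kw.setdefault("min_duration_ms", min_dur)
    return detect_band_events(signal, band, channel, kind="fast_ripple", **kw)


def exclude_overlapping(events: Sequence[OscEvent],
                        exclusions: Sequence[OscEvent]) -> list[OscEvent]:
    """Drop events overlapping any exclusion interval (e.g. keep only
    physiological ripples by excluding epileptiform epochs)."""
    return [e for e in events
            if not any(e.overlaps(x) for x in exclusions)]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_events(events: Sequence[OscEvent],
                     recording_duration_s: float,
                     segment_s: float = 300.0,
                     t0: float = 0.0) -> EventSummary:
    """Event rate (events/min, overall and per segment) and event means.

    The final segment may be shorter than ``segment_s``; its rate is
    normalised by its actual duration.  Means are ``None`` when there are
    no events.
    """
    if recording_duration_s <= 0:
        raise ValidationError("recording_duration_s must be > 0")
    events = sorted(events, key=lambda e: e.t_on)
    n = len(events)
    rate = n / (recording_duration_s / 60.0)
    n_seg = int(np.ceil(recording_duration_s / segment_s))
    counts = [0] * max(n_seg, 1)
    durations = []
    for e in events:
        si = min(int((e.t_on - t0) // segment_s), len(counts) - 1)
        counts[si] += 1
        durations.append(e.duration_s)
    seg_rates = []
    for i, c in enumerate(counts):
        seg_dur = min(segment_s, recording_duration_s - i * segment_s)
        seg_rates.append(c / (seg_dur / 60.0) if seg_dur > 0 else 0.0)

    def _mean(vals):
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else None

    return EventSummary(
        n_events=n,
        event_rate_per_min=rate,
        mean_intra_freq_hz=_mean([e.intra_freq_hz for e in events]) if n else None,
        mean_peak_amplitude=_mean([e.peak_amplitude for e in events]) if n else None,
        mean_duration_s=float(np.mean(durations)) if n else None,
        per_segment_counts=counts,
        per_segment_rates_per_min=seg_rates,
    )
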