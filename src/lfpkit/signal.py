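"""Domain types, file I/O, segmentation and band-limited filtering.

The central container is :class:`ContinuousSignal`, a multi-channel
time series with an explicit sampling rate and an explicit channel
contiguity graph (``geometry``).  The contiguity graph matters because
epileptiform-discharge detection requires events to span a minimum
number of *contiguous* electrode channels; the detector never guesses
the electrode layout, it is declared by the data producer.

Two on-disk formats are supported:

* delimited text (CSV) — one column per channel, optional leading time
  column; portable, human-readable;
* ``raw_f32`` — channel-major little-endian float32 stream with a JSON
  sidecar (``<path>.json``) holding ``fs``, ``channel_ids``, ``units``,
  ``geometry`` and ``t0``; bit-exact round trips.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class FormatError(ValueError):
    """Raised when an on-disk artifact is malformed or incomplete."""


# ---------------------------------------------------------------------------
# Band presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDef:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def check_nyquist(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValidationError(
                f"band {self.name!r} upper edge {self.f_hi} Hz >= Nyquist "
                f"({fs / 2} Hz)"
            )


#: Theta band as used for PSD band-power summaries.
THETA_PSD = BandDef("theta", 3.0, 8.0)
#: Wider theta band as used for band-limited filtering / PAC phase.
THETA_FILT = BandDef("theta_filt", 4.0, 12.0)
LOW_GAMMA = BandDef("low_gamma", 30.0, 50.0)
HIGH_GAMMA = BandDef("high_gamma", 50.0, 90.0)
#: Wide gamma band as used for band-limited filtering / PAC amplitude.
GAMMA_FILT = BandDef("gamma_filt", 30.0, 80.0)
RIPPLE = BandDef("ripple", 140.0, 200.0)
FAST_RIPPLE = BandDef("fast_ripple", 200.0, 500.0)

BAND_PRESETS: dict[str, BandDef] = {
    b.name: b
    for b in (THETA_PSD, THETA_FILT, LOW_GAMMA, HIGH_GAMMA, GAMMA_FILT,
              RIPPLE, FAST_RIPPLE)
}


def linear_geometry(channel_ids: Sequence[str]) -> list[tuple[str, str]]:
    """Chain contiguity: each channel is a neighbor of the next one."""
    ids = list(channel_ids)
    return [(a, b) for a, b in zip(ids, ids[1:])]


# ---------------------------------------------------------------------------
# ContinuousSignal
# ---------------------------------------------------------------------------

@dataclass
class ContinuousSignal:
    """Multi-channel continuous recording.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples).
    fs
        Sampling rate in Hz; must be positive.
    channel_ids
        Ordered channel labels, one per row of ``data``.
    geometry
        Contiguity relations as (id_a, id_b) pairs.  Symmetry is implied:
        storing one direction is enough.
    t0
        Start time in seconds.
    units
        Signal units, e.g. ``"uV"`` or ``"dF/F"``.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    geometry: list[tuple[str, str]] = field(default_factory=list)
    t0: float = 0.0
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("duplicate channel ids")
        known = set(self.channel_ids)
        for a, b in self.geometry:
            if a not in known or b not in known:
                raise ValidationError(
                    f"geometry references unknown channel ({a!r}, {b!r})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, key: int | str) -> np.ndarray:
        """One channel's samples, by index or by label."""
        if isinstance(key, str):
            key = self.channel_ids.index(key)
        return self.data[key]

    def neighbors(self) -> dict[str, set[str]]:
        """Symmetric adjacency map derived from ``geometry``."""
        adj: dict[str, set[str]] = {c: set() for c in self.channel_ids}
        for a, b in self.geometry:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def slice_time(self, start_s: float, end_s: float) -> "ContinuousSignal":
        i0 = max(0, int(round((start_s - self.t0) * self.fs)))
        i1 = min(self.n_samples, int(round((end_s - self.t0) * self.fs)))
        return replace(self, data=self.data[:, i0:i1],
                       t0=self.t0 + i0 / self.fs)


@dataclass(frozen=True)
class Segment:
    """A [start_s, end_s) window of a parent recording."""

    parent: ContinuousSignal
    start_s: float
    end_s: float
    index: int
    nominal_s: float = 300.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_short(self) -> bool:
        """True for a trailing segment shorter than the nominal window."""
        return self.duration_s < self.nominal_s - 1e-9

    def extract(self) -> ContinuousSignal:
        return self.parent.slice_time(self.start_s, self.end_s)


def segment(signal: ContinuousSignal, window_s: float = 300.0) -> list[Segment]:
    """Split a recording into sequential fixed-length segments.

    Recordings are processed as sequential windows (5 minutes by default);
    the final segment may be shorter and is retained, not dropped — any
    per-segment rate must therefore be normalised by the actual segment
    duration, which :func:`Segment.duration_s` reports.
    """
    if window_s <= 0:
        raise ValidationError(f"window_s must be > 0, got {window_s}")
    n = math.ceil(signal.duration_s / window_s)
    out = []
    for i in range(n):
        start = signal.t0 + i * window_s
        end = min(signal.t0 + (i + 1) * window_s, signal.t0 + signal.duration_s)
        out.append(Segment(signal, start, end, i, nominal_s=window_s))
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass(signal: ContinuousSignal, band: BandDef,
             order: int = 4) -> ContinuousSignal:
    """Zero-phase Butterworth band-pass.

    The filter is applied forward-backward (``sosfiltfilt``) so that event
    timing is not shifted; the effective magnitude response is the square
    of the single-pass Butterworth response, which keeps the monotone
    passband and better-than-20 dB/octave stopband rolloff for order >= 2.
    """
    band.check_nyquist(signal.fs)
    sos = sps.butter(order, [band.f_lo, band.f_hi], btype="bandpass",
                     fs=signal.fs, output="sos")
    out = sps.sosfiltfilt(sos, signal.data, axis=1)
    return replace(signal, data=out)


def highpass(signal: ContinuousSignal, f_lo: float,
             order: int = 4) -> ContinuousSignal:
    """Zero-phase Butterworth high-pass (used by the epileptiform detector)."""
    if not (0 < f_lo < signal.fs / 2):
        raise ValidationError(f"high-pass edge {f_lo} Hz outside (0, Nyquist)")
    sos = sps.butter(order, f_lo, btype="highpass", fs=signal.fs, output="sos")
    return replace(signal, data=sps.sosfiltfilt(sos, signal.data, axis=1))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing sidecar metadata file {sc}")
    with open(sc) as fh:
        return json.load(fh)


def _signal_from_meta(data: np.ndarray, meta: dict) -> ContinuousSignal:
    fs = float(meta["fs"])
    if fs <= 0:
        raise ValidationError(f"sidecar fs must be > 0, got {fs}")
    geometry = [tuple(pair) for pair in meta.get("geometry", [])]
    return ContinuousSignal(
        data=data,
        fs=fs,
        channel_ids=list(meta.get("channel_ids", [])),
        geometry=geometry,
        t0=float(meta.get("t0", 0.0)),
        units=meta.get("units", "uV"),
    )


def read_signal(path: str | Path, format: str = "csv") -> ContinuousSignal:
    """Read a recording from disk.

    ``csv``: one column per channel; a leading ``time`` column (detected
    by header name or by a strictly increasing first column when no
    sidecar exists) supplies the sampling rate if the sidecar is absent.
    ``raw_f32``: channel-major float32 stream; the JSON sidecar is
    mandatory (it carries fs, channel count and geometry).
    """
    path = Path(path)
    if format == "raw_f32":
        meta = _read_sidecar(path)
        for key in ("fs", "n_channels"):
            if key not in meta:
                raise FormatError(f"sidecar missing required key {key!r}")
        raw = np.fromfile(path, dtype="<f4")
        n_ch = int(meta["n_channels"])
        if n_ch <= 0 or raw.size % n_ch:
            raise ValidationError(
                f"{raw.size} samples not divisible into {n_ch} equal channels"
            )
        data = raw.reshape(n_ch, raw.size // n_ch)
        return _signal_from_meta(data, meta)
    if format == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        cols = list(df.columns)
        sc = _sidecar_path(path)
        meta = None
        if sc.exists():
            meta = _read_sidecar(path)
        time_col = None
        if cols and cols[0].lower() in ("time", "time_s", "t"):
            time_col = cols[0]
        if meta is None and time_col is None:
            raise FormatError(
                f"{path}: no sidecar and no leading time column; "
                "cannot determine sampling rate"
            )
        if time_col is not None:
            t = df[time_col].to_numpy(dtype=float)
            if len(t) < 2 or np.any(np.diff(t) <= 0):
                raise FormatError(f"{path}: time column not strictly increasing")
            fs_from_time = 1.0 / float(np.median(np.diff(t)))
            df = df.drop(columns=[time_col])
        data = df.to_numpy(dtype=float).T
        if meta is None:
            meta = {"fs": fs_from_time, "channel_ids": list(df.columns),
                    "t0": float(t[0])}
        elif "channel_ids" not in meta:
            meta = {**meta, "channel_ids": list(df.columns)}
        return _signal_from_meta(data, meta)
    raise FormatError(f"unknown format {format!r}")


def write_signal(signal: ContinuousSignal, path: str | Path,
                 format: str = "csv") -> None:
    """Write a recording; the JSON sidecar is always written."""
    path = Path(path)
    meta = {
        "fs": signal.fs,
        "n_channels": signal.n_channels,
        "channel_ids": signal.channel_ids,
        "units": signal.units,
        "geometry": [list(p) for p in signal.geometry],
        "t0": signal.t0,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    if format == "raw_f32":
        signal.data.astype("<f4").tofile(path)
        return
    if format == "csv":
        import pandas as pd

        df = pd.DataFrame(signal.data.T, columns=signal.channel_ids)
        df.insert(0, "time_s", signal.times())
        df.to_csv(path, index=False)
        return
    raise FormatError(f"unknown format {format!r}")
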