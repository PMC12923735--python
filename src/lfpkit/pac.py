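"""Theta-phase / gamma-amplitude coupling via the mean-vector-length
modulation index.

The modulation index is the modulus of the amplitude-weighted mean
phase phasor

    MIn = | n^-1 * sum_{t=1..n} A_t * exp(i * theta_t) |

where ``theta_t`` is the instantaneous phase of the low-frequency
(phase-providing) band and ``A_t`` the instantaneous amplitude envelope
of the high-frequency (amplitude-providing) band, both obtained from
the analytic signal (Hilbert transform) of the zero-phase band-passed
trace.  Raw MIn carries the amplitude scale of the signal; the
dimensionless ``MIn_normalized = MIn / mean(A_t)`` in [0, 1] is
reported alongside for cross-condition comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .signal import (BandDef, ContinuousSignal, GAMMA_FILT, THETA_FILT,
                     ValidationError, bandpass)


@dataclass
class PacSeries:
    """Paired phase / amplitude-envelope series for one band pair."""

    phase: np.ndarray  # radians in (-pi, pi]
    amplitude: np.ndarray  # envelope, signal units, >= 0
    fs: float
    low_band: BandDef
    high_band: BandDef

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise ValidationError("phase and amplitude lengths differ")

    @property
    def n(self) -> int:
        return len(self.phase)


@dataclass
class PacResult:
    MIn: float
    MIn_normalized: float
    low_band: BandDef
    high_band: BandDef
    n: int


#: documented minimum series length, in low-band cycles
MIN_CYCLES = 10


def extract_pac_series(signal: ContinuousSignal, low: BandDef,
                       high: BandDef, channel: int | str = 0,
                       edge_margin_s: float = 1.0) -> PacSeries:
    """Phase of the low band and amplitude envelope of the high band.

    Both bands are applied as zero-phase band-passes; the analytic
    signal supplies instantaneous phase (low band) and envelope (high
    band).  An ``edge_margin_s`` margin is trimmed from both ends to
    discard filter and Hilbert edge transients.
    """
    if low.f_hi > high.f_lo:
        raise ValidationError(
            f"phase band {low.name!r} overlaps amplitude band {high.name!r}"
        )
    low.check_nyquist(signal.fs)
    high.check_nyquist(signal.fs)
    ci = (signal.channel_ids.index(channel)
          if isinstance(channel, str) else channel)
    lo = bandpass(signal, low).data[ci]
    hi = bandpass(signal, high).data[ci]
    phase = np.angle(hilbert(lo))
    amp = np.abs(hilbert(hi))
    margin = int(round(edge_margin_s * signal.fs))
    if margin > 0 and 2 * margin < len(phase):
        phase = phase[margin:-margin]
        amp = amp[margin:-margin]
    return PacSeries(phase, amp, signal.fs, low, high)


def modulation_index(series: PacSeries) -> PacResult:
    """Mean-vector-length modulation index of a phase/amplitude pair.

    ``MIn`` is the modulus of the mean of ``A_t * exp(i*theta_t)``;
    ``MIn_normalized`` divides by ``mean(A_t)`` (defined as 0 when the
    envelope is identically zero) and lies in [0, 1] by the triangle
    inequality.
    """
    if series.n == 0:
        raise ValidationError("empty phase/amplitude series")
    phasor_mean = np.mean(series.amplitude * np.exp(1j * series.phase))
    min_val = float(np.abs(phasor_mean))
    mean_amp = float(np.mean(series.amplitude))
    min_norm = min_val / mean_amp if mean_amp > 0 else 0.0
    return PacResult(MIn=min_val, MIn_normalized=min_norm,
                     low_band=series.low_band, high_band=series.high_band,
                     n=series.n)


def pac(signal: ContinuousSignal, low: BandDef = THETA_FILT,
        high: BandDef = GAMMA_FILT, channel: int | str = 0,
        edge_margin_s: float = 1.0) -> PacResult:
    """Convenience: extract the series and compute the modulation index."""
    return modulation_index(
        extract_pac_series(signal, low, high, channel, edge_margin_s))


def comodulogram(signal: ContinuousSignal, low_grid: list[BandDef],
                 high_grid: list[BandDef], channel: int | str = 0,
                 edge_margin_s: float = 1.0) -> np.ndarray:
    """Matrix of normalised modulation indices over a band-pair grid.

    ``matrix[i, j]`` is ``MIn_normalized`` for phase band ``low_grid[i]``
    and amplitude band ``high_grid[j]``.  Pairs where the bands overlap
    are set to NaN.
    """
    out = np.full((len(low_grid), len(high_grid)), np.nan)
    for i, lo in enumerate(low_grid):
        for j, hi in enumerate(high_grid):
            if lo.f_hi > hi.f_lo:
                continue
            series = extract_pac_series(signal, lo, hi, channel,
                                        edge_margin_s)
            out[i, j] = modulation_index(series).MIn_normalized
    return out


def default_comodulogram_grids() -> tuple[list[BandDef], list[BandDef]]:
    """2 Hz phase bins over 3-15 Hz; 10 Hz amplitude bins over 15-95 Hz.

    Bin edges are placed on odd frequencies so that the canonical theta
    (6 Hz) and gamma (40 Hz) rhythms fall at cell centres, not edges.
    """
    low = [BandDef(f"lo{a}-{a + 2}", float(a), float(a + 2))
           for a in range(3, 15, 2)]
    high = [BandDef(f"hi{a}-{a + 10}", float(a), float(a + 10))
            for a in range(15, 95, 10)]
    return low, high


def surrogate_threshold(series: PacSeries, n_surrogates: int = 200,
                        min_shift_s: float = 1.0, seed: int = 0,
                        quantile: float = 0.95) -> float:
    """Surrogate-null MIn_normalized level by circular envelope shifts.

    The amplitude series is circularly shifted by uniform offsets of at
    least ``min_shift_s``, which destroys the phase-amplitude alignment
    while preserving both marginal autocorrelations.
    """
    rng = np.random.default_rng(seed)
    n = series.n
    min_shift = int(round(min_shift_s * series.fs))
    if 2 * min_shift >= n:
        raise ValidationError("series too short for the requested shift")
    vals = np.empty(n_surrogates)
    for k in range(n_surrogates):
        shift = int(rng.integers(min_shift, n - min_shift))
        rolled = np.roll(series.amplitude, shift)
        surr = PacSeries(series.phase, rolled, series.fs,
                         series.low_band, series.high_band)
        vals[k] = modulation_index(surr).MIn_normalized
    return float(np.quantile(vals, quantile))
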