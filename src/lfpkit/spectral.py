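"""Welch power spectral density, band power and spectrogram.

The PSD follows the acquisition-software configuration the analyses
assume: Hann-windowed segments giving 1024 one-sided frequency values,
25% segment overlap, per-window mean removal.  The density is
variance-normalised (one-sided, units^2/Hz) so that its integral over
frequency equals the signal variance (Parseval, window-power
corrected); absolute units of proprietary acquisition software differ
by a fixed scale, but every band-power ratio and cross-condition
comparison is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import BandDef, ContinuousSignal, ValidationError


@dataclass
class PsdResult:
    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # (n_channels, n_freqs), units^2/Hz, >= 0
    n_freq_values: int
    overlap_frac: float
    window: str
    channel_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.freqs) != self.n_freq_values:
            raise ValidationError("freqs length != n_freq_values")


def _welch_params(n_freq_values: int, overlap_frac: float) -> tuple[int, int]:
    nperseg = 2 * (n_freq_values - 1)
    noverlap = int(round(overlap_frac * nperseg))
    return nperseg, noverlap


def psd(signal: ContinuousSignal, n_freq_values: int = 1024,
        overlap_frac: float = 0.25, window: str = "hann") -> PsdResult:
    """Welch PSD with ``n_freq_values`` one-sided bins.

    The window length is ``2*(n_freq_values - 1)`` samples so that the
    one-sided spectrum has exactly ``n_freq_values`` bins; the mean is
    removed per window, making the estimate invariant to constant
    offsets.
    """
    if not 0 <= overlap_frac < 1:
        raise ValidationError("overlap_frac must be in [0, 1)")
    nperseg, noverlap = _welch_params(n_freq_values, overlap_frac)
    if signal.n_samples < nperseg:
        raise ValidationError(
            f"signal has {signal.n_samples} samples but one PSD window "
            f"needs {nperseg} ({nperseg / signal.fs:.3g} s at fs="
            f"{signal.fs})"
        )
    freqs, power = sps.welch(signal.data, fs=signal.fs, window=window,
                             nperseg=nperseg, noverlap=noverlap,
                             detrend="constant", scaling="density",
                             axis=1)
    return PsdResult(freqs=freqs, power=power, n_freq_values=len(freqs),
                     overlap_frac=overlap_frac, window=window,
                     channel_ids=list(signal.channel_ids))


def psd_per_segment(signal: ContinuousSignal, segment_s: float = 300.0,
                    **kw) -> PsdResult:
    """PSD computed per sequential segment, then averaged.

    Recordings stored as sequential 5-minute segments are analysed per
    segment; this helper averages the per-segment densities (trailing
    segments too short for one window are skipped).
    """
    from .signal import segment as _segment

    segs = _segment(signal, segment_s)
    results = []
    for s in segs:
        try:
            results.append(psd(s.extract(), **kw))
        except ValidationError:
            continue
    if not results:
        raise ValidationError("no segment long enough for one PSD window")
    power = np.mean([r.power for r in results], axis=0)
    r0 = results[0]
    return PsdResult(r0.freqs, power, r0.n_freq_values, r0.overlap_frac,
                     r0.window, r0.channel_ids)


def band_power(psd_result: PsdResult, band: BandDef) -> np.ndarray:
    """Trapezoidal integral of the density over [f_lo, f_hi], per channel.

    The band edges are interpolated onto the frequency grid, which makes
    the integral exactly additive over adjacent disjoint bands.
    """
    f = psd_result.freqs
    if band.f_lo < f[0] or band.f_hi > f[-1]:
        raise ValidationError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}] outside PSD "
            f"range [{f[0]}, {f[-1]}]"
        )
    inner = (f > band.f_lo) & (f < band.f_hi)
    grid = np.concatenate(([band.f_lo], f[inner], [band.f_hi]))
    out = np.empty(psd_result.power.shape[0])
    for ch in range(psd_result.power.shape[0]):
        vals = np.interp(grid, f, psd_result.power[ch])
        out[ch] = np.trapezoid(vals, grid)
    return out


def band_powers(psd_result: PsdResult,
                bands: list[BandDef]) -> dict[str, np.ndarray]:
    return {b.name: band_power(psd_result, b) for b in bands}


def spectrogram(signal: ContinuousSignal, window_s: float = 1.0,
                overlap_frac: float = 0.25, channel: int | str = 0,
                window: str = "hann"):
    """Short-time PSD of one channel.

    Returns ``(freqs, times, Sxx)`` with column times centred on each
    window and the same one-sided density normalisation per column as
    :func:`psd`.
    """
    ci = (signal.channel_ids.index(channel)
          if isinstance(channel, str) else channel)
    nperseg = int(round(window_s * signal.fs))
    if nperseg < 2 or signal.n_samples < nperseg:
        raise ValidationError("signal shorter than one spectrogram window")
    noverlap = int(round(overlap_frac * nperseg))
    freqs, times, Sxx = sps.spectrogram(
        signal.data[ci], fs=signal.fs, window=window, nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density",
        mode="psd")
    return freqs, times + signal.t0, Sxx
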