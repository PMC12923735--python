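"""dF/F computation with isosbestic control and event-aligned summaries.

The primary output is the per-tag fractional fluorescence change

    dF/F(t) = (F(t) - F0) / F0

where ``F0`` is the mean fluorescence of the same channel over the two
minutes immediately preceding the event tag.  The 410 nm isosbestic
channel (calcium-insensitive) is processed with the identical formula
and serves as a movement/photobleaching control; an optional
regression-based motion correction (470 dF/F minus the least-squares
linear transform of the 410 dF/F fitted on the baseline window) is
emitted alongside, never silently replacing the raw per-channel dF/F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal import ValidationError

BASELINE_S = 120.0  # 2-minute pre-tag baseline


@dataclass
class PhotometryRecording:
    """Paired 470/410 nm fluorescence traces with event tags (s)."""

    F470: np.ndarray
    F410: np.ndarray
    fs: float
    event_tags: list[float] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.F470 = np.asarray(self.F470, dtype=float)
        self.F410 = np.asarray(self.F410, dtype=float)
        if self.F470.shape != self.F410.shape:
            raise ValidationError("470/410 traces differ in length")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.F470)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def trace(self, channel: int | str) -> np.ndarray:
        if str(channel) == "470":
            return self.F470
        if str(channel) == "410":
            return self.F410
        raise ValidationError(f"unknown channel {channel!r}")


@dataclass
class DffTrace:
    """Per-event dF/F matrix over a common peri-event window."""

    matrix: np.ndarray  # (n_events, n_timepoints)
    time_s: np.ndarray  # relative to the tag, -pre_s .. +post_s
    channel: str
    f0_per_event: np.ndarray
    tags_used: list[float]
    n_skipped: int = 0

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.matrix.shape[0]
        if n < 2:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.std(axis=0, ddof=1) / np.sqrt(n)


def _usable_tags(rec: PhotometryRecording, pre_s: float, post_s: float
                 ) -> tuple[list[float], int]:
    usable, skipped = [], 0
    for tag in rec.event_tags:
        if tag - rec.t0 < BASELINE_S or tag - pre_s < rec.t0:
            warnings.warn(f"tag at {tag}s lacks a full 2-min baseline; "
                          "skipped", stacklevel=3)
            skipped += 1
        elif tag + post_s > rec.t0 + rec.duration_s:
            warnings.warn(f"tag at {tag}s window exceeds recording end; "
                          "skipped", stacklevel=3)
            skipped += 1
        else:
            usable.append(tag)
    return usable, skipped


def baseline_f0(rec: PhotometryRecording, channel: int | str,
                tag: float) -> float:
    """Mean fluorescence over the 2 minutes before the tag."""
    f = rec.trace(channel)
    i0 = int(round((tag - BASELINE_S - rec.t0) * rec.fs))
    i1 = int(round((tag - rec.t0) * rec.fs))
    if i0 < 0:
        raise ValidationError(f"tag at {tag}s lacks a full 2-min baseline")
    return float(np.mean(f[i0:i1]))


def dff(rec: PhotometryRecording, channel: int | str = "470",
        pre_s: float = 2.0, post_s: float = 5.0) -> DffTrace:
    """Per-tag dF/F on the peri-event window [-pre_s, +post_s].

    For each usable tag, F0 is the channel mean over [tag - 120 s, tag)
    and the window trace is (F - F0)/F0.  Tags without a full baseline
    or with a window beyond the recording end are skipped with a
    warning and counted in ``n_skipped``.
    """
    usable, skipped = _usable_tags(rec, pre_s, post_s)
    if not usable:
        raise ValidationError("no usable event tags")
    f = rec.trace(channel)
    n_pre = int(round(pre_s * rec.fs))
    n_post = int(round(post_s * rec.fs))
    time = np.arange(-n_pre, n_post + 1) / rec.fs
    rows, f0s = [], []
    for tag in usable:
        f0 = baseline_f0(rec, channel, tag)
        i_tag = int(round((tag - rec.t0) * rec.fs))
        seg = f[i_tag - n_pre:i_tag + n_post + 1]
        rows.append((seg - f0) / f0)
        f0s.append(f0)
    return DffTrace(np.vstack(rows), time, str(channel),
                    np.asarray(f0s), usable, skipped)


def event_aligned(rec: PhotometryRecording, channel: int | str = "470",
                  pre_s: float = 2.0, post_s: float = 5.0) -> DffTrace:
    """Event-aligned dF/F matrix (rows = tags) with mean and SEM.

    The matrix itself is the heatmap export; row order follows tag
    order.
    """
    return dff(rec, channel, pre_s, post_s)


def auc(trace: DffTrace, from_s: float = 0.0, to_s: float = 5.0
        ) -> tuple[np.ndarray, float]:
    """Trapezoidal area under dF/F over [from_s, to_s], per event.

    Returns (per-event AUC values, their mean); units are dF/F * s.
    The window endpoints are interpolated onto the sample grid so AUC
    is exactly additive over adjacent windows.
    """
    t = trace.time_s
    if from_s >= to_s:
        raise ValidationError("empty AUC window")
    if from_s < t[0] - 1e-9 or to_s > t[-1] + 1e-9:
        raise ValidationError(
            f"AUC window [{from_s}, {to_s}] outside trace span "
            f"[{t[0]:.3g}, {t[-1]:.3g}]"
        )
    inner = (t > from_s) & (t < to_s)
    grid = np.concatenate(([from_s], t[inner], [to_s]))
    vals = np.empty(trace.matrix.shape[0])
    for i in range(trace.matrix.shape[0]):
        y = np.interp(grid, t, trace.matrix[i])
        vals[i] = np.trapezoid(y, grid)
    return vals, float(vals.mean())


def isosbestic_check(rec: PhotometryRecording, pre_s: float = 2.0,
                     post_s: float = 5.0) -> dict:
    """Compare the 470 and 410 dF/F and optionally motion-correct.

    Reports the per-event Pearson correlation between the two channels'
    dF/F windows and a motion-share estimate (fraction of 470 variance
    explained by the 410 regression fitted on the pre-event baseline
    samples of the window).  The corrected trace (470 dF/F minus the
    fitted linear transform of 410 dF/F) is included in the report; the
    raw per-channel dF/F remains the primary output.  A constant 410
    channel makes the regression degenerate; correction is then skipped
    and reported.
    """
    d470 = dff(rec, "470", pre_s, post_s)
    d410 = dff(rec, "410", pre_s, post_s)
    n_ev = d470.matrix.shape[0]
    corr = np.empty(n_ev)
    for i in range(n_ev):
        a, b = d470.matrix[i], d410.matrix[i]
        corr[i] = (np.corrcoef(a, b)[0, 1]
                   if a.std() > 0 and b.std() > 0 else np.nan)
    base = d470.time_s < 0
    x = d410.matrix[:, base].ravel()
    y = d470.matrix[:, base].ravel()
    finite = corr[np.isfinite(corr)]
    report: dict = {"per_event_correlation": corr,
                    "mean_correlation": (float(finite.mean())
                                         if finite.size else float("nan"))}
    if x.std() == 0:
        report["correction_skipped"] = "constant 410 channel"
        report["corrected"] = None
        report["motion_share"] = 0.0
        return report
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * d410.matrix + intercept
    corrected = d470.matrix - fitted
    var470 = float(np.var(y))
    resid = float(np.var(y - (slope * x + intercept)))
    report["motion_share"] = (1.0 - resid / var470) if var470 > 0 else 0.0
    report["corrected"] = DffTrace(corrected, d470.time_s, "470-corrected",
                                   d470.f0_per_event, d470.tags_used,
                                   d470.n_skipped)
    report["regression"] = {"slope": float(slope),
                            "intercept": float(intercept)}
    return report
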