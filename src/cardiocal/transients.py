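"""Calcium-transient detection and kinetic quantification.

Operates on Fura-2 ratio traces (or calibrated concentration traces): detects
spontaneous transients, reports beating frequency, and fits the falling phase
of each transient with a mono-exponential y(t) = A*exp(-t/tau) + C.  The rate
constant k = 1/tau of that fit is the total first-order cytosolic calcium
extrusion rate, which downstream decomposition splits into SERCA2, NCX, PMCA
and mitochondrial components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "RatioTrace",
    "TransientEvent",
    "DecayFit",
    "TraceError",
    "detect_transients",
    "beating_frequency",
    "fit_decay",
    "analyze_caffeine_transient",
    "estimate_noise_sd",
]


class TraceError(ValueError):
    """Invalid trace or missing annotation."""


@dataclass
class RatioTrace:
    """A sampled two-channel (or ratio-only) Fura-2 recording.

    ``annotations`` is a list of ``(time_s, event_kind)`` protocol events,
    e.g. ``(10.0, "caffeine_on")``.  ``values`` aliases whatever signal the
    kinetic analysis should run on: the ratio for an uncalibrated trace, or
    nM after conversion.
    """

    time: np.ndarray
    ratio: np.ndarray
    sample_rate: float
    f340: np.ndarray | None = None
    f380: np.ndarray | None = None
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.ratio.shape:
            raise TraceError("time and ratio must be 1-D arrays of equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise TraceError("time must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(dt[0])):
                raise TraceError("time grid must be uniform")
        if not np.all(np.isfinite(self.ratio)):
            raise TraceError("ratio contains non-finite values")

    @property
    def values(self) -> np.ndarray:
        return self.ratio

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    def calibrated(self, calib) -> "RatioTrace":
        """Return a copy whose signal is [Ca2+] in nM."""
        from .calibration import ratio_to_concentration

        conc = ratio_to_concentration(self.ratio, calib)
        return RatioTrace(
            time=self.time.copy(),
            ratio=np.asarray(conc, dtype=float),
            sample_rate=self.sample_rate,
            annotations=list(self.annotations),
        )

    def events_of_kind(self, kind: str) -> list[float]:
        return [t for t, k in self.annotations if k == kind]


@dataclass(frozen=True)
class TransientEvent:
    """One detected calcium transient."""

    peak_time: float
    peak_index: int
    baseline: float
    amplitude: float
    onset_time: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise TraceError("amplitude must be positive")
        if self.onset_time >= self.peak_time:
            raise TraceError("onset must precede the peak")


@dataclass(frozen=True)
class DecayFit:
    """Mono-exponential fit of a transient's falling phase.

    ``k`` is defined as ``1/tau`` and the identity is preserved exactly.
    Non-converged or refused fits carry ``converged=False`` and NaN
    parameters; summaries must exclude them.
    """

    tau: float
    k: float
    amplitude: float
    offset: float
    fit_window: tuple[float, float]
    rss: float
    n_points: int
    converged: bool
    reason: str = ""

    @classmethod
    def from_tau(cls, tau, amplitude, offset, window, rss, n) -> "DecayFit":
        return cls(
            tau=tau,
            k=1.0 / tau,
            amplitude=amplitude,
            offset=offset,
            fit_window=window,
            rss=rss,
            n_points=n,
            converged=True,
        )

    @classmethod
    def refused(cls, window, n, reason) -> "DecayFit":
        return cls(
            tau=float("nan"),
            k=float("nan"),
            amplitude=float("nan"),
            offset=float("nan"),
            fit_window=window,
            rss=float("nan"),
            n_points=n,
            converged=False,
            reason=reason,
        )


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from the median absolute successive difference.

    For white noise of SD sigma, successive differences have SD sigma*sqrt(2);
    the median makes the estimate insensitive to the sparse fast upstrokes of
    the transients themselves.
    """
    d = np.abs(np.diff(np.asarray(values, dtype=float)))
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def detect_transients(
    trace: RatioTrace,
    *,
    min_prominence: float = 4.0,
    refractory: float | None = None,
    expected_bpm: float = 100.0,
    baseline_fraction: float = 0.1,
) -> list[TransientEvent]:
    """Detect calcium transients as prominent peaks in the trace.

    ``min_prominence`` is a multiple of the robust baseline noise SD; the
    default refractory period is ``60 / (3 * expected_bpm)`` seconds, i.e. a
    third of the expected beat interval.  A flat trace yields an empty list.
    """
    if trace.duration < 2.0:
        raise TraceError("trace shorter than 2 s")
    y = trace.values
    fs = trace.sample_rate
    if refractory is None:
        refractory = 60.0 / (3.0 * expected_bpm)
    sigma = estimate_noise_sd(y)
    span = float(np.ptp(y))
    if span == 0.0:
        return []
    # floor the prominence so a noiseless synthetic trace still thresholds
    prominence = max(min_prominence * sigma, 1e-3 * span)
    distance = max(1, int(round(refractory * fs)))
    peaks, _props = find_peaks(y, prominence=prominence, distance=distance)

    events: list[TransientEvent] = []
    prev_peak = 0
    for p in peaks:
        seg = y[prev_peak : p + 1]
        baseline = float(np.percentile(seg, 10)) if seg.size else float(y[p])
        amplitude = float(y[p] - baseline)
        if amplitude <= 0:
            prev_peak = p
            continue
        # onset: last sample before the peak at or below baseline + 10% amp
        thresh = baseline + baseline_fraction * amplitude
        below = np.nonzero(seg <= thresh)[0]
        onset_idx = prev_peak + (int(below[-1]) if below.size else 0)
        if onset_idx >= p:
            onset_idx = max(p - 1, 0)
        events.append(
            TransientEvent(
                peak_time=float(trace.time[p]),
                peak_index=int(p),
                baseline=baseline,
                amplitude=amplitude,
                onset_time=float(trace.time[onset_idx]),
            )
        )
        prev_peak = p
    return events


def beating_frequency(events: list[TransientEvent], duration: float) -> float:
    """Beats per minute: 60 * count / duration."""
    if duration <= 0:
        raise TraceError("duration must be positive")
    return 60.0 * len(events) / duration


def _mono_exp(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def fit_decay(
    trace: RatioTrace,
    event: TransientEvent,
    *,
    start_fraction: float = 0.9,
    end_fraction: float = 0.05,
    next_onset: float | None = None,
    min_points: int = 5,
    sigma: np.ndarray | None = None,
) -> DecayFit:
    """Fit the falling phase of one transient with A*exp(-t/tau) + C.

    The fit window opens at the first sample strictly after the peak at or
    below ``baseline + start_fraction * amplitude`` and closes at
    ``baseline + end_fraction * amplitude``, at ``next_onset``, or at the end
    of the trace, whichever comes first.  The peak sample itself is always
    excluded: on a noisy trace the detected peak is the maximum of noisy
    samples and is biased high, which would steepen the fitted decay.  The
    closing crossing is located on a 5-sample running median so a single
    noise excursion cannot truncate the window.  The offset C is free:
    blocker protocols shift the baseline.

    ``sigma`` (full-trace-aligned per-sample noise SDs, e.g. from
    :func:`~cardiocal.calibration.concentration_noise_scale`) switches the
    fit to weighted least squares, which matters for calibrated traces whose
    noise grows toward dye saturation.  Fits whose time constant exceeds 50
    times the window span are flagged as unidentifiable.
    """
    from scipy.ndimage import median_filter

    y = trace.values
    t = trace.time
    p = event.peak_index
    start_level = event.baseline + start_fraction * event.amplitude
    end_level = event.baseline + end_fraction * event.amplitude
    y_smooth = median_filter(y, size=5, mode="nearest") if y.size >= 5 else y

    i0 = p + 1
    while i0 < y.size and y[i0] > start_level:
        i0 += 1
    i1 = i0
    t_stop = next_onset if next_onset is not None else np.inf
    while i1 < y.size and y_smooth[i1] > end_level and t[i1] < t_stop:
        i1 += 1
    window = (float(t[min(i0, y.size - 1)]), float(t[min(i1, y.size - 1)]))
    n = i1 - i0
    if n < min_points:
        return DecayFit.refused(window, n, f"only {n} samples in decay window")

    tt = t[i0:i1] - t[i0]
    yy = y[i0:i1]
    ss = np.asarray(sigma, dtype=float)[i0:i1] if sigma is not None else None
    a0 = max(yy[0] - yy[-1], 1e-12)
    tau0 = max(tt[-1] / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(
            _mono_exp,
            tt,
            yy,
            p0=(a0, tau0, yy[-1]),
            sigma=ss,
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return DecayFit.refused(window, n, "fit did not converge")
    a_fit, tau_fit, c_fit = (float(v) for v in popt)
    span = float(tt[-1]) if tt[-1] > 0 else float("inf")
    if tau_fit > 50.0 * span:
        return DecayFit.refused(window, n, "tau unidentifiable within window")
    rss = float(np.sum((yy - _mono_exp(tt, *popt)) ** 2))
    return DecayFit.from_tau(tau_fit, a_fit, c_fit, window, rss, n)


def fit_shared_decay(
    trace: RatioTrace,
    events: list[TransientEvent],
    *,
    sigma: np.ndarray | None = None,
    start_offset: int = 1,
    end_offset: int = 2,
    min_seg_points: int = 4,
    tau_bounds: tuple[float, float] = (0.02, 30.0),
) -> DecayFit:
    """Joint mono-exponential fit of many transient decays with a shared tau.

    Each inter-event decay segment (from ``start_offset`` samples after its
    peak to ``end_offset`` samples before the next peak) gets its own free
    amplitude, while the time constant and the offset are shared across the
    trace.  For a given tau the model is linear in the amplitudes and
    offset, so tau is profiled by 1-D bounded minimization of the (weighted)
    residual sum of squares.  This pools the information of all twitches of
    a trace, which is what makes the estimate stable when individual decay
    windows are only a handful of samples long (fast beating at limited
    frame rates).
    """
    from scipy.optimize import minimize_scalar

    y = trace.values
    t = trace.time
    segs: list[tuple[int, int]] = []
    for ev, nxt in zip(events, events[1:] + [None]):
        i0 = ev.peak_index + start_offset
        i1 = (nxt.peak_index - end_offset) if nxt is not None else y.size
        if i1 - i0 >= min_seg_points:
            segs.append((i0, i1))
    if not segs:
        return DecayFit.refused((float(t[0]), float(t[-1])), 0, "no usable decay segments")

    rows = sum(i1 - i0 for i0, i1 in segs)
    weights = np.ones(rows)
    yy = np.empty(rows)
    r = 0
    for i0, i1 in segs:
        n = i1 - i0
        yy[r : r + n] = y[i0:i1]
        if sigma is not None:
            weights[r : r + n] = 1.0 / np.asarray(sigma, dtype=float)[i0:i1]
        r += n

    def _design(tau: float) -> np.ndarray:
        x = np.zeros((rows, len(segs) + 1))
        r = 0
        for k, (i0, i1) in enumerate(segs):
            n = i1 - i0
            x[r : r + n, k] = np.exp(-(t[i0:i1] - t[i0]) / tau)
            r += n
        x[:, -1] = 1.0
        return x

    def _sse(log_tau: float) -> float:
        x = _design(float(np.exp(log_tau))) * weights[:, None]
        coef, *_ = np.linalg.lstsq(x, yy * weights, rcond=None)
        return float(np.sum((x @ coef - yy * weights) ** 2))

    res = minimize_scalar(
        _sse, bounds=(np.log(tau_bounds[0]), np.log(tau_bounds[1])), method="bounded"
    )
    tau = float(np.exp(res.x))
    x = _design(tau) * weights[:, None]
    coef, *_ = np.linalg.lstsq(x, yy * weights, rcond=None)
    window = (float(t[segs[0][0]]), float(t[segs[-1][1] - 1]))
    return DecayFit.from_tau(
        tau,
        amplitude=float(np.mean(coef[:-1])),
        offset=float(coef[-1]),
        window=window,
        rss=float(res.fun),
        n=rows,
    )


def analyze_caffeine_transient(
    trace: RatioTrace,
    *,
    baseline_window_s: float = 5.0,
    peak_search_s: float = 15.0,
    sigma: np.ndarray | None = None,
) -> tuple[float, DecayFit]:
    """Amplitude and decay fit of the caffeine-induced transient.

    The amplitude (caffeine peak minus the pre-caffeine plateau) is a proxy
    for the sarcoplasmic-reticulum calcium content; the decay rate excludes
    SERCA recycling because continuous caffeine keeps the SR empty.  The
    decay is fitted over the full window from the peak to washout or the
    end of the trace — caffeine transients relax to a steady plateau that
    the fit offset absorbs, and the long tail is what pins the slow time
    constant.
    """
    caff = trace.events_of_kind("caffeine_on")
    if not caff:
        raise TraceError("trace has no caffeine_on annotation")
    t_caff = caff[0]
    t = trace.time
    y = trace.values
    if t_caff <= t[0] or t_caff >= t[-1]:
        raise TraceError("caffeine event outside the recorded window")

    pre = (t >= t_caff - baseline_window_s) & (t < t_caff)
    if not np.any(pre):
        raise TraceError("no pre-caffeine baseline available")
    # diastolic level: low percentile, insensitive to ongoing twitches
    baseline = float(np.percentile(y[pre], 10))

    search = (t >= t_caff) & (t <= t_caff + peak_search_s)
    idx = np.nonzero(search)[0]
    p = int(idx[np.argmax(y[idx])])
    amplitude = float(y[p] - baseline)
    if amplitude <= 0:
        raise TraceError("no caffeine transient above baseline")

    event = TransientEvent(
        peak_time=float(t[p]),
        peak_index=p,
        baseline=baseline,
        amplitude=amplitude,
        onset_time=float(t_caff) if t_caff < t[p] else float(t[max(p - 1, 0)]),
    )
    washouts = [tw for tw in trace.events_of_kind("washout") if tw > t[p]]
    next_onset = washouts[0] if washouts else None
    fit = fit_decay(
        trace, event, next_onset=next_onset, sigma=sigma, end_fraction=-np.inf
    )
    return amplitude, fit
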