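"""Ratiometric Fura-2 calcium calibration.

Converts the 340/380 nm excitation ratio R to cytosolic free calcium via the
two-point ionomycin calibration

    [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R)

where Rmin and Rmax are the ratios at zero and saturating calcium (measured
with EGTA and a high-calcium/ionomycin solution respectively), beta is the
ratio of the 380 nm signals of the free and bound dye, and Kd is the
Fura-2/calcium dissociation constant (225 nM at room temperature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FURA2_KD_NM",
    "CalibrationParams",
    "CalibrationError",
    "SaturationError",
    "ratio_to_concentration",
    "concentration_to_ratio",
    "estimate_calibration",
    "plateau_statistic",
]

#: Fura-2/Ca2+ dissociation constant (nM) used throughout the pipeline.
FURA2_KD_NM = 225.0


class CalibrationError(ValueError):
    """Invalid calibration parameters or calibration input."""


class SaturationError(CalibrationError):
    """A ratio at or above Rmax cannot be inverted to a finite concentration."""


@dataclass(frozen=True)
class CalibrationParams:
    """Two-point Fura-2 calibration constants.

    Attributes
    ----------
    r_min, r_max:
        Ratios at zero and saturating calcium.
    beta:
        Sf380/Sb380 scaling factor (380 nm signal of free over bound dye).
        Defaults to 1, the value assumed when raw channels are unavailable.
    kd:
        Fura-2/calcium dissociation constant in nM.
    flagged:
        Set by :func:`estimate_calibration` when a calibration plateau was
        not flat within tolerance; the parameters remain usable.
    """

    r_min: float
    r_max: float
    beta: float = 1.0
    kd: float = FURA2_KD_NM
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise CalibrationError(
                f"require r_max > r_min > 0, got r_min={self.r_min}, r_max={self.r_max}"
            )
        if self.beta <= 0 or self.kd <= 0:
            raise CalibrationError("beta and kd must be positive")


def ratio_to_concentration(
    r: float | np.ndarray, calib: CalibrationParams
) -> float | np.ndarray:
    """Convert Fura-2 ratio(s) to free calcium in nM.

    Ratios below ``r_min`` (noise below the zero-calcium floor) are clipped to
    0 nM with a warning; ratios at or above ``r_max`` raise
    :class:`SaturationError` because the equation diverges there.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr >= calib.r_max):
        raise SaturationError(
            "ratio at or above r_max: signal saturated, concentration undefined"
        )
    below = r_arr < calib.r_min
    if np.any(below):
        warnings.warn(
            "ratio below r_min clipped to 0 nM (noise below calibration floor)",
            RuntimeWarning,
            stacklevel=2,
        )
    c = calib.kd * calib.beta * (r_arr - calib.r_min) / (calib.r_max - r_arr)
    c = np.where(below, 0.0, c)
    return float(c) if np.isscalar(r) else c


def concentration_to_ratio(
    c: float | np.ndarray, calib: CalibrationParams
) -> float | np.ndarray:
    """Exact inverse of :func:`ratio_to_concentration` for c >= 0."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise CalibrationError("concentration must be >= 0")
    kb = calib.kd * calib.beta
    r = (calib.r_min * kb + calib.r_max * c_arr) / (kb + c_arr)
    return float(r) if np.isscalar(c) else r


def plateau_statistic(values: np.ndarray) -> float:
    """Robust plateau level: median of the final half of the segment.

    The first half of a calibration segment contains the approach transient
    after solution exchange, so it is discarded.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise CalibrationError("empty segment")
    return float(np.median(values[values.size // 2 :]))


def _segment_slice(time: np.ndarray, start: float, end: float) -> slice:
    i0 = int(np.searchsorted(time, start, side="left"))
    i1 = int(np.searchsorted(time, end, side="right"))
    return slice(i0, i1)


def estimate_calibration(
    trace,
    *,
    kd: float = FURA2_KD_NM,
    min_segment_s: float = 5.0,
    slope_tol_per_s: float = 0.01,
) -> CalibrationParams:
    """Estimate Rmin/Rmax (and beta when channels are present) from a
    calibration recording.

    The trace must be annotated with ``egta_on`` and ``high_ca_on`` events;
    each segment runs from its event to the next annotation or the end of the
    recording and must span at least ``min_segment_s`` seconds.  Rmin/Rmax are
    the plateau statistics of the two segments.  When per-channel 380 nm
    signals are available beta = F380(EGTA plateau) / F380(high-Ca plateau);
    otherwise beta defaults to 1.

    A residual slope in the plateau window larger than ``slope_tol_per_s``
    (ratio units per second) marks the estimate as flagged rather than
    rejecting it.
    """
    events = sorted(trace.annotations, key=lambda e: e[0])
    t_end = float(trace.time[-1])
    windows: dict[str, tuple[float, float]] = {}
    for idx, (t, kind) in enumerate(events):
        nxt = events[idx + 1][0] if idx + 1 < len(events) else t_end
        windows[kind] = (t, nxt)
    for needed in ("egta_on", "high_ca_on"):
        if needed not in windows:
            raise CalibrationError(f"missing calibration segment annotation {needed!r}")
        t0, t1 = windows[needed]
        if t1 - t0 < min_segment_s:
            raise CalibrationError(
                f"calibration segment {needed!r} shorter than {min_segment_s} s"
            )

    flagged = False
    levels: dict[str, float] = {}
    f380_levels: dict[str, float] = {}
    for kind in ("egta_on", "high_ca_on"):
        sl = _segment_slice(trace.time, *windows[kind])
        seg_t = trace.time[sl]
        seg_r = trace.ratio[sl]
        half = seg_r.size // 2
        levels[kind] = plateau_statistic(seg_r)
        # flatness check on the plateau half
        slope = float(np.polyfit(seg_t[half:], seg_r[half:], 1)[0])
        if abs(slope) > slope_tol_per_s:
            flagged = True
        if getattr(trace, "f380", None) is not None:
            f380_levels[kind] = plateau_statistic(trace.f380[sl])

    beta = 1.0
    if f380_levels:
        beta = f380_levels["egta_on"] / f380_levels["high_ca_on"]
    return CalibrationParams(
        r_min=levels["egta_on"],
        r_max=levels["high_ca_on"],
        beta=beta,
        kd=kd,
        flagged=flagged,
    )


def concentration_noise_scale(
    c: np.ndarray, calib: CalibrationParams
) -> np.ndarray:
    """Relative noise SD of calibrated concentrations, up to a constant.

    Additive channel noise of fixed SD maps to ratio noise growing like
    sqrt(1 + R²) and is then amplified by dC/dR = Kd·beta·(Rmax−Rmin)/(Rmax−R)²,
    which diverges toward saturation.  The returned array is proportional to
    the per-sample concentration SD and serves as weights for least-squares
    fits on calibrated traces.
    """
    c_arr = np.clip(np.asarray(c, dtype=float), 0.0, None)
    r = concentration_to_ratio(c_arr, calib)
    dcdr = calib.kd * calib.beta * (calib.r_max - calib.r_min) / (calib.r_max - r) ** 2
    return np.sqrt(1.0 + r**2) * dcdr


def with_kd(calib: CalibrationParams, kd: float) -> CalibrationParams:
    """Return a copy of ``calib`` with a different dissociation constant."""
    return replace(calib, kd=kd)
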