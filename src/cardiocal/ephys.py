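"""Whole-cell voltage-clamp analysis.

Membrane capacitance from the integral of the capacitive current transient
(Q = Cm·ΔV), input resistance from steady-state passive responses to
±10 mV/20 ms pulses, P/N-style passive subtraction using a scaled -20 mV
pulse, and I/V extraction with peak inward current density in pA/pF.

Units follow patch-clamp convention: current pA, voltage mV, time s,
capacitance pF, resistance MOhm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_data.vclamp import VoltageClampRecording

__all__ = [
    "PassiveProperties",
    "IVResult",
    "EphysError",
    "estimate_capacitance",
    "estimate_input_resistance",
    "estimate_series_resistance",
    "passive_properties",
    "leak_subtract",
    "iv_and_density",
    "MAX_SERIES_RESISTANCE",
]

#: Quality gate: recordings with higher estimated series resistance are
#: rejected from group analysis.
MAX_SERIES_RESISTANCE = 20.0  # MOhm


class EphysError(ValueError):
    """Invalid recording or analysis input."""


@dataclass(frozen=True)
class PassiveProperties:
    """Passive membrane properties of one recording."""

    cm: float  # pF
    rin: float  # MOhm
    rs: float  # MOhm
    flagged: bool = False
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return self.rs < MAX_SERIES_RESISTANCE and not self.flagged


@dataclass(frozen=True)
class IVResult:
    """Leak-subtracted current/voltage relationship."""

    voltages: np.ndarray  # mV
    peak_currents: np.ndarray  # pA (signed; inward negative)
    densities: np.ndarray  # pA/pF
    cm_used: float
    peak_density: float  # most-negative density
    v_peak: float  # command voltage of maximal inward current


def _window(time: np.ndarray, start: float, end: float) -> np.ndarray:
    return (time >= start) & (time < end)


def _exp_decay(t, a, tau):
    return a * np.exp(-t / tau)


def estimate_capacitance(
    time: np.ndarray,
    current: np.ndarray,
    *,
    pulse_start: float,
    pulse_dur: float,
    dv: float,
    divider_correction: float = 1.0,
) -> tuple[float, bool]:
    """Capacitance (pF) from one passive pulse: Cm = Q / ΔV.

    The steady-state (leak) current — the mean over the final quarter of the
    pulse — is subtracted, the remaining transient is fit with a single
    exponential, and the charge is the trapezoidal integral from the pulse
    onset to five fitted time constants plus the analytic tail of the fit.
    ``divider_correction`` compensates the attenuation of the capacitive
    charge by the series-resistance/input-resistance divider (the measured
    charge is Cm·ΔV·(Rin/(Rin+Rs))²); :func:`passive_properties` supplies it
    from the recording's own Rs and Rin estimates.  Returns ``(cm_pF,
    flagged)``; the flag is set when the transient has not settled within
    the integration window.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if dv == 0:
        raise EphysError("zero stimulation voltage")
    pre = _window(time, time[0], pulse_start)
    pulse = _window(time, pulse_start, pulse_start + pulse_dur)
    if not np.any(pre) or not np.any(pulse):
        raise EphysError("pulse window outside the trace")
    baseline = float(np.mean(current[pre]))
    t_p = time[pulse]
    i_p = current[pulse] - baseline
    n_ss = max(1, i_p.size // 4)
    i_ss = float(np.mean(i_p[-n_ss:]))
    transient = i_p - i_ss
    tt = t_p - t_p[0]

    peak = transient[0]
    if abs(peak) < 1e-12:
        return 0.0, False
    # initial tau guess: first crossing below peak/e
    below = np.nonzero(np.abs(transient) < np.abs(peak) / np.e)[0]
    tau0 = tt[below[0]] if below.size else tt[-1] / 5.0
    tau0 = max(tau0, tt[1] if tt.size > 1 else 1e-5)
    try:
        popt, _ = curve_fit(_exp_decay, tt, transient, p0=(peak, tau0), maxfev=10000)
        a_fit, tau = float(popt[0]), abs(float(popt[1]))
    except (RuntimeError, ValueError):
        a_fit, tau = float(peak), float(tau0)

    t_end = 5.0 * tau
    flagged = t_end > tt[-1]
    in_win = tt <= t_end
    q = float(np.trapezoid(transient[in_win], tt[in_win]))
    # analytic tail of the fitted exponential beyond the integration window
    q += a_fit * tau * np.exp(-min(t_end, tt[-1]) / tau)
    cm = 1000.0 * q / dv * divider_correction  # pA*s/mV -> pF
    return float(cm), bool(flagged)


def estimate_input_resistance(rec: VoltageClampRecording) -> float:
    """Input resistance (MOhm) from the ±10 mV passive steady states.

    The steady-state current change is read in the final quarter of each
    pulse and the two estimates ΔV/ΔI are averaged.
    """
    rins = []
    for sweep, dv in ((rec.passive_plus, rec.passive_dv), (rec.passive_minus, -rec.passive_dv)):
        t = rec.passive_time
        pre = _window(t, t[0], rec.passive_pulse_start)
        pulse = _window(
            t,
            rec.passive_pulse_start + 0.75 * rec.passive_pulse_dur,
            rec.passive_pulse_start + rec.passive_pulse_dur,
        )
        d_i = float(np.mean(sweep[pulse]) - np.mean(sweep[pre]))
        if d_i == 0:
            raise EphysError("zero steady-state current change: open circuit?")
        rins.append(1000.0 * dv / d_i)  # mV/pA -> GOhm; x1000 -> MOhm
    return float(np.mean(rins))


def estimate_series_resistance(rec: VoltageClampRecording) -> float:
    """Series resistance (MOhm) from the peak of the capacitive transient,
    rs ≈ ΔV / I_peak (the instantaneous current sees only rs)."""
    t = rec.passive_time
    pre = _window(t, t[0], rec.passive_pulse_start)
    pulse = _window(t, rec.passive_pulse_start, rec.passive_pulse_start + rec.passive_pulse_dur)
    baseline = float(np.mean(rec.passive_plus[pre]))
    i_peak = float(np.max(np.abs(rec.passive_plus[pulse] - baseline)))
    if i_peak == 0:
        raise EphysError("no capacitive transient")
    return 1000.0 * rec.passive_dv / i_peak


def passive_properties(rec: VoltageClampRecording) -> PassiveProperties:
    """Capacitance (mean over the ± pulses), input resistance and series
    resistance of one recording, with the rs < 20 MOhm acceptance gate."""
    rin = estimate_input_resistance(rec)
    rs = estimate_series_resistance(rec)
    # the ΔV/ΔIss estimate measures Rs + Rin in series; the charge divider
    # correction needs the membrane Rin alone
    rin_mem = max(rin - rs, 0.25 * rin)
    correction = ((rin_mem + rs) / rin_mem) ** 2
    cms, flags = [], []
    for sweep, dv in ((rec.passive_plus, rec.passive_dv), (rec.passive_minus, -rec.passive_dv)):
        cm, flagged = estimate_capacitance(
            rec.passive_time,
            sweep,
            pulse_start=rec.passive_pulse_start,
            pulse_dur=rec.passive_pulse_dur,
            dv=dv,
            divider_correction=correction,
        )
        cms.append(cm)
        flags.append(flagged)
    return PassiveProperties(
        cm=float(np.mean(cms)),
        rin=rin,
        rs=rs,
        flagged=any(flags),
        reason="capacitive transient not settled" if any(flags) else "",
    )


def leak_subtract(rec: VoltageClampRecording) -> dict:
    """Scaled passive subtraction of every step sweep.

    For a step of ΔV from holding, the passive (capacitive + leak) response
    of the -20 mV subtraction pulse is scaled by ΔV / (-20) and subtracted.
    Returns a dict command voltage -> corrected current (pA); on a purely
    passive cell every corrected sweep is ~0.
    """
    if rec.subtraction is None:
        raise EphysError("recording has no subtraction pulse")
    pre = _window(rec.time, rec.time[0], rec.pulse_start)
    sub_base = float(np.mean(rec.subtraction[pre]))
    sub_resp = rec.subtraction - sub_base
    corrected = {}
    for v, sweep in rec.sweeps.items():
        dv = v - rec.holding
        base = float(np.mean(sweep[pre]))
        corrected[v] = sweep - base - (dv / rec.subtraction_dv) * sub_resp
    return corrected


def iv_and_density(
    corrected: dict,
    cm: float,
    *,
    time: np.ndarray,
    pulse_start: float,
    window: tuple[float, float] = (0.5e-3, 20e-3),
) -> IVResult:
    """Peak inward current per sweep and its density.

    The peak is the minimum of the corrected current in the activation
    window (0.5-20 ms after step onset by default, excluding any residual
    capacitive spike); density = peak / Cm.
    """
    if cm is None or not np.isfinite(cm) or cm <= 0:
        raise EphysError("valid membrane capacitance required for densities")
    sel = _window(time, pulse_start + window[0], pulse_start + window[1])
    if not np.any(sel):
        raise EphysError("activation window outside the sweep")
    voltages = np.array(sorted(corrected))
    peaks = np.array([float(np.min(corrected[v][sel])) for v in voltages])
    densities = peaks / cm
    i_min = int(np.argmin(peaks))
    return IVResult(
        voltages=voltages,
        peak_currents=peaks,
        densities=densities,
        cm_used=float(cm),
        peak_density=float(densities[i_min]),
        v_peak=float(voltages[i_min]),
    )
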