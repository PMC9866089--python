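"""Forward model for cytosolic calcium traces and their Fura-2 encoding.

The cell is a single well-mixed compartment.  Between beats the free calcium
obeys first-order relaxation

    dc/dt = J_leak - k_eff * (c - c_dia)

where ``k_eff`` is the sum of the extrusion rate constants active under the
current pharmacological state (SERCA2 + NCX + PMCA + mitochondria by
default).  Each spontaneous beat adds ``release_amplitude`` nM instantly.
Protocol events modify the state:

- ``caffeine_on``    — dumps the full SR content into the cytosol, nulls the
  SERCA2 contribution (continuous release defeats net SR re-uptake) and
  stops the spontaneous beat clock;
- ``na_ca_free_on``  — nulls the NCX contribution;
- ``tetracaine_on``  — nulls the SR leak flux;
- ``uncoupler_on``   — nulls the mitochondrial contribution;
- ``washout``        — restores all of the above and resumes beating.

This is deliberately the same model class as the downstream analysis (a sum
of parallel first-order extrusion pathways), so decomposition recovery is a
well-posed test of the measurement chain, not of a biophysical SR model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..calibration import CalibrationParams, concentration_to_ratio

__all__ = [
    "SimulationParams",
    "ProtocolSchedule",
    "ConcentrationTrace",
    "simulate_concentration_trace",
    "fura2_forward",
    "generate_calibration_trace",
]

_EVENT_KINDS = {"caffeine_on", "na_ca_free_on", "tetracaine_on", "uncoupler_on", "washout"}

#: Sampling rates used for the two acquisition modes: fast (kinetics of
#: spontaneous transients) and slow (long blocker protocols, reduced
#: photobleaching).
KINETICS_FPS = 23.0
BLOCKER_FPS = 6.6


@dataclass(frozen=True)
class SimulationParams:
    """Generator parameters for one simulated cardiomyocyte.

    Rate constants are first-order extrusion rates in 1/s; concentrations in
    nM.  Defaults describe a wild-type-like cell: total systolic extrusion
    rate 2.0 /s split 90 / 5 / 2.5 / 2.5 % between SERCA2, NCX, PMCA and
    mitochondria, diastolic calcium 125 nM and systolic peaks in the
    350-450 nM range.
    """

    c_dia: float = 125.0
    beat_rate: float = 59.0
    beat_jitter: float = 0.06
    release_amplitude: float = 300.0
    sr_content: float = 400.0
    leak_rate: float = 5.0
    k_serca: float = 1.8
    k_ncx: float = 0.10
    k_pmca: float = 0.05
    k_mito: float = 0.05
    channel_noise_sd: float = 0.0
    sample_rate: float = KINETICS_FPS
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_serca", "k_ncx", "k_pmca", "k_mito"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        if self.beat_rate < 0 or self.release_amplitude < 0:
            raise ValueError("beat_rate and release_amplitude must be >= 0")
        if self.beat_jitter < 0 or self.sr_content < 0 or self.leak_rate < 0:
            raise ValueError("beat_jitter, sr_content and leak_rate must be >= 0")

    @property
    def k_sys(self) -> float:
        """Total extrusion rate with all pathways active (1/s)."""
        return self.k_serca + self.k_ncx + self.k_pmca + self.k_mito

    @classmethod
    def wild_type(cls, **overrides) -> "SimulationParams":
        """Wild-type study conditions: 59 bpm, k_sys 2.0 /s at 90/5/2.5/2.5 %."""
        return cls(**overrides)

    @classmethod
    def car_knockout(cls, **overrides) -> "SimulationParams":
        """CAR-knockout study conditions: 96 bpm, faster extrusion
        (k_sys 3.0 /s) with the NCX share raised to 7 %."""
        defaults = dict(
            beat_rate=96.0,
            beat_jitter=0.04,
            k_serca=2.67,
            k_ncx=0.21,
            k_pmca=0.06,
            k_mito=0.06,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered pharmacological events applied during a recording."""

    events: tuple[tuple[float, str], ...] = ()
    baseline_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple((float(t), str(k)) for t, k in self.events))
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for t, kind in self.events:
            if kind not in _EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")
            if t < 0:
                raise ValueError("event times must be >= 0")

    def validate_against(self, duration: float) -> None:
        for t, kind in self.events:
            if t > duration:
                raise ValueError(f"event {kind!r} at {t} s outside duration {duration} s")


@dataclass
class ConcentrationTrace:
    """Noise-free calcium concentration trace plus its ground-truth manifest."""

    time: np.ndarray
    conc: np.ndarray
    sample_rate: float
    beat_times: np.ndarray
    annotations: list[tuple[float, str]]
    params: SimulationParams

    @property
    def values(self) -> np.ndarray:
        return self.conc


def _beat_times(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Spontaneous beat clock: normally-jittered inter-beat intervals."""
    if params.beat_rate <= 0:
        return np.empty(0)
    mean_ibi = 60.0 / params.beat_rate
    times = []
    t = 0.0
    while True:
        ibi = mean_ibi + (rng.normal(0.0, params.beat_jitter) if params.beat_jitter > 0 else 0.0)
        ibi = max(ibi, 0.1 * mean_ibi)
        t += ibi
        if t > params.duration:
            break
        times.append(t)
    return np.asarray(times)


def simulate_concentration_trace(
    params: SimulationParams,
    protocol: ProtocolSchedule | None = None,
    *,
    oversample: int = 10,
) -> ConcentrationTrace:
    """Integrate the single-compartment model and sample it at
    ``params.sample_rate``.

    Integration is a fixed-step explicit scheme on a grid ``oversample`` times
    the sampling rate; within each step the linear ODE is advanced with its
    exact exponential update, so the sampled decay of a noiseless transient is
    mono-exponential to machine precision.  Beat and protocol event times are
    snapped to the integration grid.  Deterministic given ``params.seed``.
    """
    protocol = protocol or ProtocolSchedule()
    protocol.validate_against(params.duration)
    rng = np.random.default_rng(params.seed)

    dt = 1.0 / (oversample * params.sample_rate)
    n_sub = int(round(params.duration * params.sample_rate)) * oversample + 1

    beats = _beat_times(params, rng)
    # suppress beats while caffeine is active
    caff_windows = []
    t_on = None
    for t, kind in protocol.events:
        if kind == "caffeine_on" and t_on is None:
            t_on = t
        elif kind == "washout" and t_on is not None:
            caff_windows.append((t_on, t))
            t_on = None
    if t_on is not None:
        caff_windows.append((t_on, params.duration))
    if caff_windows:
        keep = np.ones(beats.size, dtype=bool)
        for a, b in caff_windows:
            keep &= ~((beats >= a) & (beats < b))
        beats = beats[keep]

    # impulse (instant concentration jumps) and state-toggle schedules on grid
    release = np.zeros(n_sub)
    for tb in beats:
        release[min(int(round(tb / dt)), n_sub - 1)] += params.release_amplitude
    toggles: dict[int, list[str]] = {}
    for t, kind in protocol.events:
        toggles.setdefault(min(int(round(t / dt)), n_sub - 1), []).append(kind)

    serca_on = ncx_on = mito_on = leak_on = True
    c = params.c_dia + (params.leak_rate / params.k_sys if params.k_sys > 0 else 0.0)
    conc = np.empty(n_sub)

    for i in range(n_sub):
        for kind in toggles.get(i, ()):
            if kind == "caffeine_on":
                serca_on = False
                c += params.sr_content
            elif kind == "na_ca_free_on":
                ncx_on = False
            elif kind == "tetracaine_on":
                leak_on = False
            elif kind == "uncoupler_on":
                mito_on = False
            elif kind == "washout":
                serca_on = ncx_on = mito_on = leak_on = True
        c += release[i]
        conc[i] = c
        k_eff = (
            (params.k_serca if serca_on else 0.0)
            + (params.k_ncx if ncx_on else 0.0)
            + params.k_pmca
            + (params.k_mito if mito_on else 0.0)
        )
        j_leak = params.leak_rate if leak_on else 0.0
        if k_eff > 0:
            c_inf = params.c_dia + j_leak / k_eff
            c = c_inf + (c - c_inf) * math.exp(-k_eff * dt)
        else:
            c = c + j_leak * dt

    time = np.arange(0, n_sub, oversample) * dt
    return ConcentrationTrace(
        time=time,
        conc=conc[::oversample].copy(),
        sample_rate=params.sample_rate,
        beat_times=beats,
        annotations=list(protocol.events),
        params=params,
    )


def fura2_forward(
    conc_trace: ConcentrationTrace,
    calib: CalibrationParams,
    *,
    noise_sd: float | None = None,
    f380_scale: float = 1000.0,
    seed: int | None = None,
):
    """Encode a concentration trace as noisy Fura-2 340/380 channel signals.

    The channel model is the standard two-state dye mixture: with bound
    fraction ``x = c/(c + Kd)``, the 380 nm signal interpolates between the
    free-dye level ``f380_scale`` and the bound level ``f380_scale/beta``, and
    the 340 nm signal between ``r_min`` and ``r_max`` times those levels.  The
    noiseless ratio therefore inverts exactly through the calibration
    equation.  Independent Gaussian noise of SD ``noise_sd`` (absolute channel
    units; defaults to the generator's ``channel_noise_sd``) is added per
    channel before ratioing.
    """
    from ..transients import RatioTrace

    c = np.asarray(conc_trace.conc, dtype=float)
    if np.any(~np.isfinite(c)) or np.any(c < 0):
        raise ValueError("concentration must be finite and >= 0 (R >= Rmax is unreachable)")
    if noise_sd is None:
        noise_sd = conc_trace.params.channel_noise_sd
    if seed is None:
        seed = conc_trace.params.seed + 1

    x = c / (c + calib.kd)
    sf380, sb380 = f380_scale, f380_scale / calib.beta
    f380 = sf380 * (1.0 - x) + sb380 * x
    f340 = calib.r_min * sf380 * (1.0 - x) + calib.r_max * sb380 * x

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f340 = f340 + rng.normal(0.0, noise_sd, f340.shape)
        f380 = f380 + rng.normal(0.0, noise_sd, f380.shape)

    return RatioTrace(
        time=conc_trace.time.copy(),
        ratio=f340 / f380,
        sample_rate=conc_trace.sample_rate,
        f340=f340,
        f380=f380,
        annotations=list(conc_trace.annotations),
    )


def generate_calibration_trace(
    calib: CalibrationParams,
    *,
    c_rest: float = 125.0,
    segment_s: float = 20.0,
    approach_tau: float = 1.0,
    sample_rate: float = BLOCKER_FPS,
    noise_sd: float = 0.0,
    f380_scale: float = 1000.0,
    seed: int = 0,
):
    """Simulate an EGTA / high-calcium ionomycin calibration run.

    Three segments: resting plateau, zero-calcium (EGTA) plateau and
    saturating-calcium plateau.  The dye-bound fraction approaches each new
    state exponentially over the first 40 % of the segment and then sits
    exactly at the asymptote (EGTA strips all bound calcium, x = 0;
    ionomycin + 25 mM Ca saturates the dye, x = 1), so the plateau halves hit
    Rmin and Rmax exactly.  Returns an annotated
    :class:`~cardiocal.transients.RatioTrace` carrying ``egta_on`` and
    ``high_ca_on`` events for :func:`~cardiocal.calibration.estimate_calibration`.
    """
    from ..transients import RatioTrace

    duration = 3 * segment_s
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    t_egta, t_high = segment_s, 2 * segment_s
    settle = 0.4 * segment_s

    x_rest = c_rest / (c_rest + calib.kd)
    x = np.full(n, x_rest)
    seg = t >= t_egta
    decay = np.where(t[seg] - t_egta < settle, np.exp(-(t[seg] - t_egta) / approach_tau), 0.0)
    x[seg] = x_rest * decay
    seg = t >= t_high
    decay = np.where(t[seg] - t_high < settle, np.exp(-(t[seg] - t_high) / approach_tau), 0.0)
    x[seg] = 1.0 - decay

    sf380, sb380 = f380_scale, f380_scale / calib.beta
    f380 = sf380 * (1.0 - x) + sb380 * x
    f340 = calib.r_min * sf380 * (1.0 - x) + calib.r_max * sb380 * x
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f340 = f340 + rng.normal(0.0, noise_sd, n)
        f380 = f380 + rng.normal(0.0, noise_sd, n)

    return RatioTrace(
        time=t,
        ratio=f340 / f380,
        sample_rate=sample_rate,
        f340=f340,
        f380=f380,
        annotations=[(t_egta, "egta_on"), (t_high, "high_ca_on")],
    )
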