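"""Whole-cell voltage-clamp simulation with an HH-type m³h sodium current.

The pipette clamps the cell through a residual (post-compensation) series
resistance; the membrane carries a linear leak and a Hodgkin-Huxley-style
sodium conductance

    I_Na = g_Na_max * m³ h * (Vm - E_Na)

with first-order gates relaxing toward Boltzmann steady states.  The
measured signal is the pipette current (Vcmd - Vm)/Rs_eff, which contains
the capacitive charging transient, the ohmic leak and the active current —
exactly what the offline analysis (capacitance integration, leak
subtraction, I/V extraction) has to disentangle.

Units: mV, ms, pA, pF, MOhm, nS (so mV/MOhm = nA = 1000 pA and nS·mV = pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellParams",
    "StepProtocol",
    "VoltageClampRecording",
    "simulate_voltage_clamp",
    "calibrate_gna_for_peak_density",
]

_V_LIMITS = (-120.0, 80.0)


@dataclass(frozen=True)
class CellParams:
    """Ground-truth passive and active properties of a simulated cell.

    ``rs_compensation`` is the fraction of the series resistance cancelled
    by the amplifier during the step-protocol sweeps; capacitance test
    pulses are recorded with compensation off, as the capacitive transient
    is what the amplifier's compensation circuitry itself is tuned on.
    """

    cm_true: float = 51.9  # pF
    rs: float = 10.0  # MOhm
    rs_compensation: float = 0.0  # fraction of rs cancelled for step sweeps
    rin_true: float = 435.0  # MOhm
    g_na_max: float = 0.0  # nS
    reversal_na: float = 50.0  # mV
    e_leak: float = -90.0  # mV
    m_vhalf: float = -34.0
    m_slope: float = 5.5
    tau_m_ms: float = 0.3
    h_vhalf: float = -68.0
    h_slope: float = 6.0
    tau_h_ms: float = 1.5

    def __post_init__(self) -> None:
        if min(self.cm_true, self.rs, self.rin_true) <= 0:
            raise ValueError("cm_true, rs and rin_true must be positive")
        if self.g_na_max < 0:
            raise ValueError("g_na_max must be >= 0")
        if not (0.0 <= self.rs_compensation <= 0.99):
            raise ValueError("rs_compensation must be in [0, 0.99]")

    @property
    def rs_effective(self) -> float:
        return self.rs * (1.0 - self.rs_compensation)

    @classmethod
    def wild_type(cls, **overrides) -> "CellParams":
        """Wild-type-like cell: 51.9 pF, Rin 435.1 MOhm, 10 MOhm pipette.

        The step-protocol sweeps assume near-complete series-resistance
        compensation (98 %).  At the nanoampere-scale peak sodium currents
        of these cells (hundreds of pA/pF times ~50 pF), every megaohm of
        residual series resistance shifts the command potential by ~17 mV,
        so only a well-compensated recording clamps the membrane at all;
        the residual 0.2 MOhm keeps the voltage error below ~4 mV at peak.
        Set ``g_na_max`` via :func:`calibrate_gna_for_peak_density`.
        """
        defaults = dict(cm_true=51.9, rs=10.0, rs_compensation=0.98, rin_true=435.1)
        defaults.update(overrides)
        return cls(**defaults)

    def m_inf(self, v):
        return 1.0 / (1.0 + np.exp(-(v - self.m_vhalf) / self.m_slope))

    def h_inf(self, v):
        return 1.0 / (1.0 + np.exp((v - self.h_vhalf) / self.h_slope))


@dataclass(frozen=True)
class StepProtocol:
    """Depolarizing step family plus passive test and subtraction pulses."""

    holding: float = -90.0
    v_start: float = -90.0
    v_stop: float = 50.0
    v_step: float = 10.0
    pulse_ms: float = 200.0
    pre_ms: float = 20.0
    post_ms: float = 30.0
    passive_dv: float = 10.0  # ± test pulse amplitude, mV
    passive_ms: float = 20.0
    subtraction_dv: float = -20.0
    sample_rate: float = 10000.0  # Hz

    def __post_init__(self) -> None:
        lo, hi = _V_LIMITS
        for v in list(self.commands) + [
            self.holding,
            self.holding + self.passive_dv,
            self.holding - self.passive_dv,
            self.holding + self.subtraction_dv,
        ]:
            if not (lo <= v <= hi):
                raise ValueError(f"command {v} mV outside [{lo}, {hi}] mV")
        if self.sample_rate < 10000.0:
            raise ValueError("sampling must be at least 10 kHz")

    @property
    def commands(self) -> np.ndarray:
        n = int(round((self.v_stop - self.v_start) / self.v_step)) + 1
        return self.v_start + self.v_step * np.arange(n)


@dataclass
class VoltageClampRecording:
    """Simulated (or loaded) sweep family with protocol metadata.

    ``sweeps`` maps command voltage (mV) to the pipette current (pA) on the
    shared ``time`` grid; ``subtraction`` is the -20 mV full-length pulse;
    ``passive_plus``/``passive_minus`` are the ±10 mV/20 ms capacitance test
    pulses on ``passive_time``.  ``manifest`` carries generator ground truth.
    """

    time: np.ndarray  # s
    sweeps: dict
    subtraction: np.ndarray
    passive_time: np.ndarray
    passive_plus: np.ndarray
    passive_minus: np.ndarray
    holding: float
    sample_rate: float
    pulse_start: float  # s, step onset within `time`
    pulse_dur: float  # s
    passive_pulse_start: float
    passive_pulse_dur: float
    passive_dv: float
    subtraction_dv: float
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        volts = list(self.sweeps)
        if len(set(volts)) != len(volts):
            raise ValueError("command voltages must be unique")


def _integrate_sweeps(
    cell: CellParams,
    commands: np.ndarray,
    protocol_wave,
    t_total_ms: float,
    sample_rate: float,
    rs_eff: float,
    dt_ms: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fixed-step integration of all sweeps at once.

    ``protocol_wave(t_ms)`` returns the command offset (mV, relative to each
    sweep's step amplitude scale) — here simply 0/1 gating of the pulse.
    Gates and membrane voltage use exponential (exact-for-frozen-
    coefficients) updates, unconditionally stable at the sub-microsecond
    membrane time constants of a well-compensated cell.
    """
    n_sweeps = commands.size
    sample_dt_ms = 1000.0 / sample_rate
    n_out = int(round(t_total_ms / sample_dt_ms)) + 1
    steps_per_sample = max(1, int(round(sample_dt_ms / dt_ms)))
    dt = sample_dt_ms / steps_per_sample

    g_rs = 1000.0 / rs_eff  # pA/mV
    g_leak = 1000.0 / cell.rin_true

    # initial state: holding potential, gates at steady state
    vm = protocol_wave(-1.0, commands).astype(float).copy()
    m = cell.m_inf(vm)
    h = cell.h_inf(vm)

    out = np.empty((n_out, n_sweeps))
    for i_out in range(n_out):
        # substep times derived from integers: command edges land exactly on
        # their sample, so the onset sample carries the full transient peak
        t_ms = i_out * sample_dt_ms
        vcmd = protocol_wave(t_ms, commands)
        out[i_out] = g_rs * (vcmd - vm)
        for j in range(steps_per_sample):
            t_ms = i_out * sample_dt_ms + j * dt
            vcmd = protocol_wave(t_ms, commands)
            gna = cell.g_na_max * m**3 * h
            g_tot = g_rs + g_leak + gna
            drive = g_rs * vcmd + g_leak * cell.e_leak + gna * cell.reversal_na
            v_inf = drive / g_tot
            vm = v_inf + (vm - v_inf) * np.exp(-g_tot * dt / cell.cm_true)
            m = cell.m_inf(vm) + (m - cell.m_inf(vm)) * np.exp(-dt / cell.tau_m_ms)
            h = cell.h_inf(vm) + (h - cell.h_inf(vm)) * np.exp(-dt / cell.tau_h_ms)
    times_s = np.arange(n_out) * sample_dt_ms / 1000.0
    return times_s, out


def simulate_voltage_clamp(
    cell: CellParams, protocol: StepProtocol | None = None
) -> VoltageClampRecording:
    """Simulate the full recording: step family, -20 mV subtraction pulse
    and ±10 mV capacitance test pulses.

    The step family and subtraction pulse share the compensated residual
    series resistance; the capacitance test pulses are simulated with
    compensation off (``rs`` as such).
    """
    protocol = protocol or StepProtocol()
    hold = protocol.holding

    def step_wave(t_ms, levels):
        if t_ms < protocol.pre_ms or t_ms >= protocol.pre_ms + protocol.pulse_ms:
            return np.full(np.shape(levels), hold)
        return np.asarray(levels, dtype=float)

    t_total = protocol.pre_ms + protocol.pulse_ms + protocol.post_ms
    commands = protocol.commands
    time_s, fam = _integrate_sweeps(
        cell, commands, step_wave, t_total, protocol.sample_rate, cell.rs_effective
    )
    sub_level = np.array([hold + protocol.subtraction_dv])
    _, sub = _integrate_sweeps(
        cell, sub_level, step_wave, t_total, protocol.sample_rate, cell.rs_effective
    )

    def passive_wave(t_ms, levels):
        if t_ms < protocol.pre_ms or t_ms >= protocol.pre_ms + protocol.passive_ms:
            return np.full(np.shape(levels), hold)
        return np.asarray(levels, dtype=float)

    p_total = protocol.pre_ms + protocol.passive_ms + protocol.post_ms
    p_levels = np.array([hold + protocol.passive_dv, hold - protocol.passive_dv])
    p_time, p_out = _integrate_sweeps(
        cell, p_levels, passive_wave, p_total, protocol.sample_rate, cell.rs
    )

    return VoltageClampRecording(
        time=time_s,
        sweeps={float(v): fam[:, i].copy() for i, v in enumerate(commands)},
        subtraction=sub[:, 0].copy(),
        passive_time=p_time,
        passive_plus=p_out[:, 0].copy(),
        passive_minus=p_out[:, 1].copy(),
        holding=hold,
        sample_rate=protocol.sample_rate,
        pulse_start=protocol.pre_ms / 1000.0,
        pulse_dur=protocol.pulse_ms / 1000.0,
        passive_pulse_start=protocol.pre_ms / 1000.0,
        passive_pulse_dur=protocol.passive_ms / 1000.0,
        passive_dv=protocol.passive_dv,
        subtraction_dv=protocol.subtraction_dv,
        manifest={
            "cm_true": cell.cm_true,
            "rs": cell.rs,
            "rs_effective": cell.rs_effective,
            "rin_true": cell.rin_true,
            "g_na_max": cell.g_na_max,
            "reversal_na": cell.reversal_na,
        },
    )


def ideal_clamp_peak_current(
    cell: CellParams, protocol: StepProtocol | None = None, *, dt_ms: float = 0.002
) -> tuple[float, float]:
    """Peak inward sodium current (pA) and its command voltage (mV) under a
    perfect clamp (no series resistance, no leak).

    This is the model's true peak, the reference for density calibration and
    for scoring the leak-subtraction pipeline.
    """
    protocol = protocol or StepProtocol()
    best = 0.0
    best_v = float(protocol.commands[0])
    for v in protocol.commands:
        m = cell.m_inf(protocol.holding)
        h = cell.h_inf(protocol.holding)
        m_inf, h_inf = cell.m_inf(v), cell.h_inf(v)
        n_steps = int(round(protocol.pulse_ms / dt_ms))
        t = np.arange(1, n_steps + 1) * dt_ms
        m_t = m_inf + (m - m_inf) * np.exp(-t / cell.tau_m_ms)
        h_t = h_inf + (h - h_inf) * np.exp(-t / cell.tau_h_ms)
        cur = cell.g_na_max * m_t**3 * h_t * (v - cell.reversal_na)
        peak = float(cur.min())
        if peak < best:
            best = peak
            best_v = float(v)
    return best, best_v


def calibrate_gna_for_peak_density(
    target_density: float,
    cell: CellParams,
    protocol: StepProtocol | None = None,
) -> CellParams:
    """Return a copy of ``cell`` whose maximal conductance makes the true
    (ideal-clamp) peak sodium-current density equal ``target_density``
    (pA/pF, negative for inward).

    The peak is linear in g_Na_max under ideal clamp, so a single unit-
    conductance simulation fixes the scale.
    """
    from dataclasses import replace

    if target_density >= 0:
        raise ValueError("peak inward density must be negative")
    probe = replace(cell, g_na_max=1.0)
    peak_per_ns, _ = ideal_clamp_peak_current(probe, protocol)
    if peak_per_ns >= 0:
        raise ValueError("protocol elicits no inward current")
    g = target_density * cell.cm_true / peak_per_ns
    return replace(cell, g_na_max=float(g))
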