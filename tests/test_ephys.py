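"""Patch-clamp analysis: capacitance, input resistance, leak subtraction, I/V."""

import numpy as np
import pytest

from cardiocal.ephys import (
    EphysError,
    MAX_SERIES_RESISTANCE,
    estimate_capacitance,
    estimate_input_resistance,
    iv_and_density,
    leak_subtract,
    passive_properties,
)
from cardiocal.synthetic_data.vclamp import (
    CellParams,
    StepProtocol,
    calibrate_gna_for_peak_density,
    ideal_clamp_peak_current,
    simulate_voltage_clamp,
)


class TestCapacitance:
    def test_wild_type_cell_recovered_within_two_percent(self, passive_recording):
        cell, rec = passive_recording
        props = passive_properties(rec)
        assert props.cm == pytest.approx(cell.cm_true, rel=0.02)

    def test_estimate_independent_of_series_resistance(self, short_protocol):
        """Drift below 3% across rs in {5, 10, 20} MOhm."""
        cms = []
        for rs in (5.0, 10.0, 20.0):
            cell = CellParams(cm_true=50.0, rs=rs, rin_true=400.0)
            rec = simulate_voltage_clamp(cell, short_protocol)
            cms.append(passive_properties(rec).cm)
        assert (max(cms) - min(cms)) / np.mean(cms) < 0.03

    def test_doubling_dv_leaves_cm_unchanged(self, passive_recording):
        """Linearity: integrating the same transient scaled 2x against a
        2x stimulation voltage gives the identical capacitance."""
        _, rec = passive_recording
        cm1, _ = estimate_capacitance(
            rec.passive_time, rec.passive_plus,
            pulse_start=rec.passive_pulse_start, pulse_dur=rec.passive_pulse_dur,
            dv=rec.passive_dv,
        )
        pre = rec.passive_time < rec.passive_pulse_start
        base = rec.passive_plus[pre].mean()
        doubled = base + 2.0 * (rec.passive_plus - base)
        cm2, _ = estimate_capacitance(
            rec.passive_time, doubled,
            pulse_start=rec.passive_pulse_start, pulse_dur=rec.passive_pulse_dur,
            dv=2.0 * rec.passive_dv,
        )
        assert cm2 == pytest.approx(cm1, rel=1e-9)

    def test_pure_resistor_has_no_capacitance(self):
        t = np.arange(0, 0.07, 1e-4)
        current = np.where((t >= 0.02) & (t < 0.04), 20.0, 0.0)
        cm, _ = estimate_capacitance(t, current, pulse_start=0.02, pulse_dur=0.02,
                                     dv=10.0)
        assert abs(cm) < 0.5


class TestInputResistance:
    def test_pipeline_measures_access_plus_membrane(self, passive_recording):
        """The ΔV/ΔIss readout sees rs + rin in series."""
        cell, rec = passive_recording
        rin = estimate_input_resistance(rec)
        assert rin == pytest.approx(cell.rin_true + cell.rs, rel=0.01)

    def test_ohms_law_example(self):
        """Leak only: 500 MOhm at +10 mV steady state gives 20 pA."""
        cell = CellParams(cm_true=30.0, rs=5.0, rin_true=500.0)
        rec = simulate_voltage_clamp(cell)
        pulse = (rec.passive_time >= rec.passive_pulse_start + 0.015) & (
            rec.passive_time < rec.passive_pulse_start + rec.passive_pulse_dur
        )
        d_i = rec.passive_plus[pulse].mean() - rec.passive_plus[
            rec.passive_time < rec.passive_pulse_start
        ].mean()
        assert d_i == pytest.approx(1000.0 * 10.0 / (500.0 + 5.0), rel=0.01)

    def test_symmetric_pulses_agree(self, passive_recording):
        _, rec = passive_recording
        # swap the two pulses: estimate must be identical by symmetry
        swapped = rec.__class__(**{**rec.__dict__})
        swapped.passive_plus, swapped.passive_minus = (
            rec.passive_minus, rec.passive_plus,
        )
        swapped.passive_dv = -rec.passive_dv
        assert estimate_input_resistance(swapped) == pytest.approx(
            estimate_input_resistance(rec), rel=1e-9
        )


class TestLeakSubtraction:
    def test_passive_cell_cancels_below_one_percent(self, passive_recording):
        _, rec = passive_recording
        corrected = leak_subtract(rec)
        raw_peak = max(np.max(np.abs(s)) for s in rec.sweeps.values())
        residual = max(np.max(np.abs(c)) for c in corrected.values())
        assert residual < 0.01 * raw_peak

    def test_zero_dv_sweep_stays_zero(self, passive_recording):
        _, rec = passive_recording
        corrected = leak_subtract(rec)
        assert np.max(np.abs(corrected[-90.0])) < 1e-9

    def test_active_peak_matches_model_truth(self):
        """Leak-subtracted peak equals the HH-model ideal-clamp peak within 3%."""
        cell = calibrate_gna_for_peak_density(-300.0, CellParams.wild_type())
        rec = simulate_voltage_clamp(cell)
        true_peak, _ = ideal_clamp_peak_current(cell)
        corrected = leak_subtract(rec)
        props = passive_properties(rec)
        iv = iv_and_density(corrected, props.cm, time=rec.time,
                            pulse_start=rec.pulse_start)
        measured_peak = float(np.min(iv.peak_currents))
        assert measured_peak == pytest.approx(true_peak, rel=0.03)
        # densities scale inversely with the capacitance used
        iv2 = iv_and_density(corrected, 2 * props.cm, time=rec.time,
                             pulse_start=rec.pulse_start)
        assert iv2.peak_density == pytest.approx(iv.peak_density / 2, rel=1e-9)

    def test_missing_subtraction_pulse_rejected(self, passive_recording):
        _, rec = passive_recording
        broken = rec.__class__(**{**rec.__dict__})
        broken.subtraction = None
        with pytest.raises(EphysError):
            leak_subtract(broken)


class TestQualityGate:
    def test_high_series_resistance_rejected(self, short_protocol):
        cell = CellParams(cm_true=50.0, rs=25.0, rin_true=400.0)
        rec = simulate_voltage_clamp(cell, short_protocol)
        props = passive_properties(rec)
        assert props.rs > MAX_SERIES_RESISTANCE
        assert not props.accepted

    def test_good_recording_accepted(self, passive_recording):
        _, rec = passive_recording
        assert passive_properties(rec).accepted


class TestProtocolValidation:
    def test_command_range_enforced(self):
        with pytest.raises(ValueError):
            StepProtocol(v_stop=100.0)
        with pytest.raises(ValueError):
            StepProtocol(holding=-130.0)

    def test_sampling_floor_enforced(self):
        with pytest.raises(ValueError):
            StepProtocol(sample_rate=5000.0)

    def test_quiescent_cell_iv_is_flat(self, passive_recording):
        _, rec = passive_recording
        props = passive_properties(rec)
        iv = iv_and_density(leak_subtract(rec), props.cm, time=rec.time,
                            pulse_start=rec.pulse_start)
        assert np.max(np.abs(iv.densities)) < 0.5  # pA/pF
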