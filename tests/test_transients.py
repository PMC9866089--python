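"""Transient detection, beating frequency and decay fitting."""

import numpy as np
import pytest

from cardiocal.calibration import concentration_noise_scale
from cardiocal.synthetic_data import (
    ProtocolSchedule,
    SimulationParams,
    fura2_forward,
    simulate_concentration_trace,
)
from cardiocal.transients import (
    RatioTrace,
    TraceError,
    TransientEvent,
    analyze_caffeine_transient,
    beating_frequency,
    detect_transients,
    fit_decay,
)


def _trace(values, fs=23.0, annotations=()):
    values = np.asarray(values, dtype=float)
    return RatioTrace(
        time=np.arange(values.size) / fs,
        ratio=values,
        sample_rate=fs,
        annotations=list(annotations),
    )


def _simulated(calib, **kw):
    p = SimulationParams(**kw)
    protocol = kw.pop("protocol", None)
    conc = simulate_concentration_trace(p, protocol)
    return fura2_forward(conc, calib, noise_sd=p.channel_noise_sd).calibrated(calib), conc


class TestDetection:
    def test_finds_every_noiseless_release(self, calib):
        p = SimulationParams(beat_rate=60.0, beat_jitter=0.0, duration=10.0, seed=2)
        conc = simulate_concentration_trace(p)
        trace = fura2_forward(conc, calib, noise_sd=0.0).calibrated(calib)
        events = detect_transients(trace, expected_bpm=60.0)
        # the release at exactly t = duration lands on the last sample and
        # cannot be a local maximum; all interior releases must be found
        interior = conc.beat_times[conc.beat_times < p.duration - 1.0 / p.sample_rate]
        assert len(events) == len(interior)
        dt = 1.0 / p.sample_rate
        for ev, tb in zip(events, interior):
            assert abs(ev.peak_time - tb) <= dt + 1e-9

    def test_constant_trace_yields_no_events(self):
        assert detect_transients(_trace(np.ones(200))) == []

    def test_refractory_merges_close_peaks(self):
        fs = 100.0
        y = np.zeros(500)
        y[100] = 1.0
        y[110] = 0.9  # 0.1 s later
        trace = _trace(y, fs=fs)
        events = detect_transients(trace, refractory=0.5)
        assert len(events) == 1

    def test_trace_too_short_rejected(self):
        with pytest.raises(TraceError):
            detect_transients(_trace(np.ones(10)))


class TestFrequency:
    def test_sixty_events_in_sixty_seconds(self):
        events = [
            TransientEvent(peak_time=t + 0.5, peak_index=i + 1, baseline=0.0,
                           amplitude=1.0, onset_time=t + 0.4)
            for i, t in enumerate(np.arange(60.0))
        ]
        assert beating_frequency(events, 60.0) == pytest.approx(60.0)

    def test_no_events_is_zero_bpm(self):
        assert beating_frequency([], 60.0) == 0.0

    def test_invariant_to_shift_and_scale(self, calib):
        p = SimulationParams(duration=30.0, seed=9, channel_noise_sd=20.0)
        conc = simulate_concentration_trace(p)
        trace = fura2_forward(conc, calib).calibrated(calib)
        n0 = len(detect_transients(trace, expected_bpm=p.beat_rate))
        shifted = RatioTrace(
            time=trace.time + 17.0, ratio=3.0 * trace.ratio + 100.0,
            sample_rate=trace.sample_rate,
        )
        assert len(detect_transients(shifted, expected_bpm=p.beat_rate)) == n0


class TestDecayFit:
    def test_pure_exponential_recovered(self):
        fs, tau = 50.0, 0.5
        t = np.arange(0, 8, 1 / fs)
        y = 2.0 * np.exp(-t / tau) + 0.3
        trace = _trace(y, fs=fs)
        ev = TransientEvent(peak_time=0.0, peak_index=0, baseline=0.3,
                            amplitude=2.0, onset_time=-0.02)
        fit = fit_decay(trace, ev)
        assert fit.converged
        assert fit.tau == pytest.approx(tau, abs=5e-4)
        assert fit.k * fit.tau == pytest.approx(1.0, abs=1e-12)

    def test_simulator_total_rate_on_noiseless_trace(self, calib):
        p = SimulationParams(beat_rate=30.0, beat_jitter=0.0, duration=20.0, seed=4)
        conc = simulate_concentration_trace(p)
        trace = fura2_forward(conc, calib, noise_sd=0.0).calibrated(calib)
        events = detect_transients(trace, expected_bpm=30.0)
        fit = fit_decay(trace, events[0], next_onset=events[1].onset_time)
        assert fit.converged
        assert fit.k == pytest.approx(p.k_sys, rel=0.01)

    def test_window_too_small_refused(self):
        y = np.r_[np.zeros(50), 1.0, np.zeros(3)]
        trace = _trace(y, fs=23.0)
        ev = TransientEvent(peak_time=50 / 23, peak_index=50, baseline=0.0,
                            amplitude=1.0, onset_time=49 / 23)
        fit = fit_decay(trace, ev)
        assert not fit.converged
        assert "samples" in fit.reason

    def test_noisy_replicates_have_small_bias(self, calib):
        """Monte-Carlo: 100 replicate caffeine fits at 5% amplitude noise
        recover tau with mean bias below 2%."""
        taus = []
        for seed in range(100):
            p = SimulationParams(
                beat_rate=0.0, leak_rate=0.0, duration=40.0, sample_rate=6.6,
                seed=seed, channel_noise_sd=10.0,
            )
            conc = simulate_concentration_trace(
                p, ProtocolSchedule(events=[(2.0, "caffeine_on")])
            )
            trace = fura2_forward(conc, calib).calibrated(calib)
            sigma = concentration_noise_scale(trace.values, calib)
            _, fit = analyze_caffeine_transient(trace, sigma=sigma)
            if fit.converged:
                taus.append(fit.tau)
        assert len(taus) >= 95
        assert np.mean(taus) == pytest.approx(5.0, rel=0.02)


class TestCaffeine:
    def test_amplitude_equals_sr_content(self, noiseless_caffeine_trace):
        trace, params = noiseless_caffeine_trace
        amp, fit = analyze_caffeine_transient(trace)
        assert amp == pytest.approx(params.sr_content, rel=0.01)
        assert fit.converged
        # k_eff after caffeine = k_ncx + k_pmca + k_mito = 0.2 /s
        assert fit.k == pytest.approx(0.2, rel=0.01)
        assert fit.tau == pytest.approx(5.0, rel=0.01)

    def test_missing_caffeine_annotation_rejected(self, calib):
        p = SimulationParams(duration=10.0, seed=1)
        trace = fura2_forward(
            simulate_concentration_trace(p), calib, noise_sd=0.0
        ).calibrated(calib)
        with pytest.raises(TraceError):
            analyze_caffeine_transient(trace)
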