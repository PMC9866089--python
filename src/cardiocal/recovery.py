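"""End-to-end recovery workflows at the study's group conditions.

Each function parameterizes the synthetic generators at a study group's
nominal values (beating rates, extrusion fractions, cluster statistics,
passive and active membrane properties), runs the full measurement chain on
the simulated raw data and returns the recovered quantity.  These are the
workflows the acceptance script executes; they are also exercised by the
test suite at reduced replicate counts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calibration import CalibrationParams, ratio_to_concentration
from .cluster_quant import (
    contact_summary,
    filter_by_size,
    renyi_threshold_intensity,
    segment_clusters,
)
from .ephys import iv_and_density, leak_subtract, passive_properties
from .flux_decomposition import decompose_rates, percent_table, rates_from_traces
from .synthetic_data import (
    CellParams,
    ImageParams,
    ProtocolSchedule,
    SimulationParams,
    calibrate_gna_for_peak_density,
    fura2_forward,
    generate_contact_image,
    simulate_concentration_trace,
    simulate_voltage_clamp,
)
from .synthetic_data.images import lognormal_mu_for_truncated_mean
from .transients import beating_frequency, detect_transients

__all__ = [
    "STUDY",
    "REFERENCE_CALIBRATION",
    "calibration_midpoint",
    "frequency_recovery",
    "decomposition_recovery",
    "cluster_recovery",
    "capacitance_recovery",
    "ephys_recovery",
]

#: Nominal group values of the study that parameterize the generators.
STUDY = {
    "beat_rate_wt": 59.0,  # bpm, mean ± 5 (SEM)
    "beat_rate_ko": 96.0,  # bpm, mean ± 7 (SEM)
    "beat_sd_wt": 5.0,
    "beat_sd_ko": 7.0,
    "pct_serca_wt": 90.0,  # % of systolic extrusion
    "pct_ncx_wt": 5.0,
    "pct_ncx_ko": 7.0,
    "cluster_area_wt": 0.292,  # µm², post-filter mean
    "cluster_area_ko": 0.3352,
    "density_ratio_ko": 0.6,  # KO cluster density relative to WT
    "cm_wt": 51.9,  # pF
    "rin_wt": 435.1,  # MOhm
    "peak_density_wt": -338.2,  # pA/pF
}

#: Fura-2 calibration used to encode and decode all synthetic traces.
REFERENCE_CALIBRATION = CalibrationParams(r_min=0.5, r_max=3.5, beta=1.0)

#: Channel noise (absolute units on the 1000-unit 380 nm scale): 3 %.
CHANNEL_NOISE_SD = 30.0


def _sub_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + 7919 * i + 1) % (2**31 - 1))


def _jitter_from_bpm_sd(rate: float, sd_bpm: float) -> float:
    """Map a beating-rate spread (bpm) to an inter-beat-interval SD (s)."""
    return 60.0 * sd_bpm / rate**2


def _genotype_params(genotype: str) -> SimulationParams:
    if genotype == "wt":
        base = SimulationParams.wild_type()
        return replace(
            base,
            beat_rate=STUDY["beat_rate_wt"],
            beat_jitter=_jitter_from_bpm_sd(STUDY["beat_rate_wt"], STUDY["beat_sd_wt"]),
        )
    if genotype == "ko":
        base = SimulationParams.car_knockout()
        return replace(
            base,
            beat_rate=STUDY["beat_rate_ko"],
            beat_jitter=_jitter_from_bpm_sd(STUDY["beat_rate_ko"], STUDY["beat_sd_ko"]),
        )
    raise ValueError(f"unknown genotype {genotype!r}")


def calibration_midpoint() -> float:
    """[Ca2+] at the ratio midpoint (Rmin+Rmax)/2 with beta = 1: the Kd."""
    calib = REFERENCE_CALIBRATION
    r_mid = 0.5 * (calib.r_min + calib.r_max)
    return float(ratio_to_concentration(r_mid, calib))


def frequency_recovery(genotype: str, n_traces: int, seed: int) -> float:
    """Mean detected beating frequency (bpm) over seeded 60-s traces.

    Each trace is simulated at 23 frames/s with 3 % channel noise, encoded
    through the Fura-2 forward model, calibrated back to nM, and run through
    transient detection and events-per-minute counting.
    """
    calib = REFERENCE_CALIBRATION
    params = _genotype_params(genotype)
    bpms = []
    for i in range(n_traces):
        p = replace(
            params,
            seed=_sub_seed(seed, i),
            duration=60.0,
            sample_rate=23.0,
            channel_noise_sd=CHANNEL_NOISE_SD,
        )
        trace = fura2_forward(simulate_concentration_trace(p), calib).calibrated(calib)
        events = detect_transients(trace, expected_bpm=params.beat_rate)
        bpms.append(beating_frequency(events, p.duration))
    return float(np.mean(bpms))


def decomposition_recovery(genotype: str, n_sets: int, seed: int) -> dict:
    """Four-component extrusion decomposition over simulated protocol sets.

    Each set comprises a spontaneous recording (23 frames/s), a caffeine
    protocol and a Na/Ca-free caffeine protocol (both 6.6 frames/s), all
    with 3 % channel noise.  Decays are fitted per condition, the rate
    ladder decomposed, and the group percent table returned as a dict with
    ``pct_serca`` / ``pct_ncx`` means and SEMs.
    """
    from .transients import TraceError

    calib = REFERENCE_CALIBRATION
    params = _genotype_params(genotype)
    records = []
    failed = 0
    for i in range(n_sets):
        s = _sub_seed(seed, i)
        p_sp = replace(
            params, seed=s, duration=60.0, sample_rate=23.0,
            channel_noise_sd=CHANNEL_NOISE_SD,
        )
        spont = fura2_forward(simulate_concentration_trace(p_sp), calib).calibrated(calib)
        p_cf = replace(p_sp, seed=s + 1, sample_rate=6.6)
        caff = fura2_forward(
            simulate_concentration_trace(
                p_cf, ProtocolSchedule(events=[(10.0, "caffeine_on")])
            ),
            calib,
        ).calibrated(calib)
        p_fr = replace(p_sp, seed=s + 2, sample_rate=6.6, duration=120.0)
        caff_free = fura2_forward(
            simulate_concentration_trace(
                p_fr,
                ProtocolSchedule(
                    events=[(5.0, "na_ca_free_on"), (10.0, "caffeine_on")]
                ),
            ),
            calib,
        ).calibrated(calib)
        try:
            rates = rates_from_traces(
                spont, caff, caff_free, expected_bpm=params.beat_rate, calib=calib
            )
        except TraceError:
            # non-convergent condition fits are excluded from summaries
            failed += 1
            continue
        records.append(decompose_rates(rates))
    if len(records) < max(3, n_sets // 2):
        raise TraceError(f"too many failed protocol sets ({failed}/{n_sets})")
    table = percent_table({genotype: records})
    return {
        "pct_serca": float(table["pct_serca_mean"].iloc[0]),
        "pct_serca_sem": float(table["pct_serca_sem"].iloc[0]),
        "pct_ncx": float(table["pct_ncx_mean"].iloc[0]),
        "pct_ncx_sem": float(table["pct_ncx_sem"].iloc[0]),
        "n": len(records),
        "n_failed": failed,
    }


def _image_group(
    mean_area: float, n_clusters: float, n_images: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    mu = lognormal_mu_for_truncated_mean(mean_area, 0.55)
    areas, densities = [], []
    for i in range(n_images):
        p = ImageParams(
            seed=_sub_seed(seed, i), cluster_area_log_mean=mu, n_clusters=n_clusters
        )
        img, region, _truth = generate_contact_image(p)
        threshold = renyi_threshold_intensity(img, region)
        clusters = filter_by_size(segment_clusters(img, region, threshold))
        areas.extend(c.area for c in clusters)
        densities.append(contact_summary(clusters, region).density_per_um2)
    return np.asarray(areas), np.asarray(densities)


def cluster_recovery(n_wt: int, n_ko: int, seed: int) -> dict:
    """Cluster pipeline on WT- and KO-parameterized synthetic image groups.

    WT images carry the WT post-filter mean cluster area and 20 clusters per
    contact; KO images the KO mean area and 0.6x the cluster density.
    Returns the measured post-filter mean areas and the percent density
    decrease 100·(1 − KO/WT).
    """
    wt_n_clusters = 20.0
    areas_wt, dens_wt = _image_group(
        STUDY["cluster_area_wt"], wt_n_clusters, n_wt, seed
    )
    areas_ko, dens_ko = _image_group(
        STUDY["cluster_area_ko"],
        wt_n_clusters * STUDY["density_ratio_ko"],
        n_ko,
        seed + 104729,
    )
    return {
        "mean_area_wt": float(areas_wt.mean()),
        "mean_area_ko": float(areas_ko.mean()),
        "density_wt": float(dens_wt.mean()),
        "density_ko": float(dens_ko.mean()),
        "density_decrease_pct": float(100.0 * (1.0 - dens_ko.mean() / dens_wt.mean())),
    }


def capacitance_recovery() -> float:
    """Capacitance of a passive WT-sized cell from transient integration.

    Simulates a purely passive cell (10 MOhm uncompensated pipette) with the
    ±10 mV/20 ms test pulses at 10 kHz and integrates the capacitive
    transient.  A single-step command family keeps the simulation light —
    only the test pulses matter for this estimate.
    """
    from .synthetic_data import StepProtocol

    cell = CellParams.wild_type(g_na_max=0.0, rs_compensation=0.0)
    protocol = StepProtocol(v_start=-90.0, v_stop=-90.0)
    rec = simulate_voltage_clamp(cell, protocol)
    return float(passive_properties(rec).cm)


def ephys_recovery() -> dict:
    """Capacitance and peak sodium-current density of the WT-calibrated cell.

    The cell's maximal conductance is calibrated so its ideal-clamp peak
    density equals the WT group mean; the full recording (capacitive
    transients, ohmic leak, compensated series resistance) is then analyzed
    with leak subtraction, capacitance integration and I/V extraction.
    Deterministic: the voltage-clamp forward model contains no noise source.
    """
    cell = calibrate_gna_for_peak_density(
        STUDY["peak_density_wt"], CellParams.wild_type()
    )
    rec = simulate_voltage_clamp(cell)
    props = passive_properties(rec)
    corrected = leak_subtract(rec)
    iv = iv_and_density(
        corrected, props.cm, time=rec.time, pulse_start=rec.pulse_start
    )
    return {
        "cm_pf": props.cm,
        "rin_mohm": props.rin,
        "rs_mohm": props.rs,
        "peak_density_pa_pf": iv.peak_density,
        "v_peak_mv": iv.v_peak,
        "accepted": props.accepted,
    }
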