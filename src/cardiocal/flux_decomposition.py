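"""Four-component decomposition of cytosolic calcium extrusion.

The decay rate constant k = 1/τ of a calcium transient is the sum of the
first-order rates of all extrusion pathways active during the decay.  The
pharmacological ladder isolates them by successive removal:

- spontaneous twitch            → k_sys  = k_SERCA + k_NCX + k_PMCA + k_mito
- caffeine transient            → k_caff = k_NCX + k_PMCA + k_mito
  (continuous SR release defeats net SERCA re-uptake)
- caffeine in Na/Ca-free buffer → k_caff_0na0ca = k_PMCA + k_mito
- + mitochondrial uncoupler     → k_caff_0na0ca_unc = k_PMCA

Subtraction down the ladder yields the individual components, and each
pathway's share of systolic extrusion is 100·k_x/k_sys.  The caffeine
transient amplitude measures SR calcium content; the cytosolic drop under
tetracaine (RyR block) in Na/Ca-free buffer measures the SR leak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transients import (
    RatioTrace,
    TraceError,
    analyze_caffeine_transient,
    detect_transients,
    fit_decay,
    fit_shared_decay,
)

__all__ = [
    "ConditionRates",
    "ExtrusionRates",
    "SRMeasures",
    "decompose_rates",
    "percent_table",
    "quantify_sr_leak",
    "rates_from_traces",
    "mean_twitch_rate",
]


@dataclass(frozen=True)
class ConditionRates:
    """Measured decay rate constants (1/s) of the protocol ladder.

    The uncoupler condition is optional; without it PMCA and mitochondrial
    uptake cannot be separated.  ``ladder_violated`` flags a set whose rates
    do not decrease down the ladder, which signals inconsistent fits.
    """

    k_sys: float
    k_caff: float
    k_caff_0na0ca: float | None = None
    k_caff_0na0ca_unc: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_sys", "k_caff", "k_caff_0na0ca", "k_caff_0na0ca_unc"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be a positive finite rate")

    @property
    def ladder_violated(self) -> bool:
        ladder = [self.k_sys, self.k_caff, self.k_caff_0na0ca, self.k_caff_0na0ca_unc]
        ladder = [v for v in ladder if v is not None]
        return any(b > a for a, b in zip(ladder, ladder[1:]))


@dataclass(frozen=True)
class ExtrusionRates:
    """Decomposed rate constants and their percent shares of k_sys.

    Components sum to k_sys exactly by construction.  Negative components
    (possible when condition fits are inconsistent) are reported as-is with
    ``quality_flag`` set, never clamped or redistributed.  Without an
    uncoupler condition ``k_pmca`` holds the combined PMCA + mitochondria
    rate and ``pmca_mito_combined`` is True.
    """

    k_serca: float
    k_ncx: float
    k_pmca: float
    k_mito: float
    pct_serca: float
    pct_ncx: float
    pct_pmca: float
    pct_mito: float
    pmca_mito_combined: bool = False
    quality_flag: bool = False

    @property
    def k_sys(self) -> float:
        return self.k_serca + self.k_ncx + self.k_pmca + self.k_mito


@dataclass(frozen=True)
class SRMeasures:
    """SR content proxy (caffeine amplitude) and tetracaine leak drop."""

    sr_content_amplitude: float
    leak_drop: float | None = None

    def __post_init__(self) -> None:
        if self.sr_content_amplitude < 0:
            raise ValueError("sr_content_amplitude must be >= 0")


def decompose_rates(cr: ConditionRates) -> ExtrusionRates:
    """Subtraction ladder: k_SERCA = k_sys − k_caff, k_NCX = k_caff −
    k_caff_0na0ca, k_mito = k_caff_0na0ca − k_caff_0na0ca_unc,
    k_PMCA = k_caff_0na0ca_unc.

    When the Na/Ca-free condition is missing, NCX cannot be separated from
    the slow systems and a ValueError is raised; when only the uncoupler
    condition is missing, the PMCA slot carries the combined slow-system
    rate (flagged via ``pmca_mito_combined``).
    """
    if cr.k_caff_0na0ca is None:
        raise ValueError("Na/Ca-free caffeine condition required to separate NCX")
    k_serca = cr.k_sys - cr.k_caff
    k_ncx = cr.k_caff - cr.k_caff_0na0ca
    if cr.k_caff_0na0ca_unc is not None:
        k_pmca = cr.k_caff_0na0ca_unc
        k_mito = cr.k_caff_0na0ca - cr.k_caff_0na0ca_unc
        combined = False
    else:
        k_pmca = cr.k_caff_0na0ca
        k_mito = 0.0
        combined = True
    flag = any(k < 0 for k in (k_serca, k_ncx, k_pmca, k_mito)) or cr.ladder_violated
    pct = lambda k: 100.0 * k / cr.k_sys
    return ExtrusionRates(
        k_serca=k_serca,
        k_ncx=k_ncx,
        k_pmca=k_pmca,
        k_mito=k_mito,
        pct_serca=pct(k_serca),
        pct_ncx=pct(k_ncx),
        pct_pmca=pct(k_pmca),
        pct_mito=pct(k_mito),
        pmca_mito_combined=combined,
        quality_flag=flag,
    )


def percent_table(groups: dict[str, list[ExtrusionRates]]) -> pd.DataFrame:
    """Per-group mean ± SEM of each rate constant and each percent share.

    Index: group label; columns: ``<quantity>_mean`` and ``<quantity>_sem``
    for k_serca..k_mito and pct_serca..pct_mito, plus n.
    """
    quantities = [
        "k_serca", "k_ncx", "k_pmca", "k_mito",
        "pct_serca", "pct_ncx", "pct_pmca", "pct_mito",
    ]
    rows = {}
    for label, records in groups.items():
        if not records:
            raise ValueError(f"group {label!r} is empty")
        row = {"n": len(records)}
        for q in quantities:
            vals = np.array([getattr(r, q) for r in records], dtype=float)
            row[f"{q}_mean"] = float(vals.mean())
            row[f"{q}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def quantify_sr_leak(
    trace: RatioTrace,
    *,
    plateau_s: float = 10.0,
    settle_s: float = 10.0,
) -> float:
    """SR leak readout: cytosolic calcium drop after tetracaine.

    With NCX disabled (Na/Ca-free buffer) and RyR blocked by tetracaine the
    leak flux vanishes, so cytosolic calcium relaxes to a lower plateau; the
    drop equals J_leak/k_eff of the preceding steady state.  The trace must
    be calibrated (nM) and annotated with ``tetracaine_on``; plateaus are
    medians of ``plateau_s``-second windows immediately before the event and
    after a ``settle_s`` relaxation delay.
    """
    tets = trace.events_of_kind("tetracaine_on")
    if not tets:
        raise TraceError("trace has no tetracaine_on annotation")
    t_tet = tets[0]
    t, y = trace.time, trace.values
    if t_tet <= t[0] or t_tet >= t[-1]:
        raise TraceError("tetracaine event outside the recorded window")
    pre = (t >= t_tet - plateau_s) & (t < t_tet)
    post = t >= t_tet + settle_s
    if not np.any(pre) or not np.any(post):
        raise TraceError("insufficient data around the tetracaine event")
    post_vals = y[post][-max(1, int(plateau_s * trace.sample_rate)) :]
    return float(np.median(y[pre]) - np.median(post_vals))


def _noise_sigma(trace: RatioTrace, calib, *, kind: str = "neighbor") -> np.ndarray | None:
    """Per-sample fit weights from the calibration's noise propagation.

    Weights computed from the noisy samples themselves correlate with the
    noise and bias the decay fits, so the scale is evaluated on a smoothed
    signal.  ``kind="neighbor"`` averages the four surrounding samples and
    excludes the sample itself — fully decorrelated from its own noise, the
    right choice for long single-transient windows.  ``kind="median"`` is a
    5-sample running median — more robust across the sharp peaks of densely
    beating traces, used by the short-segment shared twitch fit.
    """
    if calib is None:
        return None
    from scipy.ndimage import convolve1d, median_filter

    from .calibration import concentration_noise_scale

    y = trace.values
    if y.size < 5:
        smooth = y
    elif kind == "median":
        smooth = median_filter(y, size=5, mode="nearest")
    else:
        kernel = np.array([1.0, 1.0, 0.0, 1.0, 1.0]) / 4.0
        smooth = convolve1d(y, kernel, mode="nearest")
    return concentration_noise_scale(smooth, calib)


def mean_twitch_rate(
    trace: RatioTrace,
    *,
    min_prominence: float = 4.0,
    expected_bpm: float = 100.0,
    calib=None,
    method: str = "shared",
) -> float:
    """Decay rate constant (1/s) of the spontaneous twitches of one trace.

    ``method="shared"`` (default) fits all inter-beat decay segments jointly
    with a shared time constant (:func:`~cardiocal.transients.
    fit_shared_decay`), which stays stable when fast beating leaves only a
    handful of samples per decay.  ``method="per_twitch"`` fits every
    transient independently and takes the median k over converged fits.
    Passing the trace's :class:`~cardiocal.calibration.CalibrationParams`
    weights the fits by the saturation-dependent noise of the ratiometric
    conversion.
    """
    events = detect_transients(
        trace, min_prominence=min_prominence, expected_bpm=expected_bpm
    )
    if not events:
        raise TraceError("no transients detected")
    sigma = _noise_sigma(trace, calib, kind="median")
    if method == "shared":
        fit = fit_shared_decay(trace, events, sigma=sigma)
        if not fit.converged:
            raise TraceError(f"shared decay fit failed: {fit.reason}")
        return fit.k
    if method != "per_twitch":
        raise ValueError(f"unknown method {method!r}")
    ks = []
    for ev, nxt in zip(events, events[1:] + [None]):
        fit = fit_decay(
            trace, ev, next_onset=nxt.onset_time if nxt else None, sigma=sigma
        )
        if fit.converged and fit.tau > 0:
            ks.append(fit.k)
    if not ks:
        raise TraceError("no decay fit converged")
    return float(np.median(ks))


def rates_from_traces(
    spont: RatioTrace,
    caff: RatioTrace,
    caff_0na0ca: RatioTrace,
    caff_0na0ca_unc: RatioTrace | None = None,
    *,
    expected_bpm: float = 100.0,
    calib=None,
) -> ConditionRates:
    """Measure the full condition ladder from (calibrated) protocol traces.

    ``spont`` is a spontaneous-beating recording; the others are caffeine
    protocols under the respective buffer conditions, each annotated with
    ``caffeine_on``.  Passing ``calib`` enables noise-propagation weighting
    of every decay fit.
    """
    k_sys = mean_twitch_rate(spont, expected_bpm=expected_bpm, calib=calib)
    _, fit_caff = analyze_caffeine_transient(
        caff, sigma=_noise_sigma(caff, calib, kind="neighbor")
    )
    if not fit_caff.converged:
        raise TraceError("caffeine decay fit failed")
    _, fit_free = analyze_caffeine_transient(
        caff_0na0ca, sigma=_noise_sigma(caff_0na0ca, calib, kind="neighbor")
    )
    if not fit_free.converged:
        raise TraceError("Na/Ca-free caffeine decay fit failed")
    k_unc = None
    if caff_0na0ca_unc is not None:
        _, fit_unc = analyze_caffeine_transient(
            caff_0na0ca_unc, sigma=_noise_sigma(caff_0na0ca_unc, calib, kind="neighbor")
        )
        if not fit_unc.converged:
            raise TraceError("uncoupler caffeine decay fit failed")
        k_unc = fit_unc.k
    return ConditionRates(
        k_sys=k_sys,
        k_caff=fit_caff.k,
        k_caff_0na0ca=fit_free.k,
        k_caff_0na0ca_unc=k_unc,
    )
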