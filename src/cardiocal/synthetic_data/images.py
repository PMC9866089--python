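"""Synthetic connexin-spot images at cell-cell contacts.

Clusters are rendered as 2-D Gaussian spots whose footprint above half of
their amplitude equals the drawn area: for peak amplitude A above background,
the region where the spot exceeds A/2 is a disc of radius sigma*sqrt(2 ln 2),
so sigma is chosen as sqrt(area / (2*pi*ln 2)).  Cluster areas follow a
log-normal law (strictly positive and right-skewed, the shape empirical
plaque-size distributions show).  The contact region is a straight band
through the image centre, mimicking the encircled membrane apposition of two
neighbouring cells.

Per-cluster peak amplitudes are log-normal: plaques span dim to bright, and
that spread is what lets an entropy-based auto-threshold settle between the
background mode and the foreground rather than hugging the background.  The
default contrast (median amplitude 64 over a background of 30 with noise
SD 10) places the automatic threshold close to the half-amplitude level of
the median cluster, so threshold-level footprint areas track the half-max
ground truth with little scale error while keeping nearly every plaque
segmentable in one piece.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from scipy.optimize import brentq

from ..cluster_quant import (
    DEFAULT_PIXEL_SIZE_UM,
    ClusterRecord,
    ContactRegion,
    FluorescenceImage,
)

__all__ = [
    "ImageParams",
    "generate_contact_image",
    "truncated_lognormal_mean",
    "lognormal_mu_for_truncated_mean",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ImageParams:
    """Generator parameters for one synthetic contact image.

    ``n_clusters`` is the per-image spot count; ``cluster_area_log_mean`` /
    ``cluster_area_log_sd`` parameterize the log-normal area law in ln(µm²).
    ``cluster_intensity`` is the median spot peak amplitude above background
    and ``cluster_intensity_log_sd`` the log-SD of the per-cluster amplitude
    draw (0 for uniform brightness).  Intensities stay within 16-bit range.
    """

    width: int = 512
    height: int = 192
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    contact_band_width_um: float = 2.0
    n_clusters: float = 20.0
    cluster_area_log_mean: float = -1.363
    cluster_area_log_sd: float = 0.55
    cluster_intensity: float = 64.0
    cluster_intensity_log_sd: float = 0.5
    background_level: float = 30.0
    background_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.width < 8 or self.height < 8:
            raise ValueError("image too small")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if not (0 <= self.background_level and
                self.background_level + self.cluster_intensity <= 65535):
            raise ValueError("intensities must fit the 16-bit range")
        if self.cluster_intensity_log_sd < 0:
            raise ValueError("cluster_intensity_log_sd must be >= 0")
        if self.contact_band_width_um <= 0:
            raise ValueError("contact_band_width_um must be positive")


def truncated_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Mean of a log-normal(mu, sigma) restricted to [lo, hi].

    Used as the analytic oracle for the post-filter mean cluster area.
    """
    phi = _stats.norm.cdf
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    denom = phi(b) - phi(a)
    if denom <= 0:
        raise ValueError("truncation window has zero mass")
    num = phi(b - sigma) - phi(a - sigma)
    return float(np.exp(mu + 0.5 * sigma**2) * num / denom)


def lognormal_mu_for_truncated_mean(
    target_mean: float, sigma: float, lo: float = 0.05, hi: float = 1.0
) -> float:
    """Solve for the log-mean giving a prescribed truncated mean on [lo, hi]."""
    if not (lo < target_mean < hi):
        raise ValueError("target mean must lie inside the truncation window")
    f = lambda mu: truncated_lognormal_mean(mu, sigma, lo, hi) - target_mean
    return float(brentq(f, np.log(lo) - 5 * sigma, np.log(hi) + 5 * sigma, xtol=1e-10))


def _band_mask(p: ImageParams) -> np.ndarray:
    rows = np.arange(p.height)[:, None]
    half_px = 0.5 * p.contact_band_width_um / p.pixel_size
    centre = (p.height - 1) / 2.0
    return np.repeat(np.abs(rows - centre) <= half_px, p.width, axis=1)


def generate_contact_image(
    params: ImageParams,
    *,
    max_retries: int = 50,
) -> tuple[FluorescenceImage, ContactRegion, list[ClusterRecord]]:
    """Render one synthetic contact image.

    Returns the image, the contact-region mask and the ground-truth cluster
    manifest (true areas in µm² and centroids in pixel coordinates).  A drawn
    cluster whose footprint cannot fit inside the contact band is resampled
    up to ``max_retries`` times before being rejected with an error.
    """
    rng = np.random.default_rng(params.seed)
    mask = _band_mask(params)
    band_rows = np.nonzero(mask[:, 0])[0]
    r_lo, r_hi = band_rows[0], band_rows[-1]
    px2 = params.pixel_size**2
    band_width_px = r_hi - r_lo + 1

    # deterministic count: the expected count is the per-image count, so
    # group density ratios are set by the parameters, not by count noise
    n = int(round(params.n_clusters))
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    img = np.full((params.height, params.width), params.background_level, dtype=float)

    placed: list[tuple[float, float, float]] = []  # (cy, cx, footprint_radius)
    truth: list[ClusterRecord] = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            area_um2 = float(
                np.exp(rng.normal(params.cluster_area_log_mean, params.cluster_area_log_sd))
            )
            area_px = area_um2 / px2
            sigma = np.sqrt(area_px / (2.0 * np.pi * _LN2))
            footprint_radius = sigma * np.sqrt(2.0 * _LN2)
            if footprint_radius > (r_hi - r_lo) / 2.0:
                continue  # does not fit across the band
            cy = rng.uniform(r_lo + footprint_radius, r_hi - footprint_radius)
            cx = rng.uniform(footprint_radius, params.width - 1 - footprint_radius)
            # plaques are distinct structures: keep footprints separated so
            # two drawn clusters are not rendered as one merged object
            if all(
                np.hypot(cy - py, cx - px_) > 2.0 * (footprint_radius + pr)
                for py, px_, pr in placed
            ):
                break
        else:
            raise ValueError(
                "could not place cluster inside the contact band after "
                f"{max_retries} resampling attempts"
            )
        placed.append((cy, cx, footprint_radius))
        if params.cluster_intensity_log_sd > 0:
            amplitude = float(
                np.exp(
                    rng.normal(
                        np.log(params.cluster_intensity),
                        params.cluster_intensity_log_sd,
                    )
                )
            )
        else:
            amplitude = params.cluster_intensity
        img += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
        truth.append(
            ClusterRecord(
                area=area_um2,
                pixel_count=max(1, int(round(area_px))),
                centroid=(cy, cx),
                mean_intensity=amplitude,
            )
        )

    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, img.shape)
    np.clip(img, 0.0, 65535.0, out=img)

    return (
        FluorescenceImage(pixels=img, pixel_size=params.pixel_size),
        ContactRegion(mask=mask, pixel_size=params.pixel_size),
        truth,
    )
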