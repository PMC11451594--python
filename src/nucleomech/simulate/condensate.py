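"""Synthetic two-channel nucleus images with known condensate enrichment.

An elliptical nucleus with disk-shaped marker condensates whose
enrichment over the whole-nucleus mean is exact by construction on the
noiseless truth masks, plus a DNA counterstain channel.  Cluster centers
are placed with a tunable radial bias to emulate peripheral condensate
localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..config import SimConfig

__all__ = ["CondensateTruth", "gen_condensate_image"]


@dataclass(frozen=True)
class CondensateTruth:
    """Ground truth for a condensate image.

    enrichment_true: mean marker intensity over cluster pixels divided by
    the whole-nucleus mean (≥ 1); peripheral_bias in [0, 1]: 0 places
    cluster centers uniformly over the nucleus area, 1 places them all at
    the rim of the allowed region; cluster_radius in μm.
    """

    n_clusters: int
    enrichment_true: float = 2.0
    peripheral_bias: float = 0.0
    cluster_radius: float = 0.4

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.enrichment_true < 1.0:
            raise ValueError("enrichment_true must be >= 1")
        if not 0.0 <= self.peripheral_bias <= 1.0:
            raise ValueError("peripheral_bias must be in [0, 1]")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")


def gen_condensate_image(
    config: SimConfig,
    nucleus_axes: tuple[float, float] = (6.0, 4.5),
    truth: CondensateTruth = CondensateTruth(n_clusters=5),
    background_level: float = 0.0,
    dna_pattern: str = "uniform",
    base_intensity: float = 100.0,
    noise_sd: float = 0.0,
    max_retries: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render (marker_img, dna_img, nucleus_mask, cluster_truth_mask).

    The marker is ``base_intensity`` inside the nucleus and a brighter
    constant inside clusters, solved so that the cluster:nucleus mean
    ratio on the noiseless truth masks equals ``enrichment_true``
    exactly; the marker is zero outside the nucleus, with
    ``background_level`` added everywhere.  Cluster centers are drawn in
    elliptical coordinates with the radial density set by
    ``peripheral_bias`` and redrawn (up to ``max_retries``) if they would
    overlap the nucleus boundary or one another.
    """
    a, b = nucleus_axes  # μm semi-axes (x, y)
    if a <= 0 or b <= 0:
        raise ValueError("nucleus_axes must be positive")
    px = config.pixel_size
    rng = config.rng("condensate")

    margin_px = 2
    ny = 2 * (int(np.ceil(b / px)) + margin_px) + 1
    nx = 2 * (int(np.ceil(a / px)) + margin_px) + 1
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    y = (np.arange(ny) - cy) * px
    x = (np.arange(nx) - cx) * px
    yy, xx = np.meshgrid(y, x, indexing="ij")
    nucleus_mask = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    if not nucleus_mask.any():
        raise ValueError("nucleus does not fit in the image")

    r_c = truth.cluster_radius
    # shrink the placement ellipse so a whole cluster disk always fits
    a_eff, b_eff = a - r_c - px, b - r_c - px
    if truth.n_clusters > 0 and (a_eff <= 0 or b_eff <= 0):
        raise ValueError("cluster_radius too large for the nucleus")

    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < truth.n_clusters:
        if attempts > max_retries + truth.n_clusters:
            raise RuntimeError("could not place clusters without overlap")
        attempts += 1
        u = rng.uniform()
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rho = (1.0 - truth.peripheral_bias) * np.sqrt(u) + truth.peripheral_bias
        cxy = (rho * a_eff * np.cos(theta), rho * b_eff * np.sin(theta))
        if any(np.hypot(cxy[0] - ox, cxy[1] - oy) < 2 * r_c
               for ox, oy in centers):
            continue
        centers.append(cxy)

    cluster_mask = np.zeros_like(nucleus_mask)
    for ox, oy in centers:
        cluster_mask |= np.hypot(xx - ox, yy - oy) <= r_c
    cluster_mask &= nucleus_mask

    n_pix = int(nucleus_mask.sum())
    a_pix = int(cluster_mask.sum())
    e = truth.enrichment_true
    marker = np.zeros((ny, nx))
    base = base_intensity
    if a_pix and e > 1.0:
        if n_pix <= e * a_pix:
            raise ValueError("clusters cover too much area for this enrichment")
        v = e * base * (n_pix - a_pix) / (n_pix - e * a_pix)
        marker[nucleus_mask] = base
        marker[cluster_mask] = v
    else:
        marker[nucleus_mask] = base

    dna = np.zeros((ny, nx))
    dna[nucleus_mask] = base
    if dna_pattern == "rim_enriched":
        rho_n = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
        rim = nucleus_mask & (rho_n > 0.8)
        dna[rim] *= 1.5
    elif dna_pattern != "uniform":
        raise ValueError(f"unknown dna_pattern: {dna_pattern!r}")

    marker += background_level
    dna += background_level
    if noise_sd > 0:
        marker = np.clip(marker + rng.normal(0, noise_sd, marker.shape), 0, None)
        dna = np.clip(dna + rng.normal(0, noise_sd, dna.shape), 0, None)
    return marker, dna, nucleus_mask, cluster_mask
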