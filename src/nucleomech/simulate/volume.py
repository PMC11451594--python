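"""Digitized ellipsoid nuclei with closed-form volume and surface area."""

from __future__ import annotations

import numpy as np

from ..config import SimConfig
from ..morphometry import LabelVolume

__all__ = ["gen_nucleus_volume", "thomsen_area"]


def thomsen_area(c: float, b: float, a: float, p: float = 1.6075) -> float:
    """Thomsen approximation of the ellipsoid surface area (≤ ~1% error)."""
    return float(
        4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0)
        ** (1.0 / p)
    )


def gen_nucleus_volume(
    config: SimConfig,
    semi_axes: tuple[float, float, float],
    label: int = 1,
    margin_voxels: int = 2,
) -> tuple[LabelVolume, float, float]:
    """Voxelize an axis-aligned ellipsoid nucleus.

    ``semi_axes`` are (c, b, a) in μm along (z, y, x).  A voxel is labelled
    iff its center lies inside the ellipsoid.  Returns (labels,
    analytic_volume, analytic_area) with the exact (4/3)πabc volume and
    the Thomsen surface-area approximation.
    """
    c, b, a = semi_axes
    if min(semi_axes) <= 0:
        raise ValueError("semi-axes must be positive")
    vz, vy, vx = config.voxel_size
    nz = 2 * (int(np.ceil(c / vz)) + margin_voxels) + 1
    ny = 2 * (int(np.ceil(b / vy)) + margin_voxels) + 1
    nx = 2 * (int(np.ceil(a / vx)) + margin_voxels) + 1
    zc, yc, xc = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    z = (np.arange(nz) - zc) * vz
    y = (np.arange(ny) - yc) * vy
    x = (np.arange(nx) - xc) * vx
    inside = (
        (z[:, None, None] / c) ** 2
        + (y[None, :, None] / b) ** 2
        + (x[None, None, :] / a) ** 2
    ) <= 1.0
    labels = np.where(inside, label, 0).astype(np.int32)
    volume = 4.0 / 3.0 * np.pi * a * b * c
    return LabelVolume(labels, (vz, vy, vx)), float(volume), thomsen_area(c, b, a)
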