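"""3D nuclear morphometry from calibrated voxel label masks.

Volume, height, surface area and surface-to-volume ratio per labelled
nucleus, plus relative volume time courses.  Surface area is measured on
a marching-cubes isosurface because summed voxel-face area overestimates
smooth surfaces by up to ~50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

__all__ = [
    "LabelVolume",
    "MorphometryRecord",
    "measure_volume",
    "measure_height",
    "measure_surface_area",
    "measure_label",
    "relative_volume_timecourse",
]


@dataclass
class LabelVolume:
    """Calibrated 3D label mask: ``labels`` (z, y, x) ints, 0 = background."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]  # (z, y, x) μm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths")

    def mask(self, label: int) -> np.ndarray:
        m = self.labels == label
        if label == 0 or not m.any():
            raise ValueError(f"label {label} not present")
        return m

    @property
    def voxel_volume(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx


def measure_volume(vol: LabelVolume, label: int) -> float:
    """Volume in μm³: voxel count × voxel volume."""
    return float(vol.mask(label).sum()) * vol.voxel_volume


def measure_height(vol: LabelVolume, label: int, robust: bool = False) -> float:
    """Axial (z) extent in μm: (z_max − z_min + 1) × z step.

    ``robust=True`` uses the 5th–95th percentile of the per-voxel z index
    instead of the full extent, damping single-voxel outliers.
    """
    zs = np.nonzero(vol.mask(label).any(axis=(1, 2)))[0]
    if robust:
        occupied = np.nonzero(vol.mask(label))[0]
        lo, hi = np.percentile(occupied, [5, 95])
        return float(hi - lo + 1) * vol.voxel_size[0]
    return float(zs.max() - zs.min() + 1) * vol.voxel_size[0]


def measure_surface_area(vol: LabelVolume, label: int) -> float:
    """Surface area in μm² from a triangulated isosurface at level 0.5.

    Degenerate masks without interior fall back to summed exposed
    voxel-face area (a warning flags the fallback).
    """
    m = vol.mask(label)
    padded = np.pad(m.astype(np.float32), 2)
    # mild smoothing de-aliases the staircased binary isosurface, which
    # otherwise overestimates smooth surfaces by ~8%
    padded = ndimage.gaussian_filter(padded, sigma=1.0)
    try:
        verts, faces, _, _ = marching_cubes(padded, level=0.5,
                                            spacing=vol.voxel_size)
        return float(mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        warnings.warn(
            f"label {label}: degenerate mask, using exposed voxel-face area",
            stacklevel=2,
        )
        return _voxel_face_area(m, vol.voxel_size)


def _voxel_face_area(mask: np.ndarray, voxel_size) -> float:
    vz, vy, vx = voxel_size
    face = {0: vy * vx, 1: vz * vx, 2: vz * vy}
    total = 0.0
    padded = np.pad(mask, 1)
    for axis in range(3):
        d = np.diff(padded.astype(np.int8), axis=axis)
        total += float(np.abs(d).sum()) * face[axis]
    return total


def measure_label(vol: LabelVolume, label: int) -> "MorphometryRecord":
    v = measure_volume(vol, label)
    a = measure_surface_area(vol, label)
    return MorphometryRecord(
        label=label,
        volume=v,
        height=measure_height(vol, label),
        surface_area=a,
        sv_ratio=a / v,
    )


@dataclass
class MorphometryRecord:
    label: int
    volume: float  # μm³
    height: float  # μm
    surface_area: float  # μm²
    sv_ratio: float  # 1/μm


def relative_volume_timecourse(series: list[LabelVolume], label: int) -> np.ndarray:
    """Volume(t)/Volume(0) per time point; NaN marks frames where the
    label is missing (gaps are not interpolated)."""
    if not series:
        raise ValueError("empty time series")
    vols = np.full(len(series), np.nan)
    for i, vol in enumerate(series):
        try:
            vols[i] = measure_volume(vol, label)
        except ValueError:
            continue
    if np.isnan(vols[0]):
        raise ValueError(f"label {label} missing at t=0")
    return vols / vols[0]
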