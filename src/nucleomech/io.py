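"""Readers and writers for the package's on-disk formats.

Movies and label stacks are multi-page TIFF (via tifffile); tracks and
force curves are headered CSV; peak sets are BED4 plus a signal CSV keyed
by peak name; truth/config sidecars are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "write_movie",
    "read_movie",
    "write_labels",
    "read_labels",
    "write_bed",
    "read_bed",
    "write_yaml",
    "read_yaml",
]


def write_movie(path, frames: np.ndarray, pixel_size: float | None = None,
                frame_interval: float | None = None) -> None:
    """Write a (T, H, W) movie as multi-page TIFF with resolution metadata."""
    meta = {"axes": "TYX"}
    if frame_interval is not None:
        meta["finterval"] = frame_interval
    kwargs = {}
    if pixel_size is not None:
        kwargs["resolution"] = (1.0 / pixel_size, 1.0 / pixel_size)
        meta["unit"] = "um"
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32),
                     imagej=True, metadata=meta, **kwargs)


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def write_labels(path, labels: np.ndarray,
                 voxel_size: tuple[float, float, float] | None = None) -> None:
    meta = {"axes": "ZYX"}
    kwargs = {}
    if voxel_size is not None:
        vz, vy, vx = voxel_size
        kwargs["resolution"] = (1.0 / vx, 1.0 / vy)
        meta.update({"spacing": vz, "unit": "um"})
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16),
                     imagej=True, metadata=meta, **kwargs)


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path)


def write_bed(path, intervals: pd.DataFrame) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in intervals.columns:
        cols.append("name")
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
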