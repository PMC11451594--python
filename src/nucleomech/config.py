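"""Shared acquisition/simulation configuration.

Units throughout the package: lengths in micrometres (μm), times in
seconds (s), forces in newtons (N) unless a field name says otherwise
(AFM deflections are conventionally reported in nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimConfig"]


@dataclass(frozen=True)
class SimConfig:
    """Calibration shared by all synthetic acquisition modalities.

    Parameters
    ----------
    seed:
        Seed for the pseudo-random stream.  Identical seed and parameters
        produce bit-identical output.
    pixel_size:
        Lateral sampling, μm per pixel.  Default 0.1 μm emulates a 63x/100x
        spinning-disc acquisition.
    frame_interval:
        Time between frames, s.  Default 0.15 s matches fast envelope
        imaging; particle tracking uses 0.1 s.
    voxel_size:
        (z, y, x) voxel edge lengths in μm for 3D stacks.
    """

    seed: int = 0
    pixel_size: float = 0.1
    frame_interval: float = 0.15
    voxel_size: tuple[float, float, float] = (0.25, 0.1, 0.1)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths")

    def rng(self, stream: str = "") -> np.random.Generator:
        """Independent seeded generator for a named modality stream.

        Each modality draws from its own stream so that adding draws in one
        generator never perturbs another (tests stay decoupled).
        """
        ss = np.random.SeedSequence(self.seed, spawn_key=())
        if stream:
            # Derive a child deterministically from the stream name.
            key = [ord(c) for c in stream]
            ss = np.random.SeedSequence(entropy=self.seed, spawn_key=tuple(key))
        return np.random.default_rng(ss)
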