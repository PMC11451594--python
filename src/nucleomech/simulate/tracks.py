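"""Synthetic nanoparticle trajectories with known rheological ground truth.

Emulates single-plane tracking of genetically encoded multimeric
nanoparticles (GEMs) in the nucleoplasm: 2D trajectories whose ensemble
mean squared displacement follows MSD(t) = 4 D t^alpha, optionally
confined and blurred by localization noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..rheology import TrackSet
from ._fbm import fgn

__all__ = ["TrackTruth", "gen_tracks"]


@dataclass(frozen=True)
class TrackTruth:
    """Ground-truth transport parameters for a simulated track set.

    D_true is the generalized diffusivity in μm²/s^alpha; alpha_true is the
    anomalous exponent (1 = Brownian, <1 subdiffusive, 2 ballistic);
    loc_noise is the per-coordinate localization error sd in μm;
    confinement_radius is a reflecting circular boundary in μm
    (``inf`` = unbounded).
    """

    D_true: float
    alpha_true: float = 1.0
    loc_noise: float = 0.0
    confinement_radius: float = np.inf

    def __post_init__(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be non-negative")
        if not 0.0 < self.alpha_true <= 2.0:
            raise ValueError("alpha_true must be in (0, 2]")
        if self.loc_noise < 0:
            raise ValueError("loc_noise must be non-negative")


def _positions(truth: TrackTruth, n_tracks: int, n_steps: int, dt: float,
               rng: np.random.Generator) -> np.ndarray:
    """Noise-free positions, shape (n_tracks, n_steps, 2), starting at 0."""
    alpha = truth.alpha_true
    n_inc = n_steps - 1
    # per-axis displacement variance at time t is 2 D t^alpha
    if truth.D_true == 0.0:
        return np.zeros((n_tracks, n_steps, 2))
    if alpha == 1.0:
        sd = np.sqrt(2.0 * truth.D_true * dt)
        inc = rng.standard_normal((n_tracks, n_inc, 2)) * sd
    elif alpha == 2.0:
        # fBm with H=1 degenerates to a random straight line
        vel = rng.standard_normal((n_tracks, 1, 2)) * np.sqrt(2.0 * truth.D_true)
        inc = np.broadcast_to(vel * dt, (n_tracks, n_inc, 2)).copy()
    else:
        scale = np.sqrt(2.0 * truth.D_true) * dt ** (alpha / 2.0)
        inc = np.empty((n_tracks, n_inc, 2))
        for ax in range(2):
            inc[:, :, ax] = scale * fgn(n_inc, alpha / 2.0, n_tracks, rng)
    pos = np.zeros((n_tracks, n_steps, 2))
    pos[:, 1:] = np.cumsum(inc, axis=1)
    return pos


def _reflect_radial(pos: np.ndarray, radius: float) -> np.ndarray:
    """Fold radial coordinate back inside a circle of given radius."""
    r = np.hypot(pos[..., 0], pos[..., 1])
    out = pos.copy()
    mask = r > 0
    for _ in range(64):
        r = np.hypot(out[..., 0], out[..., 1])
        over = r > radius
        if not over.any():
            break
        scale = np.where(over & mask, (2.0 * radius - r) / np.where(r > 0, r, 1.0), 1.0)
        scale = np.clip(scale, -1.0, None)
        out = out * scale[..., None]
    return out


def gen_tracks(config: SimConfig, n_tracks: int, n_steps: int,
               truth: TrackTruth) -> TrackSet:
    """Simulate 2D particle trajectories with MSD(t) = 4·D·t^alpha.

    Brownian motion (alpha = 1) uses independent Gaussian increments;
    anomalous motion uses exact fractional Brownian motion (circulant
    embedding), so exponent-recovery tests inherit no generator bias.
    Localization noise is added i.i.d. per coordinate after an optional
    radial reflection at ``confinement_radius``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = config.rng("tracks")
    dt = config.frame_interval
    pos = _positions(truth, n_tracks, n_steps, dt, rng)
    if np.isfinite(truth.confinement_radius):
        pos = _reflect_radial(pos, truth.confinement_radius)
    if truth.loc_noise > 0:
        pos = pos + rng.standard_normal(pos.shape) * truth.loc_noise
    t = np.arange(n_steps) * dt
    frames = []
    for i in range(n_tracks):
        frames.append(pd.DataFrame({
            "track_id": i,
            "t": t,
            "x": pos[i, :, 0],
            "y": pos[i, :, 1],
        }))
    df = pd.concat(frames, ignore_index=True)
    return TrackSet(df, frame_interval=dt)
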