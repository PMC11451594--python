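"""Nuclear-envelope fluctuation quantification from fast time-lapse movies.

The statistic is the standard deviation of the envelope position about its
temporal mean, sampled along lines perpendicular to the envelope at
several locations per nucleus, after photobleaching correction and
rigid rotational-drift correction.  Larger values indicate a floppier
(less taut) envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate, warp_polar

__all__ = [
    "NucleusMovie",
    "SamplingNormal",
    "EdgeProfileSeries",
    "FluctuationResult",
    "bleach_correct",
    "correct_rigid_drift",
    "place_normals",
    "track_edge",
    "fluctuation_std",
    "quantify_nucleus",
]

MIN_VALID_FRAMES = 10


@dataclass
class NucleusMovie:
    """Time-lapse of one membrane-labelled nucleus.

    frames: (T, H, W) intensities; frame_interval in s; pixel_size in μm/px.
    """

    frames: np.ndarray
    frame_interval: float = 0.15
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be (T, H, W) with T >= 2")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SamplingNormal:
    """Line perpendicular to the envelope: anchor (y, x) px, unit direction."""

    anchor: tuple[float, float]
    direction: tuple[float, float]
    half_length: float  # μm

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.direction))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("direction must be a unit vector")


@dataclass
class EdgeProfileSeries:
    """Signed envelope position (μm) along one normal, per frame."""

    edge_position: np.ndarray
    valid: np.ndarray


@dataclass
class FluctuationResult:
    per_normal_std: np.ndarray  # μm, NaN where a normal failed
    nucleus_mean_std: float  # μm
    n_normals: int


def bleach_correct(movie: NucleusMovie) -> NucleusMovie:
    """Simple-ratio bleaching correction.

    Each frame is multiplied by mean(frame 0)/mean(frame t), so the
    frame-mean intensity is constant across the corrected movie.
    """
    means = movie.frames.mean(axis=(1, 2))
    if np.any(means <= 0):
        raise ValueError("frame with non-positive mean intensity")
    scale = means[0] / means
    return NucleusMovie(movie.frames * scale[:, None, None],
                        movie.frame_interval, movie.pixel_size)


def _intensity_centroid(frame: np.ndarray) -> tuple[float, float]:
    total = frame.sum()
    if total <= 0:
        raise ValueError("frame has no intensity")
    yy, xx = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
    return float((yy * frame).sum() / total), float((xx * frame).sum() / total)


def _contour_profiles(frames: np.ndarray, n_phi: int = 360) -> np.ndarray:
    """Envelope radius r(φ) per frame, shape (T, n_phi), px units."""
    cy, cx = _intensity_centroid(frames[0])
    r_max = min(cy, cx, frames.shape[1] - 1 - cy, frames.shape[2] - 1 - cx)
    radii = np.arange(1.0, r_max, 1.0)
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    ys = cy + radii[None, :] * np.sin(phis)[:, None]
    xs = cx + radii[None, :] * np.cos(phis)[:, None]
    coords = np.stack([ys.ravel(), xs.ravel()])
    out = np.empty((frames.shape[0], n_phi))
    for t in range(frames.shape[0]):
        prof = ndimage.map_coordinates(frames[t], coords, order=1)
        prof = prof.reshape(n_phi, radii.size)
        idx = np.clip(np.argmax(prof, axis=1), 1, radii.size - 2)
        rows = np.arange(n_phi)
        y0 = prof[rows, idx - 1]
        y1 = prof[rows, idx]
        y2 = prof[rows, idx + 1]
        denom = y0 - 2 * y1 + y2
        frac = np.where(denom == 0, 0.0, 0.5 * (y0 - y2) / np.where(denom == 0, 1.0, denom))
        out[t] = radii[idx] + np.clip(frac, -0.5, 0.5)
    return out


def estimate_rotational_drift(movie: NucleusMovie, n_harmonics: int = 8,
                              max_lag: int = 12) -> float:
    """Linear rotational drift rate in degrees/frame.

    The envelope radius profile r_t(φ) is a circular signal whose rigid
    rotation by ω per frame advances every circular harmonic k by phase
    2πkωL/N between frames L apart.  The rate is estimated from the
    lag-L cross-spectra pooled over all frame pairs and harmonics,
    weighted by cross power — robust to the envelope shape fluctuating on
    top of the drift.  A featureless (circularly symmetric) envelope has
    no angular signal; the estimate is then 0.
    """
    prof = _contour_profiles(movie.frames)
    prof = prof - prof.mean(axis=1, keepdims=True)
    n_phi = prof.shape[1]
    n = prof.shape[0]
    spec = np.fft.rfft(prof, axis=1)
    ks = np.arange(1, min(n_harmonics, spec.shape[1] - 1) + 1)
    num = 0.0
    den = 0.0
    for lag in range(1, min(max_lag, n - 1) + 1):
        cross = np.sum(spec[:-lag, ks] * np.conj(spec[lag:, ks]), axis=0)
        power = np.abs(cross)
        if power.sum() <= 0:
            continue
        # angle(cross_k) = +2π k ω lag / N; phase noise ~ 1/(power·k·lag)
        rates = np.angle(cross) * n_phi / (2.0 * np.pi * ks * lag)
        w = power * (ks * lag) ** 2
        num += float(np.sum(w * rates))
        den += float(np.sum(w))
    if den <= 0:
        return 0.0
    return (num / den) * 360.0 / n_phi


def correct_rigid_drift(
    movie: NucleusMovie,
    corr_threshold: float = 0.2,
) -> tuple[NucleusMovie, np.ndarray]:
    """Remove linear rotational drift about the nucleus centroid.

    The drift rate is estimated with :func:`estimate_rotational_drift`
    (linear drift model, as produced by slow stage/colony rotation) and
    each frame is counter-rotated by rate·t about the intensity centroid.
    Returns the corrected movie and the applied rotation per frame in
    degrees.  Frames whose post-correction correlation with frame 0 falls
    below ``corr_threshold`` are flagged with NaN in the rotation vector.
    """
    frames = movie.frames
    n = frames.shape[0]
    cy, cx = _intensity_centroid(frames[0])
    rate = estimate_rotational_drift(movie)
    tt = np.arange(n, dtype=float)
    # rotate()'s positive direction is opposite to the (row, col) angular
    # convention of the drift estimate; the correction reported to the
    # caller is the signed rotation in the movie's own convention.
    applied = rate * tt
    corrected = np.empty_like(frames)
    rotations = -applied
    ref = frames[0]
    ref_norm = ref - ref.mean()
    for t in range(n):
        corrected[t] = (
            frames[t] if applied[t] == 0.0
            else rotate(frames[t], applied[t], center=(cx, cy), order=1,
                        mode="constant", cval=0.0, preserve_range=True)
        )
        f = corrected[t] - corrected[t].mean()
        denom = np.linalg.norm(ref_norm) * np.linalg.norm(f)
        corr = float((ref_norm * f).sum() / denom) if denom > 0 else 0.0
        if corr < corr_threshold:
            rotations[t] = np.nan
    return (
        NucleusMovie(corrected, movie.frame_interval, movie.pixel_size),
        rotations,
    )


def _radial_ridge(profile: np.ndarray, radii: np.ndarray) -> float:
    """Subpixel radius of the ridge maximum via 3-point quadratic fit."""
    i = int(np.argmax(profile))
    if i == 0 or i == profile.size - 1:
        return float("nan")
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    frac = float(np.clip(frac, -0.5, 0.5))
    return float(radii[i] + frac * (radii[1] - radii[0]))


def _detect_contour(reference: np.ndarray, n_points: int = 720) -> np.ndarray:
    """Closed envelope contour as (n_points, 2) (y, x) px, star-convex."""
    if reference.max() <= reference.min():
        raise ValueError("no contour detectable: flat reference frame")
    cy, cx = _intensity_centroid(reference)
    r_max = min(cy, cx, reference.shape[0] - 1 - cy, reference.shape[1] - 1 - cx)
    radii = np.arange(1.0, r_max, 0.5)
    phis = 2 * np.pi * np.arange(n_points) / n_points
    pts = np.empty((n_points, 2))
    for k, phi in enumerate(phis):
        ys = cy + radii * np.sin(phi)
        xs = cx + radii * np.cos(phi)
        prof = ndimage.map_coordinates(reference, np.stack([ys, xs]), order=1)
        r = _radial_ridge(prof, radii)
        if np.isnan(r):
            raise ValueError("no closed contour: ridge lost at angle "
                             f"{np.rad2deg(phi):.1f} deg")
        pts[k] = (cy + r * np.sin(phi), cx + r * np.cos(phi))
    return pts


def place_normals(reference_frame: np.ndarray, n_normals: int,
                  half_length: float, pixel_size: float = 0.1) -> list[SamplingNormal]:
    """Place ``n_normals`` outward normals equally spaced in arc length.

    A closed envelope contour is detected on the reference frame (ridge
    maximum along rays from the intensity centroid); anchors are placed at
    equal arc-length intervals and directions are the outward local contour
    normals.
    """
    if n_normals == 0:
        return []
    pts = _detect_contour(reference_frame)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = total * np.arange(n_normals) / n_normals
    cy, cx = pts.mean(axis=0)
    normals = []
    for s in targets:
        k = int(np.searchsorted(arc, s, side="right") - 1) % pts.shape[0]
        anchor = pts[k]
        # wide stencil: adjacent contour points are sub-pixel apart, so a
        # short-baseline tangent would amplify ridge-detection noise
        stencil = max(1, pts.shape[0] // 144)
        prv = pts[(k - stencil) % pts.shape[0]]
        nxt = pts[(k + stencil) % pts.shape[0]]
        tangent = nxt - prv
        tangent = tangent / np.linalg.norm(tangent)
        nrm = np.array([-tangent[1], tangent[0]])
        if np.dot(nrm, anchor - np.array([cy, cx])) < 0:
            nrm = -nrm
        normals.append(SamplingNormal(
            anchor=(float(anchor[0]), float(anchor[1])),
            direction=(float(nrm[0]), float(nrm[1])),
            half_length=half_length,
        ))
    return normals


def track_edge(movie: NucleusMovie, normal: SamplingNormal,
               oversample: float = 2.0) -> EdgeProfileSeries:
    """Record the subpixel envelope position along one normal over time.

    Intensity is sampled along the normal by linear interpolation; the
    envelope position per frame is the quadratic-refined ridge maximum.
    Frames whose maximum sits at the sampling-window boundary are invalid.
    Positions are signed distances from the anchor in μm (positive =
    outward).
    """
    px = movie.pixel_size
    step = px / oversample
    s = np.arange(-normal.half_length, normal.half_length + step / 2, step)
    ay, ax = normal.anchor
    dy, dx = normal.direction
    ys = ay + (s / px) * dy
    xs = ax + (s / px) * dx
    coords = np.stack([ys, xs])
    n = movie.n_frames
    pos = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for t in range(n):
        prof = ndimage.map_coordinates(movie.frames[t], coords, order=1)
        e = _radial_ridge(prof, s)
        if not np.isnan(e):
            pos[t] = e
            valid[t] = True
    if not valid.any():
        raise ValueError("edge left the sampling window in every frame")
    return EdgeProfileSeries(edge_position=pos, valid=valid)


def fluctuation_std(series: EdgeProfileSeries) -> float:
    """Sample sd (ddof=1, μm) of the envelope position over valid frames."""
    vals = series.edge_position[series.valid]
    if vals.size < MIN_VALID_FRAMES:
        raise ValueError(
            f"need >= {MIN_VALID_FRAMES} valid frames, got {vals.size}"
        )
    return float(np.std(vals, ddof=1))


def quantify_nucleus(movie: NucleusMovie, n_normals: int = 8,
                     half_length: float = 1.0) -> FluctuationResult:
    """Full per-nucleus pipeline.

    bleach_correct → correct_rigid_drift → place_normals on the temporal
    mean frame → track_edge and fluctuation_std per normal; the summary is
    the mean per-normal sd over normals that produced a valid series.
    """
    try:
        corrected = bleach_correct(movie)
    except ValueError as exc:
        raise ValueError(f"bleach correction failed: {exc}") from exc
    corrected, _ = correct_rigid_drift(corrected)
    reference = corrected.frames.mean(axis=0)
    normals = place_normals(reference, n_normals, half_length,
                            corrected.pixel_size)
    stds = np.full(len(normals), np.nan)
    for i, nrm in enumerate(normals):
        try:
            series = track_edge(corrected, nrm)
            stds[i] = fluctuation_std(series)
        except ValueError:
            continue
    if np.all(np.isnan(stds)):
        raise ValueError("edge tracking failed on every normal")
    return FluctuationResult(
        per_normal_std=stds,
        nucleus_mean_std=float(np.nanmean(stds)),
        n_normals=len(normals),
    )
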