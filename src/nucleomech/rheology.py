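"""Particle-tracking microrheology: MSD curves and power-law transport fits.

Works on 2D single-plane trajectories (GEM nanoparticles imaged in one
focal plane), so the transport convention throughout is

    MSD(t) = 4 · D_eff · t^b        [μm², s]

with b the diffusive (anomalous) exponent: b < 1 indicates subdiffusion /
confinement, b = 1 free Brownian motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "MSDResult",
    "PowerLawFit",
    "filter_tracks",
    "msd_per_track",
    "aggregate_msd",
    "fit_powerlaw",
    "analyze_tracks",
]


@dataclass
class TrackSet:
    """Collection of 2D trajectories.

    ``data`` holds columns ``track_id, t, x, y`` (t in s, x/y in μm) with t
    strictly increasing within each track.
    """

    data: pd.DataFrame
    frame_interval: float

    def __post_init__(self) -> None:
        required = {"track_id", "t", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        if self.data.empty:
            raise ValueError("track table is empty")
        for tid, grp in self.data.groupby("track_id"):
            if not np.all(np.diff(grp["t"].to_numpy()) > 0):
                raise ValueError(f"track {tid}: time not strictly increasing")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def groups(self):
        return self.data.groupby("track_id", sort=True)

    @classmethod
    def from_csv(cls, path, frame_interval: float | None = None) -> "TrackSet":
        """Read tracks from CSV with columns (track_id, t|frame, x, y).

        A ``frame`` column is converted to seconds using ``frame_interval``.
        """
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        ren = {}
        for want, aliases in {
            "track_id": ("track_id", "particle", "track"),
            "x": ("x", "x_um"),
            "y": ("y", "y_um"),
        }.items():
            for a in aliases:
                if a in cols:
                    ren[cols[a]] = want
                    break
        df = df.rename(columns=ren)
        if "t" not in df.columns and "t_s" in cols:
            df = df.rename(columns={cols["t_s"]: "t"})
        if "t" not in df.columns:
            if "frame" not in cols:
                raise ValueError("need a 't' or 'frame' column")
            if frame_interval is None:
                raise ValueError("frame_interval required with a 'frame' column")
            df["t"] = df[cols["frame"]].astype(float) * frame_interval
        if frame_interval is None:
            frame_interval = float(np.median(np.diff(np.unique(df["t"]))))
        return cls(df[["track_id", "t", "x", "y"]], frame_interval)


@dataclass
class MSDResult:
    """Time-averaged MSD per lag: ``lags`` s, ``msd`` μm², ``n_pairs`` counts."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags, "msd_um2": self.msd, "n_pairs": self.n_pairs}
        )


@dataclass
class PowerLawFit:
    """log-log least-squares fit MSD = 4·D_eff·t^b over ``fit_range`` lags."""

    D_eff: float
    b: float
    fit_range: tuple[int, int]
    r_squared: float
    D_first_lag: float = float("nan")


def filter_tracks(ts: TrackSet, min_length: int = 10) -> TrackSet:
    """Drop tracks shorter than ``min_length`` points, preserving order."""
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    sizes = ts.data.groupby("track_id", sort=False)["t"].transform("size")
    kept = ts.data[sizes >= min_length]
    if kept.empty:
        n = ts.n_tracks
        raise ValueError(f"no tracks of length >= {min_length} (had {n})")
    return TrackSet(kept.reset_index(drop=True), ts.frame_interval)


def _check_uniform(t: np.ndarray, rtol: float = 1e-3) -> float:
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > rtol * dt[0]):
        raise ValueError("non-uniform time spacing in track")
    return float(dt[0])


def msd_per_track(track: pd.DataFrame) -> MSDResult:
    """Time-averaged MSD of one track for lags k·Δt, k = 1..N−1.

    msd(kΔt) = mean over i of |r(i+k) − r(i)|².
    """
    t = track["t"].to_numpy(float)
    if t.size < 2:
        raise ValueError("track needs at least 2 points")
    dt = _check_uniform(t)
    xy = track[["x", "y"]].to_numpy(float)
    n = xy.shape[0]
    msd = np.empty(n - 1)
    n_pairs = np.empty(n - 1, dtype=int)
    for k in range(1, n):
        d = xy[k:] - xy[:-k]
        msd[k - 1] = np.mean(np.sum(d * d, axis=1))
        n_pairs[k - 1] = n - k
    return MSDResult(lags=np.arange(1, n) * dt, msd=msd, n_pairs=n_pairs)


def aggregate_msd(ts: TrackSet, weighted: bool = True) -> MSDResult:
    """Ensemble MSD pooled over tracks.

    With ``weighted`` (default) each lag is the n_pairs-weighted mean of
    per-track time-averaged MSDs — identical to pooling every displacement
    pair across tracks.  ``weighted=False`` averages tracks with equal
    weight instead.
    """
    per = [msd_per_track(g) for _, g in ts.groups()]
    if not per:
        raise ValueError("no tracks")
    n_lags = max(m.lags.size for m in per)
    lags = max(per, key=lambda m: m.lags.size).lags
    num = np.zeros(n_lags)
    den = np.zeros(n_lags)
    for m in per:
        k = m.lags.size
        w = m.n_pairs if weighted else np.ones(k)
        num[:k] += w * m.msd
        den[:k] += w
    if not np.any(den > 0):
        raise ValueError("no common lags across tracks")
    valid = den > 0
    return MSDResult(lags=lags[valid], msd=num[valid] / den[valid],
                     n_pairs=den[valid].astype(int))


def fit_powerlaw(msd: MSDResult, fit_fraction: float = 0.25) -> PowerLawFit:
    """Fit MSD = 4·D_eff·t^b by OLS on log msd vs log lag.

    Uses the first ceil(fit_fraction · n_lags) lags (minimum 3).  D_eff is
    the intercept-based estimate exp(intercept)/4; ``D_first_lag`` reports
    the alternative single-lag estimate msd(Δt)/(4·Δt^b).
    """
    n_fit = max(3, int(np.ceil(fit_fraction * msd.lags.size)))
    if msd.lags.size < 3:
        raise ValueError("need at least 3 lags to fit")
    n_fit = min(n_fit, msd.lags.size)
    lag = msd.lags[:n_fit]
    val = msd.msd[:n_fit]
    if np.any(val <= 0):
        raise ValueError(
            "non-positive MSD in fit range; check the localization-noise floor"
        )
    lx, ly = np.log(lag), np.log(val)
    b, intercept = np.polyfit(lx, ly, 1)
    pred = b * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_eff = float(np.exp(intercept) / 4.0)
    d_first = float(val[0] / (4.0 * lag[0] ** b))
    return PowerLawFit(D_eff=d_eff, b=float(b), fit_range=(0, n_fit),
                       r_squared=min(max(r2, 0.0), 1.0), D_first_lag=d_first)


def analyze_tracks(ts: TrackSet, min_length: int = 10,
                   fit_fraction: float = 0.25) -> tuple[MSDResult, PowerLawFit]:
    """Full pipeline: length filter → aggregate MSD → power-law fit."""
    kept = filter_tracks(ts, min_length=min_length)
    msd = aggregate_msd(kept)
    return msd, fit_powerlaw(msd, fit_fraction=fit_fraction)
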