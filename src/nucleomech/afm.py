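"""AFM force-indentation processing and Hertz-model fitting.

Pipeline per approach curve: straight-line baseline removal, contact-point
identification, cantilever-bending subtraction (indentation = piezo travel
past contact minus deflection), then a least-squares fit of the contact
law to obtain the apparent Young's modulus E at Poisson's ratio 0.5.

Tip models (E' = E/(1−ν²), δ in m, F in N):

    sphere (radius R):        F = (4/3)·E'·√R·δ^{3/2}
    four-sided pyramid (θ):   F = (tanθ/√2)·E'·δ²

The tip geometry is always an explicit configuration choice, never
inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceCurve",
    "IndentationCurve",
    "HertzFit",
    "TipModel",
    "baseline_correct",
    "find_contact_point",
    "to_indentation",
    "fit_hertz",
    "process_curve",
    "process_map",
]

NM = 1e-9
UM = 1e-6


@dataclass(frozen=True)
class TipModel:
    """Indenter geometry: ``kind`` in {"sphere", "pyramid"}.

    ``radius`` is the sphere radius in μm; ``half_angle`` the pyramid
    face half-angle in degrees.
    """

    kind: str
    radius: float = 0.02
    half_angle: float = 35.0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "pyramid"):
            raise ValueError("tip model must be 'sphere' or 'pyramid'")

    @property
    def exponent(self) -> float:
        return 1.5 if self.kind == "sphere" else 2.0

    def prefactor(self, E: float, nu: float) -> float:
        """C in F = C·δ^m with δ in metres, F in newtons."""
        e_red = E / (1.0 - nu**2)
        if self.kind == "sphere":
            return (4.0 / 3.0) * e_red * np.sqrt(self.radius * UM)
        return e_red * np.tan(np.deg2rad(self.half_angle)) / np.sqrt(2.0)

    def modulus(self, prefactor: float, nu: float) -> float:
        if self.kind == "sphere":
            return prefactor * (1.0 - nu**2) * 0.75 / np.sqrt(self.radius * UM)
        return prefactor * (1.0 - nu**2) * np.sqrt(2.0) / np.tan(
            np.deg2rad(self.half_angle))

    def force(self, delta_m: np.ndarray, E: float, nu: float) -> np.ndarray:
        return self.prefactor(E, nu) * np.clip(delta_m, 0.0, None) ** self.exponent


@dataclass
class ForceCurve:
    """Approach segment of one indentation: z_piezo (μm), deflection (nm)."""

    z_piezo: np.ndarray
    deflection: np.ndarray
    k_spring: float  # N/m
    approach: bool = True

    def __post_init__(self) -> None:
        self.z_piezo = np.asarray(self.z_piezo, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z_piezo.shape != self.deflection.shape:
            raise ValueError("z and deflection must have equal length")
        if self.k_spring <= 0:
            raise ValueError("spring constant must be positive")
        dz = np.diff(self.z_piezo)
        if dz.size and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z_piezo must be strictly monotone")
        if dz.size and dz[0] < 0:  # store approach in increasing-z order
            self.z_piezo = self.z_piezo[::-1].copy()
            self.deflection = self.deflection[::-1].copy()


@dataclass
class IndentationCurve:
    indentation: np.ndarray  # nm, >= 0
    force: np.ndarray  # N
    n_dropped: int = 0


@dataclass
class HertzFit:
    E: float  # Pa
    nu: float
    z0: float  # μm
    tip: TipModel
    rmse: float  # N
    max_indentation_used: float  # nm
    n_points: int


def baseline_correct(curve: ForceCurve,
                     baseline_fraction: float = 0.3) -> ForceCurve:
    """Fit a line to the first ``baseline_fraction`` of approach samples
    (assumed pre-contact) and subtract it from the whole deflection trace."""
    if not 0.0 < baseline_fraction <= 0.9:
        raise ValueError("baseline_fraction must be in (0, 0.9]")
    n = curve.z_piezo.size
    n_base = int(np.floor(baseline_fraction * n))
    if n_base < 10:
        raise ValueError(f"only {n_base} baseline samples; need >= 10")
    z, d = curve.z_piezo[:n_base], curve.deflection[:n_base]
    slope, offset = np.polyfit(z, d, 1)
    corrected = curve.deflection - (slope * curve.z_piezo + offset)
    return ForceCurve(curve.z_piezo.copy(), corrected, curve.k_spring,
                      curve.approach)


def find_contact_point(curve: ForceCurve, threshold_k: float = 5.0,
                       baseline_fraction: float = 0.3) -> float:
    """Contact point z0 (μm) of a baseline-corrected approach curve.

    The first z from which the deflection exceeds threshold_k × the
    baseline noise sd for all subsequent samples seeds the estimate; a
    local linear fit around the crossing is intersected with zero to
    refine below the sample spacing.  On noiseless curves the noise sd
    falls back to a small machine-level floor.
    """
    z, d = curve.z_piezo, curve.deflection
    n_base = max(int(np.floor(baseline_fraction * z.size)), 2)
    noise = float(np.std(d[:n_base]))
    floor = max(1e-9, 1e-6 * np.abs(d).max())
    level = max(threshold_k * noise, floor)
    above = d > level
    # persistent crossing: suffix all-above
    suffix_all = np.logical_and.accumulate(above[::-1])[::-1]
    idx = np.nonzero(suffix_all)[0]
    if idx.size == 0:
        raise ValueError("no contact detected")
    i = int(idx[0])
    # refine: straight line through the rise, intersected with zero
    j0, j1 = i, min(i + 5, z.size)
    if j1 - j0 >= 2 and np.ptp(d[j0:j1]) > 0:
        slope, off = np.polyfit(z[j0:j1], d[j0:j1], 1)
        if slope > 0:
            z0 = -off / slope
            if z[0] <= z0 <= z[min(j1, z.size - 1)]:
                return float(z0)
    return float(z[i])


def to_indentation(curve: ForceCurve, z0: float,
                   tolerance_nm: float = 0.0) -> IndentationCurve:
    """Convert a baseline-corrected curve to indentation vs force.

    For post-contact samples (z ≥ z0): δ = (z − z0) − d (cantilever
    bending subtracted) and F = k·d.  Samples whose computed indentation
    is negative beyond ``tolerance_nm`` are dropped and counted.
    """
    z, d = curve.z_piezo, curve.deflection
    if not (z[0] <= z0 <= z[-1]):
        raise ValueError("contact point outside curve range")
    post = z >= z0
    delta_nm = (z[post] - z0) * 1e3 - d[post]
    force = curve.k_spring * d[post] * NM
    keep = delta_nm >= -tolerance_nm
    n_dropped = int(np.sum(~keep))
    delta_nm = np.clip(delta_nm[keep], 0.0, None)
    return IndentationCurve(delta_nm, force[keep], n_dropped)


def fit_hertz(ind: IndentationCurve, tip: TipModel, nu: float = 0.5,
              max_depth: float = 500.0, min_points: int = 20) -> HertzFit:
    """Least-squares contact-law fit over indentations up to ``max_depth`` nm.

    The contact law is linear in the prefactor C of F = C·δ^m, so the fit
    is the closed-form projection C = Σ F δ^m / Σ δ^{2m}; E follows from
    the tip geometry.
    """
    sel = (ind.indentation > 0) & (ind.indentation <= max_depth)
    if int(sel.sum()) < min_points:
        raise ValueError(
            f"only {int(sel.sum())} samples with 0 < δ <= {max_depth} nm "
            f"(need {min_points})"
        )
    delta_m = ind.indentation[sel] * NM
    force = ind.force[sel]
    basis = delta_m ** tip.exponent
    denom = float(np.sum(basis * basis))
    if denom == 0:
        raise ValueError("degenerate indentation range")
    c = float(np.sum(force * basis)) / denom
    if c < 0:
        raise ValueError(f"negative fitted modulus (C={c:.3e})")
    resid = force - c * basis
    return HertzFit(
        E=tip.modulus(c, nu),
        nu=nu,
        z0=float("nan"),
        tip=tip,
        rmse=float(np.sqrt(np.mean(resid**2))),
        max_indentation_used=float(delta_m.max() / NM),
        n_points=int(sel.sum()),
    )


def _fit_at_z0(curve: ForceCurve, z0: float, tip: TipModel, nu: float,
               max_depth: float, min_points: int) -> HertzFit:
    fit = fit_hertz(to_indentation(curve, z0), tip, nu, max_depth, min_points)
    return replace(fit, z0=z0)


def process_curve(curve: ForceCurve, tip: TipModel, nu: float = 0.5,
                  max_depth: float = 500.0, baseline_fraction: float = 0.3,
                  threshold_k: float = 5.0, refine_z0: bool = True,
                  min_points: int = 20) -> HertzFit:
    """Full single-curve pipeline with optional joint (E, z0) refinement.

    The threshold contact point seeds a bounded 1-D search over z0
    minimizing the fit rmse (threshold-only contact points bias E at low
    SNR); the seeded estimate is kept whenever refinement does not lower
    the rmse.
    """
    corrected = baseline_correct(curve, baseline_fraction)
    z0 = find_contact_point(corrected, threshold_k, baseline_fraction)
    try:
        best = _fit_at_z0(corrected, z0, tip, nu, max_depth, min_points)
    except ValueError:
        if not refine_z0:
            raise
        best = None  # a late/noisy seed can fail; refinement may still fit
    if refine_z0:
        z = corrected.z_piezo
        d = corrected.deflection
        dz = float(np.median(np.diff(z)))
        # fixed evaluation span: pre-contact flat plus the full rise up to
        # ~max_depth past the seeded contact.  Evaluating every candidate
        # on the same samples with the piecewise model (zero force before
        # contact) keeps the objective from collapsing onto a baseline-only
        # window, where any C fits with zero residual.  The search reaches
        # back to the end of the assumed-pre-contact baseline region: at
        # high noise the threshold seed can be arbitrarily late.
        lo = z[min(int(np.floor(baseline_fraction * z.size)), z.size - 2)]
        delta_seed = (z - z0) * 1e3 - d
        past = np.nonzero(delta_seed >= max_depth)[0]
        hi_idx = int(past[0]) if past.size else z.size - 1
        # a spuriously early seed would end the span before the contact
        # rise; always cover the climb to half the peak deflection
        half_rise = np.nonzero(d >= 0.5 * d.max())[0]
        z_half = z[int(half_rise[0])] if half_rise.size else z[-1]
        hi_idx = max(hi_idx, int(half_rise[0])) if half_rise.size else hi_idx
        span = (z >= lo) & (z <= z[hi_idx])
        z_s, d_s = z[span], d[span]
        force_s = curve.k_spring * d_s * NM
        m = tip.exponent

        def objective(zz: float) -> float:
            delta_m = np.clip((z_s - zz) * 1e3 - d_s, 0.0, None) * NM
            fit_sel = (delta_m > 0) & (delta_m <= max_depth * NM)
            if int(fit_sel.sum()) < min_points:
                return np.inf
            basis = delta_m[fit_sel] ** m
            c = float(np.sum(force_s[fit_sel] * basis) / np.sum(basis**2))
            if c < 0:
                return np.inf
            resid = force_s - c * delta_m**m
            return float(np.sqrt(np.mean(resid**2)))

        # contact lies between the baseline end and the half-rise point,
        # whatever the quality of the threshold seed
        hi = min(z[-1] - dz, max(z0 + 10 * dz, z_half))
        grid = np.linspace(lo, hi, 61)
        costs = np.array([objective(g) for g in grid])
        i = int(np.argmin(costs))
        if np.isfinite(costs[i]):
            res = minimize_scalar(
                objective, bounds=(grid[max(i - 1, 0)],
                                   grid[min(i + 1, grid.size - 1)]),
                method="bounded", options={"xatol": dz * 1e-3})
            cand = float(res.x) if res.success else float(grid[i])
            try:
                refined = _fit_at_z0(corrected, cand, tip, nu, max_depth,
                                     min_points)
                if best is None or refined.rmse <= best.rmse:
                    best = refined
            except ValueError:
                pass
    if best is None:
        raise ValueError("no valid Hertz fit at any candidate contact point")
    return best


def process_map(curves: list[ForceCurve], tip: TipModel, nu: float = 0.5,
                max_depth: float = 500.0,
                **kwargs) -> tuple[list[HertzFit], float, list[str]]:
    """Fit every curve of a force map; returns (fits, median E, skip reasons).

    Invalid curves (no contact, too few post-contact samples, negative
    modulus) are skipped with their reason recorded; the per-nucleus
    summary is the median E over valid fits.
    """
    if not curves:
        raise ValueError("no curves")
    fits: list[HertzFit] = []
    skipped: list[str] = []
    for i, curve in enumerate(curves):
        try:
            fits.append(process_curve(curve, tip, nu, max_depth, **kwargs))
        except ValueError as exc:
            skipped.append(f"curve {i}: {exc}")
    if not fits:
        raise ValueError("all curves invalid: " + "; ".join(skipped))
    return fits, float(np.median([f.E for f in fits])), skipped
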