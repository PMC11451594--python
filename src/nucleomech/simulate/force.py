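"""Synthetic AFM approach curves with known elastic modulus.

The cantilever–sample system is solved exactly: post-contact deflection d
satisfies the implicit force balance k·d = F_tip((z − z0) − d), so a
round-trip through the analysis pipeline is an exact oracle up to
discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..afm import NM, ForceCurve, TipModel

__all__ = ["HertzTruth", "gen_force_curve"]


@dataclass(frozen=True)
class HertzTruth:
    """Ground truth for one synthetic indentation.

    E_true in Pa; contact_point_true in μm (piezo coordinate); tip the
    indenter geometry; baseline_slope in nm deflection per μm of piezo
    travel (optical artifact); noise_sd in N of force noise.
    """

    E_true: float
    nu: float = 0.5
    contact_point_true: float = 2.0
    tip: TipModel = TipModel("pyramid")
    baseline_slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.E_true < 0:
            raise ValueError("E_true must be non-negative")
        if not 0.0 <= self.nu < 0.5 + 1e-9:
            raise ValueError("nu must be in [0, 0.5]")


def gen_force_curve(
    truth: HertzTruth,
    k_spring: float = 0.01,
    z_range: float = 4.0,
    n_points: int = 800,
    rng: np.random.Generator | None = None,
) -> ForceCurve:
    """Simulate one approach curve.

    z runs 0..z_range μm with ``n_points`` samples; pre-contact deflection
    is the linear baseline plus noise, post-contact deflection solves
    k·d = F_tip((z − z0) − d).  Gaussian force noise of sd ``noise_sd``
    (converted to deflection through k) is added throughout.
    """
    if k_spring <= 0:
        raise ValueError("spring constant must be positive")
    if z_range < truth.contact_point_true + 0.5:
        raise ValueError("z_range must cover the contact point + 0.5 μm")
    z = np.linspace(0.0, z_range, n_points)
    d_nm = np.zeros(n_points)
    if truth.E_true > 0:
        pre = truth.tip.prefactor(truth.E_true, truth.nu)
        m = truth.tip.exponent
        post = z > truth.contact_point_true
        travel_m = (z[post] - truth.contact_point_true) * 1e-6

        def solve(s: float) -> float:
            # g(d) = k d − pre·(s − d)^m, root in [0, s]
            g = lambda d: k_spring * d - pre * max(s - d, 0.0) ** m
            return brentq(g, 0.0, s, xtol=1e-18)

        d_nm[post] = np.array([solve(s) for s in travel_m]) / NM
    baseline = truth.baseline_slope * z
    d_nm = d_nm + baseline
    if truth.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        d_nm = d_nm + rng.normal(0.0, truth.noise_sd / k_spring / NM, n_points)
    return ForceCurve(z, d_nm, k_spring)
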