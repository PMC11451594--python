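"""Exact fractional Gaussian noise synthesis.

Davies–Harte circulant embedding gives exact finite-dimensional
distributions for fractional Gaussian noise (fGn) of any Hurst index
H in (0, 1); when the circulant eigenvalues are not all non-negative
(possible for H near 1 at small n) we fall back to a Cholesky
factorisation of the exact covariance, which is always valid.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fgn", "fbm_paths"]


def _fgn_autocov(n: int, hurst: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def fgn(n: int, hurst: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw `size` independent unit-step fGn sequences of length `n`.

    Returns an array of shape (size, n) whose rows are stationary Gaussian
    sequences with autocovariance gamma(k) = (|k+1|^{2H} - 2|k|^{2H} +
    |k-1|^{2H}) / 2, i.e. increments of standard fBm sampled at unit steps.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return rng.standard_normal((size, 1))
    gamma = _fgn_autocov(n, hurst)
    m = 2 * (n - 1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-10 * lam.max():
        return _fgn_cholesky(gamma, size, rng)
    lam = np.clip(lam, 0.0, None)
    half = m // 2
    out = np.empty((size, n))
    for i in range(size):
        w = np.zeros(m, dtype=complex)
        w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
        w[half] = np.sqrt(lam[half] / m) * rng.standard_normal()
        if half > 1:
            k = np.arange(1, half)
            u = rng.standard_normal(half - 1)
            v = rng.standard_normal(half - 1)
            w[k] = np.sqrt(lam[k] / (2 * m)) * (u + 1j * v)
            w[m - k] = np.conj(w[k])
        out[i] = np.fft.fft(w).real[:n]
    return out


def _fgn_cholesky(gamma: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    n = gamma.size
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    cov = gamma[idx]
    # jitter guards rounding on near-singular covariances (H -> 1)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return rng.standard_normal((size, n)) @ chol.T


def fbm_paths(
    n_steps: int, hurst: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Standard fBm sampled at integer times 1..n_steps, shape (size, n_steps)."""
    return np.cumsum(fgn(n_steps, hurst, size, rng), axis=1)
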