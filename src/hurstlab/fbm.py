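"""Exact fBm covariances and simulation of synthetic trajectories.

Fractional Brownian motion ``B_H`` is the zero-mean Gaussian process with
``cov(B_H(t), B_H(s)) = (t^{2H} + s^{2H} - |t-s|^{2H}) / 2`` (unit scale).
Sample paths on the regular grid ``t_i = i/m`` are generated exactly in
distribution by circulant embedding (Davies-Harte) of the increment
autocovariance.  A continuous-time random walk with heavy-tailed waiting
times is provided as a subdiffusive negative control for the trajectory
diagnosis module.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import SamplePath

__all__ = [
    "exact_cov",
    "exact_increment_autocov",
    "simulate_fbm",
    "simulate_ctrw_fixture",
]


def _check_H(H: float) -> None:
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst index must lie in (0, 1); got {H}")


def exact_cov(t, s, H: float):
    """Exact fBm covariance ``(t^{2H} + s^{2H} - |t-s|^{2H}) / 2``.

    Symmetric in ``(t, s)``; equals ``min(t, s)`` at ``H = 1/2``.
    """
    _check_H(H)
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(t < 0) or np.any(s < 0):
        raise ValueError("times must be nonnegative")
    h2 = 2.0 * H
    return 0.5 * (t**h2 + s**h2 - np.abs(t - s) ** h2)


def exact_increment_autocov(lag, m: int, H: float):
    """Autocovariance of grid increments of fBm at integer lags.

    For spacing ``1/m``, ``cov(dB_i, dB_{i+k}) =
    m^{-2H} (|k+1|^{2H} + |k-1|^{2H} - 2 |k|^{2H}) / 2``.  The sequence is
    negative at positive lags for ``H < 1/2`` (anti-persistence) and
    positive for ``H > 1/2`` (long-range dependence).
    """
    _check_H(H)
    k = np.abs(np.asarray(lag, dtype=float))
    h2 = 2.0 * H
    g = 0.5 * (np.abs(k + 1) ** h2 + np.abs(k - 1) ** h2 - 2.0 * k**h2)
    return float(m) ** (-h2) * g


def _fgn_unit(H: float, m: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-spacing fractional Gaussian noise of length m via Davies-Harte."""
    k = np.arange(m + 1, dtype=float)
    h2 = 2.0 * H
    r = 0.5 * ((k + 1) ** h2 + np.abs(k - 1) ** h2 - 2.0 * k**h2)
    # first row of the 2m circulant embedding
    c = np.concatenate([r[:m], [r[m]], r[m - 1:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        # very rare for H near 1 at large m; clipping bias is negligible
        warnings.warn(
            "circulant embedding produced negative eigenvalues "
            f"(min {lam.min():.3e}); clipping at zero",
            RuntimeWarning,
        )
    lam = np.clip(lam, 0.0, None)
    n = 2 * m
    w = np.zeros(n, dtype=complex)
    g = rng.standard_normal(m + 1)
    gi = rng.standard_normal(m - 1)
    w[0] = np.sqrt(lam[0] / n) * g[0]
    w[m] = np.sqrt(lam[m] / n) * g[m]
    w[1:m] = np.sqrt(lam[1:m] / (2 * n)) * (g[1:m] + 1j * gi)
    w[m + 1:] = np.conj(w[1:m][::-1])
    return np.fft.fft(w).real[:m]


def simulate_fbm(H: float, m: int, seed=None) -> SamplePath:
    """Simulate an fBm sample path on the regular grid ``t_i = i/m``.

    Exact in distribution: the stationary increment sequence is drawn by
    circulant embedding of its autocovariance and cumulatively summed.

    Parameters
    ----------
    H : Hurst index in (0, 1).
    m : number of observations (>= 2).
    seed : int seed or :class:`numpy.random.Generator`.
    """
    _check_H(H)
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = np.random.default_rng(seed)
    fgn = _fgn_unit(H, m, rng) * float(m) ** (-H)
    return SamplePath.from_values(np.cumsum(fgn))


def simulate_ctrw_fixture(alpha: float, m: int, seed=None, jumps: int | None = None) -> SamplePath:
    """Continuous-time random walk observed on the regular grid.

    Standard-normal jumps occur after i.i.d. Pareto(``alpha``) waiting
    times, ``0 < alpha < 1``, so the walk is trapped for heavy-tailed
    stretches; observing it on the grid yields runs of exactly-zero
    increments.  Used as a non-fBm subdiffusive control; the jump and
    waiting-time laws are a fixture choice, not an inference target.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = np.random.default_rng(seed)
    n = jumps if jumps is not None else m
    waits = rng.random(n) ** (-1.0 / alpha)  # Pareto(alpha), support [1, inf)
    arrivals = np.cumsum(waits)
    arrivals /= arrivals[-1] * (1.0 + 1e-12)  # rescale renewal epochs to (0, 1)
    walk = np.cumsum(rng.standard_normal(n))
    grid = np.arange(1, m + 1) / m
    counts = np.searchsorted(arrivals, grid, side="right")
    values = np.where(counts > 0, walk[np.minimum(counts, n) - 1], 0.0)
    return SamplePath.from_values(values)
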