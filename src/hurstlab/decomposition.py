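"""Diffusion-type series approximation of fractional Brownian motion.

The fBm increment-variance function ``V(u) = u^{2H}`` admits a Bernstein
integral representation against exponential kernels:

* anti-persistent regime, ``a = 2H`` in ``(0, 1]``::

      u^a = a / Gamma(1 - a) * int_0^inf (1 - e^{-x u}) x^{-1-a} dx

* persistent regime, ``a`` in ``[1, 2)``::

      u^a = a (a-1) / Gamma(2 - a) * int_0^inf (e^{-x u} - 1 + x u) x^{-1-a} dx

Discretising the frequency integral on a geometric ladder of mean-reversion
rates turns fBm into a superposition of *independent Ito diffusions*:

* each interior node contributes, in the short-range regime, the difference
  ``U(t) - U(0)`` of a stationary Ornstein-Uhlenbeck process (term type 1),
  and in the long-range regime the *time integral* of a stationary OU
  process, which splits into an initial-condition component (type 2) and a
  component driven by an independent Brownian motion (type 3);
* the unresolved band below the smallest rate behaves as a scaled Brownian
  motion (short) or a random linear drift (long);
* the band above the largest rate consists of OU differences
  ``U_n(t) - U_n(0)`` whose correlation time is far below the grid spacing:
  at observable lags each collapses to an independent white value ``U_n(t)``
  minus a shared random offset ``U_n(0)``, so the band contributes
  ``(v/2)(1 + 1{t=s})`` to the covariance for ``t, s > 0`` (short regime
  only; the long-regime tail is negligible).

Each term has stationary increments and starts from zero, so the summed
covariance is positive semidefinite *by construction* at every truncation
level ``N``, and it converges uniformly to the exact fBm covariance as the
ladder widens and refines with ``N``.  At ``H = 1/2`` every OU weight
vanishes and the approximation collapses to exact Brownian motion.

The increment process implied by the approximation is stationary on a
regular grid, so increment covariance matrices are Toeplitz; this is what
makes the approximate likelihood cheap enough for Metropolis-Hastings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, toeplitz
from scipy.special import rgamma

from .core import ParameterSpace

__all__ = [
    "DecompositionConfig",
    "CovarianceMatrix",
    "term_cov",
    "approx_cov",
    "inc_cov_short",
    "inc_cov_long",
    "increment_autocov",
    "build_sigma_inc",
]


def _stable_pow_diff(c: np.ndarray, beta: float) -> np.ndarray:
    """(c[1:]**beta - c[:-1]**beta) / beta, continuous at beta = 0."""
    lr = np.log(c[1:] / c[:-1])
    if abs(beta) < 1e-12:
        return lr
    return c[:-1] ** beta * np.expm1(beta * lr) / beta


@dataclass(frozen=True)
class DecompositionConfig:
    """Truncation level, rate ladder and per-term weights of the series.

    Parameters
    ----------
    H : Hurst index in (0, 1).
    N : truncation level (number of OU nodes), default 100.
    space : parameter-space regime; inferred from ``H`` when omitted
        (``H <= 1/2`` -> SHORT).
    xi_min, xi_max : rate-ladder endpoints.  The defaults
        ``xi_min = N^{-3/2}`` and ``xi_max = 10^{N/20}`` widen and refine
        the ladder as ``N`` grows, which is what drives uniform convergence
        of the summed covariance.
    include_noise : keep the high-frequency white-noise band (short regime).
    """

    H: float
    N: int = 100
    space: ParameterSpace | None = None
    xi_min: float | None = None
    xi_max: float | None = None
    include_noise: bool = True

    # derived arrays, filled in __post_init__
    cuts: np.ndarray = field(init=False, repr=False, compare=False)
    rates: np.ndarray = field(init=False, repr=False, compare=False)
    weights: np.ndarray = field(init=False, repr=False, compare=False)
    bm_weight: float = field(init=False, repr=False, compare=False)
    slope_weight: float = field(init=False, repr=False, compare=False)
    noise_weight: float = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        H, N = self.H, self.N
        if not 0.0 < H < 1.0:
            raise ValueError(f"Hurst index must lie in (0, 1); got {H}")
        if N < 1:
            raise ValueError("truncation level N must be >= 1")
        space = self.space or ParameterSpace.of(H)
        if space is ParameterSpace.FULL:
            raise ValueError("a decomposition is built for SHORT or LONG, not FULL")
        if not space.contains(H) and not (space is ParameterSpace.LONG and H == 0.5):
            raise ValueError(f"H={H} outside {space}")
        object.__setattr__(self, "space", space)

        lo = self.xi_min if self.xi_min is not None else float(N) ** -1.5
        hi = self.xi_max if self.xi_max is not None else 10.0 ** (N / 20.0)
        object.__setattr__(self, "xi_min", lo)
        object.__setattr__(self, "xi_max", hi)
        c = np.geomspace(lo, hi, N + 1)
        a = 2.0 * H
        neg = c[:-1] ** -a - c[1:] ** -a  # = a * int_{I_n} x^{-1-a} dx
        mean_num = _stable_pow_diff(c, 1.0 - a)  # = int_{I_n} x^{-a} dx
        rates = a * mean_num / np.where(neg > 0, neg, 1.0)
        if space is ParameterSpace.SHORT:
            weights = rgamma(1.0 - a) * neg
            bm = a * rgamma(2.0 - a) * c[0] ** (1.0 - a)
            slope = 0.0
            noise = rgamma(1.0 - a) * c[-1] ** -a if self.include_noise else 0.0
        else:
            weights = (a - 1.0) * rgamma(2.0 - a) * neg
            bm = a * rgamma(2.0 - a) * c[-1] ** (1.0 - a)
            slope = a * (a - 1.0) * rgamma(2.0 - a) * c[0] ** (2.0 - a) / (2.0 * (2.0 - a))
            noise = 0.0
        object.__setattr__(self, "cuts", c)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "bm_weight", float(bm))
        object.__setattr__(self, "slope_weight", float(slope))
        object.__setattr__(self, "noise_weight", float(noise))


def _vfun(u, cfg: DecompositionConfig) -> np.ndarray:
    """Continuous part of the approximate increment-variance function.

    Approximates ``u^{2H}``; excludes the white-noise band, which is not a
    continuous-path component (see :func:`approx_cov` and
    :func:`increment_autocov` for where it re-enters).
    """
    u = np.abs(np.atleast_1d(np.asarray(u, dtype=float)))
    x = np.outer(u, cfg.rates)
    if cfg.space is ParameterSpace.SHORT:
        body = (cfg.weights[None, :] * -np.expm1(-x)).sum(axis=1)
        return cfg.bm_weight * u + body
    body = (cfg.weights[None, :] * (np.expm1(-x) + x)).sum(axis=1)
    return cfg.slope_weight * u**2 + cfg.bm_weight * u + body


def term_cov(i: int, n: int, t: float, s: float, cfg: DecompositionConfig) -> float:
    """Covariance ``lambda_{i,n}(t, s)`` of a single series term.

    ``i = 1`` is the short-regime OU-difference term; ``i = 2`` and
    ``i = 3`` are the long-regime initial-condition and driven components
    of the integrated OU term (independent of each other, so their sum is
    the full node covariance).  ``n`` indexes the rate ladder from 1.
    Every term vanishes when either argument is zero.
    """
    if not 1 <= n <= cfg.N:
        raise ValueError(f"term index n must lie in 1..{cfg.N}")
    if t < 0 or s < 0:
        raise ValueError("times must be nonnegative")
    b = cfg.rates[n - 1]
    w = cfg.weights[n - 1]
    if i == 1:
        if cfg.space is not ParameterSpace.SHORT:
            raise ValueError("term type 1 requires the SHORT-range decomposition")
        return 0.5 * w * (
            np.exp(-b * abs(t - s)) - np.exp(-b * t) - np.exp(-b * s) + 1.0
        )
    if i in (2, 3):
        if cfg.space is not ParameterSpace.LONG:
            raise ValueError("term types 2 and 3 require the LONG-range decomposition")
        lam2 = 0.5 * w * (-np.expm1(-b * t)) * (-np.expm1(-b * s))
        if i == 2:
            return float(lam2)

        def g(u):
            x = b * abs(u)
            return w * (np.expm1(-x) + x)

        lam_full = 0.5 * (g(t) + g(s) - g(t - s))
        return float(lam_full - lam2)
    raise ValueError("term type must be 1, 2 or 3")


def approx_cov(t, s, cfg: DecompositionConfig):
    """N-term approximation of the fBm covariance at arbitrary times.

    Sum of the per-term covariances plus the boundary-band terms; converges
    uniformly on the unit square to :func:`hurstlab.fbm.exact_cov` as
    ``N`` grows.  The high-frequency band contributes
    ``(v/2)(1 + 1{t=s})`` off the axes (shared offset + white noise).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    t_b, s_b = np.broadcast_arrays(t_arr, s_arr)
    shape = t_b.shape
    vt = _vfun(t_b.ravel(), cfg)
    vs = _vfun(s_b.ravel(), cfg)
    vd = _vfun((t_b - s_b).ravel(), cfg)
    out = 0.5 * (vt + vs - vd)
    pos = (t_b.ravel() > 0) & (s_b.ravel() > 0)
    diag = (t_b.ravel() == s_b.ravel()) & pos
    out = out + 0.5 * cfg.noise_weight * (pos.astype(float) + diag.astype(float))
    out = out.reshape(shape)
    if np.isscalar(t) and np.isscalar(s):
        return float(out.reshape(-1)[0])
    return out


def increment_autocov(cfg: DecompositionConfig, m: int, lags=None) -> np.ndarray:
    """Model autocovariance of grid increments under the approximation.

    For spacing ``1/m`` the approximate increment process is stationary;
    the autocovariance at lag ``k`` is the second difference of the
    continuous variance function, plus an MA(1) contribution
    ``(v, -v/2, 0, ...)`` from the high-frequency band (the shared-offset
    part of the band cancels in differences, including the first
    increment, so the matrix stays exactly Toeplitz).
    """
    if lags is None:
        lags = np.arange(m - 1)
    k = np.atleast_1d(np.asarray(lags, dtype=int))
    d = 1.0 / m
    v = _vfun(np.concatenate([(k + 1) * d, np.abs(k - 1) * d, k * d]), cfg)
    nk = len(k)
    gamma = 0.5 * (v[:nk] + v[nk:2 * nk] - 2.0 * v[2 * nk:])
    gamma = gamma + np.where(k == 0, 1.0, 0.0) * cfg.noise_weight
    gamma = gamma - np.where(np.abs(k) == 1, 0.5, 0.0) * cfg.noise_weight
    return gamma


def _inc_cov(t_i: float, t_j: float, delta: float, cfg: DecompositionConfig) -> float:
    k = int(round(abs(t_i - t_j) / delta))
    return float(increment_autocov(cfg, int(round(1.0 / delta)), [k])[0])


def inc_cov_short(t_i: float, t_j: float, cfg: DecompositionConfig, delta: float) -> float:
    """Covariance of increments starting at grid times ``t_i, t_j`` (SHORT)."""
    if cfg.space is not ParameterSpace.SHORT:
        raise ValueError("inc_cov_short requires a SHORT-range configuration")
    return _inc_cov(t_i, t_j, delta, cfg)


def inc_cov_long(t_i: float, t_j: float, cfg: DecompositionConfig, delta: float) -> float:
    """Covariance of increments starting at grid times ``t_i, t_j`` (LONG)."""
    if cfg.space is not ParameterSpace.LONG:
        raise ValueError("inc_cov_long requires a LONG-range configuration")
    return _inc_cov(t_i, t_j, delta, cfg)


@dataclass(frozen=True)
class CovarianceMatrix:
    """Increment covariance matrix with the regularisation actually applied."""

    values: np.ndarray
    jitter: float
    H: float
    N: int
    space: ParameterSpace


_JITTER_LADDER = (0.0, 1e-12, 1e-10, 1e-8, 1e-6)


def build_sigma_inc(times: np.ndarray, cfg: DecompositionConfig) -> CovarianceMatrix:
    """(m-1) x (m-1) increment covariance matrix on a regular grid.

    The matrix is Toeplitz and positive semidefinite by construction;
    escalating diagonal jitter (relative to the mean diagonal, capped at
    1e-6) guards against roundoff in the Cholesky factorisation.
    """
    times = np.asarray(times, dtype=float)
    m = len(times)
    if not np.allclose(times, np.arange(1, m + 1) / m):
        raise ValueError("build_sigma_inc requires the regular grid t_i = i/m")
    gamma = increment_autocov(cfg, m, np.arange(m - 1))
    sigma = toeplitz(gamma)
    mean_diag = float(np.mean(np.diag(sigma)))
    for rel in _JITTER_LADDER:
        try:
            cho_factor(sigma + rel * mean_diag * np.eye(m - 1), lower=True)
            return CovarianceMatrix(
                values=sigma + rel * mean_diag * np.eye(m - 1),
                jitter=rel * mean_diag,
                H=cfg.H,
                N=cfg.N,
                space=cfg.space,
            )
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"increment covariance not factorizable at jitter cap (H={cfg.H}, N={cfg.N})"
    )
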