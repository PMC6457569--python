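"""Exact Pólya-Gamma PG(1, c) sampling for logistic Gibbs updates.

A Pólya-Gamma random variable PG(b, c) has Laplace transform
``E[exp(-ω t)] = cosh^b(c/2) / cosh^b(sqrt(c²/2 + t) / sqrt(2))`` and turns
Bernoulli-logit likelihoods into conditionally Gaussian ones: augmenting each
Bernoulli observation with ω ~ PG(1, x'β) makes the full conditional of β a
multivariate normal. Only PG(1, c) is needed here.

The sampler is Devroye's exact rejection algorithm for the tilted Jacobi
variable J*(1, z) (PG(1, c) = J*(1, |c|/2) / 4): propose from a mixture of a
truncated inverse-Gaussian body and an exponential tail split at t = 0.64,
then accept via the alternating-series squeeze on the Jacobi density. The
acceptance probability exceeds 0.9998 uniformly in z, so the rejection loop
almost always runs once.

Functions are numba-jitted; the module keeps its own RNG stream (numba's
internal state), seeded via :func:`seed_pg_rng`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg", "seed_pg_rng", "pg_mean", "pg_var"]

_TRUNC = 0.64  # split point of Devroye's proposal mixture


def pg_mean(c: float) -> float:
    """Closed-form mean of PG(1, c): tanh(c/2) / (2c), 1/4 at c = 0."""
    if c == 0.0:
        return 0.25
    return math.tanh(c / 2.0) / (2.0 * c)


def pg_var(c: float) -> float:
    """Closed-form variance of PG(1, c): (sinh c − c) sech²(c/2) / (4c³)."""
    if abs(c) < 1e-4:
        # series limit; avoids catastrophic cancellation near 0
        return 1.0 / 24.0 - c * c / 60.0
    return (math.sinh(c) - c) / (math.cosh(c / 2.0) ** 2 * 4.0 * c**3)


@njit(cache=True)
def _norm_logcdf(x):
    # log Φ(x) via erfc; stable for the moderately negative x seen here
    return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))


@njit(cache=True)
def _exp_tail_mass_ratio(z):
    """p/(p+q): probability the proposal draws from the exponential tail."""
    t = _TRUNC
    fz = math.pi**2 / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _norm_logcdf(b)
    xa = x0 + z + _norm_logcdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(μ = 1/z, λ = 1) truncated to (0, 0.64]."""
    t = _TRUNC
    if z < 1.0 / t:  # μ > t: sample truncated Lévy, thin by the tilt
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:  # μ ≤ t: plain IG sampler, reject outside the window
        mu = 1.0 / z
        while True:
            y = np.random.normal(0.0, 1.0)
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
                4.0 * mu * y + (mu * y) * (mu * y)
            )
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _series_coef(n, x):
    # piecewise kernel of the Jacobi density's alternating series
    h = n + 0.5
    if x > _TRUNC:
        return math.pi * h * math.exp(-h * h * math.pi**2 * x / 2.0)
    return (
        math.pi
        * h
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * h * h / x)
    )


@njit(cache=True)
def _sample_jstar(z):
    """One draw of the tilted Jacobi J*(1, z), z ≥ 0."""
    fz = math.pi**2 / 8.0 + z * z / 2.0
    ratio = _exp_tail_mass_ratio(z)
    while True:
        if np.random.random() < ratio:
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _series_coef(0, x)
        y = np.random.random() * s
        n = 0
        accepted = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _series_coef(n, x)
                if y <= s:
                    accepted = True
                    break
            else:
                s += _series_coef(n, x)
                if y > s:
                    break
        if accepted:
            return x


@njit(cache=True)
def _sample_pg_into(c, out):
    for i in range(c.shape[0]):
        out[i] = 0.25 * _sample_jstar(abs(c[i]) * 0.5)


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


def seed_pg_rng(seed: int) -> None:
    """Seed the sampler's internal RNG stream (independent of numpy's)."""
    _seed(int(seed) % 2**32)


def sample_pg(c: np.ndarray) -> np.ndarray:
    """Draw ω_i ~ PG(1, c_i) for a vector of tilting parameters.

    Parameters
    ----------
    c
        Linear predictors (any sign; PG(1, c) is symmetric in c).

    Returns
    -------
    Array of the same shape with one PG(1, c_i) draw per element.
    """
    c = np.ascontiguousarray(c, dtype=np.float64)
    out = np.empty_like(c)
    _sample_pg_into(c.ravel(), out.ravel())
    return out
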