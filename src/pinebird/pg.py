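"""Exact Polya-Gamma PG(1, c) sampling.

The logit-scale Gibbs updates in the occupancy sampler rely on the
Polya-Gamma augmentation: for a Bernoulli observation with linear
predictor ``c``, the auxiliary variable is PG(1, c), and the
conditional for the regression coefficients is then Gaussian.

PG(1, c) = J*(1, c/2) / 4, where J* is sampled with Devroye's
alternating-series rejection algorithm (truncation point 0.64),
mixing a truncated inverse-Gaussian left tail with an exponential
right tail.  All kernels are numba-compiled; the module-level entry
point seeds numba's internal RNG, so draws are reproducible given a
seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # Devroye's truncation point t for J*(1, z)


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    # n-th term of the alternating series for the J*(1) density at x
    np5 = n + 0.5
    if x <= _TRUNC:
        return (
            math.pi
            * np5
            * (2.0 / math.pi / x) ** 1.5
            * math.exp(-2.0 * np5 * np5 / x)
        )
    return math.pi * np5 * math.exp(-np5 * np5 * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _sample_trunc_invgauss(mu: float, z: float) -> float:
    # inverse-Gaussian(mu, lambda=1) truncated to (0, _TRUNC)
    if mu > _TRUNC:
        # Devroye: propose via the chi-like representation, accept on exp tilt
        while True:
            e1 = -math.log(np.random.random())
            e2 = -math.log(np.random.random())
            while e1 * e1 > 2.0 * e2 / _TRUNC:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
            x = _TRUNC / ((1.0 + _TRUNC * e1) * (1.0 + _TRUNC * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        # plain IG draws until one lands inside the truncation window
        while True:
            y = np.random.standard_normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + mu * mu * y * y)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x < _TRUNC:
                return x


@njit(cache=True)
def _pg1_scalar(c: float) -> float:
    z = 0.5 * abs(c)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    # mass of the exponential right piece vs the inverse-Gaussian left piece
    p = 0.5 * math.pi / fz * math.exp(-fz * _TRUNC)
    if z > 0.0:
        mu = 1.0 / z
        # IG(mu, 1) cdf at t
        rt = math.sqrt(_TRUNC)
        cdf = 0.5 * math.erfc(-(rt * z - 1.0 / rt) / math.sqrt(2.0))
        tail = 0.5 * math.erfc((rt * z + 1.0 / rt) / math.sqrt(2.0))
        if tail > 0.0:  # exp(2z) alone can overflow once the erfc underflows
            cdf += math.exp(2.0 * z) * tail
        q = 2.0 * math.exp(-z) * cdf
    else:
        mu = np.inf
        # z = 0: left piece is the 1/2-stable (Levy) cdf at t
        q = 2.0 * math.erfc(1.0 / math.sqrt(2.0 * _TRUNC))

    while True:
        if np.random.random() < p / (p + q):
            x = _TRUNC - math.log(np.random.random()) / fz
        else:
            x = _sample_trunc_invgauss(mu, z)
        # squeeze via the alternating series
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return 0.25 * x


@njit(cache=True)
def _pg1_array(c: np.ndarray, out: np.ndarray) -> None:
    for i in range(c.shape[0]):
        out[i] = _pg1_scalar(c[i])


@njit(cache=True)
def _seed_numba(seed: int) -> None:
    np.random.seed(seed)


def seed_pg(seed: int) -> None:
    """Seed the numba-internal RNG used by the PG sampler."""
    _seed_numba(int(seed) % (2**32 - 1))


def draw_pg1(c: np.ndarray) -> np.ndarray:
    """Draw PG(1, c_i) for each entry of ``c``.

    Uses numba's internal random state; call :func:`seed_pg` first for
    reproducibility.
    """
    c = np.ascontiguousarray(np.asarray(c, dtype=np.float64))
    out = np.empty_like(c)
    _pg1_array(c, out)
    return out


def pg_mean(c: float) -> float:
    """E[PG(1, c)] = tanh(c/2) / (2c), with the c -> 0 limit 1/4."""
    if c == 0.0:
        return 0.25
    return math.tanh(c / 2.0) / (2.0 * c)
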