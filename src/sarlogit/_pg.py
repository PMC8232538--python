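"""Exact Pólya-Gamma PG(1, z) sampling.

The logistic likelihood admits the augmentation of Polson, Scott & Windle:
with omega_i ~ PG(1, eta_i), the conditional for every Gaussian block of the
structured additive predictor is again Gaussian, which is what the blocked
Gibbs sampler in :mod:`sarlogit.model` exploits.

The sampler below is the Devroye-type alternating-series rejection sampler
for J*(1, z) (PG(1, z) = J*(1, z/2) / 4). It is exact (no series
truncation) and compiled with numba so that one draw per observation per
iteration is affordable at survey scale.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # crossover point between the two series representations
_PI2_8 = math.pi * math.pi / 8.0


@njit(cache=True)
def _log_norm_cdf(x):
    # log Phi(x) via erfc; clamp the underflow region instead of raising
    v = 0.5 * math.erfc(-x / math.sqrt(2.0))
    if v <= 0.0:
        return -1e30
    return math.log(v)


@njit(cache=True)
def _coef(n, x):
    # a_n(x) of the alternating series for the J*(1, 0) density
    if x <= _TRUNC:
        return (
            math.pi
            * (n + 0.5)
            * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * (n + 0.5) ** 2 / x)
        )
    return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _mass_texpon(z):
    """Probability that the two-piece proposal draws from the exponential tail."""
    fz = _PI2_8 + z * z / 2.0
    b = math.sqrt(1.0 / _TRUNC) * (_TRUNC * z - 1.0)
    a = -math.sqrt(1.0 / _TRUNC) * (_TRUNC * z + 1.0)
    x0 = math.log(fz) + fz * _TRUNC
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)."""
    r = _TRUNC
    if z < 1e-12 or 1.0 / z > r:
        # mu > truncation point: rejection via truncated inverse-chi-square
        while True:
            e1 = -math.log(np.random.random())
            e2 = -math.log(np.random.random())
            while e1 * e1 > 2.0 * e2 / r:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
            x = r / (1.0 + r * e1) ** 2
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = np.random.standard_normal() ** 2
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= r:
                return x


@njit(cache=True)
def _sample_pg1(c):
    """One exact PG(1, c) draw using the current numba RNG state."""
    z = 0.5 * abs(c)
    fz = _PI2_8 + z * z / 2.0
    p_exp = _mass_texpon(z)
    while True:
        if np.random.random() < p_exp:
            x = _TRUNC - math.log(np.random.random()) / fz
        else:
            x = _rtigauss(z)
        # alternating-series squeeze accept/reject
        s = _coef(0, x)
        y = np.random.random() * s
        n = 0
        accepted = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _coef(n, x)
                if y <= s:
                    accepted = True
                    break
            else:
                s += _coef(n, x)
                if y > s:
                    break
        if accepted:
            return x / 4.0


@njit(cache=True)
def _pg_batch(c, seed):
    np.random.seed(seed)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        out[i] = _sample_pg1(c[i])
    return out


def polya_gamma(c, seed):
    """Draw PG(1, c_i) for each entry of ``c``.

    Parameters
    ----------
    c : array-like
        Tilting parameters (the linear predictor in the logistic model).
    seed : int
        Seed for this batch; identical (c, seed) gives identical draws.

    Returns
    -------
    numpy.ndarray of the same length as ``c``.
    """
    c = np.ascontiguousarray(np.asarray(c, dtype=np.float64))
    if c.ndim != 1:
        raise ValueError("c must be one-dimensional")
    return _pg_batch(c, np.uint32(seed % (2**32)))


def pg_mean(c):
    """E[PG(1, c)] = tanh(c/2) / (2c), with the c -> 0 limit 1/4."""
    c = np.asarray(c, dtype=np.float64)
    out = np.full(c.shape, 0.25)
    nz = np.abs(c) > 1e-8
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    return out
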