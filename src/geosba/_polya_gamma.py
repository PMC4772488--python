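"""Exact Polya-Gamma PG(1, z) sampling, vectorised.

Implements the alternating-series rejection sampler of Devroye for the
Jacobi-type variable J*(1, z), of which PG(1, z) is J*(1, z/2)/4. The
proposal is the usual two-piece mixture: a truncated inverse-Gaussian on
(0, t) and an exponential tail on (t, inf), with t = 0.64. Acceptance uses
the partial sums of the two series representations of the Jacobi density,
so draws are exact (no truncation bias).

Used as the augmentation step of the logistic Gibbs sampler: with
omega_i ~ PG(1, eta_i), the conditional for the linear predictor
coefficients is Gaussian.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorised

_T = 0.64
_MAX_SERIES = 200
_MAX_REJECT = 1000


def _a_coefs(n: int, x: np.ndarray) -> np.ndarray:
    """n-th coefficient of the alternating series for the Jacobi density."""
    out = np.empty_like(x)
    right = x > _T
    xr = x[right]
    out[right] = np.pi * (n + 0.5) * np.exp(-((n + 0.5) ** 2) * np.pi**2 * xr / 2.0)
    xl = x[~right]
    with np.errstate(divide="ignore"):
        out[~right] = (
            np.pi
            * (n + 0.5)
            * (2.0 / (np.pi * xl)) ** 1.5
            * np.exp(-2.0 * (n + 0.5) ** 2 / xl)
        )
    return out


def _invgauss_cdf_t(z: np.ndarray) -> np.ndarray:
    """P(X <= t) for X ~ IG(mu=1/z, lambda=1), valid for z >= 0 (z=0 is the Levy limit)."""
    sqt = np.sqrt(_T)
    a = ndtr(z * sqt - 1.0 / sqt)
    # exp(2z) * Phi(-z*sqrt(t) - 1/sqrt(t)) computed in log space to avoid overflow
    with np.errstate(divide="ignore"):
        logb = 2.0 * z + _log_ndtr(-z * sqt - 1.0 / sqt)
    return a + np.exp(logb)


def _log_ndtr(x: np.ndarray) -> np.ndarray:
    from scipy.special import log_ndtr

    return log_ndtr(x)


def _sample_trunc_invgauss(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw X ~ IG(1/z, 1) truncated to (0, t), elementwise; z >= 0 allowed."""
    x = np.empty_like(z)
    todo = np.ones(z.shape, dtype=bool)
    small_mu = z >= 1.0 / _T  # mu = 1/z <= t: plain rejection on the IG
    for _ in range(_MAX_REJECT):
        if not todo.any():
            break
        # branch 1: mu <= t -> draw IG(mu, 1) until it lands below t
        idx = todo & small_mu
        if idx.any():
            mu = 1.0 / z[idx]
            draw = rng.wald(mu, 1.0)
            ok = draw <= _T
            sel = np.flatnonzero(idx)[ok]
            x[sel] = draw[ok]
            todo[sel] = False
        # branch 2: mu > t -> chi-based sampler for the Levy piece, thinned by exp(-z^2 x / 2)
        idx = todo & ~small_mu
        if idx.any():
            n = int(idx.sum())
            e1 = rng.standard_exponential(n)
            e2 = rng.standard_exponential(n)
            ok_pair = e1 * e1 <= 2.0 * e2 / _T
            draw = _T / (1.0 + _T * e1) ** 2
            accept = ok_pair & (rng.random(n) <= np.exp(-z[idx] ** 2 * draw / 2.0))
            sel = np.flatnonzero(idx)[accept]
            x[sel] = draw[accept]
            todo[sel] = False
    if todo.any():  # pragma: no cover - astronomically unlikely
        x[todo] = _T / 2.0
    return x


def _jacobi_star(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw J*(1, z) elementwise for z >= 0."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    todo = np.ones(z.shape, dtype=bool)

    k = np.pi**2 / 8.0 + z**2 / 2.0
    # mixture weights of the two proposal pieces
    log_p_right = np.log(np.pi / (2.0 * k)) - k * _T
    with np.errstate(divide="ignore"):
        log_p_left = -z + np.log(2.0) + np.log(_invgauss_cdf_t(z))
    w_right = 1.0 / (1.0 + np.exp(log_p_left - log_p_right))

    for _ in range(_MAX_REJECT):
        if not todo.any():
            break
        idx = np.flatnonzero(todo)
        zi, ki = z[idx], k[idx]
        use_right = rng.random(idx.size) < w_right[idx]
        x = np.empty(idx.size)
        if use_right.any():
            x[use_right] = _T + rng.standard_exponential(int(use_right.sum())) / ki[use_right]
        if (~use_right).any():
            x[~use_right] = _sample_trunc_invgauss(zi[~use_right], rng)

        # alternating-series squeeze: accept/reject against partial sums
        s = _a_coefs(0, x)
        y = rng.random(idx.size) * s
        decided = np.zeros(idx.size, dtype=bool)
        accepted = np.zeros(idx.size, dtype=bool)
        for n in range(1, _MAX_SERIES):
            an = _a_coefs(n, x)
            if n % 2 == 1:
                s = s - an
                newly = ~decided & (y <= s)
                accepted |= newly
            else:
                s = s + an
                newly = ~decided & (y > s)
            decided |= newly
            if decided.all():
                break
        sel = idx[accepted]
        out[sel] = x[accepted]
        todo[sel] = False
    if todo.any():  # pragma: no cover
        out[todo] = _T / 2.0
    return out


def random_polya_gamma(c, rng: np.random.Generator) -> np.ndarray:
    """Draw omega ~ PG(1, c) elementwise.

    E[omega] = tanh(c/2) / (2c) with the limit 1/4 at c = 0.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    return _jacobi_star(np.abs(c) / 2.0, rng) / 4.0


def polya_gamma_mean(c) -> np.ndarray:
    """Closed-form E[PG(1, c)], used as an independent check of the sampler."""
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, 0.25)
    nz = np.abs(c) > 1e-8
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    return out
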