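"""Closed-form results for the one-type, two-type and infinite-type chains.

For a single critical type (division and lethal mutation both at rate 1)
the generating function is rational in time, giving the survival law
``S(t) = 1/(1+t)`` and a geometric cell-number distribution conditioned
on survival.  With unbounded types, the total population is a rate-one
Yule process.  For two types, the backward Kolmogorov system reduces to a
Riccati equation which linearises to the modified-Bessel equation; the
survival probability and full generating function are ratios of modified
Bessel functions ``I`` and ``K`` of orders 0 and 1 evaluated at
``2*tau`` with ``tau = sqrt(t + 1/(1 - x2))``.

Large arguments are handled with exponentially scaled Bessel functions so
the ratio never overflows (the naive forms fail beyond t of order 7e2);
an arbitrary-precision path is available for coefficient-extraction
contexts where the cancellation between the ``I`` and ``K`` branches
matters.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial
from typing import Optional, Union

import mpmath as mp
import numpy as np
from scipy.special import ive, kve

__all__ = [
    "single_type_survival",
    "single_type_pmf",
    "single_type_gf",
    "yule_pmf",
    "yule_mean",
    "survival_constant",
    "two_type_survival",
    "two_type_gf",
    "mean_counts",
    "arrival_cdf_type2",
    "arrival_survival_type2",
]

ArrayLike = Union[float, np.ndarray]


# ---------------------------------------------------------------- one type

def single_type_survival(t: ArrayLike) -> ArrayLike:
    """P(any cell alive at t) for the single critical type: 1/(1+t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return (1.0 / (1.0 + t))[()] if t.ndim == 0 else 1.0 / (1.0 + t)


def single_type_pmf(a: int, t: float) -> float:
    """P(Z_1(t) = a) starting from one cell.

    ``a = 0`` has mass ``t/(1+t)``; for ``a >= 1`` the mass is
    ``(1+t)^{-2} (t/(1+t))^{a-1}``, i.e. geometric given survival with
    success probability ``1/(1+t)``.
    """
    if a < 0:
        raise ValueError("cell count must be non-negative")
    if a == 0:
        return t / (1.0 + t)
    return (1.0 + t) ** -2 * (t / (1.0 + t)) ** (a - 1)


def single_type_gf(x: Union[complex, np.ndarray], t: float) -> Union[complex, np.ndarray]:
    """Probability generating function E[x^{Z_1(t)}] of the single type."""
    num = t * (1 - x) + x
    den = t * (1 - x) + 1
    out = num / den
    if isinstance(out, np.ndarray):
        return out[()] if out.ndim == 0 else out
    return out  # plain complex or arbitrary-precision scalar


# ------------------------------------------------------------ Yule process

def yule_pmf(s: int, t: float) -> float:
    """P(Z(t) = s) for the rate-one Yule process from one cell, s >= 1."""
    if s < 1:
        raise ValueError("a Yule population is never empty; s must be >= 1")
    return np.exp(-t) * (1.0 - np.exp(-t)) ** (s - 1)


def yule_mean(t: ArrayLike) -> ArrayLike:
    """Mean Yule population e^t; equals the unbounded-type total mean."""
    return np.exp(t)


# ------------------------------------------------------------- two types

@lru_cache(maxsize=1)
def survival_constant() -> float:
    """The amplitude c = (I0(2) - I1(2)) / (K0(2) + K1(2)).

    Fixed by the initial condition S(0) = 1 of the two-type survival
    formula; evaluated in high precision and cached.
    """
    with mp.workdps(40):
        c = (mp.besseli(0, 2) - mp.besseli(1, 2)) / (mp.besselk(0, 2) + mp.besselk(1, 2))
        return float(c)


def _bessel_ratio(c, tau):
    """(I0(2 tau) - c K0(2 tau)) / (I1(2 tau) + c K1(2 tau)), overflow-safe.

    Works for real or complex ``tau`` with non-negative real part.  Both
    numerator and denominator are divided by ``e^{Re(2 tau)}``; the K
    terms then carry ``e^{-2 tau - Re(2 tau)}`` which underflows
    harmlessly for large arguments.
    """
    z = 2.0 * np.asarray(tau)
    w = np.exp(-z - np.real(z))
    num = ive(0, z) - c * kve(0, z) * w
    den = ive(1, z) + c * kve(1, z) * w
    return num / den


def two_type_survival(t: ArrayLike, precision: Optional[int] = None) -> ArrayLike:
    """Survival probability of the two-type chain started from one type-1 cell.

    Evaluates ``S(t) = (1/tau) (I0(2 tau) - c K0(2 tau)) /
    (I1(2 tau) + c K1(2 tau))`` with ``tau = sqrt(1+t)`` and the cached
    amplitude constant.  Stable for ``t`` up to at least 1e8 through
    exponentially scaled Bessel functions.

    ``precision`` switches to arbitrary-precision evaluation with that
    many decimal digits.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if precision is not None:
        with mp.workdps(precision):
            c = (mp.besseli(0, 2) - mp.besseli(1, 2)) / (
                mp.besselk(0, 2) + mp.besselk(1, 2)
            )

            def one(tv):
                tau = mp.sqrt(1 + mp.mpf(tv))
                num = mp.besseli(0, 2 * tau) - c * mp.besselk(0, 2 * tau)
                den = mp.besseli(1, 2 * tau) + c * mp.besselk(1, 2 * tau)
                return float(num / den / tau)

            out = np.vectorize(one)(t_arr)
            return out[()] if out.ndim == 0 else out
    tau = np.sqrt(1.0 + t_arr)
    out = _bessel_ratio(survival_constant(), tau) / tau
    return out[()] if np.ndim(out) == 0 else out


def _gf_amplitude_scaled(x1, tau0):
    """Scaled amplitude: the t = 0 condition Z(x1, x2, 0) = x1 fixes c.

    Returns ``c_hat`` with ``c = c_hat * exp(2 tau0 + 2 Re tau0)``; the
    exponential factor is never formed (it overflows as x2 -> 1) and is
    cancelled against the K-branch scaling downstream.
    """
    z0 = 2.0 * tau0
    one_minus_x1 = 1.0 - np.asarray(x1)
    num = ive(0, z0) - one_minus_x1 * tau0 * ive(1, z0)
    den = kve(0, z0) + one_minus_x1 * tau0 * kve(1, z0)
    return num / den


def two_type_gf(
    x1: Union[complex, np.ndarray],
    x2: Union[complex, np.ndarray],
    t: float,
    precision: Optional[int] = None,
) -> Union[complex, np.ndarray]:
    """Joint generating function E[x1^{Z_1(t)} x2^{Z_2(t)}] from one type-1 cell.

    ``x2 = 1`` is a singular point of the representation (``tau``
    diverges); callers needing the type-1 marginal should use the
    single-type generating function, which the chain's decomposability
    makes exact.  The principal branch of the complex square root is
    used; for ``|x2| <= r < 1`` the argument stays off the branch cut.
    """
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if np.any(np.abs(1.0 - x2) < 1e-14):
        raise ValueError("x2 = 1 is singular; use marginal limits instead")
    if precision is not None:
        return _two_type_gf_mp(x1, x2, t, precision)
    inv = 1.0 / (1.0 - x2)
    tau0 = np.sqrt(inv + 0j)
    tau = np.sqrt(t + inv + 0j)
    c_hat = _gf_amplitude_scaled(x1, tau0)
    z0, z = 2.0 * tau0, 2.0 * tau
    # c * K-scaling combine to exp(z0 + Re z0 - z - Re z), of modulus <= 1
    # because Re tau grows with t; no overflow anywhere on the unit disk.
    w = np.exp(z0 + np.real(z0) - z - np.real(z))
    num = ive(0, z) - c_hat * kve(0, z) * w
    den = ive(1, z) + c_hat * kve(1, z) * w
    out = 1.0 - num / den / tau
    return out[()] if out.ndim == 0 else out


def _two_type_gf_mp(x1, x2, t, dps: int):
    with mp.workdps(dps):
        def one(a, b):
            tau0 = mp.sqrt(1 / (1 - mp.mpc(b)))
            tau = mp.sqrt(t + 1 / (1 - mp.mpc(b)))
            om = 1 - mp.mpc(a)
            c = (mp.besseli(0, 2 * tau0) - om * tau0 * mp.besseli(1, 2 * tau0)) / (
                mp.besselk(0, 2 * tau0) + om * tau0 * mp.besselk(1, 2 * tau0)
            )
            num = mp.besseli(0, 2 * tau) - c * mp.besselk(0, 2 * tau)
            den = mp.besseli(1, 2 * tau) + c * mp.besselk(1, 2 * tau)
            return complex(1 - num / den / tau)

        out = np.vectorize(one)(x1, x2)
        return out[()] if np.ndim(out) == 0 else out


# --------------------------------------------------------------- moments

def mean_counts(i: int, t: ArrayLike) -> ArrayLike:
    """Mean number of type-i cells: t^{i-1}/(i-1)!.

    The first type's mean is conserved at 1 (criticality); each later
    type integrates the one before it.  Summed over all i this gives the
    Yule mean e^t.
    """
    if i < 1:
        raise ValueError("type index must be >= 1")
    t = np.asarray(t, dtype=float)
    out = t ** (i - 1) / factorial(i - 1)
    return out[()] if out.ndim == 0 else out


# ------------------------------------------------------- arrival of type 2

def arrival_cdf_type2(t: ArrayLike, nu: float = 1.0) -> ArrayLike:
    """P(T_2 <= t): first type-2 cell arrived by time t.

    In the critical family with constant mutation rate ``nu`` (and death
    rate ``1 - nu``) the law is ``sqrt(nu) tanh(sqrt(nu) t)`` — defective
    for ``nu < 1``, with total mass ``sqrt(nu)``.
    """
    if not 0 < nu <= 1:
        raise ValueError("mutation rate nu must be in (0, 1] for the critical family")
    t = np.asarray(t, dtype=float)
    out = np.sqrt(nu) * np.tanh(np.sqrt(nu) * t)
    return out[()] if out.ndim == 0 else out


def arrival_survival_type2(t: ArrayLike) -> ArrayLike:
    """P(T_2 > t) at nu = 1, in its explicit form 2/(1 + e^{2t})."""
    t = np.asarray(t, dtype=float)
    out = 2.0 / (1.0 + np.exp(2.0 * t))
    return out[()] if out.ndim == 0 else out
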