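"""Large-time and large-size limit laws of the n-type critical chain.

Everything here is organised around the exponent family

    chi(n) = 2**(1 - n),

which governs (i) the decay of the survival probability,
``S ~ (1+t)^{-chi}``; (ii) the generating-function asymptotics; (iii) the
stationary algebraic tail of the cell-number mass functions,
``(size)^{-1-chi}``; and (iv) the arrival-time scaling
``nu^{1-chi} tanh(nu^{1-chi} t)``.  The survival-tail exponent sometimes
written with a separate symbol coincides with this family; a single
exponent function is exported.

The scaled number of last-type cells conditioned on its presence,
``Z_n(t)/t | Z_n(t) > 0``, converges to a limit variable with density
``chi * F(1 + chi; 2; -y)`` (Kummer confluent hypergeometric) and
Laplace transform ``1 - (p/(p+1))**chi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma

import numpy as np
from scipy.special import hyp1f1, poch

__all__ = [
    "chi",
    "Expansion",
    "survival_expansion",
    "gap_expansion",
    "scaling_density",
    "laplace_transform",
    "pmf_scaling",
    "pmf_tail",
    "tail_validity",
    "arrival_scaling",
]


def chi(n: int) -> float:
    """Survival/tail exponent 2^(1-n) of the n-type chain."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 ** (1 - n)


@dataclass(frozen=True)
class Expansion:
    """Asymptotic series sum_k coeff_k * (1+t)^(-expo_k), exponents increasing."""

    target: str
    terms: tuple[tuple[float, float], ...]  # (coefficient, exponent)

    def __post_init__(self):
        expos = [e for _, e in self.terms]
        if any(b <= a for a, b in zip(expos, expos[1:])):
            raise ValueError("exponents must be strictly increasing")

    @property
    def order(self) -> int:
        return len(self.terms)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = sum(c * (1.0 + t) ** -e for c, e in self.terms)
        return out[()] if np.ndim(out) == 0 else out


def survival_expansion(n: int, order: int = 2) -> Expansion:
    """Matched-asymptotics expansion of S_{1,n}(t) for t -> infinity.

    Order 2 is available for every n >= 2:
    ``(1+t)^{-chi} + (chi/2) (1+t)^{-1/2-chi}``.  The third term,
    ``(3/32)(1+t)^{-3/2}``, is only known for the next-to-last starter
    (n = 2 when starting from type 1).  For n = 1 the single term
    ``(1+t)^{-1}`` is exact.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        if order != 1:
            raise ValueError("the single-type survival is exactly (1+t)^-1; order must be 1")
        return Expansion("S_1,1", ((1.0, 1.0),))
    x = chi(n)
    terms = [(1.0, x), (x / 2.0, 0.5 + x)]
    if order == 1:
        terms = terms[:1]
    elif order == 3:
        if n != 2:
            raise ValueError("third-order term is only available for n = 2")
        terms.append((3.0 / 32.0, 1.5))
    elif order != 2:
        raise ValueError(f"unsupported order {order}")
    return Expansion(f"S_1,{n}", tuple(terms))


def gap_expansion(j: int) -> Expansion:
    """Two-term expansion of S_{n-j,n}: start j types before the last.

    ``(1+t)^{-chi(j+1)} + 2^{-j-1} (1+t)^{-1/2-chi(j+1)}``; depends only
    on the gap j, by decomposability.
    """
    if j < 1:
        raise ValueError("gap j must be >= 1")
    x = chi(j + 1)
    return Expansion(f"S_n-{j},n", ((1.0, x), (2.0 ** (-j - 1), 0.5 + x)))


def _hyp1f1_neg(a: float, y):
    """M(a; 2; -y) for y >= 0, switching to the large-argument branch.

    For y > 50 the algebraic large-argument branch is used so the deep
    tail stays free of the direct series' cancellation:
    M(a;2;-y) ~ y^{-a}/Gamma(2-a) * sum_s (a)_s (a-1)_s / s! * y^{-s};
    18 terms keep the truncation below 1e-13 at the switch point.
    """
    y = np.asarray(y, dtype=float)
    if abs(a - 2.0) < 1e-12:
        return np.exp(-y)  # M(2;2;-y): the single-type exponential case
    out = np.empty_like(y)
    small = y <= 50.0
    out[small] = hyp1f1(a, 2.0, -y[small])
    yl = y[~small]
    if yl.size:
        acc = np.zeros_like(yl)
        for s in range(18):
            acc += poch(a, s) * poch(a - 1.0, s) / gamma(s + 1.0) * yl ** (-float(s))
        out[~small] = yl ** (-a) / gamma(2.0 - a) * acc
    return out


def scaling_density(n: int, y) -> np.ndarray:
    """Density of Y_n, the t -> infinity limit of Z_n(t)/t given presence.

    ``f(y) = chi * F(1 + chi; 2; -y)``; for n = 1 this is the exponential
    density e^{-y} (F(2;2;-y) = e^{-y}).
    """
    x = chi(n)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("the scaling variable y is non-negative")
    out = x * _hyp1f1_neg(1.0 + x, y)
    return out[()] if out.ndim == 0 else out


def laplace_transform(n: int, p) -> np.ndarray:
    """E[e^{-p Y_n}] = 1 - (p/(p+1))^chi."""
    x = chi(n)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("the Laplace variable p is non-negative")
    out = 1.0 - (p / (p + 1.0)) ** x
    return out[()] if out.ndim == 0 else out


def pmf_scaling(n: int, s, t: float) -> np.ndarray:
    """Scaling-form approximation to P(Z_n(t) = s): chi t^{-1-chi} F(1+chi;2;-s/t).

    For n = 1 this reduces to the exact geometric limit t^{-2} e^{-s/t}.
    The same form approximates the total-population mass function, since
    the surviving system is dominated by its last type.
    """
    if t <= 0:
        raise ValueError("the scaling form needs t > 0")
    s = np.asarray(s, dtype=float)
    x = chi(n)
    out = x * t ** (-1.0 - x) * _hyp1f1_neg(1.0 + x, s / t)
    return out[()] if out.ndim == 0 else out


def pmf_tail(n: int, s) -> np.ndarray:
    """Stationary algebraic tail chi/Gamma(1-chi) * s^{-1-chi}, n >= 2.

    Time-independent inside the validity window; the single-type chain
    (n = 1) has an exponential, not algebraic, tail and is rejected.
    """
    if n < 2:
        raise ValueError("the algebraic tail exists only for n >= 2")
    x = chi(n)
    s = np.asarray(s, dtype=float)
    out = x / gamma(1.0 - x) * s ** (-1.0 - x)
    return out[()] if out.ndim == 0 else out


def tail_validity(
    n: int, t: float, lo_factor: float = 5.0, hi_factor: float = 5.0
) -> tuple[float, float]:
    """Window (s_lo, s_hi) where the stationary tail applies: t << s << s*.

    The cutoff s* ∝ t^{(n-1)/(1-chi)} restores the finite mean t^{n-1};
    the "much less than" margins default to factors of 5 on both sides
    (the theory fixes only the proportionalities).
    """
    if n < 2:
        raise ValueError("the algebraic tail exists only for n >= 2")
    x = chi(n)
    s_lo = lo_factor * t
    s_hi = t ** ((n - 1) / (1.0 - x)) / hi_factor
    return s_lo, s_hi


def arrival_scaling(n: int, nu: float, t) -> np.ndarray:
    """Scaling approximation to P(T_n <= t): nu^{1-chi} tanh(nu^{1-chi} t).

    Exact for n = 2; for higher types it is the nu -> 0 scaling limit,
    with the defective total mass nu^{1-chi} as t -> infinity.
    """
    if n < 2:
        raise ValueError("arrival scaling needs n >= 2")
    if not 0 < nu <= 1:
        raise ValueError("mutation rate nu must be in (0, 1]")
    rate = nu ** (1.0 - chi(n))
    t = np.asarray(t, dtype=float)
    out = rate * np.tanh(rate * t)
    return out[()] if out.ndim == 0 else out
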