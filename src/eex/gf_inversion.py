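"""Coefficient extraction from probability generating functions by FFT.

A probability mass function hidden in an analytic generating function
``G(x) = sum_s P_s x^s`` is recovered through Cauchy's integral formula,
discretised on a circle of radius ``r < 1``:

    P_s = r^{-s} / N * sum_k G(r e^{2 pi i k / N}) e^{-2 pi i k s / N},

i.e. an inverse FFT of the contour samples.  The two-variable (joint)
case nests the same construction per axis.

Two error sources are controlled explicitly.  *Aliasing* adds
``sum_{m>=1} P_{s+mN} r^{mN}``, suppressed by taking ``N`` a multiple of
the requested truncation.  *Amplification* multiplies round-off on the
contour by ``r^{-s}``, which bounds the usable truncation at roughly
(machine digits)/|log10 r|; requests beyond the bound raise, and an
arbitrary-precision mode is available for deep tails.  The contour must
stay inside the unit disk because the two-type generating function is
singular at ``x2 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import exact_solutions as ex

__all__ = [
    "ProbabilityMass",
    "InversionQualityError",
    "max_resolvable_index",
    "invert_1d",
    "invert_2d",
    "marginal_type2_pmf",
    "total_pmf_two_type",
]

#: negative values smaller than this are treated as round-off and zeroed
ROUNDOFF_TOL = 1e-12
#: double precision mantissa, in decimal digits, used for the s_max bound
MACHINE_DIGITS = 15.65


class InversionQualityError(RuntimeError):
    """The inversion shows symptoms of aliasing or amplification failure."""


@dataclass
class ProbabilityMass:
    """An extracted (possibly truncated) probability mass function.

    ``values[s]`` (or ``values[a, b]`` in the joint case) approximates
    the mass at count ``s``; ``normalization_deficit`` is the tail mass
    beyond the truncation, ``1 - sum(values)``.
    """

    values: np.ndarray
    t: Optional[float]
    truncation: int
    radius: float
    normalization_deficit: float
    provenance: str
    max_imag: float = 0.0

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.values.shape[0])

    def to_frame(self):
        import pandas as pd

        if self.values.ndim == 1:
            return pd.DataFrame({"s": self.support, "probability": self.values})
        a, b = np.indices(self.values.shape)
        return pd.DataFrame(
            {"a": a.ravel(), "b": b.ravel(), "probability": self.values.ravel()}
        )


def max_resolvable_index(radius: float, digits: float = MACHINE_DIGITS) -> int:
    """Largest coefficient index resolvable at this contour radius.

    Round-off of size 10^-digits on the contour is amplified by
    ``r^{-s}``; beyond ``digits / |log10 r|`` the extracted value is
    noise.
    """
    if not 0 < radius < 1:
        raise ValueError("contour radius must be in (0, 1)")
    return int(digits / abs(np.log10(radius)))


def _clean(values: np.ndarray, provenance: str) -> np.ndarray:
    worst = values.min() if values.size else 0.0
    if worst < -ROUNDOFF_TOL:
        raise InversionQualityError(
            f"{provenance}: negative mass {worst:.3e} exceeds round-off tolerance"
        )
    return np.where(values < 0, 0.0, values)


def invert_1d(
    gf: Callable[[np.ndarray], np.ndarray],
    s_max: int,
    radius: float = 0.99,
    points: Optional[int] = None,
    t: Optional[float] = None,
    provenance: str = "gf",
    imag_tol: float = 1e-8,
    precision: Optional[int] = None,
) -> ProbabilityMass:
    """Extract coefficients 0..s_max of a generating function.

    ``gf`` must accept a complex ndarray (the contour samples).  With
    ``precision`` set, the contour sum is accumulated in arbitrary
    precision instead of an FFT — ``gf`` is then called pointwise with
    complex scalars — lifting the amplification bound for deep tails.
    """
    if s_max < 0:
        raise ValueError("s_max must be >= 0")
    if not 0 < radius < 1:
        raise ValueError("contour radius must be in (0, 1)")
    if precision is None and s_max > max_resolvable_index(radius):
        raise InversionQualityError(
            f"s_max={s_max} exceeds the amplification bound "
            f"{max_resolvable_index(radius)} at radius {radius}; "
            "increase the radius toward 1 or use the high-precision mode"
        )
    if points is None:
        points = max(8 * s_max, 2 * (s_max + 1), 64)
    if points < 2 * (s_max + 1):
        raise ValueError("points must be at least 2*(s_max+1) to control aliasing")

    if precision is not None:
        return _invert_1d_mp(gf, s_max, radius, points, t, provenance, precision)

    k = np.arange(points)
    x = radius * np.exp(2j * np.pi * k / points)
    vals = np.asarray(gf(x), dtype=complex)
    coeffs = np.fft.fft(vals) / points
    kept = coeffs[: s_max + 1] / radius ** np.arange(s_max + 1)
    max_imag = float(np.max(np.abs(kept.imag))) if kept.size else 0.0
    if max_imag > imag_tol:
        raise InversionQualityError(
            f"{provenance}: imaginary residue {max_imag:.3e} above tolerance {imag_tol}"
        )
    values = _clean(kept.real.copy(), provenance)
    deficit = float(1.0 - values.sum())
    if deficit < -1e-6:
        raise InversionQualityError(
            f"{provenance}: total mass exceeds 1 by {-deficit:.3e}"
        )
    return ProbabilityMass(values, t, s_max, radius, deficit, provenance, max_imag)


def _invert_1d_mp(gf, s_max, radius, points, t, provenance, dps):
    import mpmath as mp

    with mp.workdps(dps):
        r = mp.mpf(radius)
        samples = []
        for k in range(points):
            x = r * mp.e ** (2j * mp.pi * k / points)
            samples.append(mp.mpc(gf(x)))
        values = np.empty(s_max + 1)
        for s in range(s_max + 1):
            acc = mp.mpc(0)
            for k, v in enumerate(samples):
                acc += v * mp.e ** (-2j * mp.pi * k * s / points)
            values[s] = float(mp.re(acc) / points / r**s)
    values = _clean(values, provenance)
    deficit = float(1.0 - values.sum())
    return ProbabilityMass(values, t, s_max, radius, deficit, provenance)


def invert_2d(
    gf: Callable[[np.ndarray, np.ndarray], np.ndarray],
    a_max: int,
    b_max: int,
    radii: tuple[float, float] = (0.99, 0.99),
    points: Optional[tuple[int, int]] = None,
    t: Optional[float] = None,
    provenance: str = "joint gf",
    imag_tol: float = 1e-8,
) -> ProbabilityMass:
    """Joint coefficients P_{a,b} of a two-variable generating function.

    Nested contour integration realised as a 2-D FFT; marginals are
    recovered by summing the returned matrix along an axis.
    """
    r1, r2 = radii
    for r, m in ((r1, a_max), (r2, b_max)):
        if not 0 < r < 1:
            raise ValueError("contour radii must be in (0, 1)")
        if m > max_resolvable_index(r):
            raise InversionQualityError(
                f"truncation {m} exceeds the amplification bound at radius {r}"
            )
    if points is None:
        points = (max(4 * (a_max + 1), 64), max(4 * (b_max + 1), 64))
    n1, n2 = points
    x1 = r1 * np.exp(2j * np.pi * np.arange(n1) / n1)
    x2 = r2 * np.exp(2j * np.pi * np.arange(n2) / n2)
    vals = np.asarray(gf(x1[:, None], x2[None, :]), dtype=complex)
    coeffs = np.fft.fft2(vals) / (n1 * n2)
    kept = coeffs[: a_max + 1, : b_max + 1]
    kept = kept / np.outer(r1 ** np.arange(a_max + 1), r2 ** np.arange(b_max + 1))
    max_imag = float(np.max(np.abs(kept.imag)))
    if max_imag > imag_tol:
        raise InversionQualityError(
            f"{provenance}: imaginary residue {max_imag:.3e} above tolerance {imag_tol}"
        )
    values = _clean(kept.real.copy(), provenance)
    deficit = float(1.0 - values.sum())
    if deficit < -1e-6:
        raise InversionQualityError(
            f"{provenance}: total mass exceeds 1 by {-deficit:.3e}"
        )
    return ProbabilityMass(values, t, max(a_max, b_max), r1, deficit, provenance, max_imag)


def marginal_type2_pmf(
    t: float,
    s_max: int,
    radius: float = 0.99,
    points: Optional[int] = None,
    precision: Optional[int] = None,
) -> ProbabilityMass:
    """P(Z_2(t) = s) of the two-type chain, from the x1 = 1 slice.

    The amplitude constant is evaluated at x1 = 1, where it degenerates
    to a ratio of I and K at ``2/sqrt(1-x2)``.
    """
    if t <= 0:
        raise ValueError("the marginal at t = 0 is deterministic; need t > 0")
    gf = lambda x: ex.two_type_gf(1.0, x, t, precision=precision)
    return invert_1d(
        gf, s_max, radius, points, t=t, provenance="type-2 marginal", precision=precision
    )


def total_pmf_two_type(
    t: float,
    s_max: int,
    radius: float = 0.99,
    points: Optional[int] = None,
    precision: Optional[int] = None,
) -> ProbabilityMass:
    """P(Z_1(t) + Z_2(t) = s): invert the diagonal slice x1 = x2 = x."""
    if t <= 0:
        raise ValueError("need t > 0")
    gf = lambda x: ex.two_type_gf(x, x, t, precision=precision)
    return invert_1d(
        gf, s_max, radius, points, t=t, provenance="two-type total", precision=precision
    )
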