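"""Biological summaries: experiment-design quantities and genetic diversity.

For colony experiments (microbes at an intolerable mutation rate) the
useful numbers are the probability that a colony seeded by one cell is
still alive after ``t`` generations, the number of generations until
that probability falls below a threshold, and the expected colony size
— all as functions of the maximal number ``n`` of mutations a cell can
tolerate.  For genetic structure, the Shannon index of the type
proportions and the expected number of types present quantify the rise
and collapse of diversity as the population becomes dominated by the
last type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaincc

from . import exact_solutions as ex
from . import ode_numerics as ode
from .asymptotics import chi, survival_expansion
from .model import TimeGrid, Trajectory

__all__ = [
    "DiversityCurve",
    "shannon",
    "expected_types",
    "survival_after_generations",
    "generations_to_survival",
    "expected_colony_size",
]


@dataclass
class DiversityCurve:
    """Diversity summaries on a time grid.

    ``shannon`` holds H'(t) (nan where the population is extinct),
    ``proportions`` the p_i(t), ``expected_types`` K_n(t) when computed
    from the presence ODEs.
    """

    t_grid: TimeGrid
    shannon: Optional[np.ndarray] = None
    proportions: Optional[np.ndarray] = None  # (n, T)
    expected_types: Optional[np.ndarray] = None
    asymptote: Optional[np.ndarray] = None


def _counts_on_grid(traj: Trajectory, t_grid: TimeGrid) -> np.ndarray:
    """Left-continuous step interpolation of recorded counts onto a grid."""
    idx = np.searchsorted(traj.times, t_grid.points, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("grid starts before the first recorded time")
    return traj.counts[idx]


def shannon(traj: Trajectory, t_grid: Optional[TimeGrid] = None, base: float = np.e) -> DiversityCurve:
    """Shannon diversity H'(t) = -sum_i p_i log p_i of one trajectory.

    ``0 log 0`` is taken as 0; H' is recorded as nan whenever the
    population is extinct (proportions undefined).  Natural log by
    default, so H' is bounded by log(n).
    """
    if t_grid is None:
        t_grid = TimeGrid(traj.times)
        counts = traj.counts
    else:
        counts = _counts_on_grid(traj, t_grid)
    totals = counts.sum(axis=1).astype(float)
    alive = totals > 0
    p = np.zeros_like(counts, dtype=float)
    p[alive] = counts[alive] / totals[alive, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(base)
    h[~alive] = np.nan
    return DiversityCurve(t_grid=t_grid, shannon=h, proportions=p.T)


def expected_types(n: int, t_grid: TimeGrid, rtol: float = ode.DEFAULT_RTOL,
                   atol: float = ode.DEFAULT_ATOL) -> DiversityCurve:
    """Expected number of types present, K_n(t) = sum_{i<=n} Q_{1,i}(t).

    The presence probability of type i in the n-type chain equals the
    last-type presence probability of the i-type chain (decomposability),
    so each term is one presence solve; Q_{1,1} is the single-type
    survival 1/(1+t).  The leading large-t decay t^{-chi(n)} is returned
    alongside.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    K = ex.single_type_survival(t_grid.points).copy()
    for i in range(2, n + 1):
        K += ode.solve_presence(i, t_grid, rtol=rtol, atol=atol).component(1)
    with np.errstate(divide="ignore"):
        asym = t_grid.points ** -chi(n)
    return DiversityCurve(t_grid=t_grid, expected_types=K, asymptote=asym)


def survival_after_generations(
    n: int, t: float, method: str = "auto"
) -> float:
    """P(colony alive after t generations), one initial cell, n tolerable mutations.

    ``method="auto"`` uses the exact laws for n <= 2 and the ODE system
    for n >= 3; ``method="expansion"`` is the labeled fast path through
    the second-order large-time expansion (accurate for large t only).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if t < 0:
        raise ValueError("t must be non-negative")
    if method == "expansion":
        order = 1 if n == 1 else 2
        return float(survival_expansion(n, order)(t))
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if n == 1:
        return float(ex.single_type_survival(t))
    if n == 2:
        return float(ex.two_type_survival(t))
    if t == 0:
        return 1.0
    grid = TimeGrid.log(t, 120, t_min=min(1e-3, t / 10.0))
    return float(ode.solve_survival(n, grid).component(1)[-1])


def generations_to_survival(n: int, p: float, method: str = "auto") -> float:
    """Number of generations until the survival probability falls to p.

    ``method="auto"`` inverts the exact (n <= 2) or ODE (n >= 3) survival
    by bracketed root finding; the crossing is unique since survival
    decreases from 1.  ``method="expansion"`` inverts the second-order
    large-time expansion instead — the only tractable route when the
    horizon is astronomically long (small chi and small p put the
    crossing at (1/p)^(1/chi) generations, far beyond any ODE solve) and
    accurate there because the expansion error vanishes as t grows.
    """
    if not 0 < p < 1:
        raise ValueError("target probability must be in (0, 1)")
    if method == "expansion":
        if n == 1:
            return 1.0 / p - 1.0
        x = chi(n)
        # solve in u = log(1+t); exp(-x u) terms stay finite for any horizon
        f = lambda u: np.exp(-x * u) + x / 2 * np.exp(-(0.5 + x) * u) - p
        u = brentq(f, 0.0, 800.0, xtol=1e-12)
        return float(np.expm1(u)) if u < 700 else float(np.exp(u))
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if n == 1:
        return 1.0 / p - 1.0
    if n == 2:
        f = lambda logt: ex.two_type_survival(np.expm1(logt)) - p
    else:
        t_hi = max(10.0, (2.0 / p) ** (1.0 / chi(n)))
        if t_hi > 1e10:
            raise ValueError(
                "crossing beyond t = 1e10 is out of reach for the ODE route; "
                "use method='expansion'"
            )
        grid = TimeGrid.log(t_hi, 400)
        S = ode.solve_survival(n, grid).component(1)
        # interpolate the crossing on the precomputed monotone curve
        j = int(np.searchsorted(-S, -p))
        if j == 0:
            return 0.0
        if j >= len(S):
            raise RuntimeError("survival did not reach the target on the bracket")
        t0, t1 = grid.points[j - 1], grid.points[j]
        s0, s1 = S[j - 1], S[j]
        return float(t0 + (p - s0) * (t1 - t0) / (s1 - s0))
    lo, hi = 0.0, np.log1p(10.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 50:
            raise RuntimeError("failed to bracket the survival crossing")
    return float(np.expm1(brentq(f, lo, hi, xtol=1e-12)))


def expected_colony_size(n: int, t, with_reference: bool = False):
    """Expected total cells after t generations: sum_{i<=n} t^{i-1}/(i-1)!.

    Evaluated as ``e^t * Gamma(n, t)/Gamma(n)`` (regularised upper
    incomplete gamma), which is stable for large n and t.  As n grows
    the size plateaus at the unbounded-mutation reference e^t, returned
    when ``with_reference`` is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    t = np.asarray(t, dtype=float)
    size = np.exp(t) * gammaincc(n, t)
    size = size[()] if size.ndim == 0 else size
    if with_reference:
        return size, np.exp(t)[()] if np.ndim(t) == 0 else np.exp(t)
    return size
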