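"""Numerical solutions of the backward ODE families for arbitrary n.

Three closed systems are solved on a time grid:

* **survival** — ``dS_i/dt = S_{i+1} - S_i^2`` (last component
  ``dS_n/dt = -S_n^2``), ``S_i(0) = 1``: probability the whole system is
  non-empty at ``t`` starting from one type-``i`` cell.
* **presence** — the same right-hand side with ``Q_i(0) = 0`` for
  ``i < n`` and ``Q_n(0) = 1``: probability a last-type cell is present.
* **arrival** — ``dg_i/dt = -g_i^2 + nu * g_{i+1}`` with ``g_i(0) = 0``
  and ``g_n ≡ 1``: distribution function of the first-arrival time of
  type ``n``, in the critical family with constant mutation rate ``nu``
  (death rate ``1 - nu``).  The complementary ``h = 1 - g`` system is
  recovered as ``1 - g``; integrating in ``g`` keeps the equations
  autonomous-quadratic and well conditioned near the defective limit.

The integrator is LSODA (adaptive, stiffness-switching) at tight default
tolerances; solutions stay honest in the state (no clipping), with
clipping to [0, 1] applied only when reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .asymptotics import chi
from .model import TimeGrid

__all__ = [
    "OdeSolution",
    "solve_survival",
    "solve_presence",
    "solve_arrival",
    "arrival_limit",
    "maximal_type_law",
]

DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12


@dataclass
class OdeSolution:
    """Solution of one ODE family on a grid.

    ``values[i - 1]`` is the component started from (survival/presence)
    or tracking (arrival) type ``i``; shape ``(n, len(t_grid))``.
    """

    system: str
    n: int
    t_grid: TimeGrid
    values: np.ndarray
    rtol: float
    atol: float
    nu: Optional[float] = None
    nfev: int = 0

    def component(self, i: int) -> np.ndarray:
        """1-based access: component(1) is the quantity started from type 1."""
        if not 1 <= i <= self.n:
            raise ValueError(f"component index must be in 1..{self.n}")
        return self.values[i - 1]

    @property
    def clipped(self) -> np.ndarray:
        """Values clipped to [0, 1] for reporting."""
        return np.clip(self.values, 0.0, 1.0)

    def to_frame(self):
        import pandas as pd

        T = len(self.t_grid)
        return pd.DataFrame(
            {
                "time": np.repeat(self.t_grid.points, self.n),
                "component": np.tile(np.arange(1, self.n + 1), T),
                "value": self.values.T.ravel(),
            }
        )


def _integrate(rhs, y0, t_grid: TimeGrid, rtol, atol):
    pts = t_grid.points
    t0 = pts[0]
    sol = solve_ivp(
        rhs,
        (t0, pts[-1]),
        y0,
        t_eval=pts,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol


def _survival_rhs(t, S):
    d = np.empty_like(S)
    d[:-1] = S[1:] - S[:-1] ** 2
    d[-1] = -S[-1] ** 2
    return d


def solve_survival(
    n: int,
    t_grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> OdeSolution:
    """Total-survival probabilities S_{i,n}(t) for i = 1..n.

    The backwards-coupled quadratic system closes from the last type
    downwards; the last component is the single-type law 1/(1+t) and each
    earlier component decays with the halved exponent of its successor
    (2^{1-n} for the first).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if t_grid.points[0] != 0:
        raise ValueError("survival system must start at t = 0")
    sol = _integrate(_survival_rhs, np.ones(n), t_grid, rtol, atol)
    return OdeSolution("survival", n, t_grid, sol.y, rtol, atol, nfev=sol.nfev)


def solve_presence(
    n: int,
    t_grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> OdeSolution:
    """Last-type presence probabilities Q_{i,n}(t), i = 1..n.

    Same equations as the survival system but started from
    ``Q_i(0) = 0`` for ``i < n`` (no last-type cell yet) and
    ``Q_n(0) = 1``.  Q_{1,n} <= S_{1,n} pointwise and the two agree
    asymptotically: the surviving system is dominated by the last type.
    """
    if n < 2:
        raise ValueError("presence system needs n >= 2")
    if t_grid.points[0] != 0:
        raise ValueError("presence system must start at t = 0")
    y0 = np.zeros(n)
    y0[-1] = 1.0
    sol = _integrate(_survival_rhs, y0, t_grid, rtol, atol)
    return OdeSolution("presence", n, t_grid, sol.y, rtol, atol, nfev=sol.nfev)


def solve_arrival(
    n: int,
    nu: float,
    t_grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> OdeSolution:
    """Arrival-time distribution functions g_{i,n}(t), i = 1..n.

    Component 1 is P(T_n <= t) from a single type-1 cell.  The returned
    matrix includes the constant last component g_n ≡ 1.  For nu = 1
    (pure birth-mutation) and n = 2 the solution is tanh(t); generally
    g_{1,2} = sqrt(nu) tanh(sqrt(nu) t).
    """
    if n < 2:
        raise ValueError("arrival system needs n >= 2")
    if not 0 < nu <= 1:
        raise ValueError("mutation rate nu must be in (0, 1]")
    if t_grid.points[0] != 0:
        raise ValueError("arrival system must start at t = 0")

    # state holds g_1..g_{n-1}; g_n is identically one
    def rhs_free(t, g):
        nxt = np.empty_like(g)
        nxt[:-1] = g[1:]
        nxt[-1] = 1.0
        return -(g**2) + nu * nxt

    sol = _integrate(rhs_free, np.zeros(n - 1), t_grid, rtol, atol)
    values = np.vstack([sol.y, np.ones(len(t_grid))])
    return OdeSolution("arrival", n, t_grid, values, rtol, atol, nu=nu, nfev=sol.nfev)


def arrival_limit(n: int, nu: float, numeric: bool = False) -> float:
    """Probability that a type-n cell ever arrives: nu^(1 - 2^(1-n)).

    At nu = 1 every type arrives with probability one.  With
    ``numeric=True`` the limit is instead read off a long-horizon solve
    of the arrival system (the horizon scales like the inverse limiting
    rate), useful for cross-checking the closed form.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < nu <= 1:
        raise ValueError("mutation rate nu must be in (0, 1]")
    if n == 1:
        return 1.0  # the initial cell is already of type 1
    if not numeric:
        return float(nu ** (1.0 - chi(n)))
    t_max = 20.0 * nu ** -(1.0 - chi(n))
    grid = TimeGrid.log(t_max, 200)
    sol = solve_arrival(n, nu, grid)
    return float(sol.component(1)[-1])


def maximal_type_law(nu: float, n_max: int) -> np.ndarray:
    """P(M >= n) for n = 1..n_max, M the maximal type that ever appears.

    Equals the arrival limits nu^(1 - 2^(1-n)); successive conditional
    ratios nu^(2^-n) tend to one, so the mean of M is infinite even for
    tiny mutation rates.
    """
    if not 0 < nu <= 1:
        raise ValueError("mutation rate nu must be in (0, 1]")
    ns = np.arange(1, n_max + 1)
    return nu ** (1.0 - 2.0 ** (1 - ns))
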