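"""Exact stochastic simulation (Gillespie SSA) of the n-type process.

The direct method is used: with per-type counts ``Z_i`` the total event
rate is ``Lambda = sum_i (birth_i + death_i + mutation_i) Z_i``, waiting
times are exponential with rate ``Lambda``, and the event is chosen with
probability proportional to its propensity.  No tau-leaping is used:
criticality keeps populations small over the horizons of interest and
exactness is the point.

Ensembles draw one independent substream per replicate from the pair
``(seed, replicate)`` via :class:`numpy.random.SeedSequence`, so runs are
reproducible and trivially parallelizable, and the underlying bit
generator (PCG64) is pinned across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .model import ProcessSpec, TimeGrid, Trajectory

__all__ = [
    "CapExceededError",
    "EnsembleSummary",
    "simulate",
    "simulate_until_extinction",
    "ensemble",
    "empirical_pmf",
    "wilson_halfwidth",
]

#: default safety caps; critical processes have infinite-mean extinction
#: times, so unbounded runs must be guarded.
DEFAULT_MAX_EVENTS = 10**8
DEFAULT_MAX_CELLS = 10**7

_CHUNK = 4096  # uniforms drawn per RNG call in the event loop


class CapExceededError(RuntimeError):
    """An event-count or population cap was hit; carries the partial run."""

    def __init__(self, message: str, trajectory: Trajectory):
        super().__init__(message)
        self.trajectory = trajectory


class _Uniforms:
    """Chunked stream of U(0,1) draws from a numpy Generator."""

    __slots__ = ("rng", "buf", "i")

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.buf = rng.random(_CHUNK)
        self.i = 0

    def next(self) -> float:
        i = self.i
        if i == _CHUNK:
            self.buf = self.rng.random(_CHUNK)
            i = 0
        self.i = i + 1
        return self.buf[i]


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate(
    spec: ProcessSpec,
    t_max: float,
    seed: Union[int, np.random.SeedSequence],
    record: str = "grid",
    t_grid: Optional[TimeGrid] = None,
    max_events: int = DEFAULT_MAX_EVENTS,
    max_cells: int = DEFAULT_MAX_CELLS,
    stop_on_type: Optional[int] = None,
) -> Trajectory:
    """Run one exact SSA realization up to ``t_max`` (or extinction).

    Parameters
    ----------
    record
        ``"grid"`` stores counts at the times of ``t_grid`` (state
        left-continuous at each grid time, i.e. just before any event
        falling exactly there); ``"events"`` stores the state after every
        event.
    stop_on_type
        1-based type index; the run stops as soon as a cell of this type
        exists (its arrival time recorded exactly).  Useful for sampling
        arrival times T_k without paying for the rest of the excursion.
    """
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    if record not in ("grid", "events"):
        raise ValueError(f"record must be 'grid' or 'events', got {record!r}")
    if record == "grid":
        if not np.isfinite(t_max):
            raise ValueError("grid recording needs a finite t_max")
        if t_grid is None:
            t_grid = TimeGrid.linear(t_max, 51) if t_max > 0 else TimeGrid([0.0])
        grid = t_grid.points
        if grid[-1] > t_max:
            raise ValueError("recording grid extends beyond t_max")
    else:
        grid = None

    rng = np.random.default_rng(_as_seed_sequence(seed))
    u = _Uniforms(rng)

    n = spec.n
    birth = spec.birth
    death = spec.death
    mut = spec.mutation
    total_rate = tuple(b + d + m for b, d, m in zip(birth, death, mut))

    z = list(spec.initial)
    t = 0.0
    pop = sum(z)
    arrivals = [0.0 if z[i] > 0 else np.nan for i in range(n)]
    extinct_at = [np.nan] * n  # candidate last-presence time per type

    stop_idx = None if stop_on_type is None else stop_on_type - 1
    if stop_idx is not None and not 0 <= stop_idx < n:
        raise ValueError(f"stop_on_type must be in 1..{n}")

    rec_t: list[float] = []
    rec_z: list[list[int]] = []
    gi = 0

    def record_grid_upto(limit: float) -> None:
        # record the pre-event state at every grid time <= limit
        nonlocal gi
        while gi < len(grid) and grid[gi] <= limit:
            rec_t.append(grid[gi])
            rec_z.append(z.copy())
            gi += 1

    if record == "events":
        rec_t.append(0.0)
        rec_z.append(z.copy())

    n_events = 0
    capped = False
    cap_msg = ""
    log = np.log
    while not (stop_idx is not None and z[stop_idx] > 0):
        lam = 0.0
        for i in range(n):
            lam += total_rate[i] * z[i]
        if lam == 0.0:
            if np.isfinite(t_max):
                t = t_max  # nothing can ever happen again
            break
        dt = -log(1.0 - u.next()) / lam
        t_next = t + dt
        if t_next > t_max:
            t = t_max
            break
        if grid is not None:
            record_grid_upto(t_next)
        # pick the event
        x = u.next() * lam
        ev_type = -1
        kind = 0  # 0 birth, 1 death, 2 mutation
        for i in range(n):
            zi = z[i]
            if zi == 0:
                continue
            r = birth[i] * zi
            if x < r:
                ev_type, kind = i, 0
                break
            x -= r
            r = death[i] * zi
            if x < r:
                ev_type, kind = i, 1
                break
            x -= r
            r = mut[i] * zi
            if x < r:
                ev_type, kind = i, 2
                break
            x -= r
        else:  # numerical round-off at the boundary: take the last active type
            for i in range(n - 1, -1, -1):
                if z[i] > 0 and total_rate[i] > 0:
                    ev_type = i
                    kind = 0 if birth[i] > 0 else (1 if death[i] > 0 else 2)
                    break
        t = t_next
        if kind == 0:
            z[ev_type] += 1
            pop += 1
            extinct_at[ev_type] = np.nan
        else:
            z[ev_type] -= 1
            pop -= 1
            if z[ev_type] == 0:
                extinct_at[ev_type] = t
            if kind == 2:
                j = ev_type + 1
                if z[j] == 0:
                    extinct_at[j] = np.nan
                z[j] += 1
                pop += 1
                if np.isnan(arrivals[j]):
                    arrivals[j] = t
        if record == "events":
            rec_t.append(t)
            rec_z.append(z.copy())
        n_events += 1
        if n_events >= max_events:
            capped, cap_msg = True, f"event cap {max_events} exceeded"
            break
        if pop >= max_cells:
            capped, cap_msg = True, f"population cap {max_cells} exceeded"
            break

    stopped_early = stop_idx is not None and z[stop_idx] > 0
    if grid is not None and not stopped_early:
        record_grid_upto(t_max)

    alive = [z[i] > 0 for i in range(n)]
    extinctions = np.empty(n)
    censored = np.zeros(n, dtype=bool)
    finite_horizon = capped or any(alive)
    for k in range(n):
        if alive[k]:
            extinctions[k] = t
            censored[k] = True
        else:
            extinctions[k] = extinct_at[k]
            # an extinct type can recur while any earlier type survives
            if finite_horizon and any(alive[:k]):
                censored[k] = True

    traj = Trajectory(
        times=np.asarray(rec_t, dtype=float),
        counts=np.asarray(rec_z, dtype=np.int64).reshape(len(rec_t), n),
        arrivals=np.asarray(arrivals, dtype=float),
        extinctions=extinctions,
        censored=censored,
        seed=seed,
        spec=spec,
        capped=capped,
    )
    if capped:
        raise CapExceededError(cap_msg, traj)
    return traj


def simulate_until_extinction(
    spec: ProcessSpec,
    seed: Union[int, np.random.SeedSequence],
    record: str = "events",
    max_events: int = DEFAULT_MAX_EVENTS,
    max_cells: int = DEFAULT_MAX_CELLS,
) -> Trajectory:
    """Run a single realization until the whole system is extinct.

    Only almost-surely extinct (critical or subcritical) processes should
    be run this way without generous caps; the caps raise
    :class:`CapExceededError` carrying the partial trajectory otherwise.
    """
    return simulate(
        spec,
        t_max=np.inf,
        seed=seed,
        record=record,
        t_grid=None,
        max_events=max_events,
        max_cells=max_cells,
    )


@dataclass
class EnsembleSummary:
    """Monte-Carlo estimators over independent replicates.

    ``survival_any`` estimates the probability that any cell is alive,
    ``survival_type_n`` that a last-type cell is alive; the half-widths are
    95% Wilson intervals.  Means average over *all* replicates (extinct
    ones contribute zeros), matching the criticality conservation law for
    the first type.
    """

    spec: ProcessSpec
    t_grid: TimeGrid
    reps: int
    seed: int
    survival_any: np.ndarray
    survival_any_halfwidth: np.ndarray
    survival_type_n: np.ndarray
    survival_type_n_halfwidth: np.ndarray
    mean_counts: np.ndarray  # (n, T)
    sem_counts: np.ndarray  # (n, T)
    arrival_samples: list  # per type, arrival times of reps where it arrived
    extinction_samples: list  # per type, (values, censored) arrays
    counts: Optional[np.ndarray] = None  # (reps, T, n) when kept

    def to_frame(self):
        import pandas as pd

        T = len(self.t_grid)
        n = self.spec.n
        rows = {
            "time": np.repeat(self.t_grid.points, n),
            "type": np.tile(np.arange(1, n + 1), T),
            "mean_count": self.mean_counts.T.ravel(),
            "sem": self.sem_counts.T.ravel(),
        }
        return pd.DataFrame(rows)


def wilson_halfwidth(k: np.ndarray, n: int, z: float = 1.959963984540054) -> np.ndarray:
    """Half-width of the Wilson score interval for ``k`` successes of ``n``."""
    k = np.asarray(k, dtype=float)
    p = k / n
    denom = 1.0 + z**2 / n
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return half


def ensemble(
    spec: ProcessSpec,
    t_grid: TimeGrid,
    reps: int,
    seed: int,
    keep_counts: bool = False,
    max_events: int = DEFAULT_MAX_EVENTS,
    max_cells: int = DEFAULT_MAX_CELLS,
) -> EnsembleSummary:
    """Independent replicates with per-replicate substreams."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    T = len(t_grid)
    n = spec.n
    t_max = t_grid.t_max

    sum_counts = np.zeros((n, T))
    sumsq_counts = np.zeros((n, T))
    alive_any = np.zeros(T, dtype=np.int64)
    alive_last = np.zeros(T, dtype=np.int64)
    arrivals: list[list[float]] = [[] for _ in range(n)]
    ext_vals: list[list[float]] = [[] for _ in range(n)]
    ext_cens: list[list[bool]] = [[] for _ in range(n)]
    stored = np.empty((reps, T, n), dtype=np.int32) if keep_counts else None

    for r in range(reps):
        traj = simulate(
            spec,
            t_max,
            seed=np.random.SeedSequence((seed, r)),
            record="grid",
            t_grid=t_grid,
            max_events=max_events,
            max_cells=max_cells,
        )
        c = traj.counts  # (T, n)
        sum_counts += c.T
        sumsq_counts += (c.T.astype(float)) ** 2
        tot = c.sum(axis=1)
        alive_any += tot > 0
        alive_last += c[:, -1] > 0
        for k in range(n):
            if not np.isnan(traj.arrivals[k]):
                arrivals[k].append(traj.arrivals[k])
            if not np.isnan(traj.extinctions[k]):
                ext_vals[k].append(traj.extinctions[k])
                ext_cens[k].append(bool(traj.censored[k]))
        if keep_counts:
            stored[r] = c

    mean = sum_counts / reps
    var = np.maximum(sumsq_counts / reps - mean**2, 0.0)
    sem = np.sqrt(var / reps)
    return EnsembleSummary(
        spec=spec,
        t_grid=t_grid,
        reps=reps,
        seed=seed,
        survival_any=alive_any / reps,
        survival_any_halfwidth=wilson_halfwidth(alive_any, reps),
        survival_type_n=alive_last / reps,
        survival_type_n_halfwidth=wilson_halfwidth(alive_last, reps),
        mean_counts=mean,
        sem_counts=sem,
        arrival_samples=[np.asarray(a) for a in arrivals],
        extinction_samples=[
            (np.asarray(v), np.asarray(c, dtype=bool))
            for v, c in zip(ext_vals, ext_cens)
        ],
        counts=stored,
    )


def empirical_pmf(
    summary: EnsembleSummary,
    t: float,
    which: Union[int, str] = "total",
    conditional: bool = False,
) -> np.ndarray:
    """Histogram of cell counts across replicates at a recorded grid time.

    ``which`` is a 1-based type index or ``"total"``.  With
    ``conditional=True`` the histogram is conditioned on the count being
    positive.  Requires the ensemble to have been run with
    ``keep_counts=True``.
    """
    if summary.counts is None:
        raise ValueError("ensemble was run without keep_counts=True")
    idx = np.nonzero(np.isclose(summary.t_grid.points, t))[0]
    if len(idx) == 0:
        raise ValueError(f"t={t} is not on the recorded grid")
    at_t = summary.counts[:, idx[0], :]
    if which == "total":
        vals = at_t.sum(axis=1)
    else:
        vals = at_t[:, int(which) - 1]
    if conditional:
        vals = vals[vals > 0]
        if len(vals) == 0:
            raise ValueError("no surviving replicates to condition on")
    pmf = np.bincount(vals) / len(vals)
    return pmf
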