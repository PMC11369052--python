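"""Process specifications, time grids and trajectory containers.

The model is a decomposable continuous-time branching process with ``n``
cell types arranged on a consecutive mutation chain ``1 -> 2 -> ... -> n``.
A type-``i`` cell divides at rate ``birth[i]``, dies at rate ``death[i]``
and mutates into a type-``i+1`` cell at rate ``mutation[i]``; the last type
cannot mutate.  The process is *critical* when every type's appearance
rate balances its disappearance rate (``birth = death + mutation``), in
which case extinction is certain although the mean population size never
decreases.

With the division rate set to one, one time unit is interpreted as one
generation (one expected cell division); this convention is documented,
not enforced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ProcessSpec",
    "TimeGrid",
    "Trajectory",
    "make_simple_spec",
    "validate",
    "load_config",
    "dump_config",
]

#: tolerance used when checking rate balance for criticality
_CRIT_TOL = 1e-12


@dataclass(frozen=True)
class ProcessSpec:
    """Rates and initial composition of an n-type birth-death-mutation process.

    Parameters
    ----------
    birth, death, mutation
        Per-type rates, each of length ``n``.  ``mutation[-1]`` must be 0:
        the last type cannot mutate.
    initial
        Initial cell counts per type.  Defaults to a single type-1 cell.
    """

    birth: tuple[float, ...]
    death: tuple[float, ...]
    mutation: tuple[float, ...]
    initial: tuple[int, ...]

    def __init__(
        self,
        birth: Sequence[float],
        death: Sequence[float],
        mutation: Sequence[float],
        initial: Optional[Sequence[int]] = None,
    ) -> None:
        birth = tuple(float(b) for b in birth)
        death = tuple(float(d) for d in death)
        mutation = tuple(float(m) for m in mutation)
        if initial is None:
            initial = (1,) + (0,) * (len(birth) - 1)
        initial = tuple(int(z) for z in initial)
        object.__setattr__(self, "birth", birth)
        object.__setattr__(self, "death", death)
        object.__setattr__(self, "mutation", mutation)
        object.__setattr__(self, "initial", initial)

    @property
    def n(self) -> int:
        """Number of types."""
        return len(self.birth)

    @property
    def is_critical(self) -> bool:
        """True iff ``birth[i] == death[i] + mutation[i]`` for every type."""
        return all(
            abs(b - (d + m)) <= _CRIT_TOL
            for b, d, m in zip(self.birth, self.death, self.mutation)
        )

    def shifted(self) -> "ProcessSpec":
        """Drop type 1, i.e. the sub-process seen by a type-2 cell.

        For decomposable processes the chain started from a later type is a
        shifted copy of a shorter chain (the index-shift operator), so the
        spec with the first type removed describes the same dynamics with
        all labels decreased by one.
        """
        if self.n < 2:
            raise ValueError("cannot shift a single-type specification")
        return ProcessSpec(
            self.birth[1:], self.death[1:], self.mutation[1:], self.initial[1:]
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "birth": list(self.birth),
            "death": list(self.death),
            "mutation": list(self.mutation),
            "initial": list(self.initial),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessSpec":
        spec = cls(d["birth"], d["death"], d["mutation"], d.get("initial"))
        if "n" in d and int(d["n"]) != spec.n:
            raise ValueError(
                f"config declares n={d['n']} but rate vectors have length {spec.n}"
            )
        return spec


def make_simple_spec(n: int, initial: Optional[Sequence[int]] = None) -> ProcessSpec:
    """Unit-rate pure birth-mutation spec: the simplest critical chain.

    Every type ``i < n`` divides at rate 1 and mutates at rate 1 (no death);
    the last type divides and dies at rate 1.  All types are critical.
    """
    if n < 1:
        raise ValueError(f"number of types must be >= 1, got {n}")
    birth = (1.0,) * n
    death = (0.0,) * (n - 1) + (1.0,)
    mutation = (1.0,) * (n - 1) + (0.0,)
    return ProcessSpec(birth, death, mutation, initial)


def validate(spec: ProcessSpec) -> list[str]:
    """Check a spec for structural problems; returns findings, raises nothing.

    Non-criticality is reported as a warning only: the simulator can run any
    rates, but the closed-form and asymptotic results assume criticality.
    """
    findings: list[str] = []
    n = spec.n
    for name in ("birth", "death", "mutation", "initial"):
        vec = getattr(spec, name)
        if len(vec) != n:
            findings.append(f"{name} has length {len(vec)}, expected {n}")
    for name in ("birth", "death", "mutation"):
        for i, v in enumerate(getattr(spec, name)):
            if v < 0:
                findings.append(f"{name} rate of type {i + 1} is negative ({v})")
    if any(z < 0 for z in spec.initial):
        findings.append("initial counts must be non-negative")
    if spec.mutation[-1] != 0:
        findings.append(f"last type mutates (mutation[{n}] = {spec.mutation[-1]}, must be 0)")
    for i, (b, d, m) in enumerate(zip(spec.birth, spec.death, spec.mutation)):
        if abs(b - (d + m)) > _CRIT_TOL:
            findings.append(
                f"warning: type {i + 1} not critical "
                f"(birth {b} != death {d} + mutation {m})"
            )
    return findings


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing grid of non-negative times."""

    points: np.ndarray

    def __init__(self, points: Sequence[float]) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 1 or len(pts) == 0:
            raise ValueError("time grid must be a non-empty 1-d sequence")
        if pts[0] < 0:
            raise ValueError("time grid must start at a non-negative time")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "points", pts)
        self.points.setflags(write=False)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def t_max(self) -> float:
        return float(self.points[-1])

    @classmethod
    def linear(cls, t_max: float, num: int, t_min: float = 0.0) -> "TimeGrid":
        return cls(np.linspace(t_min, t_max, num))

    @classmethod
    def log(
        cls, t_max: float, num: int, t_min: float = 1e-3, include_zero: bool = True
    ) -> "TimeGrid":
        """Logarithmically spaced grid, optionally prepended with t = 0."""
        pts = np.geomspace(t_min, t_max, num - 1 if include_zero else num)
        if include_zero:
            pts = np.concatenate([[0.0], pts])
        return cls(pts)

    @classmethod
    def parse(cls, text: str, t_max: float) -> "TimeGrid":
        """Parse CLI-style grid descriptions ``lin:100`` / ``log:50``."""
        kind, _, num = text.partition(":")
        num = int(num or 50)
        if kind == "lin":
            return cls.linear(t_max, num)
        if kind == "log":
            return cls.log(t_max, num)
        raise ValueError(f"unknown grid spec {text!r}; use lin:N or log:N")


@dataclass
class Trajectory:
    """One realization of the process.

    ``arrivals[k]`` is the first time type ``k+1`` was present (nan if
    never), ``extinctions[k]`` the last time it was present (nan if never
    present; censored if the run stopped at ``t_max`` while the type could
    still recur).
    """

    times: np.ndarray
    counts: np.ndarray  # shape (len(times), n)
    arrivals: np.ndarray  # shape (n,), nan = never
    extinctions: np.ndarray  # shape (n,), nan = never present
    censored: np.ndarray  # shape (n,), bool
    seed: object
    spec: ProcessSpec
    capped: bool = False

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self):
        """Tidy (time, type, count) table."""
        import pandas as pd

        T, n = self.counts.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "type": np.tile(np.arange(1, n + 1), T),
                "count": self.counts.ravel(),
            }
        )


def load_config(path) -> tuple[ProcessSpec, dict]:
    """Read a JSON or YAML run configuration.

    Recognised keys: ``n, birth, death, mutation, initial, t_max, reps,
    seed``.  Returns the spec plus the remaining run settings.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    spec = ProcessSpec.from_dict(data)
    settings = {k: data[k] for k in ("t_max", "reps", "seed") if k in data}
    return spec, settings


def dump_config(spec: ProcessSpec, path, **settings) -> None:
    """Write a spec (plus optional t_max/reps/seed) as JSON."""
    data = spec.to_dict()
    data.update(settings)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
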