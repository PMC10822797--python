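"""Vertical swimming behaviors: open-loop schedules and passive drift.

Schedules are built from inclusive surface windows on the dt grid: the
larva holds the surface layer at every grid time inside a window (both
endpoints included), ascending one step before the window starts and
descending at the window end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import ModelParams

__all__ = [
    "Schedule",
    "PassiveProcess",
    "schedule_from_windows",
    "make_archetype",
    "passive_step",
    "ARCHETYPES",
]

ARCHETYPES = ("ovm", "dvm", "hybrid")

_GRID_TOL = 1e-9


@dataclass
class Schedule:
    """Open-loop depth-change sequence of length N."""

    actions: np.ndarray
    dt: float
    surface_windows: tuple[tuple[float, float], ...] = ()
    name: str = "schedule"

    charge_migration_cost: bool = True

    def __post_init__(self) -> None:
        self.actions = np.asarray(self.actions, dtype=np.int8)
        z = self.implied_z()
        if not np.isin(z, (0, 1)).all():
            raise ValueError("schedule leaves the {0,1} layer set (inadmissible)")

    def implied_z(self) -> np.ndarray:
        """Layer path starting from Z_0 = 0 (length N+1)."""
        z = np.zeros(len(self.actions) + 1, dtype=np.int64)
        np.cumsum(self.actions, out=z[1:])
        return z

    @property
    def n_steps(self) -> int:
        return len(self.actions)

    @property
    def surface_steps(self) -> int:
        """Held surface steps (k < N)."""
        return int(np.sum(self.implied_z()[:-1] == 1))

    @property
    def n_migrations(self) -> int:
        return int(np.sum(np.abs(self.actions)))

    @property
    def surface_time(self) -> float:
        return self.dt * self.surface_steps

    def decide_batch(self, k, t, X, Z, E, rng) -> np.ndarray:
        return np.full(np.shape(X), self.actions[k], dtype=np.int8)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_steps) * self.dt
        return pd.DataFrame({"t": t, "dZ": self.actions.astype(int)})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, params: ModelParams) -> "Schedule":
        actions = frame["dZ"].to_numpy()
        if len(actions) != params.n_steps:
            raise ValueError(
                f"schedule has {len(actions)} actions; params require {params.n_steps}"
            )
        return cls(actions=actions, dt=params.dt)


def _grid_index(value: float, dt: float) -> int:
    i = value / dt
    if abs(i - round(i)) > _GRID_TOL / dt:
        raise ValueError(f"window endpoint {value} is not on the dt={dt} grid")
    return int(round(i))


def schedule_from_windows(
    windows: Iterable[Sequence[float]],
    params: ModelParams,
    name: str = "schedule",
) -> Schedule:
    """Encode inclusive surface windows as a depth-change schedule.

    Each window [a, b] puts the larva in the surface for every grid time in
    [a, b]; the ascent is charged at a - dt (at t=0 for a window starting at
    0, making the surface reached at t=dt) and the descent at b.  Windows
    reaching past the decision horizon are clipped there (ascent charged,
    descent dropped).
    """
    N, dt = params.n_steps, params.dt
    wins = sorted((float(a), float(b)) for a, b in windows)
    z = np.zeros(N + 1, dtype=np.int8)
    prev_end = -np.inf
    for a, b in wins:
        if b < a:
            raise ValueError(f"window ({a}, {b}) has negative length")
        if a < 0 or a > params.T - dt:
            raise ValueError(f"window start {a} outside decision horizon [0, T-dt]")
        if a <= prev_end:
            raise ValueError(f"window starting at {a} overlaps the previous window")
        i0 = max(_grid_index(a, dt), 1)  # Z_0 = 0 is fixed by spawning
        i1 = min(_grid_index(b, dt), N)
        z[i0 : i1 + 1] = 1
        prev_end = b
    actions = np.diff(z.astype(np.int64))
    return Schedule(actions=actions, dt=dt, surface_windows=tuple(wins), name=name)


def make_archetype(name: str, params: ModelParams) -> Schedule:
    """Build one of the named archetypes (requires T = 20 days).

    * ``ovm``   : one surface stay over the first four days.
    * ``dvm``   : nightly surface visits 21:00-03:00 (clock 0.875-1.125).
    * ``hybrid``: nightly visits 18:00-06:00 for the first 8 days.

    Other larval durations need explicit windows via
    :func:`schedule_from_windows`.
    """
    name = name.lower()
    if name not in ARCHETYPES:
        raise ValueError(f"unknown archetype {name!r}; expected one of {ARCHETYPES}")
    if abs(params.T - 20.0) > _GRID_TOL:
        raise ValueError(
            f"named archetype {name!r} is defined for T=20 days; "
            "use schedule_from_windows for other durations"
        )
    if name == "ovm":
        windows = [(params.dt, 4.0)]
    elif name == "dvm":
        windows = [(k + 0.875, k + 1.125) for k in range(20)]
    else:  # hybrid
        windows = [(k + 0.75, k + 1.25) for k in range(8)]
    return schedule_from_windows(windows, params, name=name)


@dataclass
class PassiveProcess:
    """Two-state Markov chain for diffusion-driven vertical motion.

    Per step, a bottom larva surfaces with probability ``q_up`` and a
    surface larva sinks with probability ``q_down``.  Defaults give a
    stationary surface occupancy of 0.2, the surface/total layer-thickness
    ratio alpha/(1+alpha) at alpha=0.25, with mean surface sojourns of two
    steps (6 h).  Depth changes are not active swimming, so the migration
    cost V is waived by default.
    """

    q_up: float = 0.125
    q_down: float = 0.5
    charge_migration_cost: bool = False
    name: str = "passive"

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_up <= 1.0 and 0.0 <= self.q_down <= 1.0):
            raise ValueError("switch probabilities must lie in [0, 1]")

    @property
    def stationary_surface_occupancy(self) -> float:
        if self.q_up + self.q_down == 0:
            raise ValueError("degenerate chain: both switch probabilities are 0")
        return self.q_up / (self.q_up + self.q_down)

    def decide_batch(self, k, t, X, Z, E, rng) -> np.ndarray:
        u = rng.random(np.shape(X))
        up = (np.asarray(Z) == 0) & (u < self.q_up)
        down = (np.asarray(Z) == 1) & (u < self.q_down)
        return up.astype(np.int8) - down.astype(np.int8)


def passive_step(state, rng: np.random.Generator, proc: PassiveProcess) -> int:
    """Single-larva passive depth change from ``state``."""
    a = proc.decide_batch(0, state.t, np.array([state.X]), np.array([state.Z]),
                          np.array([state.E]), rng)
    return int(a[0])
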