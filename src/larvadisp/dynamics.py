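"""Core state types and discrete-time dynamics for larval cross-shore dispersal.

The environment is a two-layer coastal water column: a bottom layer (Z=0)
moving slowly onshore and a surface layer (Z=1) moving offshore, both with
Gaussian cross-shore diffusion.  A larva holds a layer during each time step
``[t, t+dt)``; its depth-change decision at step start takes effect at the
step end.  The shore at X=0 is a reflecting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "LarvalState",
    "Trajectory",
    "Ensemble",
    "SimulationConfig",
    "Behavior",
    "draw_initial_state",
    "step_energy",
    "step_position",
    "simulate_trajectory",
    "simulate_ensemble",
]

PREDATION_SCHEMES = ("nearshore", "diurnal")

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Biological and environmental constants of the dispersal model.

    All distances are in habitat widths, energies in metamorphosis-cost
    units, and times in days.  ``U`` and ``K`` are surface-layer advection
    and eddy diffusivity; the bottom layer uses ``-alpha*U`` and
    ``alpha*K``.
    """

    T: float = 20.0
    dt: float = 0.125
    U: float = 1.0
    K: float = 0.2
    alpha: float = 0.25
    S: float = 0.0
    G: float = 0.1
    F: float = 0.2
    V: float = 0.004
    E_max: float = 5.0
    predation_scheme: str = "nearshore"
    daylight_window: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")
        n = self.T / self.dt
        if abs(n - round(n)) > _GRID_TOL or round(n) < 1:
            raise ValueError("T/dt must be a positive integer")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.U < 0:
            raise ValueError("U must be non-negative")
        # K = 0 is permitted so that deterministic (noise-free) scenarios can
        # be exercised; the documented model domain is K > 0.
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.V < 0:
            raise ValueError("V must be non-negative")
        if self.E_max <= 0:
            raise ValueError("E_max must be positive")
        if self.F < 0 or self.G < 0:
            raise ValueError("F and G must be non-negative")
        if self.predation_scheme not in PREDATION_SCHEMES:
            raise ValueError(
                f"unknown predation scheme {self.predation_scheme!r}; "
                f"expected one of {PREDATION_SCHEMES}"
            )
        lo, hi = self.daylight_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("daylight_window must satisfy 0 <= lo < hi <= 1")

    @property
    def n_steps(self) -> int:
        """Number of decision steps N = T/dt."""
        return int(round(self.T / self.dt))

    def times(self) -> np.ndarray:
        """Grid times 0, dt, ..., T (length N+1)."""
        return np.arange(self.n_steps + 1) * self.dt

    def advection(self, z):
        """Mean cross-shore velocity of layer ``z`` (array-friendly)."""
        return np.where(np.asarray(z) == 1, self.U, -self.alpha * self.U)[()]

    def diffusivity(self, z):
        """Eddy diffusivity of layer ``z`` (array-friendly)."""
        return np.where(np.asarray(z) == 1, self.K, self.alpha * self.K)[()]

    def initial_energy(self) -> float:
        """Energy at spawning, ``clip(S + G*T, 0, E_max)``.

        Raises if the spawn budget is non-positive (a larva that would be
        born starving).
        """
        e0 = self.S + self.G * self.T
        if e0 <= 0:
            raise ValueError("nonviable initial energy: S + G*T <= 0")
        return min(e0, self.E_max)


@dataclass(frozen=True)
class LarvalState:
    """Snapshot of one larva: time, offshore distance, layer, energy."""

    t: float
    X: float
    Z: int
    E: float


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo settings.

    One standard-normal deviate is drawn per larva per step, in
    (larva, step) order, from ``numpy.random.default_rng(seed)``; identical
    seed + behavior + params gives a bit-identical ensemble.
    """

    seed: int = 0
    n_reps: int = 1000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@runtime_checkable
class Behavior(Protocol):
    """Anything that chooses depth changes for a batch of larvae."""

    charge_migration_cost: bool

    def decide_batch(
        self,
        k: int,
        t: float,
        X: np.ndarray,
        Z: np.ndarray,
        E: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray: ...


@dataclass
class Trajectory:
    """Full record of one simulated larva.

    ``times``, ``X``, ``Z``, ``E`` have length N+1; ``actions`` has length N
    (decisions at t = 0 ... T-dt).
    """

    times: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    E: np.ndarray
    actions: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.actions)

    @property
    def surface_steps(self) -> int:
        """Number of steps (k < N) held in the surface layer."""
        return int(np.sum(self.Z[:-1] == 1))

    @property
    def n_migrations(self) -> int:
        return int(np.sum(np.abs(self.actions)))

    def surface_time(self) -> float:
        """Total time (days) spent holding the surface layer."""
        dt = self.times[1] - self.times[0]
        return dt * self.surface_steps

    def state(self, k: int) -> LarvalState:
        return LarvalState(
            t=float(self.times[k]), X=float(self.X[k]), Z=int(self.Z[k]), E=float(self.E[k])
        )

    def validate(self, params: ModelParams) -> None:
        N = params.n_steps
        if len(self.times) != N + 1 or len(self.actions) != N:
            raise ValueError("trajectory length inconsistent with params")
        if not np.array_equal(self.Z[1:], self.Z[:-1] + self.actions):
            raise ValueError("Z path inconsistent with actions")
        if not np.isin(self.Z, (0, 1)).all():
            raise ValueError("Z outside {0, 1}")
        if (self.E < -_GRID_TOL).any() or (self.E > params.E_max + _GRID_TOL).any():
            raise ValueError("E outside [0, E_max]")
        if (self.X < -_GRID_TOL).any():
            raise ValueError("X negative")

    def to_frame(self) -> pd.DataFrame:
        dz = np.empty(len(self.times))
        dz[:-1] = self.actions
        dz[-1] = np.nan
        return pd.DataFrame(
            {"t": self.times, "X": self.X, "Z": self.Z, "E": self.E, "dZ": dz}
        )


@dataclass
class Ensemble:
    """Trajectories of ``n_reps`` larvae sharing a behavior and parameters.

    Path arrays are shaped (n_reps, N+1); ``actions`` is (n_reps, N).
    """

    times: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    E: np.ndarray
    actions: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.X.shape[0]

    @property
    def n_steps(self) -> int:
        return self.actions.shape[1]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(
            times=self.times,
            X=self.X[i].copy(),
            Z=self.Z[i].copy(),
            E=self.E[i].copy(),
            actions=self.actions[i].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with a ``rep`` column."""
        frames = []
        for i in range(self.n_reps):
            f = self.trajectory(i).to_frame()
            f.insert(0, "rep", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def draw_initial_state(rng: np.random.Generator, params: ModelParams) -> LarvalState:
    """Spawn a larva: X ~ Uniform[0,1], bottom layer, energy S + G*T."""
    e0 = params.initial_energy()
    return LarvalState(t=0.0, X=float(rng.uniform()), Z=0, E=e0)


def step_energy(E, z_held, action, params: ModelParams, charge_migration: bool = True):
    """One-step energy update, clipped to [0, E_max].

    ``z_held`` is the layer occupied during [t, t+dt); feeding happens at
    rate F only in the surface.  Each vertical migration costs V unless
    ``charge_migration`` is False (used for passive vertical diffusion).
    """
    z = np.asarray(z_held)
    e_raw = E + (params.F * z - params.G) * params.dt
    if charge_migration:
        e_raw = e_raw - params.V * np.abs(action)
    return np.clip(e_raw, 0.0, params.E_max)[()]


def step_position(X, z_held, xi, params: ModelParams, reflect: bool = True):
    """One-step cross-shore displacement with layer-dependent drift/noise.

    The shore at X=0 reflects (``|X'|``); pass ``reflect=False`` to run on
    an unbounded line (test mode for symmetry checks).
    """
    drift = params.advection(z_held) * params.dt
    sigma = np.sqrt(2.0 * params.diffusivity(z_held) * params.dt)
    x_new = X + drift + xi * sigma
    if reflect:
        x_new = np.abs(x_new)
    return x_new


def _charge_flag(behavior) -> bool:
    return bool(getattr(behavior, "charge_migration_cost", True))


def simulate_ensemble(
    behavior,
    params: ModelParams,
    sim: SimulationConfig,
    reflect: bool = True,
) -> Ensemble:
    """Simulate ``sim.n_reps`` larvae under one behavior.

    Per step: record state, query the behavior for depth changes, update
    energy and position using the held (pre-decision) layer, then apply the
    depth changes.
    """
    rng = np.random.default_rng(sim.seed)
    n, N = sim.n_reps, params.n_steps
    e0 = params.initial_energy()

    X = np.empty((n, N + 1))
    Z = np.zeros((n, N + 1), dtype=np.int8)
    E = np.empty((n, N + 1))
    actions = np.empty((n, N), dtype=np.int8)

    X[:, 0] = rng.uniform(size=n)
    E[:, 0] = e0
    xi = rng.standard_normal((n, N))  # (larva, step) order

    charge = _charge_flag(behavior)
    times = params.times()
    for k in range(N):
        t = float(times[k])
        a = np.asarray(behavior.decide_batch(k, t, X[:, k], Z[:, k], E[:, k], rng))
        bad = ~np.isin(a, (-1, 0, 1)) | ~np.isin(Z[:, k] + a, (0, 1))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"inadmissible action {int(a[i])} at t={t} for state "
                f"(X={X[i, k]:.6g}, Z={int(Z[i, k])}, E={E[i, k]:.6g}), rep {i}"
            )
        actions[:, k] = a
        E[:, k + 1] = step_energy(E[:, k], Z[:, k], a, params, charge_migration=charge)
        X[:, k + 1] = step_position(X[:, k], Z[:, k], xi[:, k], params, reflect=reflect)
        Z[:, k + 1] = Z[:, k] + a

    return Ensemble(times=times, X=X, Z=Z, E=E, actions=actions)


def simulate_trajectory(
    behavior,
    params: ModelParams,
    sim: SimulationConfig,
    reflect: bool = True,
) -> Trajectory:
    """Simulate a single larva (an ensemble of one)."""
    ens = simulate_ensemble(behavior, params, replace(sim, n_reps=1), reflect=reflect)
    return ens.trajectory(0)
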