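"""Backward-induction solver for optimal vertical swimming policies.

The expected trajectory score is maximized over closed-loop depth-change
policies on a discretized (t, X, E, Z) state space.  Per-step rewards use
the pre-decision state; the depth change affects only the future.  The
expectation over the Gaussian displacement is taken by fixed-node
Gauss-Hermite quadrature and the next-step value is evaluated by bilinear
interpolation in (X, E).  Ties between staying and migrating break toward
staying, so policies are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .dynamics import LarvalState, ModelParams
from .scoring import ScoreWeights, in_high_predation, metamorphosis_penalty, settling_penalty

__all__ = [
    "SolverConfig",
    "StateGrids",
    "ValueFunction",
    "OptimalPolicy",
    "PolicyBehavior",
    "suggested_x_max",
    "build_grids",
    "terminal_value",
    "bellman_backup",
    "solve",
    "policy_lookup",
    "policy_frame",
    "policy_metadata",
]


@dataclass(frozen=True)
class SolverConfig:
    """Grid spacings, domain truncation, and quadrature order."""

    dx: float = 0.1
    de: float = 0.05
    x_max: float | None = None  # None: rounded-up default rule
    n_quad: int = 9

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.de <= 0:
            raise ValueError("grid spacings must be positive")
        if self.n_quad < 1:
            raise ValueError("n_quad must be >= 1")


@dataclass(frozen=True)
class StateGrids:
    """Uniform node grids for offshore distance and energy."""

    x_nodes: np.ndarray
    e_nodes: np.ndarray

    @property
    def nx(self) -> int:
        return len(self.x_nodes)

    @property
    def ne(self) -> int:
        return len(self.e_nodes)

    @property
    def dx(self) -> float:
        return float(self.x_nodes[1] - self.x_nodes[0])

    @property
    def de(self) -> float:
        return float(self.e_nodes[1] - self.e_nodes[0])

    @property
    def x_max(self) -> float:
        return float(self.x_nodes[-1])


@dataclass
class ValueFunction:
    """Expected-score values over (t_step, x_node, e_node, z)."""

    values: np.ndarray
    grids: StateGrids


@dataclass
class OptimalPolicy:
    """Depth-change actions over (t_step, x_node, e_node, z)."""

    actions: np.ndarray
    grids: StateGrids


def suggested_x_max(params: ModelParams) -> float:
    """Offshore truncation rule: 1 + U*T + 6*sqrt(2*K*T)."""
    return 1.0 + params.U * params.T + 6.0 * math.sqrt(2.0 * params.K * params.T)


def build_grids(params: ModelParams, cfg: SolverConfig = SolverConfig()) -> StateGrids:
    """Lay out uniform (X, E) grids covering the reachable domain.

    Without an explicit ``x_max`` the truncation rule is rounded up to the
    next multiple of 10 (40 at upwelling defaults, 20 in still water).  A
    user-supplied ``x_max`` below the rule triggers a warning.
    """
    rule = suggested_x_max(params)
    if cfg.x_max is None:
        x_max = 10.0 * math.ceil(rule / 10.0)
    else:
        x_max = float(cfg.x_max)
        if x_max < rule:
            warnings.warn(
                f"x_max={x_max} is below the suggested truncation {rule:.3g}; "
                "offshore truncation error may be non-negligible"
            )
    nx = int(round(x_max / cfg.dx)) + 1
    ne = int(round(params.E_max / cfg.de)) + 1
    x_nodes = np.arange(nx) * cfg.dx
    e_nodes = np.arange(ne) * cfg.de
    # make sure the domain endpoints are hit exactly
    x_nodes[-1] = x_max
    e_nodes[-1] = params.E_max
    return StateGrids(x_nodes=x_nodes, e_nodes=e_nodes)


def terminal_value(grids: StateGrids, weights: ScoreWeights) -> np.ndarray:
    """Terminal reward over (x_node, e_node); independent of layer."""
    j_settle = 1.0 - settling_penalty(grids.x_nodes)
    j_meta = 1.0 - metamorphosis_penalty(grids.e_nodes)
    return weights.p_settle * j_settle[:, None] + weights.p_meta * j_meta[None, :]


def _quadrature(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes and normalized weights."""
    nodes, w = np.polynomial.hermite_e.hermegauss(n)
    return nodes, w / w.sum()


class _Precomputed:
    """Time-invariant interpolation tables for the backward sweep."""

    def __init__(self, grids: StateGrids, params: ModelParams, cfg: SolverConfig):
        self.grids = grids
        nodes, wq = _quadrature(cfg.n_quad)
        self.wq = wq
        x, e = grids.x_nodes, grids.e_nodes
        dx, de = grids.dx, grids.de
        self.xi0: dict[int, np.ndarray] = {}
        self.xw: dict[int, np.ndarray] = {}
        for z in (0, 1):
            drift = params.advection(z) * params.dt
            sigma = math.sqrt(2.0 * params.diffusivity(z) * params.dt)
            # reflect at the shore, clamp at the offshore truncation
            xp = np.abs(x[None, :] + drift + nodes[:, None] * sigma)
            xp = np.minimum(xp, grids.x_max)
            pos = xp / dx
            i0 = np.clip(np.floor(pos).astype(np.int64), 0, grids.nx - 2)
            self.xi0[z] = i0
            self.xw[z] = np.clip(pos - i0, 0.0, 1.0)
        self.ej0: dict[tuple[int, int], np.ndarray] = {}
        self.ew: dict[tuple[int, int], np.ndarray] = {}
        for z in (0, 1):
            for mig in (0, 1):
                ep = np.clip(
                    e + (params.F * z - params.G) * params.dt - params.V * mig,
                    0.0,
                    params.E_max,
                )
                pos = ep / de
                j0 = np.clip(np.floor(pos).astype(np.int64), 0, grids.ne - 2)
                self.ej0[(z, mig)] = j0
                self.ew[(z, mig)] = np.clip(pos - j0, 0.0, 1.0)

    def expected_next(self, V_next: np.ndarray, z: int, zp: int) -> np.ndarray:
        """E_xi[ V_next(X'(x, xi; z), e_nodes, zp) ] over the x grid."""
        Vz = V_next[:, :, zp]
        i0, w = self.xi0[z], self.xw[z]
        acc = np.zeros((self.grids.nx, self.grids.ne))
        for q in range(len(self.wq)):
            acc += self.wq[q] * (
                (1.0 - w[q])[:, None] * Vz[i0[q]] + w[q][:, None] * Vz[i0[q] + 1]
            )
        return acc

    def shift_energy(self, W: np.ndarray, z: int, mig: int) -> np.ndarray:
        """Interpolate W(x, .) at the post-update energies for layer z."""
        j0, w = self.ej0[(z, mig)], self.ew[(z, mig)]
        return (1.0 - w)[None, :] * W[:, j0] + w[None, :] * W[:, j0 + 1]


def _running_reward(
    t: float, z: int, grids: StateGrids, params: ModelParams, weights: ScoreWeights
) -> np.ndarray:
    """Per-step reward (nx, ne) for holding layer z during [t, t+dt)."""
    high = in_high_predation(t, grids.x_nodes, z, params)
    not_high = 1.0 - np.asarray(high, dtype=float)  # scalar or (nx,)
    pred = weights.p_pred * np.broadcast_to(np.atleast_1d(not_high), (grids.nx,))
    starve = weights.p_starve * (grids.e_nodes > 0).astype(float)
    return (params.dt / params.T) * (pred[:, None] + starve[None, :])


def _backup(
    V_next: np.ndarray,
    t: float,
    pre: _Precomputed,
    params: ModelParams,
    weights: ScoreWeights,
) -> tuple[np.ndarray, np.ndarray]:
    grids = pre.grids
    V_t = np.empty_like(V_next)
    A_t = np.zeros(V_next.shape, dtype=np.int8)
    for z in (0, 1):
        stay = pre.shift_energy(pre.expected_next(V_next, z, z), z, 0)
        move = pre.shift_energy(pre.expected_next(V_next, z, 1 - z), z, 1)
        r = _running_reward(t, z, grids, params, weights)
        # ties break toward staying put; the epsilon absorbs 1-ulp
        # interpolation round-off between equal-valued alternatives
        better = move > stay + 1e-12
        A_t[:, :, z] = np.where(better, 1 if z == 0 else -1, 0)
        V_t[:, :, z] = r + np.maximum(move, stay)
    if not np.isfinite(V_t).all():
        bad = np.argwhere(~np.isfinite(V_t))[0]
        raise FloatingPointError(f"non-finite value at node (x,e,z)={tuple(bad)}")
    return V_t, A_t


def bellman_backup(
    V_next: np.ndarray,
    t: float,
    grids: StateGrids,
    params: ModelParams,
    weights: ScoreWeights,
    cfg: SolverConfig = SolverConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """One backward step: value and policy slices at time t.

    ``V_next`` is the (nx, ne, 2) value slice at t + dt.
    """
    pre = _Precomputed(grids, params, cfg)
    return _backup(V_next, t, pre, params, weights)


def solve(
    params: ModelParams,
    weights: ScoreWeights = ScoreWeights(),
    cfg: SolverConfig = SolverConfig(),
) -> tuple[OptimalPolicy, ValueFunction]:
    """Backward induction over t = T-dt ... 0; deterministic (no RNG)."""
    grids = build_grids(params, cfg)
    pre = _Precomputed(grids, params, cfg)
    N = params.n_steps
    values = np.empty((N + 1, grids.nx, grids.ne, 2))
    actions = np.zeros((N, grids.nx, grids.ne, 2), dtype=np.int8)
    vT = terminal_value(grids, weights)
    values[N, :, :, 0] = vT
    values[N, :, :, 1] = vT
    for k in range(N - 1, -1, -1):
        t = k * params.dt
        values[k], actions[k] = _backup(values[k + 1], t, pre, params, weights)
    return OptimalPolicy(actions=actions, grids=grids), ValueFunction(
        values=values, grids=grids
    )


def policy_lookup(policy: OptimalPolicy, state: LarvalState, dt: float) -> int:
    """Action at the nearest grid node (X clamped into the domain)."""
    g = policy.grids
    k = int(round(state.t / dt))
    i = int(np.clip(round(state.X / g.dx), 0, g.nx - 1))
    j = int(np.clip(round(state.E / g.de), 0, g.ne - 1))
    return int(policy.actions[k, i, j, int(state.Z)])


@dataclass
class PolicyBehavior:
    """Closed-loop adapter: feeds nearest-node policy actions to the simulator."""

    policy: OptimalPolicy
    name: str = "optimal"

    charge_migration_cost: bool = True

    def decide_batch(self, k, t, X, Z, E, rng) -> np.ndarray:
        g = self.policy.grids
        i = np.clip(np.rint(np.asarray(X) / g.dx).astype(np.int64), 0, g.nx - 1)
        j = np.clip(np.rint(np.asarray(E) / g.de).astype(np.int64), 0, g.ne - 1)
        return self.policy.actions[k, i, j, np.asarray(Z, dtype=np.int64)]


def policy_frame(policy: OptimalPolicy, value: ValueFunction | None = None) -> pd.DataFrame:
    """Long-format export: one row per (t_index, x_index, e_index, z)."""
    N, nx, ne, _ = policy.actions.shape
    t_idx, x_idx, e_idx, z = np.meshgrid(
        np.arange(N), np.arange(nx), np.arange(ne), np.arange(2), indexing="ij"
    )
    out = pd.DataFrame(
        {
            "t_index": t_idx.ravel(),
            "x_index": x_idx.ravel(),
            "e_index": e_idx.ravel(),
            "z": z.ravel(),
            "action": policy.actions.ravel(),
        }
    )
    if value is not None:
        out["value"] = value.values[:N].ravel()
    return out


def policy_metadata(
    policy: OptimalPolicy,
    params: ModelParams,
    weights: ScoreWeights,
    cfg: SolverConfig,
) -> dict:
    """JSON-ready sidecar: grids, inputs, and a content hash of the actions."""
    h = hashlib.sha256(np.ascontiguousarray(policy.actions).tobytes()).hexdigest()
    return {
        "params": asdict(params),
        "weights": asdict(weights),
        "solver": asdict(cfg),
        "grids": {
            "nx": policy.grids.nx,
            "ne": policy.grids.ne,
            "dx": policy.grids.dx,
            "de": policy.grids.de,
            "x_max": policy.grids.x_max,
        },
        "actions_sha256": h,
    }
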