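"""Monte-Carlo experiment surfaces: ensemble summaries, parameter sweeps,
feeding thresholds, and cross-behavior subscore comparisons."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .behaviors import PassiveProcess, make_archetype, Schedule
from .dynamics import ModelParams, SimulationConfig, simulate_ensemble
from .dp import PolicyBehavior, SolverConfig, solve
from .scoring import ScoreWeights, score_ensemble

__all__ = [
    "BehaviorSummary",
    "evaluate_behavior",
    "sweep_parameter",
    "feeding_threshold",
    "compare_subscores",
    "standard_behaviors",
]

_SCORE_COLS = ("J", "J_pred", "J_starve", "J_settle", "J_meta")

BehaviorFactory = Callable[[ModelParams], object]


@dataclass
class BehaviorSummary:
    """Aggregate scores of one behavior over a Monte-Carlo ensemble."""

    behavior: str
    n_reps: int
    mean: dict[str, float]
    q25: dict[str, float]
    q50: dict[str, float]
    q75: dict[str, float]
    frac_settled: float  # X_T <= 1
    frac_provisioned: float  # E_T >= 1

    def to_row(self) -> dict[str, float | str | int]:
        row: dict[str, float | str | int] = {
            "behavior": self.behavior,
            "n_reps": self.n_reps,
        }
        for col in _SCORE_COLS:
            row[f"mean_{col}"] = self.mean[col]
            row[f"q25_{col}"] = self.q25[col]
            row[f"q50_{col}"] = self.q50[col]
            row[f"q75_{col}"] = self.q75[col]
        row["frac_settled"] = self.frac_settled
        row["frac_provisioned"] = self.frac_provisioned
        return row


def _behavior_name(behavior) -> str:
    return getattr(behavior, "name", type(behavior).__name__.lower())


def evaluate_behavior(
    behavior,
    params: ModelParams,
    weights: ScoreWeights,
    sim: SimulationConfig,
    name: str | None = None,
) -> BehaviorSummary:
    """Simulate, score, and aggregate ``sim.n_reps`` replicates."""
    if sim.n_reps < 2:
        raise ValueError("summaries require n_reps >= 2")
    ens = simulate_ensemble(behavior, params, sim)
    scores = score_ensemble(ens, weights, params)
    return BehaviorSummary(
        behavior=name or _behavior_name(behavior),
        n_reps=sim.n_reps,
        mean={c: float(scores[c].mean()) for c in _SCORE_COLS},
        q25={c: float(scores[c].quantile(0.25)) for c in _SCORE_COLS},
        q50={c: float(scores[c].quantile(0.50)) for c in _SCORE_COLS},
        q75={c: float(scores[c].quantile(0.75)) for c in _SCORE_COLS},
        frac_settled=float((scores["X_T"] <= 1.0).mean()),
        frac_provisioned=float((scores["E_T"] >= 1.0).mean()),
    )


def standard_behaviors(
    params: ModelParams,
    weights: ScoreWeights = ScoreWeights(),
    include_optimal: bool = False,
    solver_cfg: SolverConfig = SolverConfig(),
) -> dict[str, object]:
    """Passive drifting plus the three named archetypes (optionally the
    solved optimal policy for ``params``)."""
    behaviors: dict[str, object] = {
        "passive": PassiveProcess(),
        "ovm": make_archetype("ovm", params),
        "dvm": make_archetype("dvm", params),
        "hybrid": make_archetype("hybrid", params),
    }
    if include_optimal:
        policy, _ = solve(params, weights, solver_cfg)
        behaviors["optimal"] = PolicyBehavior(policy)
    return behaviors


def sweep_parameter(
    name: str,
    values,
    behaviors: Mapping[str, object],
    params: ModelParams,
    weights: ScoreWeights,
    sim: SimulationConfig,
) -> pd.DataFrame:
    """Evaluate each behavior at each swept value of U or F.

    Behaviors may be behavior objects or callables taking the per-value
    params (used, e.g., to re-solve the optimal policy per value).  All
    behaviors within a cell share the same seed (common random numbers).
    """
    if name not in ("U", "F"):
        raise ValueError("swept parameter must be 'U' or 'F'")
    vals = [float(v) for v in values]
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValueError("sweep values must be strictly increasing")
    if any(v < 0 for v in vals):
        raise ValueError(f"{name} values must be non-negative")
    rows = []
    for i, v in enumerate(vals):
        p_v = replace(params, **{name: v})
        cell_sim = replace(sim, seed=sim.seed + i)
        for bname, b in behaviors.items():
            behavior = b(p_v) if callable(b) and not hasattr(b, "decide_batch") else b
            summary = evaluate_behavior(behavior, p_v, weights, cell_sim, name=bname)
            row = {"param": name, "value": v, **summary.to_row()}
            rows.append(row)
    return pd.DataFrame(rows)


def feeding_threshold(
    schedule: Schedule, params: ModelParams
) -> tuple[float, float]:
    """Smallest feeding rate letting a fixed schedule end with E_T >= 1.

    Open-loop schedules have deterministic energy paths, so the threshold
    has the closed form ``F* = (1 - E_0 + G*T + V*m) / tau`` with ``tau``
    the surface residence time and ``m`` the migration count.  Returns
    ``(F*, F* rounded to the nearest 0.05)``.  The clip-free assumption is
    verified by replaying the deterministic energy recursion at F*.
    """
    tau = schedule.surface_time
    if tau <= 0:
        raise ValueError("nonfeeding schedule has no threshold (no surface time)")
    m = schedule.n_migrations
    e0 = params.initial_energy()
    f_star = max(0.0, (1.0 - e0 + params.G * params.T + params.V * m) / tau)
    _check_clip_free(schedule, replace(params, F=f_star))
    return f_star, round(f_star * 20.0) / 20.0


def _check_clip_free(schedule: Schedule, params: ModelParams) -> None:
    """Replay the deterministic energy recursion and reject any clipping."""
    e = params.initial_energy()
    z = 0
    charge = 1.0 if schedule.charge_migration_cost else 0.0
    for a in schedule.actions:
        e_raw = e + (params.F * z - params.G) * params.dt - charge * params.V * abs(int(a))
        if e_raw <= 0 or e_raw >= params.E_max:
            raise ValueError(
                "energy path clips at the reserve bounds; the closed-form "
                "threshold does not apply"
            )
        e = e_raw
        z += int(a)


def compare_subscores(
    params: ModelParams,
    weights: ScoreWeights,
    sim: SimulationConfig,
    optimal_policies: Mapping[str, object] | None = None,
    solver_cfg: SolverConfig = SolverConfig(),
    include_optimal: bool = True,
) -> pd.DataFrame:
    """Behavior-by-scheme table of score summaries.

    ``optimal_policies`` maps scheme name to a closed-loop behavior; when
    omitted (and ``include_optimal``) a policy is solved per scheme.
    """
    rows = []
    for scheme in ("nearshore", "diurnal"):
        p_s = replace(params, predation_scheme=scheme)
        behaviors = standard_behaviors(p_s)
        if include_optimal:
            if optimal_policies is not None and scheme in optimal_policies:
                behaviors["optimal"] = optimal_policies[scheme]
            else:
                policy, _ = solve(p_s, weights, solver_cfg)
                behaviors["optimal"] = PolicyBehavior(policy)
        for bname, behavior in behaviors.items():
            summary = evaluate_behavior(behavior, p_s, weights, sim, name=bname)
            rows.append({"scheme": scheme, **summary.to_row()})
    return pd.DataFrame(rows)
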