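"""Trajectory scoring: four subscores and their weighted composite.

A trajectory earns credit for time spent outside the high-predation
region, time spent unstarved, ending inside the nearshore habitat, and
ending with enough energy for metamorphosis.  Exposure is accounted on
step-start states (the interval [t, t+dt) belongs to the state at t); the
terminal state contributes only through the two endpoint penalties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Ensemble, ModelParams, Trajectory

__all__ = [
    "ScoreWeights",
    "ScoreBreakdown",
    "in_high_predation",
    "predation_subscore",
    "starvation_subscore",
    "settling_penalty",
    "metamorphosis_penalty",
    "trajectory_score",
    "score_ensemble",
]

_TOL = 1e-12


@dataclass(frozen=True)
class ScoreWeights:
    """Non-negative subscore weights summing to 1."""

    p_pred: float = 0.25
    p_starve: float = 0.25
    p_settle: float = 0.25
    p_meta: float = 0.25

    def __post_init__(self) -> None:
        w = self.as_array()
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > _TOL:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_pred, self.p_starve, self.p_settle, self.p_meta])


@dataclass(frozen=True)
class ScoreBreakdown:
    """The four subscores, penalties, and composite score of one trajectory."""

    J_pred: float
    J_starve: float
    J_settle: float
    J_meta: float
    phi_settle: float
    phi_meta: float
    J: float
    weights: ScoreWeights
    scheme: str

    def to_dict(self) -> dict:
        return {
            "J": self.J,
            "J_pred": self.J_pred,
            "J_starve": self.J_starve,
            "J_settle": self.J_settle,
            "J_meta": self.J_meta,
            "phi_settle": self.phi_settle,
            "phi_meta": self.phi_meta,
            "weights": {
                "p_pred": self.weights.p_pred,
                "p_starve": self.weights.p_starve,
                "p_settle": self.weights.p_settle,
                "p_meta": self.weights.p_meta,
            },
            "scheme": self.scheme,
        }


def in_high_predation(t, X, Z, params: ModelParams):
    """Whether state(s) sit in the high-predation region (array-friendly).

    Nearshore scheme: the strip X <= 1, both layers, at all times.
    Diurnal scheme: the surface layer while the clock time (t mod 1) lies in
    the half-open daylight window.
    """
    if params.predation_scheme == "nearshore":
        return (np.asarray(X) <= 1.0)[()]
    lo, hi = params.daylight_window
    clock = np.mod(np.asarray(t), 1.0)
    return ((np.asarray(Z) == 1) & (clock >= lo) & (clock < hi))[()]


def _exposure_fraction(times, X, Z, params: ModelParams):
    """Fraction of duration spent inside the high-predation region."""
    high = in_high_predation(times, X, Z, params)
    frac = np.sum(high, axis=-1) * (params.dt / params.T)
    return frac


def predation_subscore(traj: Trajectory, params: ModelParams) -> float:
    """Fraction of the larval duration outside the high-predation region."""
    return float(1.0 - _exposure_fraction(traj.times[:-1], traj.X[:-1], traj.Z[:-1], params))


def starvation_subscore(traj: Trajectory, params: ModelParams) -> float:
    """Fraction of the larval duration with a positive energy reserve."""
    return float(np.sum(traj.E[:-1] > 0) * (params.dt / params.T))


def settling_penalty(X_T):
    """0 inside the habitat (X <= 1); 1 - 1/X beyond it."""
    x = np.asarray(X_T, dtype=float)
    return np.where(x <= 1.0, 0.0, 1.0 - 1.0 / np.maximum(x, 1.0))[()]


def metamorphosis_penalty(E_T):
    """0 when ending with E >= 1; otherwise the shortfall 1 - E."""
    e = np.asarray(E_T, dtype=float)
    return np.where(e >= 1.0, 0.0, 1.0 - e)[()]


def trajectory_score(
    traj: Trajectory, weights: ScoreWeights, params: ModelParams
) -> ScoreBreakdown:
    """Assemble the four subscores and the composite score J."""
    j_pred = predation_subscore(traj, params)
    j_starve = starvation_subscore(traj, params)
    phi_s = float(settling_penalty(traj.X[-1]))
    phi_m = float(metamorphosis_penalty(traj.E[-1]))
    j_settle = 1.0 - phi_s
    j_meta = 1.0 - phi_m
    j = (
        weights.p_pred * j_pred
        + weights.p_starve * j_starve
        + weights.p_settle * j_settle
        + weights.p_meta * j_meta
    )
    return ScoreBreakdown(
        J_pred=j_pred,
        J_starve=j_starve,
        J_settle=j_settle,
        J_meta=j_meta,
        phi_settle=phi_s,
        phi_meta=phi_m,
        J=j,
        weights=weights,
        scheme=params.predation_scheme,
    )


def score_ensemble(
    ens: Ensemble, weights: ScoreWeights, params: ModelParams
) -> pd.DataFrame:
    """Score every replicate; one row per trajectory.

    Columns: J, the four subscores, X_T, E_T.
    """
    t_held = ens.times[:-1]
    j_pred = 1.0 - _exposure_fraction(t_held, ens.X[:, :-1], ens.Z[:, :-1], params)
    j_starve = np.sum(ens.E[:, :-1] > 0, axis=1) * (params.dt / params.T)
    j_settle = 1.0 - settling_penalty(ens.X[:, -1])
    j_meta = 1.0 - metamorphosis_penalty(ens.E[:, -1])
    j = (
        weights.p_pred * j_pred
        + weights.p_starve * j_starve
        + weights.p_settle * j_settle
        + weights.p_meta * j_meta
    )
    return pd.DataFrame(
        {
            "J": j,
            "J_pred": j_pred,
            "J_starve": j_starve,
            "J_settle": j_settle,
            "J_meta": j_meta,
            "X_T": ens.X[:, -1],
            "E_T": ens.E[:, -1],
        }
    )
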