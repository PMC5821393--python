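"""Cohort projection: scenario-specific transition matrices, occupancy
trajectories, per-cycle reward accrual and discounting.

State order everywhere is (PF, STHPD, PD, DEAD).  Structurally forbidden
moves — PF→PD and PD→PF without passing through STHPD, and any exit from
DEAD — are exactly zero.  Rewards are attributed at cycle end by default
(state membership after each annual transition, discount exponents
t = 1..horizon) with no half-cycle correction; start-of-cycle attribution is
available through ``ModelSettings.reward_timing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    ModelParameters,
    ModelSettings,
    ScenarioSpec,
    TransitionSpec,
    ValidationError,
    aggregate_state_cost,
)
from .states import ALIVE_STATES, N_STATES, HealthState

__all__ = [
    "build_transition_matrix",
    "project_cohort",
    "state_cycle_values",
    "cycle_rewards",
    "discount_factors",
    "discounted_total",
    "RewardStream",
]

_ROW_TOL = 1e-12


def blended_sthpd_pd_probability(
    trans: TransitionSpec, scenario: ScenarioSpec
) -> float:
    """Cohort-average STHPD→PD probability under a scenario.

    Adherent recipients of the early intervention progress with probability
    ``p * RR`` (times the sensitivity-analysis multiplier on the treated
    probability); everyone else with ``p``.  With uptake ``u`` and effective
    adherence ``a`` the memoryless cohort blend is
    ``p * (1 - u*a*(1 - RR*m))``.
    """
    p = trans.p_sthpd_to_pd
    for iv in scenario.interventions_for(HealthState.STHPD):
        if iv.transition_rr is None:
            continue
        rr = iv.transition_rr * scenario.treated_transition_multiplier
        frac = iv.uptake * iv.effective_adherence
        p = p * (1.0 - frac * (1.0 - rr))
    return p


def build_transition_matrix(
    trans: TransitionSpec, scenario: ScenarioSpec
) -> np.ndarray:
    """Row-stochastic 4×4 annual transition matrix for one scenario.

    The early intervention's risk-ratio effect on STHPD→PD is blended over
    its uptake × effective adherence; the removed probability mass is added
    to the STHPD stay probability.  Death applies identically from every
    alive state, and DEAD is absorbing.
    """
    p_sthpd_pd = blended_sthpd_pd_probability(trans, scenario)
    d = trans.p_death
    m = np.zeros((N_STATES, N_STATES))
    PF, S, PD, DEAD = HealthState.PF, HealthState.STHPD, HealthState.PD, HealthState.DEAD
    m[PF, S] = trans.p_pf_to_sthpd
    m[PF, DEAD] = d
    m[PF, PF] = 1.0 - trans.p_pf_to_sthpd - d
    m[S, PF] = trans.p_sthpd_to_pf
    m[S, PD] = p_sthpd_pd
    m[S, DEAD] = d
    m[S, S] = 1.0 - trans.p_sthpd_to_pf - p_sthpd_pd - d
    m[PD, S] = trans.p_pd_to_sthpd
    m[PD, DEAD] = d
    m[PD, PD] = 1.0 - trans.p_pd_to_sthpd - d
    m[DEAD, DEAD] = 1.0
    if (m < -0.0).any() or (m > 1.0).any():
        raise ValidationError("transition matrix entry outside [0, 1]")
    if np.abs(m.sum(axis=1) - 1.0).max() > _ROW_TOL:
        raise ValidationError("transition matrix rows must sum to 1")
    return m


def project_cohort(
    initial: np.ndarray, matrix: np.ndarray, horizon: int
) -> np.ndarray:
    """Occupancy trajectory, shape ``(horizon + 1, 4)``, row ``t`` being the
    occupancy after ``t`` annual transitions (row 0 is the initial vector)."""
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,) or matrix.shape != (N_STATES, N_STATES):
        raise ValidationError("dimension mismatch between occupancy and matrix")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ValidationError("initial occupancy must sum to 1")
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    traj = np.empty((horizon + 1, N_STATES))
    traj[0] = initial
    for t in range(1, horizon + 1):
        traj[t] = traj[t - 1] @ matrix
    return traj


def state_cycle_values(
    params: ModelParameters, scenario: ScenarioSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-person per-cycle utility and cost by state, with intervention
    blending folded in.

    Utility of an alive state is its base utility plus, for each
    intervention targeting it, ``uptake × effective_adherence ×
    utility_gain`` (non-adherent recipients gain nothing).  Cost is the
    annual societal state cost plus ``uptake × annual_cost`` for each
    targeting intervention — full costs are incurred regardless of
    adherence.  DEAD contributes zero to both.
    """
    utilities = np.zeros(N_STATES)
    costs = np.zeros(N_STATES)
    for state in ALIVE_STATES:
        econ = params.economics_for(state)
        u = econ.utility
        c = aggregate_state_cost(econ)
        for iv in scenario.interventions_for(state):
            u += iv.uptake * iv.effective_adherence * iv.utility_gain
            c += iv.uptake * iv.annual_cost
        utilities[state] = u
        costs[state] = c
    return utilities, costs


@dataclass(frozen=True)
class RewardStream:
    """Undiscounted per-cycle rewards (length = horizon) and the matching
    discount factors for effects and costs."""

    utility: np.ndarray
    cost: np.ndarray
    discount_effects: np.ndarray
    discount_costs: np.ndarray

    @property
    def discounted_qalys(self) -> float:
        return float(self.utility @ self.discount_effects)

    @property
    def discounted_cost(self) -> float:
        return float(self.cost @ self.discount_costs)


def discount_factors(rate: float, horizon: int, timing: str = "end") -> np.ndarray:
    """Annual discount factors for cycles 1..horizon ("end" timing,
    exponents 1..horizon) or 0..horizon-1 ("start" timing)."""
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    exponents = np.arange(1, horizon + 1) if timing == "end" else np.arange(horizon)
    return (1.0 + rate) ** -exponents.astype(float)


def cycle_rewards(
    trajectory: np.ndarray,
    params: ModelParameters,
    scenario: ScenarioSpec,
    settings: ModelSettings | None = None,
) -> RewardStream:
    """Accrue per-cycle utility and cost rewards along a trajectory."""
    settings = scenario.resolve_settings(settings or params.settings)
    horizon = trajectory.shape[0] - 1
    utilities, costs = state_cycle_values(params, scenario)
    occ = trajectory[1:] if settings.reward_timing == "end" else trajectory[:-1]
    return RewardStream(
        utility=occ @ utilities,
        cost=occ @ costs,
        discount_effects=discount_factors(
            settings.discount_rate_effects, horizon, settings.reward_timing
        ),
        discount_costs=discount_factors(
            settings.discount_rate_costs, horizon, settings.reward_timing
        ),
    )


def discounted_total(values: np.ndarray, annual_rate: float, timing: str = "end") -> float:
    """Discounted sum of a per-cycle value stream."""
    values = np.asarray(values, dtype=float)
    return float(values @ discount_factors(annual_rate, values.shape[0], timing))
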