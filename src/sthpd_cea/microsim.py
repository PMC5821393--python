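"""Individual-level microsimulation oracle.

Simulates person-by-person trajectories under exactly the stochastic
assumptions the cohort model integrates over: annual Markov transitions with
STHPD as the obligatory intermediate, per-cycle intervention assignment by
uptake with adherence as a per-assignment coin flip (memoryless — treatment
status is redrawn every cycle, never carried over), per-cycle reward accrual
(full intervention cost whenever assigned, utility gain only when assigned
and adherent) and the same discounting as the cohort engine.  Monte-Carlo
means therefore converge to the cohort model's values, which is the primary
correctness oracle for the whole package.

Within a cycle, the treatment draw that modifies an STHPD occupant's
progression probability is made against the start-of-cycle state, while the
treatment draw that sets reward flags is made against the state the rewards
are attributed to (end-of-cycle state under the default timing) — mirroring
how the cohort model blends uptake into the transition matrix and into the
reward layer independently.

All randomness comes from a single seeded generator consumed in a fixed
cycle-major layout, so results do not depend on person iteration order and
two scenarios identical in law produce bit-identical output from the same
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov
from .parameters import (
    ModelParameters,
    ScenarioSpec,
    ValidationError,
    initial_occupancy,
)
from .states import N_STATES, HealthState

__all__ = ["MicrosimResult", "IndividualTrajectory", "simulate_population"]


@dataclass(frozen=True)
class IndividualTrajectory:
    """One simulated person: state path, per-cycle treatment flags (for the
    reward layer) and the per-cycle utility/cost ledger."""

    person: int
    states: np.ndarray          # (horizon + 1,) HealthState values
    assigned: np.ndarray        # (horizon, n_interventions) bool
    adherent: np.ndarray        # (horizon, n_interventions) bool
    utility: np.ndarray         # (horizon,) undiscounted
    cost: np.ndarray            # (horizon,) undiscounted
    intervention_names: tuple[str, ...]

    def ledger_frame(self) -> pd.DataFrame:
        horizon = self.utility.shape[0]
        return pd.DataFrame(
            {
                "cycle": np.arange(1, horizon + 1),
                "state": [HealthState(s).name for s in self.states[1:]],
                "utility": self.utility,
                "cost": self.cost,
            }
        )


@dataclass(frozen=True)
class MicrosimResult:
    """Population summary plus the full per-person ledgers."""

    scenario: str
    cohort: str
    n: int
    seed: int
    states: np.ndarray            # (n, horizon + 1) int8
    assigned: np.ndarray          # (n, horizon, K) bool
    adherent: np.ndarray          # (n, horizon, K) bool
    utility_ledger: np.ndarray    # (n, horizon) undiscounted per-cycle utility
    cost_ledger: np.ndarray       # (n, horizon)
    discount_effects: np.ndarray  # (horizon,)
    discount_costs: np.ndarray    # (horizon,)
    intervention_names: tuple[str, ...]

    @property
    def qalys(self) -> np.ndarray:
        return self.utility_ledger @ self.discount_effects

    @property
    def costs(self) -> np.ndarray:
        return self.cost_ledger @ self.discount_costs

    @property
    def mean_qalys(self) -> float:
        return float(self.qalys.mean())

    @property
    def se_qalys(self) -> float:
        return float(self.qalys.std(ddof=1) / np.sqrt(self.n))

    @property
    def mean_cost(self) -> float:
        return float(self.costs.mean())

    @property
    def se_cost(self) -> float:
        return float(self.costs.std(ddof=1) / np.sqrt(self.n))

    def state_frequencies(self) -> np.ndarray:
        """Empirical occupancy, shape (horizon + 1, 4); the microsim
        counterpart of the cohort trajectory."""
        horizon_p1 = self.states.shape[1]
        freq = np.empty((horizon_p1, N_STATES))
        for s in range(N_STATES):
            freq[:, s] = (self.states == s).mean(axis=0)
        return freq

    def trajectory(self, person: int) -> IndividualTrajectory:
        return IndividualTrajectory(
            person=person,
            states=self.states[person].copy(),
            assigned=self.assigned[person].copy(),
            adherent=self.adherent[person].copy(),
            utility=self.utility_ledger[person].copy(),
            cost=self.cost_ledger[person].copy(),
            intervention_names=self.intervention_names,
        )

    def per_person_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person": np.arange(self.n),
                "qalys": self.qalys,
                "cost": self.costs,
                "final_state": [HealthState(s).name for s in self.states[:, -1]],
            }
        )


def _treated_matrix(params: ModelParameters, scenario: ScenarioSpec) -> np.ndarray:
    """Transition matrix for an STHPD occupant assigned-and-adherent to the
    early intervention: STHPD→PD is p·RR (times the sensitivity multiplier),
    the removed mass moving to the stay probability."""
    t = params.transitions
    rr = 1.0
    for iv in scenario.interventions_for(HealthState.STHPD):
        if iv.transition_rr is not None:
            rr *= iv.transition_rr * scenario.treated_transition_multiplier
    p = min(t.p_sthpd_to_pd * rr, 1.0)
    m = markov.build_transition_matrix(
        t, ScenarioSpec(name="_untreated", interventions=())
    ).copy()
    S = HealthState.STHPD
    m[S, HealthState.PD] = p
    m[S, S] = 1.0 - t.p_sthpd_to_pf - p - t.p_death
    return m


def simulate_population(
    params: ModelParameters,
    scenario: ScenarioSpec,
    cohort: str = "mixed",
    n: int = 10_000,
    seed: int = 0,
) -> MicrosimResult:
    """Simulate ``n`` individual trajectories under one scenario.

    Each person starts in a state drawn from the cohort's initial occupancy
    and is followed over the horizon; see the module docstring for the
    per-cycle mechanics.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    settings = scenario.resolve_settings(params.settings)
    horizon = settings.horizon
    rng = np.random.default_rng(seed)

    ivs = scenario.interventions
    K = len(ivs)
    names = tuple(iv.name for iv in ivs)
    early_idx = [
        k for k, iv in enumerate(ivs)
        if iv.transition_rr is not None and iv.target_state is HealthState.STHPD
    ]

    m_untreated = markov.build_transition_matrix(
        params.transitions, ScenarioSpec(name="_untreated", interventions=())
    )
    m_treated = _treated_matrix(params, scenario)
    cum_untreated = np.cumsum(m_untreated, axis=1)
    cum_treated_sthpd = np.cumsum(m_treated[HealthState.STHPD])
    cum_untreated[:, -1] = 1.0
    cum_treated_sthpd[-1] = 1.0

    utilities, costs = markov.state_cycle_values(params, scenario)

    initial = initial_occupancy(settings, cohort)
    states = np.empty((n, horizon + 1), dtype=np.int8)
    u0 = rng.random(n)
    states[:, 0] = np.searchsorted(np.cumsum(initial), u0, side="right")

    assigned = np.zeros((n, horizon, K), dtype=bool)
    adherent = np.zeros((n, horizon, K), dtype=bool)
    utility_ledger = np.zeros((n, horizon))
    cost_ledger = np.zeros((n, horizon))

    for t in range(horizon):
        current = states[:, t]
        # (1) early-intervention assignment governing this cycle's transition
        u_assign = rng.random(n)
        u_adhere = rng.random(n)
        treated = np.zeros(n, dtype=bool)
        for k in early_idx:
            iv = ivs[k]
            mask = (
                (current == HealthState.STHPD)
                & (u_assign < iv.uptake)
                & (u_adhere < iv.effective_adherence)
            )
            treated |= mask
        # (2) transition
        u_move = rng.random(n)
        cum_rows = cum_untreated[current]
        if treated.any():
            cum_rows[treated] = cum_treated_sthpd
        nxt = (u_move[:, None] > cum_rows).sum(axis=1).astype(np.int8)
        states[:, t + 1] = nxt
        # (3) reward-layer assignment against the reward state
        reward_state = nxt if settings.reward_timing == "end" else current
        util_t = utilities[reward_state].copy()
        cost_t = costs[reward_state].copy()
        # strip the cohort blending: rewards here are individual
        for k, iv in enumerate(ivs):
            in_target = reward_state == iv.target_state
            util_t[in_target] -= iv.uptake * iv.effective_adherence * iv.utility_gain
            cost_t[in_target] -= iv.uptake * iv.annual_cost
            u_a = rng.random(n)
            u_h = rng.random(n)
            got = in_target & (u_a < iv.uptake)
            held = got & (u_h < iv.effective_adherence)
            assigned[:, t, k] = got
            adherent[:, t, k] = held
            cost_t[got] += iv.annual_cost
            util_t[held] += iv.utility_gain
        utility_ledger[:, t] = util_t
        cost_ledger[:, t] = cost_t

    return MicrosimResult(
        scenario=scenario.name,
        cohort=cohort if isinstance(cohort, str) else "custom",
        n=n,
        seed=int(seed),
        states=states,
        assigned=assigned,
        adherent=adherent,
        utility_ledger=utility_ledger,
        cost_ledger=cost_ledger,
        discount_effects=markov.discount_factors(
            settings.discount_rate_effects, horizon, settings.reward_timing
        ),
        discount_costs=markov.discount_factors(
            settings.discount_rate_costs, horizon, settings.reward_timing
        ),
        intervention_names=names,
    )
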