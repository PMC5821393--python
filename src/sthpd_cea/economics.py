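"""Scenario evaluation and incremental cost-effectiveness statistics:
per-patient discounted QALYs and societal costs, ICER with dominance
quadrant, net monetary benefit, and the cost-effectiveness acceptability
curve."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import markov
from .parameters import (
    ModelParameters,
    ScenarioSpec,
    ValidationError,
    initial_occupancy,
)

__all__ = [
    "ScenarioResult",
    "IncrementalResult",
    "evaluate_scenario",
    "incremental",
    "net_monetary_benefit",
    "ceac",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class ScenarioResult:
    """Per-patient discounted totals for one scenario × cohort."""

    scenario: str
    cohort: str
    qalys: float
    cost: float


@dataclass(frozen=True)
class IncrementalResult:
    """Alternative-minus-comparator deltas with the derived ICER and the
    cost-effectiveness-plane quadrant."""

    delta_qaly: float
    delta_cost: float
    icer: float | None
    quadrant: str


def evaluate_scenario(
    params: ModelParameters,
    scenario: ScenarioSpec,
    cohort: str | np.ndarray = "mixed",
    trajectory: np.ndarray | None = None,
) -> ScenarioResult:
    """Run the cohort model for one scenario.

    Composes the initial occupancy, the scenario transition matrix, the
    occupancy projection, reward accrual and differential discounting
    (effects at 1.5%/year, costs at 4%/year by default).  ``cohort`` may be
    a label (``mixed`` / ``sthpd_only``) or an explicit occupancy vector.
    A precomputed ``trajectory`` skips the projection (used by the PSA,
    where transitions are fixed across draws).
    """
    settings = scenario.resolve_settings(params.settings)
    if trajectory is None:
        if isinstance(cohort, str):
            initial = initial_occupancy(settings, cohort)
        else:
            initial = np.asarray(cohort, dtype=float)
        matrix = markov.build_transition_matrix(params.transitions, scenario)
        trajectory = markov.project_cohort(initial, matrix, settings.horizon)
    stream = markov.cycle_rewards(trajectory, params, scenario, params.settings)
    label = cohort if isinstance(cohort, str) else "custom"
    return ScenarioResult(
        scenario=scenario.name,
        cohort=label,
        qalys=stream.discounted_qalys,
        cost=stream.discounted_cost,
    )


def _classify(delta_qaly: float, delta_cost: float) -> str:
    if delta_qaly > 0 and delta_cost < 0:
        return "dominant"
    if delta_qaly < 0 and delta_cost > 0:
        return "dominated"
    if delta_qaly > 0 and delta_cost >= 0:
        return "NE"
    if delta_qaly < 0 and delta_cost <= 0:
        return "SW"
    # delta_qaly == 0: classify by cost sign alone
    if delta_cost > 0:
        return "dominated"
    if delta_cost < 0:
        return "dominant"
    return "undefined"


def incremental(base: ScenarioResult, alt: ScenarioResult) -> IncrementalResult:
    """Alternative vs comparator: ΔQALY, Δcost, ICER and quadrant.

    The ICER is Δcost/ΔQALY; it is undefined (``None``) when ΔQALY is zero.
    """
    if base.cohort != alt.cohort:
        raise ValidationError(
            f"cohort mismatch: {base.cohort!r} vs {alt.cohort!r}"
        )
    dq = alt.qalys - base.qalys
    dc = alt.cost - base.cost
    icer = dc / dq if dq != 0.0 else None
    return IncrementalResult(delta_qaly=dq, delta_cost=dc, icer=icer,
                             quadrant=_classify(dq, dc))


def net_monetary_benefit(delta_qaly, delta_cost, wtp: float):
    """NMB = wtp × ΔQALY − Δcost (array-friendly)."""
    if wtp < 0:
        raise ValidationError("wtp must be >= 0")
    return wtp * np.asarray(delta_qaly) - np.asarray(delta_cost)


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid for the CEAC: €0–80,000 in €1,000 steps,
    bracketing the €20,000/QALY threshold."""
    return np.arange(0.0, 80_001.0, 1_000.0)


def ceac(
    iteration_deltas: np.ndarray | list,
    wtp_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    ``iteration_deltas`` is an (n, 2) array of per-iteration (ΔQALY, Δcost);
    the curve gives, at each willingness-to-pay value, the fraction of
    iterations with strictly positive net monetary benefit.
    """
    deltas = np.asarray(iteration_deltas, dtype=float)
    if deltas.ndim != 2 or deltas.shape[1] != 2 or deltas.shape[0] == 0:
        raise ValidationError("iteration_deltas must be a non-empty (n, 2) array")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    nmb = wtp_grid[:, None] * deltas[:, 0][None, :] - deltas[:, 1][None, :]
    return (nmb > 0).mean(axis=1)
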