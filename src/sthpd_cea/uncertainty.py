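"""Probabilistic and deterministic (one-way) sensitivity analysis.

The PSA draws one joint parameter set per iteration — normal utilities
(truncated to [0, 1]), normal utility gains (truncated at 0), gamma cost
parameters (mean-preserving shape = 1/CV², scale = mean·CV²) — and
evaluates comparator and alternative scenarios on the *same* draw (common
random numbers).  Transition probabilities and discount rates stay fixed.
The one-way analyses rerun the PSA under single structured assumption
changes (horizon, uptakes, treated-transition multiplier, uncorrected
utilities).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import economics, markov
from .parameters import (
    InterventionProfile,
    ModelParameters,
    ScenarioSpec,
    StateEconomics,
    ValidationError,
    initial_occupancy,
    uncorrect_utilities,
)
from .states import ALIVE_STATES, HealthState

__all__ = [
    "DistributionSpec",
    "gamma_shape_scale",
    "sample_parameters",
    "PsaResult",
    "run_psa",
    "DsaScenario",
    "one_way_scenarios",
    "apply_dsa",
    "run_dsa",
]


def gamma_shape_scale(mean: float, cv: float) -> tuple[float, float]:
    """Mean-preserving gamma parameterisation from a coefficient of
    variation: shape = 1/CV², scale = mean·CV²."""
    if mean <= 0:
        raise ValidationError("gamma mean must be > 0")
    if cv <= 0:
        raise ValidationError("gamma cv must be > 0")
    return 1.0 / cv**2, mean * cv**2


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling annotation for one parameter.

    ``normal`` uses ``spread`` as the standard error and truncates to
    ``bounds`` by resampling; ``gamma`` uses ``spread`` as the coefficient
    of variation; ``fixed`` ignores ``spread``.  Zero spread degenerates to
    the mean for every family.
    """

    family: str
    mean: float
    spread: float = 0.0
    bounds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if self.family not in ("normal", "gamma", "fixed"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.spread < 0:
            raise ValidationError("spread must be >= 0")
        if self.family == "gamma" and self.spread > 0 and self.mean <= 0:
            raise ValidationError("gamma requires mean > 0")

    def sample(self, rng: np.random.Generator):
        if self.family == "fixed" or self.spread == 0.0:
            return self.mean
        if self.family == "gamma":
            shape, scale = gamma_shape_scale(self.mean, self.spread)
            return rng.gamma(shape, scale)
        lo = -np.inf if self.bounds[0] is None else self.bounds[0]
        hi = np.inf if self.bounds[1] is None else self.bounds[1]
        while True:  # truncation by resampling
            x = rng.normal(self.mean, self.spread)
            if lo <= x <= hi:
                return x


def _utility_spec(econ: StateEconomics) -> DistributionSpec:
    return DistributionSpec("normal", econ.utility, econ.utility_se, (0.0, 1.0))


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> ModelParameters:
    """One joint PSA draw of the full parameter set.

    Draw order is canonical (states in declaration order: utility then the
    three cost categories; then interventions: utility gain then cost), so
    a fixed generator state yields a reproducible draw.
    """
    se_frac = params.uncertainty.utility_gain_se_frac
    econ_out: list[StateEconomics] = []
    for econ in params.state_economics:
        if econ.state is HealthState.DEAD:
            econ_out.append(econ)
            continue
        utility = _utility_spec(econ).sample(rng)
        cats = {}
        for name in ("cost_direct_medical", "cost_direct_nonmedical",
                     "cost_indirect_nonmedical"):
            mean = getattr(econ, name)
            if mean == 0.0 or econ.cost_cv == 0.0:
                cats[name] = mean
            else:
                cats[name] = DistributionSpec("gamma", mean, econ.cost_cv).sample(rng)
        econ_out.append(replace(econ, utility=utility, **cats))

    ivs_out: list[InterventionProfile] = []
    for iv in params.interventions:
        gain = DistributionSpec(
            "normal", iv.utility_gain, se_frac * iv.utility_gain, (0.0, None)
        ).sample(rng)
        if iv.annual_cost > 0.0 and params.uncertainty.cost_cv > 0.0:
            cost = DistributionSpec(
                "gamma", iv.annual_cost, params.uncertainty.cost_cv
            ).sample(rng)
        else:
            cost = iv.annual_cost
        ivs_out.append(replace(iv, utility_gain=gain, annual_cost=cost))

    return params.replace(
        state_economics=tuple(econ_out), interventions=tuple(ivs_out)
    )


def _apply_draw(scenario: ScenarioSpec, draw: ModelParameters) -> ScenarioSpec:
    """Propagate a joint draw to a scenario's profiles by intervention name,
    preserving the scenario's own uptake settings."""
    ivs = []
    for iv in scenario.interventions:
        drawn = draw.intervention(iv.name)
        ivs.append(replace(iv, utility_gain=drawn.utility_gain,
                           annual_cost=drawn.annual_cost))
    return replace(scenario, interventions=tuple(ivs))


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration PSA table plus summaries.

    ``qalys``/``costs`` arrays are per iteration; deltas are alternative
    minus comparator on common random numbers.  Two ICER summaries are
    provided: the ratio of mean incremental cost to mean incremental QALY
    (``icer_ratio_of_means``, the headline statistic) and the 2.5th/97.5th
    percentiles of the per-iteration ICERs (``icer_percentiles``), which are
    wide and may cross sign because per-iteration ratios are unstable when
    ΔQALY is near zero.
    """

    comparator: str
    alternative: str
    cohort: str
    seed: int
    qalys_base: np.ndarray
    qalys_alt: np.ndarray
    costs_base: np.ndarray
    costs_alt: np.ndarray
    wtp_grid: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.qalys_base.shape[0]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qalys_alt - self.qalys_base

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs_alt - self.costs_base

    @property
    def icer_ratio_of_means(self) -> float:
        return float(self.delta_cost.mean() / self.delta_qaly.mean())

    @property
    def icer_mean_of_ratios(self) -> float:
        dq = self.delta_qaly
        return float(np.mean(self.delta_cost[dq != 0] / dq[dq != 0]))

    def icer_percentiles(self, q=(2.5, 97.5)) -> np.ndarray:
        dq = self.delta_qaly
        ratios = self.delta_cost[dq != 0] / dq[dq != 0]
        return np.percentile(ratios, q)

    def ceac(self, wtp_grid: np.ndarray | None = None) -> np.ndarray:
        grid = self.wtp_grid if wtp_grid is None else np.asarray(wtp_grid)
        deltas = np.column_stack([self.delta_qaly, self.delta_cost])
        return economics.ceac(deltas, grid)

    def probability_cost_effective(self, wtp: float) -> float:
        return float(self.ceac(np.array([wtp]))[0])

    def iteration_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                f"qalys_{self.comparator}": self.qalys_base,
                f"qalys_{self.alternative}": self.qalys_alt,
                f"cost_{self.comparator}": self.costs_base,
                f"cost_{self.alternative}": self.costs_alt,
                "delta_qaly": self.delta_qaly,
                "delta_cost": self.delta_cost,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        def row(name, values):
            lo, hi = np.percentile(values, [2.5, 97.5])
            return {"quantity": name, "mean": values.mean(), "p2.5": lo, "p97.5": hi}

        rows = [
            row(f"qalys_{self.comparator}", self.qalys_base),
            row(f"qalys_{self.alternative}", self.qalys_alt),
            row(f"cost_{self.comparator}", self.costs_base),
            row(f"cost_{self.alternative}", self.costs_alt),
            row("delta_qaly", self.delta_qaly),
            row("delta_cost", self.delta_cost),
        ]
        icer_lo, icer_hi = self.icer_percentiles()
        rows.append(
            {"quantity": "icer", "mean": self.icer_ratio_of_means,
             "p2.5": icer_lo, "p97.5": icer_hi}
        )
        return pd.DataFrame(rows)

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "probability_cost_effective": self.ceac()}
        )


def run_psa(
    params: ModelParameters,
    scenarios: tuple[ScenarioSpec, ScenarioSpec],
    cohort: str = "mixed",
    iterations: int | None = None,
    seed: int | None = None,
    wtp_grid: np.ndarray | None = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis over a (comparator, alternative)
    scenario pair.

    Both scenarios share each iteration's joint parameter draw.  Because
    transition probabilities are fixed, each scenario's occupancy
    trajectory is projected once and only the reward layer is re-evaluated
    per draw.  Re-running with the same seed is bit-identical.
    """
    base, alt = scenarios
    iterations = iterations if iterations is not None else params.settings.psa_iterations
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    seed = seed if seed is not None else params.settings.rng_seed
    rng = np.random.default_rng(seed)
    grid = economics.default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid)

    trajectories = {}
    for scen in (base, alt):
        settings = scen.resolve_settings(params.settings)
        initial = initial_occupancy(settings, cohort)
        matrix = markov.build_transition_matrix(params.transitions, scen)
        trajectories[scen.name] = markov.project_cohort(
            initial, matrix, settings.horizon
        )

    qb = np.empty(iterations)
    qa = np.empty(iterations)
    cb = np.empty(iterations)
    ca = np.empty(iterations)
    for i in range(iterations):
        draw = sample_parameters(params, rng)
        res_b = economics.evaluate_scenario(
            draw, _apply_draw(base, draw), cohort, trajectory=trajectories[base.name]
        )
        res_a = economics.evaluate_scenario(
            draw, _apply_draw(alt, draw), cohort, trajectory=trajectories[alt.name]
        )
        qb[i], cb[i] = res_b.qalys, res_b.cost
        qa[i], ca[i] = res_a.qalys, res_a.cost

    return PsaResult(
        comparator=base.name,
        alternative=alt.name,
        cohort=cohort,
        seed=int(seed),
        qalys_base=qb,
        qalys_alt=qa,
        costs_base=cb,
        costs_alt=ca,
        wtp_grid=grid,
    )


# ---------------------------------------------------------------------------
# one-way (deterministic) sensitivity scenarios

@dataclass(frozen=True)
class DsaScenario:
    """A single structured assumption change applied on top of the base
    case.  Unset fields keep their reference values."""

    name: str
    horizon: int | None = None
    early_uptake: float | None = None
    treated_transition_multiplier: float | None = None
    pd_uptake_total: float | None = None
    uncorrected_utilities: bool = False


def one_way_scenarios() -> tuple[DsaScenario, ...]:
    """The eight shipped one-way sensitivity scenarios."""
    return (
        DsaScenario("Time horizon 1 year", horizon=1),
        DsaScenario("Time horizon 10 years", horizon=10),
        DsaScenario("Early intervention 5% uptake rate", early_uptake=0.05),
        DsaScenario("Early intervention 15% uptake rate", early_uptake=0.15),
        DsaScenario(
            "Early intervention transition from STHPD to PD 10% lower",
            treated_transition_multiplier=0.9,
        ),
        DsaScenario(
            "Early intervention transition from STHPD to PD 10% higher",
            treated_transition_multiplier=1.1,
        ),
        DsaScenario("Uptake rate PD interventions 100%", pd_uptake_total=1.0),
        DsaScenario("Uncorrected utility values", uncorrected_utilities=True),
    )


def _scale_pd_uptakes(scenario: ScenarioSpec, total: float) -> ScenarioSpec:
    pd_ivs = scenario.interventions_for(HealthState.PD)
    current = sum(iv.uptake for iv in pd_ivs)
    if current <= 0:
        raise ValidationError("cannot rescale PD uptakes: current total is 0")
    factor = total / current
    ivs = tuple(
        replace(iv, uptake=min(iv.uptake * factor, 1.0))
        if iv.target_state is HealthState.PD
        else iv
        for iv in scenario.interventions
    )
    return replace(scenario, interventions=ivs)


def apply_dsa(
    params: ModelParameters,
    base: ScenarioSpec,
    alt: ScenarioSpec,
    dsa: DsaScenario,
) -> tuple[ModelParameters, ScenarioSpec, ScenarioSpec]:
    """Resolve a one-way scenario against the reference inputs."""
    if dsa.horizon is not None:
        params = params.replace(
            settings=dataclasses.replace(params.settings, horizon=dsa.horizon)
        )
    if dsa.uncorrected_utilities:
        params = params.replace(
            state_economics=uncorrect_utilities(params.state_economics),
            settings=dataclasses.replace(params.settings, utilities_corrected=False),
        )
    if dsa.early_uptake is not None:
        ivs = tuple(
            replace(iv, uptake=dsa.early_uptake) if iv.transition_rr is not None else iv
            for iv in alt.interventions
        )
        alt = replace(alt, interventions=ivs)
    if dsa.treated_transition_multiplier is not None:
        base = replace(
            base, treated_transition_multiplier=dsa.treated_transition_multiplier
        )
        alt = replace(
            alt, treated_transition_multiplier=dsa.treated_transition_multiplier
        )
    if dsa.pd_uptake_total is not None:
        base = _scale_pd_uptakes(base, dsa.pd_uptake_total)
        alt = _scale_pd_uptakes(alt, dsa.pd_uptake_total)
    return params, base, alt


def run_dsa(
    params: ModelParameters,
    scenarios: tuple[ScenarioSpec, ScenarioSpec],
    dsa_list: tuple[DsaScenario, ...] | None = None,
    cohort: str = "mixed",
    iterations: int | None = None,
    seed: int | None = None,
    include_reference: bool = True,
) -> pd.DataFrame:
    """One PSA summary per one-way scenario (plus the reference case).

    Every row reports the mean incremental QALYs and costs, the
    ratio-of-means ICER and the 2.5th/97.5th percentiles of per-iteration
    ICERs.  All rows use the same seed, so scenario-to-scenario contrasts
    are on common random numbers.
    """
    base, alt = scenarios
    if dsa_list is None:
        dsa_list = one_way_scenarios()
    rows = []
    runs: list[tuple[str, DsaScenario | None]] = []
    if include_reference:
        runs.append(("Reference case", None))
    runs.extend((d.name, d) for d in dsa_list)
    for name, dsa in runs:
        p, b, a = (params, base, alt) if dsa is None else apply_dsa(params, base, alt, dsa)
        psa = run_psa(p, (b, a), cohort=cohort, iterations=iterations, seed=seed)
        lo, hi = psa.icer_percentiles()
        rows.append(
            {
                "scenario": name,
                "mean_delta_qaly": psa.delta_qaly.mean(),
                "mean_delta_cost": psa.delta_cost.mean(),
                "icer": psa.icer_ratio_of_means,
                "icer_p2.5": lo,
                "icer_p97.5": hi,
            }
        )
    return pd.DataFrame(rows)
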