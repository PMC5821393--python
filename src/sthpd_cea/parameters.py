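"""Model inputs: intervention profiles, per-state economics, transitions,
run settings, scenarios, and the YAML configuration round-trip.

Every default reproduces the published input tables for Dutch panic-disorder
care (uptake/adherence of usual-care interventions, annual transition
probabilities, EQ-5D-based state utilities with standard errors, annual
societal cost categories, per-intervention utility gains and costs, and the
Dutch differential discount rates of 4% for costs and 1.5% for effects).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

from .states import HealthState

__all__ = [
    "ValidationError",
    "ConfigError",
    "InterventionProfile",
    "StateEconomics",
    "TransitionSpec",
    "ModelSettings",
    "UncertaintySettings",
    "ModelParameters",
    "ScenarioSpec",
    "effective_adherence",
    "aggregate_state_cost",
    "uncorrect_utilities",
    "initial_occupancy",
    "default_parameters",
    "load_config",
    "save_config",
    "usual_care_scenario",
    "early_intervention_scenario",
]


class ValidationError(ValueError):
    """A model input violates its constraints."""


class ConfigError(ValidationError):
    """A configuration file is malformed; the message names the offending
    key path (or, for YAML syntax errors, the line)."""


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def _check_nonneg(value: float, name: str) -> float:
    value = float(value)
    if not value >= 0.0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return value


def effective_adherence(base_adherence: float, dropout: float) -> float:
    """Adherence after treatment dropout.

    Dropping out of pharmacotherapy lowers the fraction of treated patients
    who actually realise the treatment benefit:
    ``base_adherence * (1 - dropout)``.
    """
    base_adherence = _check_prob(base_adherence, "base_adherence")
    dropout = _check_prob(dropout, "dropout")
    return base_adherence * (1.0 - dropout)


@dataclass(frozen=True)
class InterventionProfile:
    """One intervention row: who gets it, how well it is followed, what it
    costs per treated person per year, and what it does.

    ``utility_gain`` is an additive per-cycle utility increment realised by
    adherent recipients only; ``annual_cost`` is incurred by every recipient
    regardless of adherence.  ``transition_rr`` (early intervention only) is
    the risk ratio applied to the STHPD→PD transition of adherent recipients.
    """

    name: str
    target_state: HealthState
    uptake: float
    base_adherence: float = 0.70
    dropout: float = 0.0
    annual_cost: float = 0.0
    utility_gain: float = 0.0
    transition_rr: float | None = None

    def __post_init__(self) -> None:
        if self.target_state not in (HealthState.STHPD, HealthState.PD):
            raise ValidationError(
                f"intervention {self.name!r}: target_state must be STHPD or PD"
            )
        _check_prob(self.uptake, f"intervention {self.name!r}: uptake")
        _check_prob(self.base_adherence, f"intervention {self.name!r}: base_adherence")
        _check_prob(self.dropout, f"intervention {self.name!r}: dropout")
        _check_nonneg(self.annual_cost, f"intervention {self.name!r}: annual_cost")
        _check_nonneg(self.utility_gain, f"intervention {self.name!r}: utility_gain")
        if self.transition_rr is not None and not 0.0 < self.transition_rr <= 1.0:
            raise ValidationError(
                f"intervention {self.name!r}: transition_rr must lie in (0, 1]"
            )

    @property
    def effective_adherence(self) -> float:
        return effective_adherence(self.base_adherence, self.dropout)


@dataclass(frozen=True)
class StateEconomics:
    """Per-state utility (with its sampling SE) and the three annual
    societal cost categories, plus the gamma coefficient of variation used
    when sampling each cost category in the PSA."""

    state: HealthState
    utility: float
    utility_se: float = 0.0
    cost_direct_medical: float = 0.0
    cost_direct_nonmedical: float = 0.0
    cost_indirect_nonmedical: float = 0.0
    cost_cv: float = 0.25

    def __post_init__(self) -> None:
        name = f"state {self.state.name}"
        _check_prob(self.utility, f"{name}: utility")
        _check_nonneg(self.utility_se, f"{name}: utility_se")
        for cat in (
            "cost_direct_medical",
            "cost_direct_nonmedical",
            "cost_indirect_nonmedical",
        ):
            _check_nonneg(getattr(self, cat), f"{name}: {cat}")
        _check_nonneg(self.cost_cv, f"{name}: cost_cv")
        if self.state is HealthState.DEAD:
            if self.utility != 0.0 or self.utility_se != 0.0 or self.societal_cost != 0.0:
                raise ValidationError("DEAD must have zero utility and zero costs")

    @property
    def societal_cost(self) -> float:
        return aggregate_state_cost(self)

    @property
    def cost_categories(self) -> tuple[float, float, float]:
        return (
            self.cost_direct_medical,
            self.cost_direct_nonmedical,
            self.cost_indirect_nonmedical,
        )


def aggregate_state_cost(econ: StateEconomics) -> float:
    """Annual societal cost of a state: direct medical + direct non-medical
    + indirect non-medical (productivity) costs."""
    return (
        econ.cost_direct_medical
        + econ.cost_direct_nonmedical
        + econ.cost_indirect_nonmedical
    )


@dataclass(frozen=True)
class TransitionSpec:
    """Annual transition probabilities.  Death applies identically from
    every alive state; remaining exit mass defines each stay probability."""

    p_pf_to_sthpd: float = 0.0016
    p_sthpd_to_pf: float = 0.0815
    p_sthpd_to_pd: float = 0.6037
    p_pd_to_sthpd: float = 0.5214
    p_death: float = 0.0028

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_prob(getattr(self, f.name), f.name)
        exits = {
            "PF": self.p_pf_to_sthpd + self.p_death,
            "STHPD": self.p_sthpd_to_pf + self.p_sthpd_to_pd + self.p_death,
            "PD": self.p_pd_to_sthpd + self.p_death,
        }
        for state, total in exits.items():
            if not total < 1.0:
                raise ValidationError(
                    f"exit probabilities from {state} sum to {total}, must be < 1"
                )


_REWARD_TIMINGS = ("end", "start")
_COHORT_LABELS = ("mixed", "sthpd_only")


@dataclass(frozen=True)
class ModelSettings:
    """Run-level settings: horizon, differential discounting, the
    willingness-to-pay threshold, cohort prevalences and PSA defaults."""

    horizon: int = 5
    cycle_length: float = 1.0
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    wtp_threshold: float = 20_000.0
    prevalence_sthpd: float = 0.019
    prevalence_pd: float = 0.022
    utilities_corrected: bool = True
    psa_iterations: int = 10_000
    rng_seed: int = 2014
    reward_timing: str = "end"

    def __post_init__(self) -> None:
        if int(self.horizon) != self.horizon or self.horizon < 1:
            raise ValidationError(f"horizon must be an integer >= 1, got {self.horizon!r}")
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length must be positive")
        for name in ("discount_rate_costs", "discount_rate_effects"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1), got {rate!r}")
        _check_nonneg(self.wtp_threshold, "wtp_threshold")
        for name in ("prevalence_sthpd", "prevalence_pd"):
            if not getattr(self, name) > 0.0:
                raise ValidationError(f"{name} must be > 0")
        if self.psa_iterations < 1:
            raise ValidationError("psa_iterations must be >= 1")
        if self.reward_timing not in _REWARD_TIMINGS:
            raise ValidationError(
                f"reward_timing must be one of {_REWARD_TIMINGS}, got {self.reward_timing!r}"
            )


@dataclass(frozen=True)
class UncertaintySettings:
    """Spread assumptions for PSA parameters whose sampling spread is not
    reported: gamma CV for cost parameters and the utility-gain SE as a
    fraction of its mean."""

    cost_cv: float = 0.25
    utility_gain_se_frac: float = 0.20

    def __post_init__(self) -> None:
        _check_nonneg(self.cost_cv, "cost_cv")
        _check_nonneg(self.utility_gain_se_frac, "utility_gain_se_frac")


def _dead_economics() -> StateEconomics:
    return StateEconomics(state=HealthState.DEAD, utility=0.0, utility_se=0.0,
                          cost_direct_medical=0.0, cost_direct_nonmedical=0.0,
                          cost_indirect_nonmedical=0.0, cost_cv=0.0)


@dataclass(frozen=True)
class ModelParameters:
    """The full annotated input set: transitions, per-state economics, the
    master intervention table (with the early intervention at its
    alternative-scenario uptake), run settings and PSA spreads."""

    transitions: TransitionSpec = field(default_factory=TransitionSpec)
    state_economics: tuple[StateEconomics, ...] = ()
    interventions: tuple[InterventionProfile, ...] = ()
    settings: ModelSettings = field(default_factory=ModelSettings)
    uncertainty: UncertaintySettings = field(default_factory=UncertaintySettings)

    def __post_init__(self) -> None:
        states = [e.state for e in self.state_economics]
        if HealthState.DEAD not in states:
            object.__setattr__(
                self, "state_economics", tuple(self.state_economics) + (_dead_economics(),)
            )
            states.append(HealthState.DEAD)
        if sorted(states) != sorted(HealthState) or len(states) != len(set(states)):
            raise ValidationError("state_economics must cover each health state exactly once")
        names = [iv.name for iv in self.interventions]
        if len(names) != len(set(names)):
            raise ValidationError("intervention names must be unique")

    def economics_for(self, state: HealthState) -> StateEconomics:
        for econ in self.state_economics:
            if econ.state is state:
                return econ
        raise KeyError(state)

    def intervention(self, name: str) -> InterventionProfile:
        for iv in self.interventions:
            if iv.name == name:
                return iv
        raise KeyError(name)

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)


def uncorrect_utilities(
    econ_set: Iterable[StateEconomics],
) -> tuple[StateEconomics, ...]:
    """Undo the general-population utility correction.

    The base-case STHPD/PD utilities are the burden-of-disease weights
    multiplied by the general-population (PF) utility; the "uncorrected"
    sensitivity scenario divides them back out.  PF and DEAD are unchanged.
    """
    econ_set = tuple(econ_set)
    pf = next(e for e in econ_set if e.state is HealthState.PF)
    if pf.utility <= 0.0:
        raise ValidationError("PF utility must be > 0 to uncorrect utilities")
    out = []
    for econ in econ_set:
        if econ.state in (HealthState.STHPD, HealthState.PD):
            out.append(
                dataclasses.replace(
                    econ,
                    utility=min(econ.utility / pf.utility, 1.0),
                    utility_se=econ.utility_se / pf.utility,
                )
            )
        else:
            out.append(econ)
    return tuple(out)


def initial_occupancy(settings: ModelSettings, cohort: str = "mixed") -> np.ndarray:
    """Starting occupancy vector over (PF, STHPD, PD, DEAD).

    ``mixed`` splits the cohort between STHPD and PD in proportion to their
    annual prevalences (1.9% vs 2.2% by default); ``sthpd_only`` starts the
    whole cohort in STHPD.
    """
    if cohort == "mixed":
        total = settings.prevalence_sthpd + settings.prevalence_pd
        sthpd = settings.prevalence_sthpd / total
        vec = np.array([0.0, sthpd, 1.0 - sthpd, 0.0])
    elif cohort in ("sthpd_only", "sthpd"):
        vec = np.array([0.0, 1.0, 0.0, 0.0])
    else:
        raise ValidationError(f"unknown cohort label {cohort!r}")
    return vec


@dataclass
class ScenarioSpec:
    """One strategy to evaluate: a named set of intervention profiles plus
    optional setting overrides and the multiplier applied to the treated
    (post-risk-ratio) STHPD→PD probability in one-way sensitivity runs."""

    name: str
    interventions: tuple[InterventionProfile, ...]
    treated_transition_multiplier: float = 1.0
    settings_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.interventions = tuple(self.interventions)
        names = [iv.name for iv in self.interventions]
        if len(names) != len(set(names)):
            raise ValidationError("intervention names must be unique within a scenario")
        if self.treated_transition_multiplier < 0:
            raise ValidationError("treated_transition_multiplier must be >= 0")

    def intervention(self, name: str) -> InterventionProfile:
        for iv in self.interventions:
            if iv.name == name:
                return iv
        raise KeyError(name)

    def interventions_for(self, state: HealthState) -> tuple[InterventionProfile, ...]:
        return tuple(iv for iv in self.interventions if iv.target_state is state)

    def resolve_settings(self, settings: ModelSettings) -> ModelSettings:
        if not self.settings_overrides:
            return settings
        return dataclasses.replace(settings, **self.settings_overrides)

    def with_uptake(self, name: str, uptake: float) -> "ScenarioSpec":
        ivs = tuple(
            dataclasses.replace(iv, uptake=uptake) if iv.name == name else iv
            for iv in self.interventions
        )
        if name not in {iv.name for iv in ivs}:
            raise KeyError(name)
        return dataclasses.replace(self, interventions=ivs)


def usual_care_scenario(params: ModelParameters) -> ScenarioSpec:
    """Usual care: the four PD interventions at their usual-care uptake and
    no early intervention (uptake 0)."""
    ivs = tuple(
        dataclasses.replace(iv, uptake=0.0) if iv.transition_rr is not None else iv
        for iv in params.interventions
    )
    return ScenarioSpec(name="usual_care", interventions=ivs)


def early_intervention_scenario(
    params: ModelParameters, uptake: float | None = None
) -> ScenarioSpec:
    """Usual care plus the CBT-based early intervention for STHPD occupants
    (10% uptake in the base case)."""
    ivs = params.interventions
    if uptake is not None:
        ivs = tuple(
            dataclasses.replace(iv, uptake=uptake) if iv.transition_rr is not None else iv
            for iv in ivs
        )
    return ScenarioSpec(name="early_intervention", interventions=ivs)


# ---------------------------------------------------------------------------
# configuration round-trip

def _require(mapping: Mapping, key: str, path: str):
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    if key not in mapping:
        raise ConfigError(f"{path}.{key}: missing required key")
    return mapping[key]


def _params_from_dict(doc: Mapping) -> ModelParameters:
    if not isinstance(doc, Mapping):
        raise ConfigError("top level: expected a mapping of sections")
    known = {"settings", "transitions", "states", "interventions", "uncertainty"}
    for key in doc:
        if key not in known:
            raise ConfigError(f"{key}: unknown top-level section")

    unc_doc = doc.get("uncertainty", {})
    try:
        uncertainty = UncertaintySettings(**dict(unc_doc))
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"uncertainty: {exc}") from exc

    try:
        settings = ModelSettings(**dict(doc.get("settings", {})))
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"settings: {exc}") from exc

    trans_doc = doc.get("transitions", {})
    mapping = {
        "pf_to_sthpd": "p_pf_to_sthpd",
        "sthpd_to_pf": "p_sthpd_to_pf",
        "sthpd_to_pd": "p_sthpd_to_pd",
        "pd_to_sthpd": "p_pd_to_sthpd",
        "death": "p_death",
    }
    kwargs = {}
    for key, val in dict(trans_doc).items():
        if key not in mapping:
            raise ConfigError(f"transitions.{key}: unknown transition")
        kwargs[mapping[key]] = val
    try:
        transitions = TransitionSpec(**kwargs)
    except ValidationError as exc:
        raise ConfigError(f"transitions: {exc}") from exc

    econ = []
    for state_name, fields in dict(_require(doc, "states", "top level")).items():
        try:
            state = HealthState[state_name]
        except KeyError:
            raise ConfigError(f"states.{state_name}: unknown health state") from None
        try:
            econ.append(StateEconomics(state=state, cost_cv=uncertainty.cost_cv,
                                       **dict(fields)))
        except (TypeError, ValidationError) as exc:
            raise ConfigError(f"states.{state_name}: {exc}") from exc

    interventions = []
    for i, row in enumerate(_require(doc, "interventions", "top level")):
        path = f"interventions[{i}]"
        row = dict(row)
        target = row.pop("target_state", None)
        if target is None:
            raise ConfigError(f"{path}.target_state: missing required key")
        try:
            row["target_state"] = HealthState[target]
        except KeyError:
            raise ConfigError(f"{path}.target_state: unknown health state {target!r}") from None
        try:
            interventions.append(InterventionProfile(**row))
        except (TypeError, ValidationError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    return ModelParameters(
        transitions=transitions,
        state_economics=tuple(econ),
        interventions=tuple(interventions),
        settings=settings,
        uncertainty=uncertainty,
    )


def _params_to_dict(params: ModelParameters) -> dict:
    doc: dict = {}
    doc["settings"] = dataclasses.asdict(params.settings)
    t = params.transitions
    doc["transitions"] = {
        "pf_to_sthpd": t.p_pf_to_sthpd,
        "sthpd_to_pf": t.p_sthpd_to_pf,
        "sthpd_to_pd": t.p_sthpd_to_pd,
        "pd_to_sthpd": t.p_pd_to_sthpd,
        "death": t.p_death,
    }
    doc["states"] = {}
    for econ in params.state_economics:
        if econ.state is HealthState.DEAD:
            continue
        row = dataclasses.asdict(econ)
        row.pop("state")
        row.pop("cost_cv")
        doc["states"][econ.state.name] = row
    doc["interventions"] = []
    for iv in params.interventions:
        row = dataclasses.asdict(iv)
        row["target_state"] = iv.target_state.name
        if row["transition_rr"] is None:
            row.pop("transition_rr")
        doc["interventions"].append(row)
    doc["uncertainty"] = dataclasses.asdict(params.uncertainty)
    return doc


def load_config(path) -> ModelParameters:
    """Read a YAML configuration file into a validated :class:`ModelParameters`.

    YAML syntax errors carry the parser's line/column mark; semantic errors
    name the offending key path.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    return _params_from_dict(doc)


def save_config(params: ModelParameters, path) -> None:
    """Write a configuration file that :func:`load_config` reads back into
    identical parameter values."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """The packaged default inputs (the published base case)."""
    ref = resources.files("sthpd_cea").joinpath("data/default_config.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _params_from_dict(doc)
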