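"""Model/Results front end.

:class:`CostEffectivenessModel` bundles the parameter set with a
(comparator, alternative) scenario pair and a cohort; ``fit`` evaluates it —
deterministically or by probabilistic sensitivity analysis — and returns a
:class:`CostEffectivenessResults` carrying the per-arm estimates, their
uncertainty, incremental statistics, the acceptability curve and a
``summary()`` table.  Microsimulation and the one-way sensitivity analyses
hang off the model object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import economics, microsim, uncertainty
from .economics import IncrementalResult, ScenarioResult
from .parameters import (
    ModelParameters,
    ScenarioSpec,
    default_parameters,
    early_intervention_scenario,
    load_config,
    usual_care_scenario,
)

__all__ = ["CostEffectivenessModel", "CostEffectivenessResults"]


class CostEffectivenessModel:
    """Cost-effectiveness comparison of two care strategies for a cohort of
    panic-disorder / subthreshold-panic-disorder patients.

    Parameters
    ----------
    params
        Full model inputs; defaults to the packaged base case.
    comparator, alternative
        Scenario specifications; default to usual care and usual care plus
        the CBT-based early intervention at 10% uptake.
    cohort
        ``"mixed"`` (STHPD and PD by prevalence) or ``"sthpd_only"``.

    Examples
    --------
    >>> model = CostEffectivenessModel()
    >>> res = model.fit(iterations=1000, seed=7)
    >>> print(res.summary())           # doctest: +SKIP
    """

    def __init__(
        self,
        params: ModelParameters | None = None,
        comparator: ScenarioSpec | None = None,
        alternative: ScenarioSpec | None = None,
        cohort: str = "mixed",
    ) -> None:
        self.params = params if params is not None else default_parameters()
        self.comparator = (
            comparator if comparator is not None else usual_care_scenario(self.params)
        )
        self.alternative = (
            alternative
            if alternative is not None
            else early_intervention_scenario(self.params)
        )
        self.cohort = cohort

    @classmethod
    def from_config(cls, path, cohort: str = "mixed") -> "CostEffectivenessModel":
        """Build the model from a YAML configuration file."""
        return cls(params=load_config(path), cohort=cohort)

    @property
    def scenarios(self) -> tuple[ScenarioSpec, ScenarioSpec]:
        return (self.comparator, self.alternative)

    def fit(
        self,
        method: str = "psa",
        iterations: int | None = None,
        seed: int | None = None,
        wtp_grid: np.ndarray | None = None,
    ) -> "CostEffectivenessResults":
        """Evaluate the comparison.

        ``method="psa"`` runs the probabilistic sensitivity analysis
        (default 10,000 iterations); ``method="deterministic"`` evaluates
        the point estimates only.
        """
        det_base = economics.evaluate_scenario(self.params, self.comparator, self.cohort)
        det_alt = economics.evaluate_scenario(self.params, self.alternative, self.cohort)
        psa = None
        if method == "psa":
            psa = uncertainty.run_psa(
                self.params,
                self.scenarios,
                cohort=self.cohort,
                iterations=iterations,
                seed=seed,
                wtp_grid=wtp_grid,
            )
        elif method != "deterministic":
            raise ValueError(f"unknown fit method {method!r}")
        return CostEffectivenessResults(self, det_base, det_alt, psa)

    def simulate(
        self,
        n: int = 10_000,
        seed: int = 0,
        scenario: str = "alternative",
    ) -> microsim.MicrosimResult:
        """Individual-level microsimulation of one arm (the Monte-Carlo
        oracle for the cohort engine)."""
        scen = self.alternative if scenario == "alternative" else self.comparator
        return microsim.simulate_population(
            self.params, scen, cohort=self.cohort, n=n, seed=seed
        )

    def sensitivity(
        self,
        dsa_list=None,
        iterations: int | None = None,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """The one-way sensitivity table (reference case + shipped
        scenarios), one PSA per row."""
        return uncertainty.run_dsa(
            self.params,
            self.scenarios,
            dsa_list=dsa_list,
            cohort=self.cohort,
            iterations=iterations,
            seed=seed,
        )


class CostEffectivenessResults:
    """Fitted comparison: deterministic point estimates, PSA distributions
    (when fitted probabilistically), incremental statistics and plots."""

    def __init__(
        self,
        model: CostEffectivenessModel,
        det_comparator: ScenarioResult,
        det_alternative: ScenarioResult,
        psa: uncertainty.PsaResult | None,
    ) -> None:
        self.model = model
        self.deterministic_comparator = det_comparator
        self.deterministic_alternative = det_alternative
        self.psa = psa

    # -- point/summary statistics ------------------------------------------

    @property
    def incremental(self) -> IncrementalResult:
        """Deterministic incremental result (alternative − comparator)."""
        return economics.incremental(
            self.deterministic_comparator, self.deterministic_alternative
        )

    @property
    def icer(self) -> float | None:
        """Headline ICER: PSA ratio of means when fitted probabilistically,
        otherwise the deterministic ratio."""
        if self.psa is not None:
            return self.psa.icer_ratio_of_means
        return self.incremental.icer

    def probability_cost_effective(self, wtp: float | None = None) -> float:
        if self.psa is None:
            raise ValueError("probability requires a PSA fit")
        wtp = wtp if wtp is not None else self.model.params.settings.wtp_threshold
        return self.psa.probability_cost_effective(wtp)

    def ceac(self, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
        if self.psa is None:
            raise ValueError("CEAC requires a PSA fit")
        if wtp_grid is None:
            return self.psa.ceac_frame()
        return pd.DataFrame(
            {"wtp": np.asarray(wtp_grid), "probability_cost_effective": self.psa.ceac(wtp_grid)}
        )

    def scenario_frame(self) -> pd.DataFrame:
        rows = []
        for res in (self.deterministic_comparator, self.deterministic_alternative):
            rows.append(
                {"scenario": res.scenario, "cohort": res.cohort,
                 "qalys": res.qalys, "cost": res.cost, "kind": "deterministic"}
            )
        if self.psa is not None:
            p = self.psa
            for name, q, c in (
                (p.comparator, p.qalys_base, p.costs_base),
                (p.alternative, p.qalys_alt, p.costs_alt),
            ):
                rows.append(
                    {"scenario": name, "cohort": p.cohort,
                     "qalys": q.mean(), "cost": c.mean(), "kind": "psa_mean"}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table of the fitted comparison."""
        s = self.model.params.settings
        inc = self.incremental
        lines = []
        lines.append("Cost-effectiveness comparison")
        lines.append("=" * 64)
        lines.append(
            f"cohort: {self.model.cohort}   horizon: {s.horizon} years   "
            f"discounting: costs {s.discount_rate_costs:.1%} / "
            f"effects {s.discount_rate_effects:.1%}"
        )
        lines.append("-" * 64)
        lines.append(f"{'':28s}{'QALYs':>12s}{'cost (EUR)':>16s}")
        src = "PSA mean" if self.psa is not None else "deterministic"
        if self.psa is not None:
            p = self.psa
            rows = [
                (p.comparator, p.qalys_base.mean(), p.costs_base.mean()),
                (p.alternative, p.qalys_alt.mean(), p.costs_alt.mean()),
            ]
        else:
            rows = [
                (self.deterministic_comparator.scenario,
                 self.deterministic_comparator.qalys,
                 self.deterministic_comparator.cost),
                (self.deterministic_alternative.scenario,
                 self.deterministic_alternative.qalys,
                 self.deterministic_alternative.cost),
            ]
        for name, q, c in rows:
            lines.append(f"{name:<28s}{q:>12.4f}{c:>16,.0f}")
        lines.append("-" * 64)
        if self.psa is not None:
            dq, dc = self.psa.delta_qaly.mean(), self.psa.delta_cost.mean()
            lo, hi = self.psa.icer_percentiles()
            lines.append(f"incremental ({src}): dQALY {dq:+.4f}   dcost {dc:+,.0f} EUR")
            lines.append(
                f"ICER (ratio of means): {self.icer:,.0f} EUR/QALY   "
                f"[per-iteration 2.5/97.5%: {lo:,.0f}, {hi:,.0f}]"
            )
            pce = self.probability_cost_effective()
            lines.append(
                f"P(cost-effective at {s.wtp_threshold:,.0f} EUR/QALY): {pce:.1%}"
            )
            lines.append(f"PSA iterations: {self.psa.n_iterations}   seed: {self.psa.seed}")
        else:
            icer = "undefined" if inc.icer is None else f"{inc.icer:,.0f} EUR/QALY"
            lines.append(
                f"incremental: dQALY {inc.delta_qaly:+.4f}   "
                f"dcost {inc.delta_cost:+,.0f} EUR   ICER {icer}   [{inc.quadrant}]"
            )
        return "\n".join(lines)

    # -- plots -------------------------------------------------------------

    def plot_ce_plane(self, ax=None):
        """Scatter of per-iteration (ΔQALY, Δcost) on the
        cost-effectiveness plane, with the WTP threshold line."""
        if self.psa is None:
            raise ValueError("CE plane requires a PSA fit")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dq, dc = self.psa.delta_qaly, self.psa.delta_cost
        ax.scatter(dq, dc, s=4, alpha=0.25, edgecolors="none")
        ax.axhline(0.0, color="0.4", lw=0.8)
        ax.axvline(0.0, color="0.4", lw=0.8)
        wtp = self.model.params.settings.wtp_threshold
        xs = np.linspace(min(dq.min(), 0), max(dq.max(), 0), 50)
        ax.plot(xs, wtp * xs, "--", color="0.2", lw=0.8,
                label=f"WTP {wtp:,.0f} EUR/QALY")
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost (EUR)")
        ax.legend(frameon=False)
        return ax

    def plot_ceac(self, ax=None):
        """Cost-effectiveness acceptability curve."""
        if self.psa is None:
            raise ValueError("CEAC requires a PSA fit")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.psa.ceac_frame()
        ax.plot(frame["wtp"], frame["probability_cost_effective"])
        ax.axvline(self.model.params.settings.wtp_threshold, ls="--", color="0.4", lw=0.8)
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("willingness to pay (EUR/QALY)")
        ax.set_ylabel("P(cost-effective)")
        return ax
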