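"""Probabilistic and one-way sensitivity analysis."""

import dataclasses

import numpy as np
import pytest

from sthpd_cea import (
    HealthState,
    ValidationError,
    default_parameters,
    evaluate_scenario,
    run_dsa,
    run_psa,
    sample_parameters,
)
from sthpd_cea.uncertainty import (
    DistributionSpec,
    DsaScenario,
    apply_dsa,
    gamma_shape_scale,
    one_way_scenarios,
)


def _zero_spread(params):
    econ = tuple(
        dataclasses.replace(e, utility_se=0.0, cost_cv=0.0)
        for e in params.state_economics
    )
    unc = dataclasses.replace(params.uncertainty, cost_cv=0.0, utility_gain_se_frac=0.0)
    return params.replace(state_economics=econ, uncertainty=unc)


class TestSampling:
    def test_gamma_parameterisation_identity(self):
        shape, scale = gamma_shape_scale(18_295.0, 0.25)
        assert shape == pytest.approx(16.0)
        assert scale == pytest.approx(1_143.4375)
        # mean-preserving by construction
        assert shape * scale == pytest.approx(18_295.0)

    def test_zero_spread_draw_equals_deterministic(self, params):
        rng = np.random.default_rng(5)
        draw = sample_parameters(_zero_spread(params), rng)
        assert draw == _zero_spread(params)

    def test_normal_utility_sample_mean(self, params):
        """PF utility draws average to the specified mean within 3 SEM."""
        rng = np.random.default_rng(11)
        n = 10_000
        draws = np.array([
            sample_parameters(params, rng).economics_for(HealthState.PF).utility
            for _ in range(n)
        ])
        sem = 0.0054 / np.sqrt(n)
        assert abs(draws.mean() - 0.869) < 3 * sem

    def test_gamma_sampling_mean_preserving(self):
        rng = np.random.default_rng(3)
        mean, cv, n = 16_771.0, 0.25, 100_000
        shape, scale = gamma_shape_scale(mean, cv)
        draws = rng.gamma(shape, scale, size=n)
        sem = mean * cv / np.sqrt(n)
        assert abs(draws.mean() - mean) < 3 * sem

    def test_truncation_respects_bounds(self):
        rng = np.random.default_rng(9)
        spec = DistributionSpec("normal", 0.02, 0.05, (0.0, None))
        draws = np.array([spec.sample(rng) for _ in range(2_000)])
        assert (draws >= 0.0).all()

    def test_invalid_spread_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("gamma", -5.0, 0.2)
        with pytest.raises(ValidationError):
            DistributionSpec("normal", 0.5, -0.1)


class TestRunPsa:
    def test_same_seed_bit_identical(self, params, usual_care, early_intervention):
        kwargs = dict(cohort="mixed", iterations=200, seed=77)
        a = run_psa(params, (usual_care, early_intervention), **kwargs)
        b = run_psa(params, (usual_care, early_intervention), **kwargs)
        assert np.array_equal(a.qalys_base, b.qalys_base)
        assert np.array_equal(a.costs_alt, b.costs_alt)
        assert np.array_equal(a.ceac(), b.ceac())

    def test_zero_spread_psa_equals_deterministic(self, params, usual_care,
                                                  early_intervention):
        zp = _zero_spread(params)
        psa = run_psa(zp, (usual_care, early_intervention), iterations=20, seed=1)
        det_base = evaluate_scenario(zp, usual_care, "mixed")
        det_alt = evaluate_scenario(zp, early_intervention, "mixed")
        assert (psa.qalys_base == det_base.qalys).all()
        assert (psa.costs_base == det_base.cost).all()
        assert (psa.qalys_alt == det_alt.qalys).all()
        assert (psa.costs_alt == det_alt.cost).all()

    def test_iteration_table_shape_and_intervals(self, params, usual_care,
                                                 early_intervention):
        psa = run_psa(params, (usual_care, early_intervention),
                      iterations=300, seed=4)
        frame = psa.iteration_frame()
        assert len(frame) == 300
        summary = psa.summary_frame().set_index("quantity")
        for qty in ("qalys_usual_care", "cost_usual_care", "delta_qaly"):
            row = summary.loc[qty]
            assert row["p2.5"] <= row["mean"] <= row["p97.5"]

    def test_ceac_stable_across_seeds(self, params, usual_care, early_intervention):
        """Monte-Carlo noise on the acceptability probability at the
        threshold is small at full iteration counts."""
        probs = [
            run_psa(params, (usual_care, early_intervention),
                    iterations=10_000, seed=s).probability_cost_effective(20_000.0)
            for s in (101, 202)
        ]
        assert abs(probs[0] - probs[1]) < 0.01

    def test_invalid_iteration_count(self, params, usual_care, early_intervention):
        with pytest.raises(ValidationError):
            run_psa(params, (usual_care, early_intervention), iterations=0, seed=1)


class TestDsa:
    def test_shipped_scenarios_match_published_labels(self):
        names = [d.name for d in one_way_scenarios()]
        assert names == [
            "Time horizon 1 year",
            "Time horizon 10 years",
            "Early intervention 5% uptake rate",
            "Early intervention 15% uptake rate",
            "Early intervention transition from STHPD to PD 10% lower",
            "Early intervention transition from STHPD to PD 10% higher",
            "Uptake rate PD interventions 100%",
            "Uncorrected utility values",
        ]

    def test_no_override_reproduces_reference(self, params, usual_care,
                                              early_intervention):
        table = run_dsa(
            params, (usual_care, early_intervention),
            dsa_list=(DsaScenario("noop"),), iterations=150, seed=10,
        )
        ref = table.loc[table["scenario"] == "Reference case"].iloc[0]
        noop = table.loc[table["scenario"] == "noop"].iloc[0]
        assert noop["icer"] == ref["icer"]
        assert noop["mean_delta_cost"] == ref["mean_delta_cost"]

    def test_transition_multipliers_bracket_reference(self, params, usual_care,
                                                      early_intervention):
        from sthpd_cea.markov import blended_sthpd_pd_probability

        lower = apply_dsa(params, usual_care, early_intervention,
                          DsaScenario("lo", treated_transition_multiplier=0.9))
        higher = apply_dsa(params, usual_care, early_intervention,
                           DsaScenario("hi", treated_transition_multiplier=1.1))
        p_lo = blended_sthpd_pd_probability(params.transitions, lower[2])
        p_ref = blended_sthpd_pd_probability(params.transitions, early_intervention)
        p_hi = blended_sthpd_pd_probability(params.transitions, higher[2])
        assert p_lo < p_ref < p_hi

    def test_pd_uptake_rescaling_preserves_mix(self, params, usual_care,
                                               early_intervention):
        _, base, _ = apply_dsa(params, usual_care, early_intervention,
                               DsaScenario("full", pd_uptake_total=1.0))
        pd_ivs = base.interventions_for(HealthState.PD)
        total = sum(iv.uptake for iv in pd_ivs)
        assert total == pytest.approx(1.0)
        # proportions preserved relative to the 29.4% base mix
        ref = {iv.name: iv.uptake for iv in usual_care.interventions_for(HealthState.PD)}
        for iv in pd_ivs:
            assert iv.uptake == pytest.approx(ref[iv.name] / 0.294)

    def test_uncorrected_utilities_override(self, params, usual_care,
                                            early_intervention):
        p, _, _ = apply_dsa(params, usual_care, early_intervention,
                            DsaScenario("uncorr", uncorrected_utilities=True))
        assert p.economics_for(HealthState.STHPD).utility == pytest.approx(0.730 / 0.869)
        assert not p.settings.utilities_corrected

    def test_horizon_override_changes_settings(self, params, usual_care,
                                               early_intervention):
        p, _, _ = apply_dsa(params, usual_care, early_intervention,
                            DsaScenario("h10", horizon=10))
        assert p.settings.horizon == 10
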