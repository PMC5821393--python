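# Default model inputs: Dutch care for panic disorder (PD) and subthreshold
# panic disorder (STHPD), societal perspective, EUR at the 2014 price level.
settings:
  horizon: 5
  cycle_length: 1.0
  discount_rate_costs: 0.04
  discount_rate_effects: 0.015
  wtp_threshold: 20000.0
  prevalence_sthpd: 0.019
  prevalence_pd: 0.022
  utilities_corrected: true
  psa_iterations: 10000
  rng_seed: 2014
  reward_timing: end

# Annual transition probabilities; held fixed in the PSA.
transitions:
  pf_to_sthpd: 0.0016
  sthpd_to_pf: 0.0815
  sthpd_to_pd: 0.6037
  pd_to_sthpd: 0.5214
  death: 0.0028

# Per-state utilities (EQ-5D based, corrected by the general-population
# utility) and annual societal cost categories.
states:
  PF:
    utility: 0.869
    utility_se: 0.0054
    cost_direct_medical: 340.0
    cost_direct_nonmedical: 99.0
    cost_indirect_nonmedical: 6643.0
  STHPD:
    utility: 0.730
    utility_se: 0.037
    cost_direct_medical: 1503.0
    cost_direct_nonmedical: 494.0
    cost_indirect_nonmedical: 9741.0
  PD:
    utility: 0.660
    utility_se: 0.030
    cost_direct_medical: 666.0
    cost_direct_nonmedical: 858.0
    cost_indirect_nonmedical: 16771.0

# Intervention profiles. Uptake values are the alternative-scenario rates;
# usual care differs only in setting the early-intervention uptake to zero.
interventions:
  - name: cbt
    target_state: PD
    uptake: 0.088
    base_adherence: 0.70
    dropout: 0.0
    annual_cost: 1176.0
    utility_gain: 0.0327
  - name: ssri
    target_state: PD
    uptake: 0.092
    base_adherence: 0.70
    dropout: 0.18
    annual_cost: 1128.0
    utility_gain: 0.0450
  - name: tca
    target_state: PD
    uptake: 0.024
    base_adherence: 0.70
    dropout: 0.30
    annual_cost: 1200.0
    utility_gain: 0.0445
  - name: combination
    target_state: PD
    uptake: 0.090
    base_adherence: 0.70
    dropout: 0.0
    annual_cost: 2315.0
    utility_gain: 0.0568
  - name: early_intervention
    target_state: STHPD
    uptake: 0.10
    base_adherence: 0.70
    dropout: 0.0
    annual_cost: 905.0
    utility_gain: 0.0655
    transition_rr: 0.538

# PSA spread assumptions for parameters whose sampling spread is not pinned
# down by the utility standard errors: gamma coefficient of variation for all
# cost parameters, and the utility-gain SE as a fraction of the mean.
uncertainty:
  cost_cv: 0.25
  utility_gain_se_frac: 0.20
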