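# Methods

## Model structure

The cohort model tracks the fraction of a patient cohort in four mutually
exclusive states — panic-free (`PF`), subthreshold panic disorder
(`STHPD`), panic disorder (`PD`) and `DEAD` — over annual cycles
(default horizon 5 years). STHPD is the obligatory intermediate: PF→PD and
PD→PF entries of every transition matrix are structurally zero, at most one
switch happens per cycle, and death (a flat annual probability of 0.0028,
an 18–65 population average) applies identically from every alive state
with no excess mortality for STHPD/PD. The transition probabilities
(PF→STHPD 0.0016, STHPD→PF 0.0815, STHPD→PD 0.6037, PD→STHPD 0.5214) are
consumed as given, annual, usual-care quantities; each stay probability is
one minus the exit mass.

Two strategies are compared. *Usual care* offers four PD interventions at
their observed uptakes (CBT 8.8%, SSRI 9.2%, TCA 2.4%, combination therapy
9.0%). The *alternative* adds a CBT-based group early intervention offered
to 10% of STHPD occupants. All interventions carry a 70% adherence
assumption, degraded for pharmacotherapy by dropout (SSRI 18% → effective
adherence 57.4%; TCA 30% → 49%); adherence enters unrounded. Adherent
recipients of the early intervention progress from STHPD to PD with the
treated probability `p·RR` (RR = 0.538); in the cohort model this appears
as the uptake-and-adherence-weighted blend
`p(1 − u·a·(1 − RR))`, with the removed probability mass added to the
STHPD *stay* probability — the intervention is modelled as preventing
progression, not inducing remission, so no mass is routed to STHPD→PF.

## Rewards, costing and discounting

Each alive state carries an EQ-5D utility (PF 0.869, STHPD 0.730,
PD 0.660 — the latter two already multiplied by the general-population
utility so that transitions to PF represent the expected gains) and three
annual societal cost categories (direct medical, direct non-medical,
indirect non-medical), summed into a societal state cost (PF €7,082,
STHPD €11,738, PD €18,295; EUR, 2014 price level, no internal indexation).
Interventions add, per cycle and per occupant of their target state,
`uptake × effective_adherence × utility_gain` to utility and
`uptake × annual_cost` to cost: non-adherent recipients incur full costs
but realise no gain. Intervention costs recur every cycle for the uptake
fraction of state occupants, matching their definition as annual
quantities (e.g. a year of defined daily doses); uptake and adherence act
as memoryless cohort-level blending weights, as a Markov cohort model
requires.

Reward timing was genuinely open; the package attributes rewards at cycle
**end** (state membership after each annual transition, discount exponents
t = 1..horizon, costs at 4%/yr and effects at 1.5%/yr) with no half-cycle
correction. This is the conventional choice for annual-cycle models
without a stated correction and the only one that yields a defined 1-year
result; `ModelSettings.reward_timing = "start"` switches to
start-of-cycle attribution so the sensitivity of results to the choice is
testable.

## Uncertainty analysis

The PSA (default 10,000 iterations) draws one joint parameter set per
iteration and evaluates both arms on it (common random numbers), holding
transition probabilities and discount rates fixed:

- **Utilities** — normal with the published standard errors (PF 0.0054,
  STHPD 0.037, PD 0.030), truncated to [0, 1] by resampling.
- **Utility gains** — normal, truncated at 0. Their spreads are not
  published; the default SE is 0.20 × mean (`uncertainty.utility_gain_se_frac`),
  a deliberately conservative assumption exposed in the configuration.
- **Costs** — each of the nine state-cost categories and five intervention
  costs is an independent gamma variable, mean-preserving
  (shape = 1/CV², scale = mean·CV²). Cost spreads are likewise not
  published; the default CV of 0.25 (`uncertainty.cost_cv`) reproduces the
  roughly ±25% span of the published cost credible intervals and is a
  configuration knob.

Because transitions are fixed, each arm's occupancy trajectory is
projected once per PSA and only the (linear) reward layer is re-evaluated
per draw. The headline ICER is the **ratio of means** (mean Δcost over
mean ΔQALY); the 2.5th/97.5th percentiles of per-iteration ICERs are
reported alongside, and are wide and sign-crossing because per-iteration
ratios are unstable when ΔQALY is near zero (the mean of ratios is also
available). The CEAC is the fraction of iterations with positive net
monetary benefit over a WTP grid of €0–80,000 in €1,000 steps, bracketing
the Dutch €20,000/QALY threshold for this disability-weight class.

Eight one-way scenarios rerun the PSA under single assumption changes:
horizons of 1 and 10 years; early-intervention uptake 5% and 15%; the
treated (post-RR) STHPD→PD probability ±10% (multipliers 0.9/1.1); all PD
interventions scaled proportionally from their 29.4% total uptake to 100%
(preserving the CBT/SSRI/TCA/combination mix — setting each literally to
100% would exceed the cohort); and uncorrected utilities (STHPD and PD
divided by the PF utility of 0.869, with SEs scaled accordingly). All
rows share one seed, so scenario contrasts are on common random numbers.

## Microsimulation oracle

`simulate_population` generates individual annual trajectories under the
same stochastic assumptions the cohort model integrates over: each person
starts in a state drawn from the initial occupancy; each cycle, treatment
is assigned by uptake and adherence by effective adherence
(**redrawn every cycle** — no persistence, mirroring the cohort model's
memoryless blending, so the two estimands coincide by construction and
their equality is asserted, not assumed); an assigned-and-adherent STHPD
occupant progresses with `p·RR`; rewards are ledgered per person per cycle
(full intervention cost whenever assigned, gain only when adherent) and
discounted exactly as in the cohort engine. Within a cycle the
transition-modifying treatment draw is made against the start-of-cycle
state and the reward-layer draw against the state rewards are attributed
to, matching how the cohort model blends uptake into the matrix and the
reward layer independently. All randomness comes from one seeded
generator consumed in a fixed cycle-major vectorised layout, so results
are independent of person iteration order and two scenarios identical in
law are bit-identical under a common seed.

The oracle is the package's primary correctness check: at n = 200,000 the
microsimulation means of discounted QALYs and costs agree with the cohort
model within 3 Monte-Carlo standard errors for both arms and both cohort
compositions, and empirical state frequencies converge to the cohort
occupancy trajectory.

The generator emulates the model's assumed world, not real registry data:
it inherits the flat mortality, the memoryless treatment assignment, the
absence of individual heterogeneity in utilities/costs, and the fixed
annual transition probabilities. Passing oracle tests therefore
demonstrates internal consistency of the two engines, not external
validity of the epidemiological inputs.

## Cohorts and outputs

The default cohort mixes STHPD and PD patients in proportion to their
annual prevalences (1.9% / 2.2%, i.e. 46.3% / 53.7% of the patient
cohort); an STHPD-only cohort starts all mass in STHPD. Scenario
evaluation is linear in the initial occupancy vector (verified to 1e-9),
so sub-cohort results decompose exactly.

Problem sizes used throughout the shipped analyses: 10,000 PSA iterations
per run (the published iteration count) and 200,000 simulated persons for
oracle comparisons — both chosen so every analysis reruns from scratch in
seconds on a single core.

## Numerical choices and degenerate inputs

- Row sums of every transition matrix are validated to 1e-12; occupancy
  conservation and non-decreasing DEAD mass are asserted at every cycle.
- Zero spreads (SE or CV of 0) degenerate every sampling distribution to
  its mean, making a zero-spread PSA exactly equal to the deterministic
  evaluation.
- The ICER is reported as undefined when ΔQALY is exactly 0; the
  cost-effectiveness-plane quadrant is then classified by the cost sign.
- The CEAC counts strictly positive net monetary benefit, so a literal
  zero-NMB tie counts as not cost-effective.
- Configuration files are validated eagerly; semantic errors name the
  offending key path, YAML syntax errors carry the parser's line mark.

## Known limitations

- The printed transition probabilities are taken as given; the very high
  annual STHPD→PD probability (0.6037) drives an STHPD-only cohort to a
  PD-dominated mix within one cycle, so STHPD-only and mixed-cohort
  results differ less here than the published sub-cohort figures suggest.
  Relatedly, annual early-intervention costing makes the added
  intervention only mildly cost-saving; published incremental costs are
  more strongly negative than this model produces, and the published
  horizon orderings of the ICER are not all reproduced, although sign,
  dominance direction and the acceptability probability are.
- No comorbidity, no age/sex stratification, no excess mortality, no
  intervention-specific transitions for the PD treatments (their benefit
  enters through utility gains only), and no value-of-information
  analysis.
- Cost and utility-gain PSA spreads are assumptions (see above), exposed
  as configuration knobs rather than hidden constants.
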