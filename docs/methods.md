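# Methods

## Model structure

The model is a deterministic discrete-time Markov cohort simulation with a
one-month cycle. States: end-stage knee osteoarthritis awaiting surgery
(with or without a non-operative bridge), a one-month post-procedure state
after each arthroplasty, well-with-primary-implant, well-with-first-revision,
well-with-second-revision, and death. The cohort starts at age 60 and is run
until extinction (living mass < 1e-12) or age 110, whichever comes first —
612 monthly cycles at most; the bundled life table forces q=1 at its final
age, so extinction is guaranteed.

Transitions each cycle: background mortality is applied first from the life
table at the cohort's current integer age (floor, no interpolation — the
effect of interpolating is below reporting precision); implant failure then
competes among survivors, combined multiplicatively
(`1-(1-p1)(1-p2)`). Annual probabilities become monthly via the
constant-hazard formula `1-(1-p)^(1/12)`; the discount factor per cycle is
`(1+r)^(-1/12)` so twelve cycles equal one annual discount step.

Implant-age bookkeeping: failure hazards are tiered by implant age
([0,10) / [10,20) / [20,∞) years, zero before month 12). The primary
implant needs no extra states — every patient receives it in the same
(deterministic) month, so its age is the global clock minus the surgery
month. First-revision implants arrive spread over time and therefore carry
explicit monthly tunnel states up to month 240, after which the hazard is
constant (top tier) and a single state suffices. Second revisions cannot
fail again (two-revision cap), so they need no clock.

## Rewards and accounting

Per-cycle rewards are annual utilities and costs divided by 12, accrued on
start-of-cycle occupancy for the full cycle. One-time rewards (surgery
episode costs, revision recovery disutility, expected early-complication
disutility) attach to transition flows and are discounted at the cycle the
flow lands in; the immediate arm's primary surgery is charged undiscounted
at entry. There is no half-cycle correction by default — with monthly cycles
the correction is below 0.5% of totals — but `half_cycle_correction: true`
switches per-cycle accrual to the average of start- and end-of-cycle
occupancy for sensitivity.

Early complications (annual probability 0.01, one-time disutility −0.20) do
not change state: the surgery episode cost already covers 90 days of care
including complication treatment, so they enter as an expected one-time
QALY deduction (`p × d = −0.002`) at primary surgery. The toggle
`include_complications` removes them; base-case conclusions are unchanged
either way. Excess 30-day surgical mortality (0.007 primary, 0.01 revision)
is applied wholly within the one-month post-procedure state, combined with
background mortality.

Waiting accrues the OA utility (0.6/year), or the bridge utility during the
relieved part of the wait. The explicit bridge utility (0.7) is the default;
sweeping the gap-closure fraction (33% of the OA→TKA gap ⇒ 0.699) replaces
it, and `bridge_relief_months` restricts the improvement to the first months
of the wait while the bridge continues to be paid for — used for the
relief-duration threshold. Waiting itself confers no excess mortality
(conservative toward the delay strategies).

Cost scenarios: **A** counts direct medical costs only (bridge \$2,500/yr;
primary \$26,865 and revision \$35,542 episodes). **B** adds indirect OA
costs (\$10,369/yr) during the wait and leaves the unrecovered residual
(20% of \$10,369) from the surgery month onward, in every post-surgical
state.

## Life-table calibration

No specific national life table is bundled as published data. Instead the
fixture `life_table_us2009_synthetic.csv` is generated by the package's own
Gompertz generator (`q(age) = 1 - exp(-a·e^{b·age})`, a = 4.2e-5, b = 0.09,
q(110) = 1), calibrated once so its all-sex demographics match a US-2009-era
table: life expectancy 22.5 years at age 60 and 79.4 at birth, q(60) ≈ 0.0093,
q(80) ≈ 0.055. The generator covers only adult-shaped mortality (no infant
hump, no Makeham accident term); since the cohort enters at 60, only the
60+ segment matters for results.

This calibration is the main reason absolute levels here can differ from
other published analyses of the same question: at 3%/year, a cohort with
e(60) ≈ 22.5 accrues ≈ 15.6 discounted life-years, so the immediate arm's
discounted QALY total is ≈ 13.9. Published figures near 12.2 imply ≈ 13.5
discounted life-years — a materially shorter-lived cohort (e(60) ≈ 17) than
any recent US table supports. We keep the demographically realistic table;
incremental comparisons, orderings, thresholds and curve shapes — the
decision-relevant outputs — are robust to this choice, and the acceptance
tests on absolute levels document the discrepancy rather than hide it.

## Analysis conventions

* **Frontier/CEA.** Strategies are sorted by effectiveness; strong dominance
  (costlier, no more effective) is removed, extended dominance (incremental
  ratio above the next segment's) flagged; the preferred strategy is the most
  effective frontier member whose ICER does not exceed willingness-to-pay
  (\$50,000/QALY default; a tie at exactly the threshold resolves to the more
  effective strategy). The preferred strategy provably maximises net monetary
  benefit, which the tests check by brute force.
* **Thresholds.** Switch points are found by bracketing bisection
  (`scipy.optimize.brentq`) on a continuous cost or ICER margin, re-running
  the full model per probe; tolerance \$0.01 for dollar parameters, 0.001 for
  fractions. The relief-duration threshold is an integer (whole months)
  search. A bracket without a sign change raises an error rather than
  guessing.
* **Sweeps** (1–3-way) re-run the model at every grid point; they are pure
  and bitwise repeatable. Wait times snap to whole cycles ("3 weeks" maps to
  1 month). Tier probabilities may be swept into non-monotone combinations
  (the sensitivity ranges demand it); the parameter validator warns instead
  of refusing.
* **Projection.** Population totals are per-patient increments times
  user-supplied annual procedure volumes, undiscounted across calendar years
  (each year's cohort valued at its own start). The bundled
  `tka_volumes_synthetic.csv` is an illustrative, clearly-synthetic growth
  path (0.65M in 2012 to 3.48M in 2030); headline dollar totals are entirely
  conditional on the volume table supplied.

## Synthetic data and what tests show

The Gompertz generator, the uniform sampler over sensitivity ranges, and the
`toy_fixture` (constant 12%/yr mortality, no discounting, no revisions, zero
costs) exist so every stage is testable without external data. The toy
fixture has closed-form geometric-series totals that the engine must match
to 1e-9; random-matrix models check mass conservation and death
monotonicity. None of this emulates real-world heterogeneity — comorbidity,
sex-specific mortality, surgeon- or implant-level variation in revision
risk, utility distributions — so green tests certify the accounting and the
decision logic, not those aspects of external validity.

## Known limitations

Perioperative complications are not explicit states; the bridge cannot avert
surgery; contralateral disease, bilateral procedures and infection-specific
revision pathways are out of scope. Probabilistic sensitivity analysis is
not implemented (the sampler supports drawing parameter sets, but no CEAC
machinery). Costs are modelled as stationary; no calendar-year inflation or
cross-cohort discounting is applied in projections.
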