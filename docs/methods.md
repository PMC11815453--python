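# Methods

This note documents the model, its assumptions, the defaults, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Micro-costing

Activity ledgers record either staff time (role + minutes) or a direct
expense, each tagged with a fiscal price year. Staff time is priced at
`minutes/60 × hourly rate` from a unit-cost table whose rates carry their
own source price year. Everything is re-expressed at a target price year
(default 2019/20) by the ratio of a chain-linked index: the HCHS pay &
prices index up to fiscal year 2014/15, grown thereafter by the NHSCII pay &
prices index rebased at the handover year. Chain-linking is a ratio product
— `index(to)/index(from)` on the spliced series — because two named indices
with a handover year admit no other continuous interpretation; the
inflation round-trip is exact by construction.

One-off toolkit outlays are converted to an equivalent annual cost with an
annuity-due factor (5 years, 3.5%, payment in advance):
`A = (1 − (1+r)^−n)/r × (1+r)`, degenerating to `n` at `r = 0`. The
annuitization happens **before** aggregation, so the toolkit row of the
summary table is the annual equivalent for the delivery period.

Summary exports round GBP to whole pounds and shares to whole percent,
half-up; pence are kept internally. Cell percentages are shares of the
category row; total rows/columns are shares of the grand total. Per-patient
cost scales a group's cost by `reference_days / followup_days` (reference
204 days — the longer delivery window — configurable) before dividing by
the patient count. The bundled fixture ledger is constructed at pence level
so the rounded table is internally consistent even where naive re-addition
of rounded rows would differ by £1; the patient counts attached to it are
synthetic (the originating trial's counts are not public), so per-patient
figures computed from the fixture are demonstrations of the formula, not
estimates.

## Effect profiles and waning

The intervention acts through additive per-cycle offsets on the five
biomarkers and a log odds ratio on SSME attendance. The base case encodes:
year-1 offsets for all biomarkers; a year-2 HbA1c offset with BMI/HDL/LDL
(and, by default, SBP — the evidence is silent on SBP, so a
`carry_sbp_forward` flag exists) carried from year 1; the year-2 level held
through year 3; full waning by the end of year 4. With annual cycles a
waning year is sampled at its midpoint, so the cycle-4 offset is half the
plateau value. Default base-case magnitudes: HbA1c −0.01 percentage points
at year 1 and −0.05 at year 2, attendance odds ratios 0.82 then 1.15
(log-transformed), other biomarkers zero.

Offsets are applied **after** the natural progression step each cycle, so
they propagate forward through the autoregressive dynamics rather than
being overwritten.

Scenario families:

- **S1** zeroes every biomarker except HbA1c (non-significant secondary
  outcomes treated as no change).
- **S2** uses 12-month read-outs only: year-2 values collapse onto year 1
  for biomarkers and attendance.
- **S3/S4/S6** replace trial biomarker effects with a literature-based SSME
  effect among attenders (default −0.30 pp HbA1c, configurable), delivered
  to the *extra* attenders the intervention creates: each cycle's change in
  attendance probability (inverse-logit of baseline log-odds plus the
  cycle's log-OR) launches the literature effect, which follows its own
  plateau/wane curve (full 6 years, zero at 10 for S3/S4; 10→15 for S6a;
  lifetime for S6b); overlapping attendance cohorts are summed by discrete
  convolution. Because the year-1 attendance OR is below 1, the year-1
  contribution is adverse — a faithful consequence of the inputs.
  A `referrals` switch with a multiplier covers the reading in which the
  literature effect attaches to referrals rather than attendances.
- **S5a/S5b** hold the year-2 plateau for 5/10 years with a hard stop.
- **S7a–g** swap the year-1 HbA1c estimate's source; **S8a–c** do the same
  and restrict the simulated population (white / minority ethnicity, or
  baseline HbA1c ≥ 47.5 mmol/mol via the IFCC conversion
  `mmol/mol = 10.929 × (% − 2.15)`).

The alternative point estimates for S2/S7/S8 and the literature effect are
configuration inputs; the bundled `default_scenarios()` values are
synthetic placeholders of plausible sign and magnitude, flagged as such in
the docstring, so the full grid runs end to end.

## Risk engine

Equations are data. Event and mortality equations take one of four forms;
continuous-time PH hazards are discretised to annual probabilities by the
exact hazard increment over `[t, t+1)` (exact for piecewise-constant
covariates): exponential `1 − e^{−e^{LP}}`; Weibull
`1 − exp(−e^{LP}[(t+1)^ρ − t^ρ])`; Gompertz
`1 − exp(−e^{LP}(e^{φ(t+1)} − e^{φt})/φ)`. The clock is diabetes duration
for complications and age for mortality by convention, configurable per
equation. Progression equations are linear in the current value, baseline
value and demographics plus a normal residual; HbA1c is floored at 4.0%
and BMI at 15 kg/m² (configurable per equation). A coefficient naming a
covariate the person state does not expose raises an error rather than
contributing zero.

Published UKPDS OM2 / UKPDS 90 coefficient tables are not redistributed
here; the engine is validated against closed forms (survival telescoping at
machine precision, Weibull ρ=1 ≡ exponential, Gompertz φ→0 → exponential)
and shipped with documented toy engines. Users supply real coefficient
tables as JSON.

## Microsimulation

Annual cycles from baseline to death or age 100 (configurable). Cycle
order: progression → intervention offsets → non-fatal events (one uniform
per event per cycle, events absorbing, simultaneous events allowed) →
mortality (an event-year equation in cycles with a new complication,
otherwise the no-event equation) → accrual. Costs: annual management cost,
first-year complication cost for new events, subsequent-year cost for
established ones; no half-cycle correction for costs. Utility: baseline
linear in age with a sex offset, plus additive complication decrements
(multiplicative combination available), clamped to `[−0.594, 1]`; a death
credits half a cycle of utility and life-years. Discounting is
`(1+r)^−(cycle−1)` at `r = 0.035`, chosen so the cycle-1 intervention
charge is undiscounted — which is what makes a per-patient intervention
cost and a treatment-cost increment add exactly in the totals.

Randomness: one generator per purpose (each progression equation, each
event, mortality) spawned from the master seed, with full-length vectors
drawn every cycle whether or not a person is still alive. Both arms of a
comparison therefore consume identical streams — common random numbers —
and identical effect profiles give bitwise-identical outcomes; the QALY
increment of a null comparison is exactly zero (the cost increment equals
the intervention charge up to ~1e−12 of floating-point mean arithmetic).

## PSA and decision statistics

Outer-loop draws instantiate the engine, economics and effect inputs via
dotted target addresses; supported families are normal, lognormal, gamma,
beta and joint multivariate-normal blocks (PSD-checked at spec time).
Trial-effect parameters are sampled parametrically (normal on mean
differences and log-ORs). Each draw simulates a fresh cohort per arm with
CRN. The ICER is the ratio of expected increments across draws — never a
mean of per-draw ratios; per-draw pairs are exported only for the
cost-effectiveness plane. CEAC: fraction of draws with `λ·ΔQ − ΔC > 0`;
ties count as not cost-effective (conservative). Monte-Carlo standard
errors are reported rather than a formal stopping rule.

## Value of information

EVPI is computed directly on the draws × decisions NMB matrix. EVPPI uses a
regression surrogate: each decision's NMB is regressed on the parameter
subset with an additive cubic B-spline basis (5 knots per parameter,
pairwise linear interactions when the subset has ≤ 4 members) under a small
ridge penalty — a penalised-spline implementation of the
Sheffield-accelerated-VoI idea, chosen over nearest-neighbour methods for
stability in 2–10 dimensions at desk scale. Standard errors for both EVPI
and EVPPI come from a bootstrap over draws (defaults 1000 and 200
resamples respectively; each EVPPI resample refits with one knot fewer).
One mechanism covers both quantities, which is why the bootstrap was
preferred to an analytic approximation. Raw EVPPI can be slightly negative
by estimation noise; exports clamp at zero and keep the raw value, so a
genuinely worthless group prints 0.00 with a nonzero SE. Group membership
is user-supplied (the bundled mapping derives from the distribution set's
group tags: effectiveness, cost, utility, micro/macrovascular risk,
mortality, progression).

## Synthetic data, and what passing tests do not show

The generators emulate the *structure* of the real inputs: a cohort of
people diagnosed with T2DM within 12 months (realistic but synthetic
moments, documented in `synthdata`), ledgers with the delivery-cost
category × site-group shape, and a PSA spec with every group tag
represented and effectiveness means equal to the base-case effect inputs.
They do not emulate trial randomisation, the wait-list stepped-wedge
timing, COVID-19 disruption, or correlation between biomarkers. The toy
risk engines are two-event miniatures with hand-chosen coefficients — the
"calibration" engine has constant 0.5/year mortality and inert events so
lifetimes are exactly geometric; the "low" engine keeps all annual
probabilities below 5% for the mean person. Green tests therefore
demonstrate that the *machinery* is correct (costing arithmetic,
discretisation, CRN, estimator consistency), not that any real-world
intervention is cost-effective: headline outputs with the synthetic engine
are illustrative magnitudes only.

## Numerical choices and problem sizes

- Half-up rounding everywhere a table is exported; pence/pp retained
  internally.
- Event probabilities are exact transforms of the linear predictor; a
  non-finite LP is an error, not a clamp.
- Closed-form oracle tests run at n = 100 000 persons (geometric and
  Gompertz lifetimes, 3 Monte-Carlo SE), hazard recovery at n = 50 000
  (99% Clopper-Pearson), the conjugate VoI oracle at 10 000 draws, and the
  end-to-end PSA at 200 × 500 — sizes at which each check resolves its
  target comfortably while the whole suite runs in well under a minute of
  simulation time. The full-scale 2000 × 5000 PSA is a parameter choice
  (`n_outer`, `n_inner`), not a different code path.

## Known limitations

- No within-cycle event timing, no recurrent events, no treatment
  escalation algebra (management cost is an annual aggregate), no carer or
  societal costs.
- EVPPI interactions beyond pairwise-linear are not modelled; for strongly
  interacting groups the surrogate may under-fit.
- Population-level EVPI scaling and EVSI are out of scope.
- The utility combination rule (additive vs multiplicative) is a switch
  because the source model's exact rule is not public; defaults follow the
  additive-with-floor convention.
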