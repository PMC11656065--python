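# Methods

`rdncea` projects the lifetime health and cost consequences of catheter-based
radiofrequency renal denervation (RF RDN) versus standard of care in
uncontrolled hypertension, from a UK NHS payer perspective. This note
documents the model, its assumptions, the synthetic fixture that stands in
for inputs we cannot redistribute, the numerical conventions, and the known
limitations — in particular, what agreement with published results does and
does not demonstrate.

## Model structure

The core is a deterministic Markov cohort model with a cycle length of one
month and a horizon running to age 110 (by which point >99.9% of the cohort
is absorbed). The default state space has 33 states:

* hypertension alone (the starting state);
* primary event states for stroke, myocardial infarction (MI), angina/other
  symptomatic CHD (stable and unstable presentations), heart failure (HF),
  and end-stage renal disease (ESRD), with tunnel sub-states that encode
  time since the event: an acute month, the remainder of year one (months
  1–6 for MI, whose utility changes at month six), and a year-two-plus
  chronic state;
* secondary combined states for the clinically salient pairs (stroke after
  MI, MI after stroke, HF after stroke/MI/angina/ESRD, stroke and MI after
  HF, late angina or ESRD after an earlier event), each with an entry month
  and a chronic state;
* two absorbing states: cardiovascular (CV) death and non-CV death.

Repeat events of the same kind are not modelled; histories deeper than one
prior condition map to the most recent severe state. Acute tunnels last
exactly one cycle; longer tunnels use a geometric sojourn whose mean matches
the nominal duration (11 months for post-stroke year one, 5 months for MI
months 1–6). A cohort model of this size cannot count residence months
exactly without one sub-state per month; the geometric approximation keeps
the state count at 33 and preserves expected durations.

Within a cycle, death is resolved first (background plus condition-specific
excess hazards, competing on the hazard scale and attributed to CV or non-CV
death in proportion to their hazards); incident events are then allocated
proportionally among survivors; the remainder advances through tunnels. Every
transition matrix row is checked to sum to 1 within 1e-10, and cohort
occupancy is checked to be conserved within 1e-9 at every cycle.

## Baseline risks

Each endpoint's baseline risk comes from a multivariate risk equation of
log-hazard form,

    p_10y = 1 − exp(−10 · exp(β₀ + Σ βᵢ (xᵢ − cᵢ))),

re-evaluated every cycle at the cohort's attained age (the chain is
time-inhomogeneous) and converted to a monthly probability on the rate
scale. Binary covariates supplied as cohort fractions (sex, smoking,
diabetes) are handled by evaluating the equation per stratum and mixing the
probabilities — the equations are defined for indicator covariates, and
plugging in prevalences would be wrong for nonlinear links. Sex is
stratified at the engine level: male and female cohorts are run separately
and mixed 80.1/19.9.

Ages outside an equation's validity range are clamped to the range bound
rather than extrapolated, which prevents runaway lifetime risks at ages 90+;
a warning is logged once per equation.

Baseline risks can be adjusted per endpoint with a hazard ratio
(`CalibrationSet`), applied as p′ = 1 − (1 − p)^hr. The "clinical event
adjustment factor" scenarios scale all endpoints at once.

### The shipped equations are calibrated stand-ins

The published analysis uses Framingham (stroke, CHD, HF), PROCAM (MI) and
NHANES (ESRD) risk equations whose transcriptions live in supplementary
material we do not redistribute. The fixture therefore ships **synthetic**
equations in age, sex, SBP, smoking and diabetes, produced by
`scripts/calibrate_fixture.py`:

* SBP slopes equal the meta-regression per-10-mmHg log relative risks, so
  cross-sectional SBP gradients and the treatment-effect mapping are
  mutually consistent;
* linear age slopes are fixed at literature-like mid-life gradients (stroke
  and HF hazards roughly double per decade); sex/smoking/diabetes slopes are
  round, epidemiologically plausible values;
* the intercept and a quadratic age term per endpoint are fitted so that the
  comparator arm reproduces the published comparator-arm 10-year (stroke
  9.0%, MI 7.5%, AP/CHD 14.5%, HF 5.0%, ESRD 0.40%) and lifetime
  (33.8/38.0/28.0/20.9/1.03%) cumulative incidences;
* a global scale on case fatality and excess mortality is fitted to the
  published 10-year CV death (4.9%) and the background lifetable to the
  10-year all-cause death (11.1%).

The calibrated CHD and ESRD hazards peak in late mid-life and decline
thereafter — epidemiologically defensible for new-onset angina and ESRD
incidence, and forced by the published lifetime/10-year incidence ratios
under competing mortality.

What this means for interpretation: comparator-arm incidences and everything
downstream of them agree with the published base case **by construction of
the calibration**; the genuine tests of the implementation are the
incremental quantities (relative risks, ΔQALYs, ΔCosts, ICERs, scenario
orderings), which the calibration never targets.

## Treatment effect

The treated arm's office-SBP reduction (base case 4.9 mmHg versus sham) maps
to endpoint-specific relative risks log-linearly:
RR(Δ) = exp(ln(RR_ref)·Δ/Δ_ref), anchored at per-10-mmHg standardized RRs
(stroke 0.64, CHD/MI 0.77, HF 0.51, ESRD 0.92). These anchors reproduce the
published 10-year model RRs (0.80/0.88/0.89/0.72/0.96) at Δ = 4.9. The RR is
applied each cycle to the baseline event probability, by default as a hazard
ratio (a probability-scale multiplication is selectable; the two agree to
first order at monthly probabilities). The effect is assumed maintained over
the lifetime; an exponential-waning hook exists and is off by default.

CV death receives no direct RR: it emerges from event avoidance through
acute case fatality and condition-state excess mortality. A
case-fatality-weighted mix of the event RRs lands near the published
10-year CV-death RR of 0.84, supporting this reading.

The published source is internally inconsistent about the RR curve: its
cited 0.47-at-32-mmHg stroke anchor and its 0.80-at-4.9-mmHg model RR cannot
lie on one log-linear curve (the former implies 0.89 at 4.9 mmHg). We keep
the log-linear form with per-10-mmHg anchors and do not attempt to
reconcile the two; consequences are listed under Limitations.

## Mortality

Background mortality comes from an age/sex lifetable and applies in every
alive state; it is attributed to non-CV death. The synthetic lifetable is
Gompertz–Makeham, h(age) = c + a·e^{b·age}, with parameters giving remaining
life expectancy at 55 of 28.3 years (men) and 31.6 years (women) — England-
like, slightly above the national all-cause figures because the table
represents only the background component; the model adds CV deaths through
condition states. Condition states add annual excess CV hazards (e.g.
post-stroke year one 3.9%, chronic HF 6.2%, ESRD 10.8%) and incident events
carry acute case fatality (stroke 11.7%, MI 9.3%, unstable angina 1.5%, HF
3.1%); hazards add across the conditions of combined states. An optional
age-slope on the excess hazards exists (`MortalitySpec.excess_age_slope`)
and defaults to 0.

## Economics

Costs (2022 GBP) and utilities follow the published key-parameter table.
Annual state costs and utilities accrue at 1/12 per cycle with trapezoidal
half-cycle correction and mid-cycle discounting at 3.5% per annum for both
costs and effects. Acute event costs are charged once on the entry
transition without half-cycle correction (fatal events included — the acute
episode is still incurred). The background hypertension-management cost
(£279/year) applies additively in every alive state of both arms. The RF RDN
procedure cost (£6 862) is charged at cycle 0 in the treated arm; the
repeat-procedure scenario charges a second, survival-weighted and
discounted, at cycle 120.

Combined-state utilities take the minimum of the component utilities
(multiplicative combination is selectable). Utilities are multiplied by a UK
population age-utility curve (quadratic in age with a sex term) normalized
to 1.0 at the cohort's starting age, so the hypertension-alone state starts
at the published 1.00. Scenario utility scaling multiplies **all** utilities
including hypertension and caps at 1.0 — this convention was identified from
the published scenario table, whose "utilities 10% lower" ICER equals the
base ICER divided by 0.9 exactly.

ICERs are computed on unrounded incremental values, with dominance flags and
NICE banding (<£20 000 cost-effective; £20 000–30 000 potentially;
>£30 000 not cost-effective). Shorter-horizon results truncate the
discounted accrual at the horizon; nothing beyond the horizon is credited.

## Uncertainty analysis

One-way sensitivity varies each parameter of the fixture's parameter table
to its 95% CI (mean ± 1.96 SE, clipped to the distribution's support) and
reports the ICER span, sorted descending (tornado). The dominant parameters
are the treatment effect size, the RF RDN procedure cost and the stroke/CHD
effect-mapping RRs, in line with the published tornado.

The PSA samples every tabled parameter — Normal for demographics and effect
size, Gamma for costs, Beta for utilities and proportions, method-of-moments
parameterization — plus the per-10-mmHg anchor RRs themselves (Beta, SEs
0.035–0.045, matching typical published CI widths for these meta-regression
estimates). Draws are independent; demographics can be held fixed to treat
them as heterogeneity rather than uncertainty. Each draw re-evaluates the
full two-arm model. Cost-effectiveness probabilities use net monetary
benefit (λ·ΔQ − ΔC > 0), which handles all four quadrants; the mean ICER is
the ratio of means E[ΔC]/E[ΔQ] (the mean of per-draw ratios is also
reported); the 95% credibility interval takes empirical percentiles of
per-draw ICERs within the ΔQ > 0 quadrant, with quadrant counts reported.
All randomness flows through one `numpy` Generator seeded by the caller;
results are bitwise reproducible for a fixed seed.

Default problem sizes: a lifetime run is 660 monthly cycles over 33 states,
per sex and arm; the PSA default is 10 000 draws (a few minutes on one CPU);
the test suite's microsimulation oracle uses 10⁶ simulated individuals on a
4-state toy space.

## What the synthetic fixture does and does not show

Passing tests on the shipped fixture demonstrate that the engine,
effect-mapping, accrual and uncertainty machinery are internally correct
(closed-form oracles, an independent microsimulation, conservation and
dominance properties) and that, when the comparator arm is calibrated to the
published epidemiology, the incremental results land close to the published
ones. They do not validate the synthetic equations against real cohort data,
and they cannot reproduce supplement-only details. Known residual
discrepancies, with our best diagnosis:

* **Shorter-horizon ICERs.** Truncated accrual gives ~£96k/£43k/£26k per
  QALY at 10/15/20 years versus the published £28 639/£19 790/£15 812. The
  published short-horizon block is hard to reconcile with its own 10-year
  all-cause death difference (0.6 percentage points, bounding incremental
  life-years at 10 years to ≈0.06, while the published 15-year row prints
  0.27 LYs gained). Our sweep is internally consistent with our lifetime
  results; the published build-up appears to follow a different, unstated
  accrual convention.
* **Large effect sizes.** At 6.9 and 9.9 mmHg our ICERs are 22–50% below
  the published rows. The published incremental benefit grows markedly
  sub-linearly in the effect size (ΔQALY rises only 1.39× when the effect
  doubles), which no log-linear or linear RR(Δ) curve applied per cycle can
  produce; the published 6.9-mmHg row also uses a trial subcohort whose
  demographics are not printed.
* **PSA tail.** With the tabled parameter set our ICER distribution is
  slightly tighter than published (93.4% → 98% of draws below £20 000);
  the supplement's full sampled-parameter list is not printed.

## Limitations

Beyond the stand-in inputs: no repeat events; no blood-pressure drift with
age; effect durability assumed lifetime; monthly-cycle geometric tunnels
rather than exact residence counting; CV/non-CV death attribution follows
the hazard split, so lifetable deaths are never counted as CV; costs fixed
in 2022 GBP with no inflation machinery; no individual-level heterogeneity
beyond sex stratification in the production path.
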