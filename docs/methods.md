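# Methods

## Endpoint definitions

**Components.** At every scheduled post-baseline visit a patient is
flagged for the FEV1 component when baseline pre-dose FEV1 minus the visit
value is ≥ 0.100 L, and for the SGRQ component when the visit SGRQ total
score exceeds baseline by ≥ 4 points. Both boundaries are inclusive (a
drop of exactly 100 mL flags; a drop of 99 mL does not — a numerical
guard of 10⁻⁹ absorbs float representation noise only, six orders of
magnitude below a 1 mL perturbation). The exacerbation component triggers
at the onset day of the first moderate-to-severe episode on or after
day 1 (day 1 = day of first dose); moderate and severe episodes are
treated identically. A missing visit measurement yields a *missing* flag,
never "not deteriorated"; a missing baseline excludes the patient from
that component with a logged warning.

**First CID.** The event day is the minimum over triggered component
times (visit day = 7 × visit week for FEV1/SGRQ; onset day for
exacerbations). All components attaining the minimum are recorded — ties
are kept, not broken. Without any trigger the patient is censored at
study end (completers) or last contact (early discontinuations). An event
on the day of discontinuation counts as an event.

**Sustained CID.** Evaluated per component, retrospectively over the full
follow-up (as in a post-hoc analysis, not adaptively visit by visit):

- *(a) consecutive rule* — the component flags at visit *v* and at the
  visit exactly one nominal interval (4 weeks) later. The later visit
  must exist on the schedule, be measured, and flag; if the intervening
  measurement is missing, visits 8 weeks apart do **not** satisfy (a)
  ("4 weeks apart" is read literally; rule (b) still offers a path).
  The run length is configurable (`sustained_min_consecutive`, default 2).
- *(b) fraction rule* — the component flags at ≥ 50% of all *available*
  subsequent visits, where "available" means visits at or after *v*,
  through last contact, with a non-missing measurement for that
  component, **including the triggering visit itself**. "Available"
  qualifies the visits: the denominator must be observable. FEV1 and
  SGRQ availability sets are independent.

The sustained time is the visit day of the earliest qualifying *v*. A
single qualifying exacerbation is sustained by definition, with the same
time as the first-CID exacerbation component — so the per-component
sustained exacerbation count always equals its first-CID count. The
overall sustained day is again the minimum over sustained components,
ties kept.

One consequence of including the triggering visit in (b)'s denominator: a
component that first flags at a patient's *final* available visit is
sustained (1/1 = 100%). This makes sustained rates track first-event
rates more closely than a strictly prospective reading would; both rules
and the denominator convention are explicit interpretation choices, kept
configurable via `CidThresholds`.

The rule engine is verified exhaustively against an independent
plain-Python evaluation of the written rule over every flag pattern on a
6-visit grid, with and without a missing visit (448 cases), and
property-tested on random patterns up to 10 visits.

## Survival analysis

Kaplan–Meier estimation, the log-rank test and Cox proportional-hazards
fits are provided by lifelines behind this package's validated wrappers;
tests cross-check them against direct product-limit arithmetic, hand
risk-set (O−E / V) computation, a direct numerical maximization of the
partial likelihood, and null-calibration / coverage simulations.

Choices:

- **Ties** — Efron's approximation (lifelines' default). FEV1/SGRQ events
  land on a 28-day grid, so ties are heavy and Breslow would be visibly
  biased.
- **Pooling** — Cox baseline hazard stratified by study by default, since
  the pooled studies run 12–52 weeks with different censoring profiles.
  A single-stratum fit equals the unstratified fit (tested).
- **Covariates** — the adjusted model uses treatment, sex, age group
  (<65/≥65 years), GOLD severity (moderate/severe), smoking status
  (current vs ex) and baseline eosinophil status (<300/≥300 cells/µL),
  all binary-coded. Subgroup forest rows use a treatment-only model
  within the level by default (the adjusted variant is a flag), because
  mixed adjustment within small levels is fragile and the unadjusted
  within-level HR is the conventional forest-plot quantity.
- **Median CI** — log–log (exponential Greenwood) construction; quartiles
  are the earliest times at which survival reaches 0.75 / 0.25. A curve
  that never crosses the level reports an infinite (flagged) value.
- **P-values** — two-sided at α = 0.05; Wald for Cox, 1-df chi-square for
  the log-rank. Because trial tables do not say which of the two produced
  a printed p, the event summary emits both `p_logrank` and `p_cox`.
- **Degenerate fits** — zero-event strata and suspected separation are
  surfaced in a `diagnostics` list (and forest rows that cannot be fit
  are emitted with a note and NaN estimates), never silently dropped.

## The synthetic cohort generator

No patient-level data from the pooled LAMA trials are publicly
deposited, so the generator is a first-class, tested component that
emulates the *structure* the analysis assumes. Defaults were chosen once
as plausible trial conditions:

| parameter | default | rationale |
|---|---|---|
| designs | 26 w (GLY:PBO 2:1), 52 w (GLY:TIO:PBO 2:1:1), 12 w (GLY:TIO 1:1), 26 w (GLY:TIO:PBO 2:2:1) | durations and approximate allocations of a four-trial LAMA pool (~1,885 / 1,071 / 774 patients per pooled arm) |
| baseline moments | FEV1 1.3 L (SD 0.47), SGRQ 48.0 (SD 17.66), 74% male, 41% current smokers, 25% prior-year exacerbation, 38% GOLD 3, BDI 6.2 (2.1), age 63.9 (8.9) | published pooled-cohort characteristics (calibration inputs, verified within 3 SE at n = 10,000) |
| eosinophils | log-normal, median 150 cells/µL, σ_log 0.8 | ≈ 19% of patients ≥ 300 cells/µL, typical of COPD cohorts |
| FEV1 arm effects | +0.09 L both LAMAs, 0 placebo | trough FEV1 improvements of ~90–100 mL vs placebo reported for once-daily LAMAs; identical active effects encode the no-difference comparison |
| SGRQ arm effects | −3 both LAMAs, 0 placebo | typical LAMA health-status benefit, below the 4-point MCID |
| FEV1 slope | −0.03 L/year | moderate-to-severe COPD decline |
| visit noise | AR(1), ρ = 0.6; SD 0.12 L / 7 SGRQ units; patient intercepts SD 0.10 L / 6 units | within-patient spirometry/questionnaire variability with both serial correlation and stable between-patient heterogeneity |
| exacerbations | 0.55/yr (LAMA), 0.85/yr (placebo); gamma frailty, dispersion 0.5; 20% severe | low-exacerbation pooled population; frailty reproduces the over-dispersion of real count data |
| dropout | annual hazard 0.18, non-informative, rounded up to the next 4-weekly visit | ~16% discontinuation over a year; censoring independent of outcome, as the survival methods assume. An optional coupling flag inflates the hazard after a first exacerbation for sensitivity analyses |
| missingness | per-measurement probability 0 (configurable) | exercised in tests of the sustained-rule edge cases |

All randomness flows through per-patient substreams keyed on
(seed, patient_id), so cohorts are byte-identical across reruns and
invariant to study/patient ordering.

**What the generator does not emulate:** symptom-level exacerbation
adjudication (episodes arrive pre-adjudicated), informative dropout by
default, visit-window jitter (visits sit exactly on the nominal grid),
learning/placebo effects in SGRQ, and any correlation between baseline
covariates beyond GOLD grade ↔ %-predicted consistency. Passing tests
therefore demonstrate correctness of the *derivation and analysis
machinery* under the stated stochastic structure — not that real pooled
trial data would yield any particular effect size. Headline hazard
ratios from the real pooled cohort are qualitative references only: the
synthetic defaults reproduce their direction (active ≈ active; active
strongly better than placebo), not their magnitudes.

The spec-level contrast "visit grids of 12/26/52-week studies every
4 weeks" cannot make 26 a multiple of 4; scheduled visits run at 4-week
multiples up to the duration (weeks 4–24), while study end (censoring for
completers) is day 7 × duration (182).

## Reporting conventions

- Percentages are rounded half-away-from-zero to one decimal (the
  convention of printed trial tables), and always recompute exactly from
  their count and arm N.
- At-event summaries report mean ± SD (ddof = 1) of the measure at
  baseline and at the triggering visit, restricted to patients whose
  corresponding component triggered; single-patient cells report SD 0
  with n = 1 visible; event days without a matching measured visit are
  counted per arm and logged. Between-arm p-values are Welch t-tests.
- The nine shipped subgroup splitters are total on valid baselines;
  boundary values go to the "high" level for age (≥65) and eosinophils
  (≥300), and to the "low" level for SGRQ (≤25) and BDI (≤7). A GOLD
  A+B / C+D surrogate splitter (risk from prior-year exacerbation
  history) is available but off by default: with ~25% prior-year
  exacerbation prevalence the grouping is not representative.

## Problem sizes used in the test suite

Simulator calibration uses one 10,000-patient cohort (moments within
3 SE); the exacerbation process is checked against its Poisson mean at
n = 10,000; log-rank null calibration uses 5,000 replicates of n = 50+50;
Cox coverage uses 200 replicates at n = 2,000 with a planted HR of 0.5;
planted-effect recovery tests use 1,200–3,000 patients. These sizes put
Monte-Carlo error well inside the asserted 3-SE bands while keeping the
full suite around three minutes.

## Known limitations

- The 4-week grid interval-censors FEV1/SGRQ deterioration times; no
  interval-censoring correction is applied (the analysis convention this
  package mirrors shares the limitation).
- No competing-risks treatment of death/withdrawal, and no
  recurrent-event modelling of exacerbations beyond the first.
- The sustained rule's two written branches leave genuine ambiguity
  (denominator membership of the triggering visit; behaviour at the end
  of follow-up); the interpretations above are documented and
  configurable rather than uniquely forced.
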