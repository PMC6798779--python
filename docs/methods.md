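# Methods

## Scope and perspective

The package evaluates a pre/post quality-improvement program for STEMI care
from a societal, human-capital perspective. It takes as inputs (i) life
tables (deaths per 1,000 at each single year of age, by sex), (ii) labour
data (employment shares per 1,000 in 5-year age bins, total labour force by
sex, single-age population counts), (iii) national accounts (GDP, labour
share, employed workers), (iv) a patient cohort with age, sex, study arm
and 1-year vital status, and (v) a program cost breakdown over an
enrollment window. It deliberately does not attempt QALY-based
cost-effectiveness, covariate-adjusted effect estimation, or ICER
calculation: the clinical contrast is taken as the plain difference of arm
mortality proportions, in keeping with the aggregate character of the rest
of the calculation.

## Survival construction

Survival from age *j* to the end of age *t* is computed by the
cumulative-deaths rule: s(j,t) = 1 − min(1, Σ d_u/1000, u = j..t), where
d_u is the tabulated deaths per 1,000 at age u. This treats per-1,000
death counts as additive over the interval; over long horizons the
accumulated count can exceed 1,000, and survival is clamped at zero from
that age on. The standard actuarial alternative — the product of
single-age conditional survivals Π(1 − d_u/1000) — is implemented behind
`method="product"` for comparison. The cumulative rule is the default
because the downstream benefit arithmetic (and the published aggregates the
fixture reproduces) is built on it; for the mortality levels involved the
two differ by at most a few percent inside the working-age range.

## Participation and working years

Published employment-by-age tables come per 1,000 employed in 5-year bins.
Each bin's share is split uniformly over its single years; the head count
employed at age t is (per-age share) × total labour force / 1000; dividing
by the single-age population gives the participation rate l_t, clamped
into [0, 1] (sparse old-age populations can otherwise push the ratio above
one). Participation is forced to zero from the retirement age R (default
70), which also makes the upper limit of the working-years sum immaterial:

    T_j = Σ_{t=j}^{R} s(j,t) · l_t.

T_j is zero at and beyond R, and ages above the life table's coverage are
assigned T = 0. LFPR (employed + unemployed over population) and the
worker-population ratio are used interchangeably at the single-age level,
as labour-force surveys at this granularity effectively publish the
employed-based quantity; the overall LFPR per 1,000 is carried only for
reporting.

## Valuation

Average annual labour income is I₀ = GDP·s/w. The income stream lost by a
death with T working years left is valued at PV = Σ_{i=0}^{T} I₀
((1+g)/(1+r))^i, income credited at the start of each year (the i = 0 term
undiscounted, so PV(T=0) = I₀ exactly). T is an expectation and generally
fractional; the fractional remainder f contributes f times the term at
⌊T⌋+1, making PV continuous and strictly monotone in T. Truncation would
discard expected income; rounding up would over-count. Defaults g = 3%,
r = 6% follow standard guidance for low- and middle-income settings;
Tamil Nadu life expectancies of 68.6 (men) and 72.7 (women) years are the
life-years baselines. Costs observed over a window of D days are
annualized by ×365.25/D.

## Arm comparison and annualization

The two arms are enrolled over the same window but differ in size, so arm
totals are never compared directly: each arm is reduced to a per-patient
average and scaled to a common annualized patient base, by default
(n_pre + n_post) × 365.25 / enrollment_days. This is the only
normalisation under which the pre − post difference isolates the care
effect; scaling each arm by its own calendar factor would confound the
contrast with arm size. The program's own published base of 2,265
annualized patients is not derivable from 2,420 × 365.25/319 (= 2,771) and
is therefore supported as an explicit override, which the fixture uses.
Deaths averted per year is ARR × base, reported both unrounded (77.0 at
the published figures) and as the whole-death ceiling (78) used when
quoting cost per life saved, matching how NNT-style quantities are quoted.

## Sensitivity analysis

Two routes compute the benefit-cost grid over (g, r) pairs. The
patient-level route revalues every deceased patient's PV at each pair
(survival, participation and T are independent of g and r). The
aggregate-calibrated route is for the situation the fixture represents —
published aggregate PVs without microdata: each arm's aggregate PV is
inverted (PV is strictly monotone in T, so the inverse is well defined) to
the effective duration that reproduces it at the baseline rates, and the
grid revalues both arms with those durations fixed. By construction the
baseline cell equals the headline ratio.

A known discrepancy: the program's published sensitivity table is flatter
along the growth axis than compound growth permits. Inverting the
published PVs (INR 228.7M/175.6M over 398.6/321.6 annualized deaths at
I₀ = 85,662.37) gives effective durations of 6.3 and 5.9 years, and the
(g = 12%, r = 4%) corner then evaluates to 5.29 — versus 4.7 in the
published table. Any patient-level mixture of durations consistent with
the same baseline aggregate gives a *larger* corner value (the annuity
factor at (1+g)/(1+r) > 1 is convex in the baseline factor), so no
duration composition reconciles the published corner with the published
formula; the low-growth rows, by contrast, reproduce to the table's 0.1
printed precision. The package reports what the formula yields.

## Synthetic data

The cohort generator draws ages from a truncated normal (mean 56, SD 12,
range 25–90), sex with 78% male, and 1-year death as Bernoulli with
arm-specific rates (defaults 17.6%/14.2%, arm sizes 898/1,522, 319-day
window). The age/sex parameters are conventions resembling published
Indian STEMI registry demographics. An optional logistic age effect on
mortality is available (intercept calibrated by root-finding so the
marginal rate is preserved); it is off by default because the aggregate
arithmetic uses arm-level rates only. Life tables are Gompertz-like
(doubling every 8 years from 0.08 per 1,000 at age 0, females lagging
males by 4 years — roughly 35 per 1,000 for men at age 70, a plausible
stand-in for official Indian life tables). Employment bins follow a hump
peaking at ages 30–50 and vanishing by 70. All generators are
bit-reproducible given a seed.

What the synthetic data do **not** emulate: hospital clustering,
covariate-driven mortality (unless the age effect is enabled), secular
trends between the pre and post phases, or the program's true age/sex
distribution. Tests passing on synthetic cohorts therefore demonstrate the
pipeline's arithmetic and statistical calibration, not the clinical
validity of any particular effect estimate.

## Numerical choices and degenerate inputs

- days_per_year = 365.25 throughout (13.2 × 365.25/319 = 15.114, matching
  the published annualized cost at its printed precision; 365 would give
  15.10).
- NNT uses the ceiling; years-per-death-averted uses round-half-to-even.
- ARR ≤ 0: NNT and the per-life/per-life-year costs are reported as
  undefined (JSON null, "n/a" in tables) — never as zero — and the CLI
  exits with a distinct code. Negative gain is reported as is, with a
  warning.
- A deceased patient older than the working-years coverage contributes the
  T = 0 value (one year's income), with a warning.
- Cost subtotals and totals are always computed from the six leaf
  components; the published leaves sum to 15.10 against a printed total of
  15.11 (rounding in the source table), a 0.07% gap the fixture preserves
  rather than hides.
- The published average labour income (85,662.37) differs by 0.008% from
  the arithmetic on its published inputs (85,669.0, presumably unrounded
  GDP upstream); the package computes, it does not match.

## Problem sizes

The statistical tests use 20 seeded cohorts of 10,000 patients per arm for
parameter recovery and 50,000 per arm for marginal-rate calibration —
large enough that three Monte-Carlo standard errors sit well inside the
effect sizes being checked, and small enough that the whole suite runs in
seconds.

## Limitations

Mortality is the only endpoint (no morbidity, no quality adjustment); the
gender pay gap is not modelled (one national average income); no
competing-risk correction beyond the life table itself; all amounts are in
2013 INR with currency conversion treated as display-only; and the
effect estimate inherits whatever confounding the pre/post design carries.
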