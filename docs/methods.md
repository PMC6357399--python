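# Methods

## The estimand

For a bounded age window [a, b] (80–89, 90–99, or 100–105; the last is six
annual steps, the others ten), partial total LE is the expected number of
years lived between exact ages a and b + 1 by a cohort entering the window
alive; DFLE is the part spent nondisabled and disabled LE the remainder,
so total = DFLE + disabled LE holds exactly by construction everywhere in
the package. Partial quantities are bounded by the window length, which
keeps cohorts comparable without extrapolating beyond observed ages.

## Disability coding

Katz ADL coding: disabled = needing personal assistance in ≥ 1 of bathing,
transferring, dressing, eating, toileting, or incontinence. Missing ADL
items are a hard error; there is no item-level imputation (none is
defensible without knowing the missingness mechanism), but a row may carry
a precoded state instead of items. Reading a file with items and a
contradictory precoded state is an error, not a silent preference.

## Person-year expansion

Observed intervals span L whole years (integer interview ages; wave
offsets are shared by the whole panel). With equal endpoint states, L
identity records are emitted. With different living states, a single
transition (first-order Markov assumption) is placed in a year drawn
uniformly from the L years. Deaths with a recorded date are placed in the
year containing the date — death-certificate dates are treated as
authoritative — and uniform placement is used only when the date is
missing. Intervals ending in loss to follow-up contribute nothing beyond
the last observation. The expansion seed is independent of the
microsimulation and bootstrap seeds; by default each bootstrap replicate
re-draws the placements so placement uncertainty propagates into the
intervals (a `redraw_placement=False` switch freezes them).

## Transition model

Two separate fits by origin state (no shared parameters between strata) on
the ordered outcome nondisabled < disabled < dead — death as the top
category of one severity scale, not a competing risk (a multinomial
sensitivity route can be added by users from the same person-year table).
Age enters as a continuous shared-slope term centered at the window's
lower bound (numerical stability, interpretable cutpoints); integer age at
the start of the person-year is used. Sex, residence and schooling get
logit-specific coefficients. Optional age² and age×sex shared terms are
available through `test_extra_terms`, which reports Wald z and p per term
and a keep/drop recommendation at α = 0.05.

Estimation is exact Newton on the analytic gradient and Hessian of the
weighted cumulative-logit likelihood, aggregated over (age × profile ×
destination) cells, with ridge fallback when the (non-concave) partial-PO
Hessian is not positive definite, backtracking line search, gradient
tolerance 1e-8 (∞-norm) and a 100-iteration cap. When the objective
decrease falls below float resolution the full Newton step is still taken
while it shrinks the gradient. Standard errors come from the inverse
Hessian at the optimum.

Partial-PO fits can produce crossing cumulative curves (negative middle
probability). After fitting, the full age × profile grid is checked:
violations beyond −1e-8 raise at prediction time; smaller ones are clamped
to zero and the row renormalized. The bootstrap treats a crossing
replicate like a failed fit: re-drawn up to 5 times, then dropped with a
warning.

## Attrition weights

A complete case is an individual not lost to follow-up; death before the
next wave counts as complete because the outcome is observed (otherwise
mortality would be down-weighted). Completeness is modeled with an
ordinary logistic regression (statsmodels) on the sociodemographic
profile, baseline disability, any auxiliary covariates in the panel, and
the sampling weight as a covariate; the final analysis weight is
(1 / predicted completeness probability) × sampling weight, attached to
all of a complete individual's person-years, with lost individuals
excluded (weight 0) from the weighted analysis. Weights are truncated at
the (1, 99) percentiles by default to bound variance; truncation is
configurable and can be disabled. Constant predictors are dropped before
fitting; perfect separation raises with the suspect predictor named.

## Life-table computation

Occupancy credit convention (shared by the simulator and the oracle via
one `death_credit` flag): a no-transition year credits 1.0 to the origin
state; a living-to-living transition credits 0.5 to each side; a death
year credits `death_credit` (default 0.5, the standard a = 0.5 rule;
0 and 1 are available since wave data cannot identify the within-year
death time). Under constant annual death probability q with no disability
this yields the closed form (1 − q/2)(1 − (1 − q)^L)/q, used as an exact
engine check.

The microsimulation draws each simulated individual's baseline (profile,
state) from the weighted observed baseline joint distribution (an exact
proportional-allocation mode exists for variance reduction) and walks a
pre-assigned row of uniforms through the matrix schedule, so estimates do
not depend on any iteration order. The oracle propagates the baseline
distribution through the same matrices and accumulates expected credits —
no randomness, used for ground truth and Monte-Carlo validation.

The end-of-life adjustment addresses the harshest Markov artefact: a death
from the nondisabled state carries a `death_credit` final-year credit, a
uniform fraction u of which is reclassified as disabled. Totals are
untouched; DFLE can only fall. The expected reallocation is
E(u)·death_credit = 0.25 years per such death at the default convention.

## Synthetic data: what it emulates and what it does not

The generator simulates annual-cycle truth — states change at integer
ages under the same model class the estimator fits — so parameter
recovery tests the estimation code, not model misspecification. It
reproduces the study design: three paired age groups (80–89, 90–99,
100–105) with baseline totals 7,334 / 7,705 / 5,481 split evenly between
an earlier cohort observed at +2/+4 years and a later cohort at +3/+6
years; baseline disabled prevalence 17.3% / 11.8% for octogenarians and
stated assumptions (29/24% and 50/44%) for the older groups; a covariate
mix with a woman majority, two-thirds rural, and schooling much rarer
among women; deaths dated to the day within the death year; logistic MAR
dropout; and optional two-stratum sampling weights.

Default true-model coefficients are a calibration chosen once with the
occupancy oracle so implied magnitudes sit in the plausible range for
these ages (octogenarian partial total LE ≈ 6.3/6.5 years with DFLE share
≈ 0.83, nonagenarian ≈ 3.9 with share ≈ 0.63, centenarian ≈ 1.4 with
share ≈ 0.5, with a modest later-cohort improvement); they are not
estimates from any survey.

What passing tests do *not* show about real data: with 2–3-year wave
gaps the generator produces within-interval double transitions
(nd→dis→nd, nd→dis→dead) that the single-transition expansion cannot see,
so estimates from the default study configs carry the interval-censoring
bias intrinsic to such designs (on the order of −0.3 years of partial LE
for octogenarians at the default truth). This is a property of the
design, not a defect of the code; the estimator-validation scenarios
therefore use annual waves, where the model class matches exactly:

- `coverage_validation_config`: annual waves, no dropout, n = 2,000 — the
  bootstrap-coverage study isolates interval calibration from
  misspecification.
- `ipw_validation_config`: annual waves plus a binary frailty mixture
  (prevalence 0.35, logit shift −0.8 on both cumulative logits) that also
  drives dropout (coefficient +2.2) decided once at baseline
  (`per_wave=False`), so completeness is exactly independent of the
  health path given covariates and inverse-probability weighting is the
  exact correction. Frailty is deliberately absent from the transition
  model: the weighted estimate retains a small residual bias because a
  frailty mixture makes the marginal process non-Markov, but the
  selection component — the dominant error of the unweighted analysis —
  is removed. With per-wave dropout (the default for study-like configs)
  simple completeness weighting overcorrects mortality predictors, which
  is why the validation scenario pins down the mechanism it tests.

The parameter-recovery checks draw person-years directly from a
well-conditioned truth (balanced outcome categories, ages uniform on
74–86 symmetric about the centering age, all eight profiles equally
likely) so that coefficient information, not design sparsity, limits the
error.

## Inference conventions

Resampling unit: the individual with all their waves (within-person
correlation). Point estimates always use the full sample; replicates
default to the same microsimulation n (100,000) but are configurable down
for desk-scale work. Intervals are linearly interpolated 2.5/97.5
percentiles of the replicate distribution. Cohort differences pair
replicates by index (an all-pairs pooled mode is provided and agrees
within Monte-Carlo tolerance under independent resampling); p-values are
2·min(#{d ≤ 0}, #{d ≥ 0})/B capped at 1, with a zero count reported as
"< 0.001" — at B = 499 the smallest non-floor value is 2/499 ≈ 0.004.
Differences and p-values are computed unrounded and rounded to two
decimals only for display, so printed components can miss printed totals
by one last-digit unit (the table emits a rounding note when they do).

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale chosen as the
package's own validation design: microsimulation n = 100,000 where a
single estimate is checked, 20,000 inside bootstrap replicates;
B = 99 replicates for coverage (100 datasets of n = 2,000) and for the
reduced paired-cohort analysis (cohorts of n = 2,000); 50,000
person-years per recovery fit; 20 seeded runs for the weighting
comparison.

## Known limitations

First-order Markov, no state-duration dependence; death modeled as the
top ordinal category rather than a competing risk; single stochastic
expansion per run (no multiple imputation over placements beyond the
bootstrap re-draws); percentile intervals only (no BCa/studentized); no
doubly-robust or stabilized weights; cross-sectional sampling weights
only, so estimates represent the study cohort rather than the national
population.
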