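# Methods

## State space and classification

Four states: robust (1), IADL-disabled (2), BADL-disabled (3), dead (4).
Classification uses item *counts*, not item identities: any BADL limitation
defines the BADL state even when IADL limitations coexist; IADL limitation
with intact BADL defines the IADL state; death dominates. Cohort item
batteries differ across surveys, so pre-counted columns are the common
denominator the reader accepts. A wave with a missing BADL or IADL count
(and no pre-coded state) is dropped as non-response rather than
interpolated — no defensible imputation rule exists for single disability
items. Subjects entering below age 50 are rejected outright, keeping the
entry-age semantics of a 50+ cohort simple; subjects left with fewer than
two usable interviews are excluded and counted.

## Death dates

Deaths are ascertained at the first wave after they occur. When the date
itself is unrecorded, it is imputed at the calendar midpoint of the
interval between the last interview alive and the ascertainment wave, at
day resolution with the floor taken on odd spans (month arithmetic is
ambiguous; days are not). Early/late variants (one day inside either end
of the interval) support sensitivity analysis. Imputed dates are treated
as exact in the likelihood; the sensitivity machinery quantifies the
consequences (below).

## The multi-state model

Intensities are time-homogeneous per fitted population with gender as the
sole default covariate, `q_rs(z) = exp(log q⁰_rs + β_rs z)` over nine
allowed transitions (R↔I, R↔B, I↔B, and R/I/B→D). Age deliberately enters
the *microsimulation* stage rather than the chain: one intensity matrix
per population keeps the multi-year transition tables well-defined, and
the age-and-gender adjustment belongs to the discrete next-state models.
An optional age-at-interval-start covariate on the intensities exists but
is off by default. The process clock is years since each subject's first
interview; under time homogeneity only interval lengths matter, computed
in exact fractional years from calendar dates. Same-day interview and
death are separated by half a day to avoid zero-length intervals.

Likelihood: live-to-live pairs contribute `log expm(Q dt)[r,s]`
(conditioning on the first observed state, so no initial-state term);
deaths contribute the exact-time density summed over the unobserved
penultimate state. Intervals are flattened and grouped by covariate
pattern, and each group's propagators `expm(Q dt_i)` are evaluated in one
batch through the eigendecomposition of Q (with a conditioning check and a
scipy `expm` fallback), which makes the likelihood cost essentially linear
in the number of intervals.

### Optimisation and uncertainty

BFGS on the unconstrained log-intensity scale. Gradients are complex-step
derivatives — exact to truncation order h² with no subtractive
cancellation — evaluated for all free parameters simultaneously via a
batched eigendecomposition of the perturbed intensity matrices. The step
is h = 1e-8 rather than the textbook 1e-20: the eigensolver's
real-arithmetic rounding (~1e-15) leaks into the imaginary channel near
eigenvalue degeneracies, and 1e-8 keeps the derivative signal far above
that leakage while truncation error stays near 1e-16. The default
convergence tolerance is a gradient norm of 1e-6 (a tighter 1e-8 is not
reliably attainable once likelihood-sum rounding at n≈10³–10⁴ subjects is
accounted for); a stalled line search triggers up to two fresh BFGS
restarts from the best point. A penalty wall above e⁸ events/year keeps
line searches out of the overflow region. The covariance is the inverse
observed information, obtained by central finite differences of the exact
gradient (relative step 1e-5) and symmetrised; a non-positive-definite
information marks the fit unconverged.

Crude initialisation sets each baseline intensity to the observed
consecutive-pair count divided by person-years at risk in the origin
state, floored at 1e-4/year, with covariate effects at zero. A transition
never observed as a consecutive pair is unidentified: its rate is fixed at
the floor, its effects at zero, and it is excluded from optimisation and
reported in `FitResult.dropped`.

Hazard ratios are `exp(β̂)` with Wald intervals on the log scale from the
covariance diagonal.

## Microsimulation and life tables

The discrete stage fits, per origin live state, a multinomial logit over
the four destinations (staying put is the reference) with covariates age
at interval start (centred at 70, per decade), its square (optional,
default on — "adjusted for age" without a stated functional form warrants
mild curvature), and gender, using observed pairs whose length is within
25% of one cycle. The cycle is 2 years — the modal inter-wave gap — so
the model matches the observation process instead of requiring an
interval-to-annual embedding. Death is a destination like any other; an
origin with fewer than 30 usable pairs is an error naming the state.

`simulate_cohort` dispatches on its model argument:

* a **DiscreteTransitionModel** advances 100 000 individuals in cycles
  from age 50, drawing destinations at the current (age, gender); death
  receives the standard half-cycle credit in the origin state;
* an **intensity matrix Q** is simulated as an exact event-driven chain
  (exponential holding times, embedded jump probabilities) with exact
  person-years. This path exists so that simulated life expectancy can be
  compared to the analytic temporary expectancies `∫₀⁴⁰ expm(Qu)[s,live] du`
  free of discretisation bias; a 2-year-cycle discretisation of a CTMC
  would disagree with the integral by more than Monte-Carlo error in
  state-specific occupancy.

Life expectancy is *temporary* — years on [start_age, 90] — because the
simulation is explicitly truncated at 90; no open-ended tail is
extrapolated beyond observed ages. Tables report total and per-state
years by gender; the gap table decomposes the women-minus-men difference
as Δtotal = Δrobust + Δdisabled by construction. Conditional tables
(ages 50/60/70/80 × starting state) spawn one deterministic child seed
per cell from the configured seed.

## The synthetic generator

The generator *is* the study conditions: ~55% women; baseline ages drawn
from bands 50–59/60–69/70–79/80–89/90+ with weights
0.32/0.33/0.25/0.09/0.01; baseline states 75/10/15% robust/IADL/BADL;
four waves 2.0 ± 0.25 years apart; 8% monotone dropout per wave; 30% of
death dates unrecorded. Gender hazard ratios default to the canonical
demo effects (women: IADL onset 1.392, BADL onset 0.856, I→B 1.028,
B→I 1.356, B→R 0.692, I→R 0.970, deaths 0.232/0.285/0.692). Baseline
intensities are package-chosen — no published values exist for them — and
were calibrated once so the population 10-year robust→death probability
falls in the plausible 7–19% window and deaths over four waves land near
10–30% of subjects; the resulting per-year rates are frozen in
`synthetic.py`. Item counts are synthesised consistently with the latent
state. Dropout is non-informative (independent of state), a simplifying
assumption real attrition violates.

What passing tests on these data do **not** show: robustness to
informative censoring, to age-dependent intensities (the generator's chain
is age-homogeneous), to misclassified disability states, or to the
questionnaire heterogeneity of real surveys. They do show that the
likelihood, optimiser, covariance, and life-table machinery are correct
for the data-generating process the model assumes.

## Death-date sensitivity

Life expectancy in this package (as in the analysis pipeline it
implements) flows through the wave-cycle multinomial stage, where a death
enters through the interval it falls in — not through its exact date. With
biennial ascertainment and monotone attrition, sliding an unrecorded death
date inside its censoring interval leaves the LE tables essentially
unchanged; this structural fact is what the acceptance property verifies,
after first checking that the early/midpoint/late variants genuinely move
the imputed dates. The *intensity* fit, by contrast, is genuinely
sensitive: early placement shortens observed survival exposure and
re-attributes immediate deaths to the origin state, lowering the implied
intensity-based life expectancy (by roughly 0.05–0.17 years across
genders under the default conditions). A directional test covers that
path; the magnitude is documented here rather than asserted, because it
depends on the fraction of missing dates and on how far inside the
interval the variants sit.

## Numerical conventions

* Matrix exponentials: `scipy.linalg.expm` for reported probabilities
  (with rounding dust clipped and rows renormalised at ~1e-16); batched
  eigendecomposition inside the likelihood.
* Test oracles are independent of both: a truncated Taylor series with
  scaling-and-squaring for `expm`, Simpson quadrature for expectancies,
  and per-pair likelihood recomputation from dates.
* Probability floors at 1e-300 prevent `log(0)` only in real (value)
  evaluations; the complex (gradient) channel is never clipped.
* All simulation randomness goes through `numpy.random.default_rng`
  seeded from configuration; equal seeds give byte-identical CSV output.

## Scaling of the shipped checks

The test suite fits at n = 2000 subjects (parameter recovery) and runs 200
coverage replicates at n = 1000 — sizes at which one full suite completes
in a few minutes while leaving the recovery z-scores and coverage
estimates well-resolved. The acceptance script uses n = 4000 subjects and
100 000 simulated lives per gender, the cohort size at which the fitted
hazard ratios visibly re-approach the generator's values.

## Known limitations

* One intensity matrix per population: cohort-by-cohort or age-banded
  intensities are out of scope (the optional age covariate is a partial
  escape hatch, not piecewise-constant modelling).
* No frailty, no hidden-Markov misclassification layer, no survey weights,
  no bootstrap intervals for life expectancy.
* Temporary LE on [50, 90] cannot exceed 40 years by construction;
  populations with substantial survival past 90 are under-represented by
  this truncation.
* Wald intervals for very sparse transitions (few observed deaths from a
  state) can be wide or, when the information is nearly singular, the fit
  may report non-convergence; enlarging the data is the remedy.
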