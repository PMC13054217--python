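# Methods

## Wound-state space

A wound is a vector of eight closed categorical attributes: `phase`
(acute/chronic), `depth` (shallow/deep), `surface` (intact blister /
erosion or shallow ulcer / open deep ulcer), `necrosis` (none / dry black /
moist yellow), `infection` (absent/present), `pocket` (absent / present with
necrotic tissue), `granulation` (not applicable / insufficient / healthy and
sufficient) and `exudate` (minimal/high). Two invariants shape the space: an
acute-phase wound carries the neutral value for depth, necrosis, pocket and
granulation (those axes are only assessed on chronic wounds), and
granulation is only assessed on deep chronic wounds. Under these rules the
full cross-product of 864 combinations reduces to exactly 300 valid states
(12 acute, 72 chronic-shallow, 216 chronic-deep), which is small enough that
every engine property is checked exhaustively rather than sampled.

Deliberate reductions: exudate is binary (descriptions such as "abundant"
map to `high`; no scenario distinguishes more than two levels); wound size
is omitted because no recommendation depends on it; infection is binary —
intermediate "critical colonization" is collapsed into present/absent; a
pocket without necrotic tissue is not representable, as only the necrotic
pocket drives a contraindication. A blister is modelled as an acute-phase
wound with `surface=intact_blister`, which shares the acute recommendation.

## Decision engine

The clinical logic is a JSON decision tree interpreted by a generic engine;
each internal node tests one attribute, each leaf carries exactly one
(ointment, dressing) pair. Keeping the logic as data makes it auditable and
diffable, and lets `validate_tree` prove three properties by exhaustive
walk-through of all 300 states: totality (every state reaches a leaf),
safety (no occlusive dressing — codes 1–5 — is ever paired with infection or
a necrotic pocket) and absence of dead nodes.

Rule precedence on the chronic branch is **infection > pocket > necrosis >
(wound bed × exudate)**, i.e. conflicts resolve toward risk avoidance. The
ten calibration scenarios pin down most leaves; the remaining states are
covered by generalized rules flagged `"extension": true` in the tree JSON:

- any infected wound (including acute): iodine-family antimicrobial
  ointment (code 2), no dressing (code 6);
- black necrosis with high exudate: exudate-absorbing iodine preparations
  (code 2), no dressing — occluding wet necrosis is exactly the risk the
  safety layer exists to block;
- yellow necrosis without infection: iodine-family ointment (code 2), and
  hydrogel (code 5) at minimal exudate / no dressing at high exudate,
  mirroring the black-necrosis rules.

Leaves carry exactly one payload by construction, so no tie-breaking is
needed. Clean wound beds follow moist-wound-healing logic: moisture-donating
or retaining dressings (hydrocolloid/hydrogel) at minimal exudate,
absorptive dressings (hydrofiber/foam) at high exudate.

## Scoring

Scoring is strict exact match per component with no partial credit: each
question has a single "most appropriate" ointment and dressing (for question
4 only plain povidone-iodine counts, although silver sulfadiazine is
defensible clinically). `both_correct = ointment_correct × dressing_correct`
is the primary outcome. Phase rates are raw arithmetic proportions with
explicit denominators; missing responses are excluded from denominators and
counted, never silently zeroed. Model-adjusted estimates are the GEE's job —
the two are kept separate because printed "adjusted percentage" tables are
ambiguous about which is which.

## Crossover design

Sequence A receives decision support in period 1 (questions 1–5) and answers
questions 6–10 unaided in period 2; sequence B the reverse. The washout
(default 7 days, the design minimum) is bookkeeping only — carryover is
handled statistically by the period and sequence terms, not by a decay
model. Block randomization uses permuted blocks (default size 4, a common
choice for two-arm 1:1 allocation; the block size is configurable because it
is a design input, not a derived quantity). Covariate coding is
control/period 1/sequence A = 0, so the treatment coefficient is directly
the log adjusted odds ratio.

Note the structural confounding inherent in this design: within a sequence,
treatment is aliased with the question set (sequence A's intervention
responses are exactly questions 1–5). The sequence term absorbs the
between-group part of this; question-set difficulty differences load on the
period effect.

## GEE estimator

Coefficients solve the estimating equations Σᵢ Dᵢ′Vᵢ⁻¹(yᵢ−μᵢ)=0 by Fisher
scoring with the exchangeable correlation α re-estimated each iteration from
Pearson-residual cross-products (moment estimator, denominator
Σᵢnᵢ(nᵢ−1)/2 − p; dispersion fixed at 1 for binary data). Convergence is a
maximum absolute coefficient update below 1e-8 (default, max 100
iterations). The exchangeable working inverse uses the closed form
R⁻¹ = [I − α/(1+(n−1)α)·J]/(1−α). α is clipped to (−1/(max nᵢ−1), 1) to keep
the working covariance positive definite, and defined as 0 when no
within-cluster pairs exist (all singleton clusters), in which case the
estimator reduces exactly to the logistic MLE. The robust covariance is the
standard sandwich; a Mancl–DeRouen small-sample correction is available as
an opt-in flag but off by default, matching common reporting practice at
this study size. Inference is Wald throughout: z against the standard
normal, odds ratios exp(β) with exp(β±1.96·se) intervals. Divergence of any
coefficient beyond ±15 on the logit scale is reported as a separation error
naming the covariate rather than returned as a spurious estimate. Text
output formats p-values journal-style ("<.001"); machine output keeps full
precision.

With an independence working correlation the point estimates coincide with
the logistic MLE; the test suite verifies this against an independent
Newton–Raphson oracle to 1e-6 on twenty generated tables, and verifies full
agreement (coefficients and robust SEs to 1e-6) with statsmodels' GEE under
the exchangeable structure.

## Simulator and its estimand

Responses are generated from a conditional random-intercept logistic model:
clinician i answers correctly with probability
expit(logit(p_phase) + uᵢ + β_period·1[period 2] + β_sequence·1[sequence B]),
uᵢ ~ N(0, sd²). The ointment and dressing components are independent binary
streams (separate intercepts) by default; a shared-intercept flag couples
them, and the total outcome is always their product. Defaults mirror the
pilot scale: 28 clinicians, block size 4, anchor probabilities 0.043
(control) and 0.493 (intervention), intercept SD 1.0 on the logit scale — a
moderate within-clinician correlation (exchangeable α ≈ 0.1–0.2 on the
binary scale).

Because a GEE is a population-averaged model, the estimand it recovers is
not the conditional log-odds difference but the attenuated marginal
contrast. `marginalize` computes E[expit(logit(p)+sd·U)] per phase by
80-node Gauss–Hermite quadrature (cross-checked against adaptive quadrature
to 1e-9) and returns the implied marginal log-OR; simulation studies test
recovery against that value, evaluated at the reference cell (period 1,
sequence A).

What the simulator does **not** emulate: per-question difficulty variation,
learning dynamics beyond a constant period shift, clinician covariates, and
the dependence between ointment and dressing choices induced by the real
decision process. Passing recovery tests therefore show the estimator is
correct for exchangeable-by-design data, not that the real study's printed
estimates are reproducible — those depend on unpublished individual-level
responses.

## Problem sizes and numerical checks in the test suite

Recovery and coverage use 200 replicates of 100-clinician trials (mean
treatment log-OR within 0.06 of the quadrature truth — Monte-Carlo SE ≈ 0.01
plus an O(1/K) finite-cluster bias allowance — and 95% robust-interval
coverage within [0.90, 0.99]). Type-I error uses 500 replicates of a null
trial (equal phase probabilities 0.30, intercept SD 1, 100 clinicians) with
an acceptance band of 5% ± 2 points. One hundred clusters is used for both
stochastic checks because the sandwich estimator is asymptotic in the number
of clusters; at the pilot's 28 clusters its known small-sample
anti-conservatism would confound the check of the implementation with a
property of the method itself.

## Known limitations

- The engine reproduces the input→output relation of the question flow, not
  the phone-screen sequence; screen wording is out of scope.
- The strict single-answer key builds in the safety-first philosophy; the
  engine cannot express "several acceptable options".
- No debridement, antibiotic or pressure-redistribution recommendations:
  the use case assumes surgical intervention is unavailable.
- The GEE supports only the binomial/logit marginal model with
  exchangeable or independence working correlation — exactly the analysis
  the evaluation design needs, nothing more.
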