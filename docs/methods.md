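# Methods

## The design in brief

A phase I trial evaluates J ordered dose levels with two binary toxicity
endpoints per patient: a clinician-graded DLT (C-DLT, NCI-CTCAE grade >= 3
GI/GU) and a patient-reported DLT (P-DLT, PRO-CTCAE GI score 4–5).  The MTD
is the *minimum* over endpoints of the dose whose DLT rate is closest to
that endpoint's target (`phi_1 = 0.20` clinician, `phi_2 = 0.55` patient in
the reference radiotherapy design).  Cohorts of 3 are assigned adaptively:
the first cohort at the configured start dose, every later cohort at the
capped minimum-rule recommendation, until 15 patients or a safety stop.

## Working model and estimation

Each endpoint has an independent one-parameter empiric model
`F(x_j, beta) = p(x_j)^exp(beta)` with a zero-mean normal prior on `beta`.
The likelihood is the product of per-dose binomials in the accumulated
counts `(y_j, n_j)`; untried doses (`n_j = 0`) contribute nothing.

Two per-dose estimators are exposed:

* **plug-in** (default): `p_j^exp(beta_hat)` with `beta_hat = E[beta | D]`.
  One common power tilts the whole skeleton.  This is what the widely used
  CRM implementations report, and it is the estimator under which the
  package reproduces the reference design's published operating
  characteristics and in-trial estimates.
* **posterior-mean**: `E[p_j^exp(beta) | D]`, the probability-scale
  posterior mean.  It is systematically closer to 1/2 than the plug-in
  (Jensen gap growing with posterior spread and with |log p_j|), which
  matters most early in a trial; with the same data it selects lower doses
  somewhat more often.

Both are monotone in dose and respond monotonically to added DLTs /
DLT-free patients.  The choice is a config switch (`trial.estimator`);
changing it changes operating characteristics by several percentage points,
so it is part of the design specification, not a numerical detail.

## Skeleton calibration

Skeletons come from the indifference-interval recursion: anchor
`p[nu] = phi`, then moving up solve `p_k^exp(b) = phi - delta` and set
`p_{k+1} = (phi + delta)^(1/exp(b))` (symmetrically downward).  Halfwidth
`delta = 0.05` gives (0.20, 0.30849) and (0.55, 0.64366) for the two-level
design.  **Full-precision skeleton values are used everywhere internally**;
rounding to two decimals is display-only.  This matters: with skeletons
rounded to 2 dp, simulated selection percentages shift by about two
percentage points on the two-level grid, because the dose-2 estimate's
distance to target is sensitive to the second skeleton value.

Prior variances (1.60 clinician, 1.58 patient) are least-informative
calibration outputs treated as given constants; the package does not
re-derive them.

## Posterior computation

Default quadrature is adaptive Gauss–Kronrod over the whole real line with
absolute tolerance 1e-10, integrating in the standardized variable
`u = beta / prior_sd` so that near-degenerate priors keep a resolvable
peak.  A fixed 100-node Gauss–Hermite rule scaled to the prior is the fast
alternative; the two agree to ~1e-6 or better for trial-sized data, and
both are validated against a brute-force trapezoid oracle (beta in
[-15, 15], 20,001 points) in the tests.  The likelihood is evaluated in the
log domain (`log F = exp(beta) log p`, `log(1-F) = log(-expm1(·))`) and is
finite for |beta| <= 20 with counts up to 10^4; probabilities are clipped
at 1e-300 inside logarithms only.  A normalizing constant below 1e-300
raises a quadrature error rather than returning garbage.

The simulator uses the Hermite rule and memoizes estimates on the discrete
space of count configurations (an LRU cache keyed by endpoint spec, counts
and estimator), which makes a 10,000-replicate study run in roughly a
second on one CPU.

## Dose decisions

`argmin_j |estimate_j - phi|` per endpoint, with ties (within 1e-12)
broken toward the lower dose — a conservative convention.  The combined
recommendation is the minimum of the two nominations; escalation is capped
at one level above the current dose, de-escalation may skip levels.  The
end-of-trial MTD is the dose the next cohort would have received, computed
on all accumulated data.  All user-facing dose indices are 1-based.

## Safety stopping

After every completed cohort the cumulative counts at the lowest dose are
checked per endpoint: stop if the observed DLT count reaches the smallest
`y` whose Agresti–Coull lower limit (z at the two-sided (1+conf)/2
quantile; 70% confidence by default) *strictly* exceeds the target.  The
strict reading and the two-sided quantile are the combination that
reproduces the published boundary table for both endpoints at every n from
3 to 15.  Boundaries are tabulated once per trial and are non-decreasing in
n and in the target.  A configurable dose-cap rule (stop and select when
the recommended dose already holds a given number of patients, default 16)
exists but never triggers at the 15-patient maximum.

## The 5+2 comparator

A deterministic state machine: 5 patients at level 1, optionally expanded
by 2, then 7 at level 2, with fixed count thresholds (see the module
docstring for the full rule set).  Two gap cases in the verbal rules are
resolved as follows and the resolution is load-bearing for the simulated
operating characteristics: (a) the cohort-1 "kill" thresholds (>= 2 C-DLT
and/or >= 4 P-DLT) apply unconditionally within cohort 1, dominating the
expansion rules; (b) "1 of the 7" is read inclusively as "at most 1 of 7".
Under these readings the design's exact outcome-tree probability of an
early infeasibility stop in the scenario with clinician toxicity
(0.20, 0.40) and patient toxicity (0.18, 0.35) is 42.23%, matching the
benchmark value, and the simulator is tested against the exact tree.

## Simulator

Outcomes are independent Bernoulli draws per endpoint per patient at the
assigned dose — the default study condition for all reported numbers.  A
shared-latent-uniform hook (`correlation` in (0, 1]) induces positive
dependence between the two endpoints without changing marginals, for
sensitivity analyses only.  Replicates use substreams spawned from one
`SeedSequence`, so results are reproducible and order-independent.
Operating characteristics report per-dose selection percentages (summing
with the stop percentage to 100 before rounding), early stops per endpoint,
mean patients and mean DLTs per dose, and mean sample size.  Benchmark
studies use 10,000 replicates; at that size the Monte-Carlo standard error
of a selection percentage is at most 0.5 points.

## What the simulator does not model

No staggered entry or time-to-event accrual, no dropout/replacement, no
patient covariates, no intra-cohort adaptation, and no correlation between
endpoints by default.  Passing benchmarks therefore validates the decision
logic and estimation under idealized accrual, not behavior under real-world
accrual patterns or dependent endpoints.

## Known limitations

* The two-estimator ambiguity is inherent to the method family;
  publications rarely state which quantity is tabulated.  The package makes
  it explicit and defaults to the plug-in form.
* The 5+2 machine is hard-coded to two levels and cohort sizes 5/2/7;
  generalization was deliberately excluded.
* Skeleton calibration assumes the empiric model; logistic or
  two-parameter working models are out of scope.
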