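# procrmb

Phase I dose-finding with **two toxicity endpoints**: a Bayesian continual
reassessment method (CRM) that adaptively assigns patient cohorts using both
clinician-reported DLTs (NCI-CTCAE) and patient-reported DLTs (PRO-CTCAE),
plus a rule-based 5+2 stepwise comparator and a trial simulator.

The motivating setting is a two-level hypofractionated whole-pelvis
radiotherapy trial in endometrial cancer (level 1: 41.25 Gy / 15 fractions;
level 2: 38 Gy / 10 fractions, ordered by expected toxicity), with a target
clinician DLT rate of 20% and a target patient-reported DLT rate of 55%.
The package is for trial statisticians who need to (a) simulate operating
characteristics at the design stage and (b) compute sequential dose
recommendations during trial conduct.

## Model

Each endpoint *i* (1 = clinician, 2 = patient) gets a one-parameter empiric
working model for the DLT probability at dose *x_j*:

```
pi_i(x_j) = p_i(x_j) ^ exp(beta_i),     beta_i ~ N(0, sigma_i^2)
```

where the skeleton `p_i(x_1) < ... < p_i(x_J)` holds prior guesses of the
per-dose DLT probabilities, calibrated by an indifference-interval recursion
(halfwidth delta = 0.05 here), and the prior variances (1.60 / 1.58) are
fixed design inputs.  After each cohort, the accumulated per-dose counts
update the posterior of `beta_i`; each endpoint nominates the dose whose
estimated DLT rate is closest to its target `phi_i`, and the next cohort
receives

```
gamma = min(x_1*, x_2*)      (escalation capped at one level per step)
```

Two estimators of the per-dose DLT rate are provided: the **plug-in**
estimate `p^exp(E[beta | data])` (the default, and the quantity reported by
standard CRM software) and the per-dose **posterior mean**
`E[p^exp(beta) | data]`.  Safety is monitored at the lowest dose with
Agresti–Coull 70%-confidence boundaries; the MTD is the dose the next cohort
would have received after the maximum of 15 patients.

## Worked example

Sequential use during a trial: after the first cohort of three at level 1
with no DLTs of either kind,

```
$ procrmb next --c-dlt 0,0 --c-n 3,0 --p-dlt 0,0 --p-n 3,0 --current 1
generated: 2026-09-22T19:49:26+00:00
clinician: estimates (0.02, 0.06)  target 0.2  best dose 2
patient: estimates (0.09, 0.17)  target 0.55  best dose 2
recommended next dose: level 2 (38 Gy / 10 fractions)
```

Both models have shifted well below their skeletons after three clean
patients, both endpoints nominate level 2, and the design escalates (the
no-skip rule is not binding).  Each invocation appends a timestamped JSON
record to an audit log for trial documentation.

Design-stage simulation under a scenario where the true clinician DLT
probabilities are (0.05, 0.15) and the true patient probabilities
(0.18, 0.35) — both levels safe, level 2 the target course:

```
$ procrmb simulate --scenario 1 --n-sim 10000 --seed 1
design: procrmb   scenario: 1   replicates: 10000
 dose                   label  true_c_dlt  true_p_dlt  selection_pct  mean_patients  mean_c_dlt  mean_p_dlt
    1 41.25 Gy / 15 fractions        0.05        0.18           12.6            5.6        0.29        1.02
    2    38 Gy / 10 fractions        0.15        0.35           85.6            9.2        1.38        3.20
stopped early for safety: 1.7% (clinician 1.0%, patient 0.7%)
average sample size: 14.8
skeletons: clinician (0.2, 0.31); patient (0.55, 0.64)
```

Level 2 is selected as the MTD in ~86% of replicate trials, receives 9.2 of
the 14.8 enrolled patients on average, and fewer than 2% of trials trip the
lowest-dose safety boundary.  `procrmb bounds` prints the per-endpoint
stopping tables, and `procrmb calibrate` the skeletons.

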