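# Methods

## Model

Disease course is a time-homogeneous continuous-time Markov chain on an
ordered state space: the risk categories of a prognostic score (IPSS: Low,
Int-1, Int-2, High; WPSS: Very-low, Low, Intermediate, High, Very-high),
then AML, then absorbing death. Allowed moves from a risk state are to the
next risk state, to AML, and to death; AML moves only to death. The chain
is therefore *progressive*: states never decrease, which the package
exploits both numerically (triangular generators) and in validation
(subject state sequences must be nondecreasing).

Transplantation is a time-dependent binary covariate acting on mortality:
after HSCT the death intensity of state *k* becomes `q_kD · exp(β_k)`.
Progression intensities (risk→risk, risk→AML) are left unchanged after
transplantation. Whether transplantation should also alter progression
rates is a genuinely open modelling question; we model death-only effects
because the covariate is defined as an effect on mortality, and
`apply_transplant_effects` is the single switch point where an alternative
could be implemented. Under WPSS, very-low-risk patients are not
transplant candidates, so no hazard ratio exists for that state; AML *is*
transplantable (registry cohorts contain many AML-from-MDS transplants,
and the policies below transplant on progression, which can be progression
to AML).

Time is measured in years throughout; policy delays are specified in
months and converted by t/12.

## Likelihood

Both cohorts enter one joint likelihood. For an interval of length `dt`
between consecutive observations of a subject, with `P(dt) = exp(Q_eff dt)`
and `Q_eff` the covariate-appropriate generator:

* state `j` observed at a visit (panel): `P_ij(dt)`;
* exact death, state just before death unknown: `Σ_m P_im(dt) · q_mD`;
* censored alive: `1 − P_iD(dt)`.

Intervals containing the transplant switch are split at `hsct_time` with
the state distribution propagated across the two pieces. Supportive-care
subjects contribute covariate-0 intervals from diagnosis; transplanted
subjects enter at their (known) transplant state with covariate 1 and
contribute no pre-transplant history — their time origin is
transplantation. Whether to pool the cohorts in one likelihood or estimate
hazard ratios in a second stage was an open choice; the joint likelihood
is statistically cleaner and is what `fit_model` does.

Parameters (log intensities, log hazard ratios; ≤ 20 in total) are
unconstrained on the log scale and maximized with L-BFGS-B using
finite-difference gradients (`fd: "3-point"` available when closed-form
precision is needed). Default stopping: relative log-likelihood change
1e-8, projected gradient 1e-7; fits are bit-for-bit reproducible given
identical inputs and options. The covariance is the inverse of a central
finite-difference Hessian. Intensities estimated below 1e-6/yr trigger a
boundary warning (typically: no events observed for that transition).
Non-convergence is flagged on the result, not raised.

Matrix exponentials use scipy's dense scaling-and-squaring (`expm`) for
single matrices. Inside the likelihood, where thousands of interval
lengths are evaluated per objective call, the generator's eigendecomposition
is used instead (a triangular generator with distinct diagonal entries is
diagonalisable, and `P(t) = V e^{Λt} V⁻¹` vectorises over all intervals);
the decomposition is verified against `expm` at construction and the code
falls back to per-interval `expm` if it is ill-conditioned (near-coincident
exit rates). Probabilities are clipped to [0, 1] and rows renormalised to
absorb last-ulp noise; zero-probability observations floor at 1e-300
inside optimization and raise with subject context in the reference path.

## Policy values

A policy is (threshold state s\*, delay t months, age at diagnosis a0,
eligibility age 65): no transplant below s\*; on first entry into s\* at
time u a transplant is scheduled for u + t/12 provided that lands before
the eligibility horizon; progression out of s\* before the scheduled time
— or direct progression from below s\* past it, including jumps straight
to AML — triggers immediate transplantation while age < 65; the delay
clock starts at first entry into s\* and is never restarted; a missed
schedule is never rescheduled; after age 65 no transplant ever occurs;
post-transplant evolution uses the HR-modified generator permanently.

Expected (utility-weighted) survival decomposes into:

1. expected weighted time in the pre-threshold states, `α'(−Q_B)⁻¹ w_B`
   (this phase is never interrupted, so no truncation is needed);
2. the sojourn in s\*, where the exponential sojourn races the scheduled
   transplant and the eligibility deadline — integrated in closed form;
3. post-transplant (and never-eligible) regimes, which are plain
   phase-type expectations `α'(−A)⁻¹ w`.

The only numerical step is the quadrature of the phase-type entry-time
density into s\* (and into bypass states) against the calendar-dependent
residual value, on a uniform grid of step 0.01 yr over the eligibility
horizon, split at the breakpoint where the scheduled transplant stops
fitting before the horizon (the integrand has a genuine jump there — the
policy itself is discontinuous through the eligibility deadline). The grid
rows are advanced by exact matrix-power steps, so the density itself
carries no ODE error. `policy_expected_survival` re-evaluates at step
0.005 (Richardson check) and reports the difference as its tolerance;
observed tolerances on the fixtures are ~1e-4–1e-5 yr, comfortably inside
the 1e-3 yr target.

QALY adjustment weights state occupancy: pre-transplant utilities 1.0
(very-low WPSS), 0.95 (low/intermediate WPSS; low/int-1 IPSS), 0.90
(high/very-high WPSS; int-2/high IPSS), 0.85 (AML), and a flat 0.9 for all
post-transplant survival (chronic graft-versus-host disease averaged in).
No temporal discounting is applied.

## Microsimulation

The simulator draws exact event paths: exponential total-rate sojourns
with categorical destinations (same law as per-transition competing
exponentials, fewer draws), with deterministic interrupts at the scheduled
transplant time; eligibility is checked at trigger moments. Policy
semantics are one-to-one with the algebraic engine, which is the point —
the two implementations validate each other to within Monte-Carlo error
(the acceptance suite requires |algebraic − mean| ≤ 3 SE at 200 000
paths across thresholds, delays and ages). Because the chain is
progressive, a path has at most `n_states` jumps plus one interrupt, so
whole batches are simulated in a handful of vectorised sweeps from one
seeded `numpy` Generator; results are exactly reproducible given
(seed, n). The horizon default is 120 years; truncated paths contribute
their truncated value and a warning fires if they exceed 0.1%.

## Synthetic cohorts

The generators emulate the two-cohort design the analysis assumes — they
define the conditions under which everything here is tested:

* natural-history cohort (default n = 660): entry states drawn from a
  lower-risk-skewed mix, exact paths from the true generator, panel
  observations every 0.5 yr, exact death times, administrative censoring
  at 15 yr (a plausible registry cadence; real visit schedules are
  irregular and possibly state-dependent, which is not modelled);
* transplanted cohort (default n = 477): entry at a transplant state drawn
  from an advanced-disease-skewed mix (≈ 30% AML), covariate 1 from time
  zero, evolution under the HR-modified generator, exact death or censor
  at 10 yr of follow-up — no intermediate visits, which is why per-state
  hazard ratios are the weakest-identified parameters.

Fixture parameters are **invented**: death intensities strictly increase
along the risk ordering (AML highest), and hazard ratios are 3.0 in
low-risk disease falling to 0.4 by AML, so that policy sweeps show the
directional pattern of interest — transplant-at-diagnosis harmful in the
lowest state, delay beneficial there, immediate transplantation best at
intermediate risk, and losses from delaying once at intermediate risk. In
this death-only-effect model that pattern is algebraically equivalent to
HR > 1 in the lowest state and HR < 1 from the intermediate states on:
comparing "transplant now in s" with "wait in s and transplant on exit"
reduces to comparing post- and pre-transplant death rates in s. No fixture
number is an estimate from any real cohort, and passing tests demonstrate
correctness of the machinery under these conditions, not clinical
conclusions about real MDS populations.

Parameter-recovery experiments in the test suite use larger cohorts
(5000 + 5000) and a balanced transplant entry-state mix so every hazard
ratio is informed by a comparable number of subjects; the coverage study
runs 50 replicate worlds at n = 300 + 200. The suite's problem sizes
(microsimulation at 200 000 paths, bootstrap at B = 200 on cohorts of
150 + 100 and 300 + 200 subjects) are the package's chosen demonstration
scales.

## Bootstrap

Uncertainty in policy values propagates estimation error by resampling
subjects with replacement within each cohort (preserving the two-sample
design and cohort sizes), refitting from the full-data MLE as starting
values with a slightly looser tolerance (1e-6), and recomputing the value;
intervals are percentile-based (no BCa correction — simple, and adequate
for the near-symmetric sampling distributions seen here). Replicate seeds
spawn deterministically from one `SeedSequence`, so results are exactly
reproducible; more than 20% failed refits flags the interval as
unreliable.

## Known limitations

* Time-homogeneous intensities: no age- or calendar-dependence of the
  baseline rates; the only calendar structure is the eligibility cutoff.
* Death-only transplant effects (see above); post-transplant relapse
  dynamics are absorbed into the state-specific hazard ratios.
* No misclassification of panel states, no informative visit timing, no
  frailty; risk scores are inputs, never computed from clinical variables.
* Wald intervals and the percentile bootstrap are first-order methods;
  with boundary-near intensities (zero observed events) they degrade, and
  the code warns rather than corrects.
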