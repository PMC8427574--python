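# Methods

## Deterministic transmission model

The model follows colonies of a eusocial host through two stages, foundress
and mature colony, each either carrying a phoretic symbiont ("infected") or
not. Foundress counts F_i, F_u are exogenous constants: the model deliberately
omits feedback from mature colonies to foundress production, because the
equilibrium prevalence is unchanged by it. Infected foundresses mature at rate
s_i and keep their infection with probability z; uninfected foundresses mature
at rate s_u; both mature classes die at the common rate q. The assumptions
worth stating explicitly:

* maturation chances do not depend on how long an infection lasted (a
  foundress that loses its symbiont still matures at s_i);
* infected and uninfected mature colonies share the mortality rate q
  (avirulence at the mature stage);
* strictly vertical transmission — no force-of-infection term, no spatial
  structure, no density dependence.

At the fixed point, V = M_i/(M_i+M_u) = δz/(1/J − 1 + δ) with δ = s_i/s_u and
J = F_i/(F_i+F_u). Useful sanity limits: δ = 1, z = 1 gives V = J; J = 1
gives V = z; V ≤ z always; V is nondecreasing in δ, J and z. All of these are
property-tested.

Degenerate inputs: J = 0 or δ = 0 return V = 0 by continuity so sensitivity
grids stay total; the single genuinely indeterminate point (J = 1, δ = 0)
raises `DegenerateInputError`.

The absolute rates never enter V. Where they are needed (dynamics,
simulation) the package defaults are s_u = 0.01 colonies·foundress⁻¹·yr⁻¹ and
q = 0.1 yr⁻¹ — placeholders on realistic orders of magnitude for long-lived
colonies, flagged as defaults in every report.

### Numerical integration

`integrate_dynamics` uses a fixed-step classical Runge–Kutta (RK4) scheme.
The system is linear and non-stiff for q·step < 1; the default step 0.05/q
and horizon 20/q put the final prevalence within 1e−6 of the closed form
(e^−20 ≈ 2e−9 residual transient). A step ≥ 1/q is refused: the integrator
warns and refines to 0.05/q. Tiny negative counts from round-off are clipped
at zero.

## Stochastic cohort simulator

An independent Monte-Carlo check on the algebra, not a new model. Time is
discretised to years; rates are reinterpreted as per-year probabilities (so
all of s_i, s_u, q must be ≤ 1). Each year, per replicate: the number of
infected foundresses is Binomial(N, J); maturation and symbiont retention are
one-shot binomial events at founding; mortality is applied to the colonies
standing at the start of the year, after which the year's recruits are added.
That ordering makes the stationary mean of each class exactly
(yearly inflow)/q, mirroring the continuous model; the alternative order
(recruits exposed to death in their founding year) would scale counts by
(1 − q) — a 10% bias at q = 0.1 — though the prevalence ratio is unaffected
either way.

The Monte-Carlo standard error of the mean prevalence V̂ is computed across
replicate means (replicates are independent); a single-replicate run falls
back to batch means over blocks of ≈3/q years, since colony lifetimes of
order 1/q autocorrelate the yearly series. Agreement with the closed form is
asserted at 3 SE over randomised parameter draws; with a calibrated SE about
1–2 of 100 independent draws are expected outside 3 SE by chance, so the
test allows a small number of exceedances rather than demanding all 100.

## Survival estimation

The garden-failure experiment is analysed by Cox proportional hazards with a
single binary covariate (roach presence). The partial likelihood is maximised
by Newton–Raphson with step halving (convergence: change in log-likelihood
< 1e−9 or |score| < 1e−8); the SE comes from the inverse observed
information. Daily checks make event times heavily tied, so both Breslow and
Efron corrections are implemented; they agree exactly on tie-free data. The
package default is Breslow (explicit and switchable), but note that under
heavy ties Breslow attenuates the log hazard ratio noticeably (≈ −0.06 at
500 chambers per arm in our recovery simulations) while Efron is nearly
unbiased; recovery-oriented analyses in the test suite therefore use Efron.
A treatment arm with no events makes the likelihood monotone; this is
detected and reported as a convergence error naming the arm.

Two endpoint definitions are supported. *combined* counts both "uncaring"
foundresses and foundress deaths as garden failure; *uncaring_only* counts
only uncaring and right-censors foundress deaths at the death day (censoring
rather than row deletion preserves risk sets — an interpretation choice).
Because foundress death is treatment-independent, the combined endpoint's
estimand mixes the garden effect with a null competing event and sits
slightly below the garden-failure hazard ratio; recovery of a configured
garden hazard ratio is therefore assessed on the uncaring_only endpoint.

Nest-within-flight heterogeneity is handled two ways: stratification by
flight (separate baselines), or a gamma shared frailty. The frailty model is
fitted by EM (posterior frailty means given the Breslow baseline, then a
refit with log-frailty offsets) with the frailty variance θ profiled on the
gamma marginal likelihood; boundary solutions collapse to θ = 0 and the
plain fit. This is the penalised-likelihood gamma frailty model in its
EM form; on a synthetic 96-chamber dataset with strong nest effects it
matches R `survival::coxph(… + frailty.gamma(nest))` to four decimals
(frozen as a cross-check fixture in the tests). Reported SEs condition on
θ̂, i.e. they do not propagate uncertainty in the frailty variance, and a
lognormal-frailty fit (as in `coxme`) may differ slightly. Whether a
published hazard ratio is on the frailty (conditional) or marginal scale is
often unstated; both fits are available and reported separately.

Auxiliary estimators are delegated to standard libraries: Kaplan–Meier
curves (lifelines), the 2×2 chi-square with optional Yates correction
(scipy), and binomial proportion intervals (statsmodels), with
Clopper–Pearson as the default because exact intervals are the conservative
choice at n ≈ 100 — and the only method that reproduces the printed
52.0–72.2% interval for 60/96.

The field survey summary counts a colony as infected when any sampled alate
carries a roach; V_field is the infected fraction of colonies, and the
maximum per-colony alate prevalence serves as the conservative J. Colonies
with zero sampled alates are excluded with a warning.

## Synthetic data

The survival generator emulates the experiment's structure: two flights of
53 and 43 chambers, an even treatment split, nests assigned uniformly within
flight (4 nests per flight by default — the true number per flight is
unknown, so this is a free design knob), garden-failure times exponential
under proportional hazards with a log-normal nest frailty (SD 0.3 on the log
hazard by default), and an independent, treatment-free foundress death
process (0.005/day). Times are discretised by ceiling to whole days, which
forces the tied event times the ties corrections exist for. Competing
outcomes resolve to the earliest day; a same-day collision is recorded as
foundress death, since a dead caretaker makes the garden effectively dead.
Default baseline garden hazard 0.05/day with a 60-day follow-up puts most
failures inside the observation window, and the default true hazard ratio
is 3.36. The survey generator draws 11 colonies, each infected with
probability 8/11, a few hundred to ~1200 alates per colony, and per-colony
prevalences uniform on [0.022, 0.068].

What the generators do *not* emulate: garden-mass dynamics, tending-behaviour
durations, the behavioural scoring protocol behind the disturbed/undisturbed
flags (generated as plain Bernoulli draws), non-proportional hazards, or
informative censoring. Passing tests therefore certify the estimation chain
under a proportional-hazards world with exchangeable nests, not robustness to
violations of it.

## Reproduction pipeline

`run_reproduction` assembles δ (config, or a Cox fit of a survival CSV), J
and V_field (config, or a survey CSV), and z, computes V under the supplied
δ and under δ = 1, and reports both ceilings V/V_field rounded to the
nearest percent, with V itself reported at two decimals (raw values always
retained). Every number carries a provenance tag (config / computed /
default) so conservative assumptions stay auditable. Defaults are the
conservative scenario: δ = 0.3, J = 0.07, z = 1, V_field = 0.73.

## Problem sizes used in checks

Oracle-equivalence checks use 100 random parameter draws with 20,000
foundresses/year, 120 simulated years (40 burn-in), 12 replicates; Cox
parameter recovery uses 200 replicates of 500 chambers per arm; end-to-end
recovery uses 100 seeds at the 96-chamber study scale. These sizes give
Monte-Carlo noise well below the asserted tolerances.

## Known limitations

* Strictly vertical, unstructured model: V is a ceiling, not a prediction.
* Single binary covariate in the Cox engine (all the design requires);
  no time-varying covariates or proportional-hazards diagnostics beyond KM
  comparison.
* Frailty SEs condition on the estimated frailty variance.
* The chi-square statistic printed for foundress deaths in the original
  study is not reproducible here because the underlying counts are not
  published; the estimator is implemented and tested on constructed tables.
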