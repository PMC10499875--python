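# Methods

## The problem

Radiation-epidemiology dose estimates carry measurement error of two
kinds.  Under *Berkson* error the true dose varies randomly around the
nominal (assigned) dose, and nominal dose and error are independent;
under *classical* error the observed dose varies around the true dose,
and true dose and error are independent.  Either kind may be *shared* — a
single error realisation common to a whole cohort (for instance a
dosimetry-system bias) — or *unshared* (individual-specific).  When the
dose response has curvature, error distorts the fitted shape: the
quadratic coefficient of a linear-quadratic excess-relative-risk (ERR)
model is particularly sensitive.

`sharederr` simulates a small grouped cohort under a composite
shared/unshared Berkson-classical error model and compares four
correction strategies for grouped Poisson linear-relative-risk
regression: unadjusted fitting at surrogate doses, regression calibration
(RC), extended regression calibration (ERC), and Monte Carlo maximum
likelihood (MCML).

## Cohort and error model

The synthetic cohort condenses an LSS-like person-year distribution into
K = 5 dose groups with central doses (0.01, 0.1, 0.5, 1.5, 2) Gy and
person counts (2591, 334, 438, 102, 6) — person-years scaled by 0.002.
True and surrogate doses for individual i of group k are multiplicative
lognormal perturbations of the central dose:

    D_true,i = d_k · exp[−(s_B² + u_B²)/2] · exp[s_B·ε + u_B·δ_i]
    D_surr,i = d_k · exp[−(s_C² + u_C²)/2] · exp[s_C·μ + u_C·κ_i]

with ε, μ single standard-normal draws shared by every individual of an
ensemble, δ_i, κ_i individual draws, and (s_B, u_B, s_C, u_C) the four
geometric standard deviations (GSDs; 0.2 ≙ "20%").  The leading constants
make every dose's expectation equal its central estimate exactly.  Note
that the surrogate is generated around the central dose, not around the
ensemble's true dose: true and surrogate doses are conditionally
independent given the group, which is what makes the calibration
estimators invariant to the classical GSDs.

Closed forms used as test oracles: the Pearson correlation between two
individuals' true doses is (e^{s_B²} − 1)/(e^{s_B²+u_B²} − 1), and the
between-realisation covariance of group-mean doses is dominated by the
shared component once unshared error averages out within a group.

## Dose realisation sets and case allocation

Each scenario draws one *realisation set*: n = 1000 independent true-dose
ensembles collapsed to K group means.  Its column average is the RC dose
vector, its between-realisation covariance C drives the ERC adjustment,
and its rows are the MCML support points.  The set is drawn once per
scenario and shared by all ensembles and estimators.

Each of the m = 500 dose+cancer ensembles allocates a fixed total of
N = 250 cancers by a single multinomial draw over individuals with
probability proportional to the *realisation-averaged* relative risk,

    p_i ∝ 1 + α·mean_r(D_i,r) + β·mean_r(D²_i,r),

which equals 1 + α d_i + β d_i² e^{s_B²+u_B²} up to Monte-Carlo noise;
true coefficients are α = 0.25/Gy, β = 2/Gy².  Averaging the relative
risk over the dose realisations (rather than evaluating it at a single
per-ensemble dose draw) makes the case distribution identical across
ensembles of a scenario up to multinomial noise.  This choice is what
reproduces the reported coverage pattern: it leaves the beta-coverage
degradation symmetric in the shared and unshared Berkson GSDs, whereas a
per-ensemble draw would let the shared Berkson tilt enter each ensemble's
case profile coherently and collapse unadjusted/RC beta coverage far
below the reported levels (mirroring, incorrectly, the classical-shared
rows).  The per-draw allocation is still available as
`simulate_cases(true_doses, model, rng)` for users who want the
fully conditional variant.

## Estimators

All four estimators fit the grouped Poisson model with expected counts
r_k = e^{θ₀} N_k (1 + α d_k + β d_k²), offsets N_k the group person
counts, by maximum likelihood with the intercept profiled out in closed
form (e^{θ₀} = Σc / Σ N_k RR_k) and Nelder-Mead over (α, β) from the
deterministic start (0.1, 0.5) with a fixed restart schedule and a final
polish restart.  Positivity 1 + αd + βd² > 10⁻⁶ is enforced at all
working doses.

* **Unadjusted** — working doses are the group means of one surrogate
  draw per ensemble.
* **RC** — working doses are the realisation-averaged group means
  (≈ central doses).
* **ERC** — the marginal likelihood E[L(θ; d)] over the group-mean dose
  distribution, expanded to second order around the RC dose vector d̄:

      ℓ_ERC(θ) = ℓ(θ; d̄) + log(1 + ½[∇_d ℓᵀ C ∇_d ℓ + Σ_k C_kk ∂²ℓ/∂d_k²])

  The adjustment vanishes identically when C = 0, so ERC reduces exactly
  to RC in classical-only scenarios.  Regions where the bracket is
  non-positive are treated as infeasible (the quadratic expansion stops
  being a likelihood there).  In u = e^{θ₀} the bracket is a quadratic,
  so the intercept profile is found by root-finding the score on the
  feasible u-interval containing the unadjusted intercept; a second
  feasible branch far from it is an artifact of the expansion and is not
  searched.
* **MCML** — the marginal likelihood computed exactly over the
  realisation set: ℓ_M(θ) = log mean_r exp ℓ(θ; d_r), evaluated by
  log-sum-exp (stable for spreads of >10³ log units).  Duplicate
  realisation rows are collapsed with weights, which makes the
  classical-only reduction to RC exact.  Realisations with an infeasible
  relative risk contribute zero likelihood.  The intercept is profiled by
  Newton iteration on its score (C/φ = ⟨Σ N_k RR_k⟩_w with posterior row
  weights w), with a bounded 1-D fallback.

The second-order expansion of the expected *likelihood* (not the expected
log-likelihood) was adopted for ERC after comparing both candidates: the
log-likelihood expansion ½ΣC_kk ∂²ℓ/∂d² degenerates under large shared
error (the correction term overwhelms the likelihood and drives β̂ to the
positivity boundary), while the likelihood expansion reproduces the
reported qualitative and quantitative behaviour (strong attenuation of
α̂, reduction of the upward bias in β̂, conservative coverage under
moderate Berkson error).  The exact reference form of the adjustment was
not available to this implementation, so residual systematic differences
of order 0.1 in mean α̂ and 0.2–0.8 in mean β̂ for some Berkson settings
are expected and documented rather than tuned away.

## Confidence intervals and coverage

95% profile-likelihood intervals solve 2[ℓ_max − ℓ_profile(t)] = 3.841
(χ²₁), profiling the other coefficient (1-D bounded Brent, with the
intercept handled analytically or by the solvers above) and locating the
crossing by geometric bracket expansion from the MLE plus Brent
root-finding (|Δdeviance| well below 10⁻⁴).  A side whose search hits the
positivity constraint or the search cap is flagged and counted as
non-covering — conservative and auditable.  Coverage is the percentage of
the m ensembles whose interval contains the true coefficient; mean
coefficients are averaged over converged fits, with non-converged fits
counted and excluded (none occur in the default study).

## Randomness and reproducibility

One master seed per scenario spawns independent child streams per random
component (realisation set, per-ensemble true doses, case allocation,
surrogate doses).  Streams feeding true doses and cases are keyed on the
Berkson GSDs only and the surrogate stream on the classical GSDs only, so
scenarios differing only in classical error share identical true doses,
cases and realisation sets — RC/ERC/MCML results are then bit-identical
across such scenarios, reproducing the block structure of the study
tables.  Ensembles may run concurrently without affecting results because
every ensemble consumes a pre-assigned stream.

## Diagnostics

* Interindividual correlation: sample Pearson correlation between two
  individuals' true doses, averaged over 100 disjoint pairs across the
  n realisations; the closed form above is pair-independent, so averaging
  only reduces noise.
* Group-mean correlation summary: person-weighted average off-diagonal
  correlation of the realisation set's group means.  The weighting
  matters: pairs involving the 6-person top group have correlation well
  below the shared-dominated level (the unshared error cannot average out
  over 6 individuals — closed form ≈ 0.92 at GSDs 0.2/0.2, ≈ 0.67 at
  0.5/0.2), so an unweighted minimum over pairs would not exceed 0.95
  even though the correlation "experienced" by almost all cohort members
  does.
* Dose-ratio statistic: per-ensemble mean surrogate/true dose ratio, with
  moments and histogram counts; under purely shared classical error its
  variance equals the shared lognormal variance e^{σ²} − 1 exactly.

## What the generator does and does not emulate

The cohort is a five-group fixture, not the underlying survivor data:
there is no person-time structure, no covariates, no competing risks, and
case totals are fixed rather than Poisson.  Passing tests therefore
demonstrate the estimators' behaviour under the stated error model and
grouped-likelihood conditions, not performance on individual-level cohort
data with realistic confounding.  Additive-error variants and
dose-dependent (differential) error are out of scope.

## Numerical choices

* Positivity floor 10⁻⁶ on every working relative risk; optimiser and
  profile searches treat violations as infeasible.
* Nelder-Mead tolerances xatol 10⁻⁷/fatol 10⁻⁹ plus a polish restart;
  fits match a dense grid-search oracle to 4 decimals on 3-group toys.
* Profile root-finding: brentq with xtol 10⁻⁸ after geometric bracket
  expansion; coefficient search capped at |t| = 10⁴ (cap hits are
  flagged).
* MCML intercept Newton tolerance keeps the profiled log-likelihood
  accurate to ~10⁻¹⁰; inner 1-D profiles use xtol 10⁻⁶ (the deviance
  error is quadratic in the nuisance error).
* Degenerate inputs: zero covariance short-circuits ERC to RC exactly;
  identical realisation rows collapse MCML to the grouped likelihood
  exactly; zero total cases yields a log-likelihood of 0 with the
  intercept at −∞.

## Problem sizes

The default study conditions are the reported ones: m = 500 ensembles,
n = 1000 realisations, N = 250 cases, 20 scenarios.  The acceptance
script runs the scenarios the headline results come from (two
classical-only rows and three Berkson blocks) at full m and n, restricted
per scenario to the estimators those results concern; a complete 20-row
study at full scale is available through `sharederr run-study` and takes
on the order of an hour on one CPU.
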