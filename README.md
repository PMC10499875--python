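# sharederr

Simulation and correction of **shared/unshared Berkson-classical dose
error** in grouped Poisson excess-relative-risk regression.

Radiation-epidemiology cohorts (the Japanese atomic-bomb-survivor Life
Span Study is the template here) estimate cancer risk from doses that
carry both *Berkson* error (true dose varies around the assigned dose)
and *classical* error (observed dose varies around the true dose), each
with a *shared* component common to the whole cohort and an *unshared*
individual component.  When the dose response is curved, these errors
distort the fitted shape — especially the quadratic coefficient — and
standard regression calibration can break down.  `sharederr` is for
biostatisticians studying such dose-error corrections: it simulates a
five-group LSS-like cohort under a multiplicative lognormal error model
and compares four estimators by coverage and bias.

## Model

True and surrogate doses for individual *i* of dose group *k* are

```
D_true,i = d_k · exp[−(s_B²+u_B²)/2] · exp[s_B·ε + u_B·δ_i]
D_surr,i = d_k · exp[−(s_C²+u_C²)/2] · exp[s_C·μ + u_C·κ_i]
```

with `d_k` the group central dose, `ε, μ` shared and `δ_i, κ_i`
individual standard-normal draws, and the four geometric standard
deviations (GSDs) set to 0.2 or 0.5 ("20%"/"50%").  N = 250 cancers per
ensemble are allocated multinomially with probability proportional to
the realisation-averaged relative risk `1 + α·E[D] + β·E[D²]`, with true
coefficients α = 0.25/Gy, β = 2/Gy².  Grouped Poisson
linear-relative-risk models with rates `exp(θ₀)·N_k·(1 + α d_k + β d_k²)`
are then fitted four ways:

* **unadjusted** — at the group means of one surrogate-dose draw;
* **regression calibration (RC)** — at group-mean true doses averaged
  over n = 1000 Monte-Carlo dose realisations;
* **extended regression calibration (ERC)** — RC plus a second-order
  likelihood adjustment driven by the between-realisation covariance of
  the group-mean doses (reduces exactly to RC when that covariance is
  zero);
* **Monte Carlo maximum likelihood (MCML)** — maximising the average
  over realisations of the likelihood (log-sum-exp).

All confidence intervals are 95% profile-likelihood intervals (χ²₁
threshold 3.841).  See `docs/methods.md` for assumptions, numerical
choices and limitations.

## Worked example

```bash
python examples/02_fit_four_estimators.py
```

simulates one ensemble under 50% shared / 20% unshared Berkson error and
20% classical errors, and prints:

```
cases per group: [132  34  44  36   4] (total 250)
method         alpha            95% CI    beta            95% CI
unadjusted     1.388  (-0.323, 3.636)    1.274  (-0.216, 2.753)
rc             1.619  (-0.311, 4.168)    1.559  (-0.322, 3.412)
erc            1.096  (-0.808, 4.982)    1.291  (-0.319, 4.693)
mcml           2.001  (-0.238, 7.280)    1.783  (-0.786,14.017)
```

The truth is α = 0.25, β = 2/Gy².  A single 250-case ensemble pins the
coefficients down only loosely — every interval above covers the truth —
but the pattern the full study quantifies is already visible: ERC widens
the β interval relative to RC (its adjustment accounts for the shared
dose uncertainty), and MCML widens it much more.  The per-capability scripts
in `examples/` cover dose simulation, single fits and a reduced scenario
run; the CLI runs scenarios from YAML "steering" configs:

```bash
sharederr run-scenario --gsds 0.2 0.5 0.2 0.2 --seed 1   # uB sB uC sC
sharederr run-study --out study_output                   # full 20-row tables
sharederr self-check --rows 1,2                          # compare vs reference
```

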