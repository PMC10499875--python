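"""Fit one simulated ensemble with all four dose-error estimators.

Simulates a single dose+cancer ensemble under moderate shared Berkson
error, fits the grouped Poisson linear-quadratic model four ways and
prints the point estimates with profile-likelihood 95% intervals.
"""

import numpy as np

from sharederr import (
    ErrorGSDs,
    build_realisation_set,
    default_cohort,
    default_model,
    fit_extended_rc,
    fit_mcml,
    fit_regression_calibration,
    fit_unadjusted,
    sample_surrogate_doses,
    simulate_ensemble_cases,
)

cohort = default_cohort()
model = default_model()  # alpha = 0.25/Gy, beta = 2/Gy^2, 250 cases
gsds = ErrorGSDs(share_berkson=0.5, unshare_berkson=0.2,
                 share_class=0.2, unshare_class=0.2)
rng = np.random.default_rng(7)

realisations = build_realisation_set(cohort, gsds, n=1000, rng=rng)
cases = simulate_ensemble_cases(realisations, cohort, model, rng)
surrogate = sample_surrogate_doses(cohort, gsds, rng)

print(f"cases per group: {cases.counts} (total {cases.total})")
print(f"{'method':<12}{'alpha':>8}{'95% CI':>18}{'beta':>8}{'95% CI':>18}")
for fit in (
    fit_unadjusted(surrogate, cases, cohort),
    fit_regression_calibration(realisations, cases, cohort),
    fit_extended_rc(realisations, cases, cohort),
    fit_mcml(realisations, cases, cohort),
):
    ca, cb = fit.ci_alpha, fit.ci_beta
    print(
        f"{fit.method:<12}{fit.params.alpha:8.3f}"
        f"  ({ca[0]:6.3f},{ca[1]:6.3f}) {fit.params.beta:8.3f}"
        f"  ({cb[0]:6.3f},{cb[1]:6.3f})"
    )

print(
    "\nalpha is the linear excess relative risk per Gy (truth 0.25), beta the"
    "\nquadratic term per Gy^2 (truth 2).  RC fits at the realisation-averaged"
    "\ngroup doses; extended RC adds the covariance-driven likelihood"
    "\nadjustment; MCML averages the likelihood over all dose realisations,"
    "\nwhich typically widens the beta interval."
)
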