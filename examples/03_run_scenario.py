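"""Run one study scenario end to end and summarise coverage.

Runs a reduced version (m = 50 ensembles) of the grid scenario with 20%
unshared / 50% shared Berkson error and 20% classical errors, and prints
coverage probabilities and mean coefficients per estimator.  The full
study uses m = 500; sharederr's CLI (`sharederr run-study`) reproduces
the complete 20-row tables.
"""

from sharederr import ErrorGSDs, default_scenario, run_scenario

scenario = default_scenario(
    ErrorGSDs(share_berkson=0.5, unshare_berkson=0.2,
              share_class=0.2, unshare_class=0.2),
    seed=1,
    m_ensembles=50,
)
summary = run_scenario(scenario)

print(f"scenario {scenario.label()} (m={scenario.m_ensembles}, "
      f"n={scenario.n_realisations})")
print(f"interindividual true-dose correlation: {summary.interindividual_corr:.2f} "
      "(closed form 0.845)")
print("\ncoverage of the true coefficients (alpha=0.25, beta=2), %:")
print(summary.coverage.round(1).to_string())
print("\nmean fitted coefficients over ensembles:")
print(summary.means[["alpha", "beta"]].round(3).to_string())
print(
    "\nWith large shared Berkson error the quadratic coefficient is biased"
    "\nupward for every method except extended regression calibration, and"
    "\nits nominal-95% interval under-covers for the unadjusted and RC fits;"
    "\nMCML over-covers because the marginal likelihood absorbs the shared"
    "\ndose uncertainty."
)
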