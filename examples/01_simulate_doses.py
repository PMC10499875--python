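"""Simulate true and surrogate doses under shared/unshared lognormal error.

Builds the default five-group cohort, draws one ensemble of true doses
(Berkson error: true dose varies around the group's central estimate) and
surrogate doses (classical error: observed dose varies around the truth),
and prints per-group summaries.
"""

import numpy as np

from sharederr import (
    ErrorGSDs,
    collapse_to_groups,
    default_cohort,
    sample_surrogate_doses,
    sample_true_doses,
)

cohort = default_cohort()
gsds = ErrorGSDs(
    share_berkson=0.5, unshare_berkson=0.2, share_class=0.2, unshare_class=0.2
)
rng = np.random.default_rng(42)

true = sample_true_doses(cohort, gsds, rng)
surr = sample_surrogate_doses(cohort, gsds, rng)

print(f"cohort: {cohort.n_groups} groups, {cohort.total_persons} persons")
print("group  central  mean-true  mean-surrogate")
true_means = collapse_to_groups(true.doses, cohort)
surr_means = collapse_to_groups(surr.doses, cohort)
for g, t, s in zip(cohort.groups, true_means, surr_means):
    print(f"  {g.index}    {g.central_dose:7.2f}  {t:9.3f}  {s:13.3f}")

print(
    "\nThe true-dose group means all shift by a common factor (the shared"
    "\nBerkson draw for this ensemble); the surrogate means shift by an"
    "\nindependent shared classical draw.  Averaged over many ensembles both"
    "\nconverge to the central doses (the lognormal mean correction is exact)."
)
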