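"""Case allocation under the linear-quadratic excess-relative-risk model.

A fixed total of N cancers is distributed over the cohort's individuals
with per-individual probability proportional to the relative risk
1 + alpha*D + beta*D^2, then collapsed to per-group case counts (summing
cases, averaging doses) for the grouped Poisson fits.

Two allocation variants are provided.  ``simulate_cases`` evaluates the
relative risk at a single true-dose draw.  ``simulate_ensemble_cases``
uses the realisation-averaged relative risk per individual (the mean of
1 + a*D + b*D^2 over the scenario's Monte-Carlo dose samples); this is
the allocation the study driver uses, and it makes the case distribution
identical across ensembles of a scenario up to multinomial noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, TrueModel
from .doses import RealisationSet, TrueDoseVector

__all__ = [
    "CaseCounts",
    "case_probabilities",
    "ensemble_case_probabilities",
    "simulate_cases",
    "simulate_ensemble_cases",
    "collapse_to_groups",
]


@dataclass
class CaseCounts:
    """Per-group case counts; sums to the scenario's total number of cases."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def case_probabilities(true_doses: TrueDoseVector, model: TrueModel) -> np.ndarray:
    """Normalised per-individual case probabilities lambda*(1 + a*D + b*D^2)."""
    rr = 1.0 + model.alpha * true_doses.doses + model.beta * true_doses.doses**2
    if np.any(rr <= 0):
        raise ValueError("relative risk non-positive for some individual")
    return rr / rr.sum()


def ensemble_case_probabilities(
    realisations: RealisationSet, cohort: Cohort, model: TrueModel
) -> np.ndarray:
    """Per-individual probabilities from the realisation-averaged relative risk.

    p_i is proportional to mean_r [1 + a*D_ir + b*D_ir^2] =
    1 + a*mean(D)_i + b*mean(D^2)_i.
    """
    if realisations.indiv_mean_dose is None or realisations.indiv_mean_sq is None:
        raise ValueError("realisation set lacks per-individual dose moments")
    rr = (
        1.0
        + model.alpha * realisations.indiv_mean_dose
        + model.beta * realisations.indiv_mean_sq
    )
    if np.any(rr <= 0):
        raise ValueError("relative risk non-positive for some individual")
    return rr / rr.sum()


def _allocate(
    probs: np.ndarray, group_index: np.ndarray, n_cases: int, rng: np.random.Generator
) -> CaseCounts:
    n_groups = int(group_index.max()) + 1
    if n_cases == 0:
        return CaseCounts(np.zeros(n_groups, dtype=np.int64))
    individual_cases = rng.multinomial(n_cases, probs)
    counts = np.bincount(group_index, weights=individual_cases, minlength=n_groups)
    return CaseCounts(counts.astype(np.int64))


def simulate_cases(
    true_doses: TrueDoseVector, model: TrueModel, rng: np.random.Generator
) -> CaseCounts:
    """Multinomial allocation of ``model.n_cases`` cases, collapsed to groups.

    The allocation is a single multinomial draw over individuals with
    probabilities evaluated at the given true doses; because the fitted
    data are group totals, assigning more than one case to the same
    individual is immaterial.
    """
    probs = case_probabilities(true_doses, model)
    return _allocate(probs, true_doses.group_index, model.n_cases, rng)


def simulate_ensemble_cases(
    realisations: RealisationSet,
    cohort: Cohort,
    model: TrueModel,
    rng: np.random.Generator,
) -> CaseCounts:
    """Multinomial case allocation from the realisation-averaged relative risk."""
    probs = ensemble_case_probabilities(realisations, cohort, model)
    return _allocate(probs, cohort.individual_groups, model.n_cases, rng)


def collapse_to_groups(doses: np.ndarray, cohort: Cohort) -> np.ndarray:
    """Arithmetic mean dose within each cohort group, in cohort group order."""
    doses = np.asarray(doses, dtype=float)
    if doses.size != cohort.total_persons:
        raise ValueError("dose vector length does not match cohort size")
    sums = np.bincount(cohort.individual_groups, weights=doses, minlength=cohort.n_groups)
    return sums / cohort.persons
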