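"""True/surrogate dose simulation under shared+unshared lognormal error.

True dose for individual i of group k in ensemble j:

    D_true,i,j = D_cent,k * exp[-(s_B^2 + u_B^2)/2] * exp[s_B*eps_j + u_B*delta_i,j]

with s_B/u_B the shared/unshared Berkson GSDs, eps_j a single standard
normal draw shared by every individual in the ensemble and delta_i,j
individual standard normals.  Surrogate doses mirror this with the
classical GSDs and their own shared/unshared draws.  The leading constant
makes the theoretical mean of each dose equal its group central estimate.

A ``RealisationSet`` collects the per-group means of n independent true
dose draws; its column average is the regression-calibration dose vector
and its between-realisation covariance drives the extended-regression-
calibration likelihood adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, ErrorGSDs

__all__ = [
    "TrueDoseVector",
    "SurrogateDoseVector",
    "RealisationSet",
    "sample_true_doses",
    "sample_surrogate_doses",
    "build_realisation_set",
    "interindividual_correlation",
    "interindividual_correlation_theory",
    "groupmean_correlations",
]


@dataclass
class TrueDoseVector:
    """Per-individual true doses (Gy) with group membership (0-based)."""

    doses: np.ndarray
    group_index: np.ndarray

    def __len__(self) -> int:
        return self.doses.size


@dataclass
class SurrogateDoseVector:
    """Per-individual surrogate (observed) doses (Gy) with group membership."""

    doses: np.ndarray
    group_index: np.ndarray

    def __len__(self) -> int:
        return self.doses.size


@dataclass
class RealisationSet:
    """n Monte-Carlo realisations of group-mean true doses.

    Attributes
    ----------
    matrix : (n, K) array
        Group means of each true-dose realisation.
    mean_doses : (K,) array
        Column average of ``matrix`` — the RC dose vector.
    covariance : (K, K) array
        Between-realisation covariance of the group means (zero for n = 1).
    indiv_mean_dose, indiv_mean_sq : (total_persons,) arrays
        Per-individual realisation averages of D and D^2; these define the
        case-allocation probabilities (the realisation-averaged relative
        risk per individual).
    """

    matrix: np.ndarray
    mean_doses: np.ndarray
    covariance: np.ndarray
    indiv_mean_dose: np.ndarray | None = None
    indiv_mean_sq: np.ndarray | None = None
    _unique: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_realisations(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[1]

    def unique_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct realisation rows and their weights (counts / n).

        Collapsing duplicate rows leaves the MCML marginal likelihood
        unchanged; with zero Berkson error all rows coincide and the
        marginal likelihood reduces exactly to the grouped likelihood.
        """
        if self._unique is None:
            rows, counts = np.unique(self.matrix, axis=0, return_counts=True)
            self._unique = (rows, counts / counts.sum())
        return self._unique

    def to_csv(self, path: str | Path) -> None:
        """Write the realisation matrix with a trailing covariance block."""
        import pandas as pd

        k = self.n_groups
        cols = [f"group_{i + 1}" for i in range(k)]
        frame = pd.DataFrame(self.matrix, columns=cols)
        with open(path, "w") as fh:
            frame.to_csv(fh, index=False)
            fh.write("# covariance\n")
            pd.DataFrame(self.covariance, columns=cols).to_csv(fh, index=False)


def _mean_bias(shared: float, unshared: float) -> float:
    # lognormal mean correction: E[exp(s*Z1 + u*Z2)] = exp((s^2+u^2)/2)
    return float(np.exp(-0.5 * (shared**2 + unshared**2)))


def sample_true_doses(
    cohort: Cohort, gsds: ErrorGSDs, rng: np.random.Generator
) -> TrueDoseVector:
    """Draw one ensemble of per-individual true doses (Berkson error only)."""
    s, u = gsds.share_berkson, gsds.unshare_berkson
    base = cohort.individual_central_doses
    if s == 0.0 and u == 0.0:
        doses = base.copy()
    else:
        shared = rng.standard_normal() if s > 0 else 0.0
        delta = rng.standard_normal(base.size) if u > 0 else 0.0
        doses = base * _mean_bias(s, u) * np.exp(s * shared + u * delta)
    return TrueDoseVector(doses=doses, group_index=cohort.individual_groups)


def sample_surrogate_doses(
    cohort: Cohort, gsds: ErrorGSDs, rng: np.random.Generator
) -> SurrogateDoseVector:
    """Draw one ensemble of per-individual surrogate doses (classical error only)."""
    s, u = gsds.share_class, gsds.unshare_class
    base = cohort.individual_central_doses
    if s == 0.0 and u == 0.0:
        doses = base.copy()
    else:
        shared = rng.standard_normal() if s > 0 else 0.0
        kappa = rng.standard_normal(base.size) if u > 0 else 0.0
        doses = base * _mean_bias(s, u) * np.exp(s * shared + u * kappa)
    return SurrogateDoseVector(doses=doses, group_index=cohort.individual_groups)


def build_realisation_set(
    cohort: Cohort, gsds: ErrorGSDs, n: int, rng: np.random.Generator
) -> RealisationSet:
    """Draw n true-dose realisations and collapse each to group means.

    Sampling is individual-level (one lognormal factor per person per
    realisation) with the shared Berkson deviate drawn once per
    realisation, vectorised over realisations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s, u = gsds.share_berkson, gsds.unshare_berkson
    doses = cohort.central_doses
    persons = cohort.persons
    base = cohort.individual_central_doses
    if s == 0.0 and u == 0.0:
        matrix = np.tile(doses, (n, 1))
        indiv_mean = base.copy()
        indiv_sq = base * base
    else:
        bias = _mean_bias(s, u)
        shared = np.exp(s * rng.standard_normal(n)) if s > 0 else np.ones(n)
        if u > 0:
            # per-individual factors, averaged within group; individuals are
            # ordered by group so reduceat boundaries come from cumsum
            factors = np.exp(u * rng.standard_normal((n, base.size)))
            starts = np.concatenate(([0], np.cumsum(persons)[:-1]))
            group_mean_factor = np.add.reduceat(factors, starts, axis=1) / persons
            total_factor = bias * shared[:, None] * factors
            indiv_mean = total_factor.mean(axis=0) * base
            indiv_sq = (total_factor**2).mean(axis=0) * base * base
        else:
            group_mean_factor = np.ones((n, doses.size))
            indiv_mean = bias * shared.mean() * base
            indiv_sq = bias**2 * np.mean(shared**2) * base * base
        matrix = bias * shared[:, None] * group_mean_factor * doses
    if s == 0.0 and u == 0.0:
        mean_doses = doses.copy()  # exact: every realisation is the central vector
    else:
        mean_doses = matrix.mean(axis=0)
    if n > 1 and (s > 0.0 or u > 0.0):
        covariance = np.cov(matrix, rowvar=False)
    else:
        # degenerate set: all rows identical (or a single row)
        covariance = np.zeros((doses.size, doses.size))
    return RealisationSet(
        matrix=matrix,
        mean_doses=mean_doses,
        covariance=covariance,
        indiv_mean_dose=indiv_mean,
        indiv_mean_sq=indiv_sq,
    )


def interindividual_correlation_theory(gsds: ErrorGSDs) -> float:
    """Closed-form Pearson correlation between two individuals' true doses.

    corr = (exp(s_B^2) - 1) / (exp(s_B^2 + u_B^2) - 1); undefined when both
    Berkson GSDs are zero.
    """
    s, u = gsds.share_berkson, gsds.unshare_berkson
    if s == 0.0 and u == 0.0:
        raise ValueError("correlation undefined when both Berkson GSDs are zero")
    if s == 0.0:
        return 0.0
    return float(np.expm1(s**2) / np.expm1(s**2 + u**2))


def interindividual_correlation(
    gsds: ErrorGSDs,
    n_draws: int,
    rng: np.random.Generator,
    *,
    n_pairs: int = 100,
) -> float:
    """Sample Pearson correlation between two individuals' true doses.

    Averages the pairwise sample correlation over ``n_pairs`` disjoint
    individual pairs observed across ``n_draws`` ensembles.  The central
    dose and mean-correction factors cancel in the correlation, so only
    the error factors are simulated.  Raises when both Berkson GSDs are
    zero (true doses are then degenerate and the correlation undefined).
    """
    s, u = gsds.share_berkson, gsds.unshare_berkson
    if s == 0.0 and u == 0.0:
        raise ValueError("correlation undefined when both Berkson GSDs are zero")
    shared = s * rng.standard_normal(n_draws)
    x = np.exp(shared[:, None] + u * rng.standard_normal((n_draws, 2 * n_pairs)))
    a, b = x[:, 0::2], x[:, 1::2]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    return float(np.mean(num / den))


def groupmean_correlations(rset: RealisationSet) -> np.ndarray:
    """Between-realisation correlation matrix of the group-mean doses.

    Degenerate (zero-variance) columns yield NaN entries.
    """
    sd = np.sqrt(np.diag(rset.covariance))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = rset.covariance / np.outer(sd, sd)
    return corr


def groupmean_correlation_summary(rset: RealisationSet, persons: np.ndarray) -> float:
    """Person-weighted average off-diagonal group-mean correlation.

    Pairs are weighted by the product of the two groups' person counts, so
    the summary reflects the correlation structure experienced by typical
    pairs of cohort members in different groups.  Unshared error shrinks
    with group size, so small groups (where it does not average out) carry
    correspondingly little weight.
    """
    corr = groupmean_correlations(rset)
    persons = np.asarray(persons, dtype=float)
    w = np.outer(persons, persons)
    mask = ~np.eye(corr.shape[0], dtype=bool)
    return float(np.sum(corr[mask] * w[mask]) / np.sum(w[mask]))
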