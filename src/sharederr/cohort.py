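"""Cohort structure, error-model parameters and scenario descriptors.

The default cohort is a five-group summary of an LSS-like person-year
distribution (person-years scaled by 0.002 to person counts), with group
central doses in Gy.  Dose errors are multiplicative lognormal factors
parameterised by four geometric standard deviations (GSDs, log-scale
standard deviations): shared/unshared x Berkson/classical.  A ``Scenario``
bundles cohort, error magnitudes, the true linear-quadratic risk model and
the Monte-Carlo design (number of dose+cancer ensembles ``m`` and number
of dose realisations ``n``) together with a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DoseGroup",
    "Cohort",
    "ErrorGSDs",
    "TrueModel",
    "Scenario",
    "default_cohort",
    "default_model",
    "default_scenario",
    "scenario_grid",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]

#: Default cohort fixture: (central dose Gy, persons) per dose group.
DEFAULT_GROUPS: tuple[tuple[float, int], ...] = (
    (0.01, 2591),
    (0.1, 334),
    (0.5, 438),
    (1.5, 102),
    (2.0, 6),
)

DEFAULT_ALPHA = 0.25  # ERR/Gy
DEFAULT_BETA = 2.0  # ERR/Gy^2
DEFAULT_N_CASES = 250
DEFAULT_M_ENSEMBLES = 500
DEFAULT_N_REALISATIONS = 1000


@dataclass(frozen=True)
class DoseGroup:
    """One dose group: integer label, central dose estimate and person count."""

    index: int
    central_dose: float  # Gy
    persons: int

    def __post_init__(self) -> None:
        if self.central_dose < 0:
            raise ValueError(f"central_dose must be >= 0, got {self.central_dose}")
        if self.persons < 1:
            raise ValueError(f"persons must be >= 1, got {self.persons}")


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of dose groups.

    Groups must be ordered by strictly increasing central dose and carry
    unique indices.  Convenience array views (``central_doses``,
    ``persons``, ``individual_groups``) are used throughout the simulator.
    """

    groups: tuple[DoseGroup, ...]

    def __post_init__(self) -> None:
        doses = [g.central_dose for g in self.groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("groups must be ordered by strictly increasing central dose")
        indices = [g.index for g in self.groups]
        if len(set(indices)) != len(indices):
            raise ValueError("group indices must be unique")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def central_doses(self) -> np.ndarray:
        return np.array([g.central_dose for g in self.groups], dtype=float)

    @property
    def persons(self) -> np.ndarray:
        return np.array([g.persons for g in self.groups], dtype=np.int64)

    @property
    def total_persons(self) -> int:
        return int(self.persons.sum())

    @property
    def individual_groups(self) -> np.ndarray:
        """Group membership (0-based positions) expanded to one entry per person."""
        return np.repeat(np.arange(self.n_groups), self.persons)

    @property
    def individual_central_doses(self) -> np.ndarray:
        """Central dose expanded to one entry per person."""
        return self.central_doses[self.individual_groups]


@dataclass(frozen=True)
class ErrorGSDs:
    """Log-scale standard deviations of the four multiplicative error factors.

    ``share_berkson``/``unshare_berkson`` act on true dose (Berkson: true
    dose varies around the nominal group dose); ``share_class``/
    ``unshare_class`` act on surrogate dose (classical: observed dose
    varies around the true dose).  A GSD of 0.2 corresponds to "20%" error.
    """

    share_berkson: float = 0.0
    unshare_berkson: float = 0.0
    share_class: float = 0.0
    unshare_class: float = 0.0

    def __post_init__(self) -> None:
        for name in ("share_berkson", "unshare_berkson", "share_class", "unshare_class"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def berkson_key(self) -> tuple[int, int]:
        """Integer key of the Berkson GSDs (thousandths), used for seed sharing."""
        return (round(self.unshare_berkson * 1000), round(self.share_berkson * 1000))

    @property
    def classical_key(self) -> tuple[int, int]:
        return (round(self.unshare_class * 1000), round(self.share_class * 1000))

    def label(self) -> str:
        """Compact percent label in table order (uB, sB, uC, sC), e.g. ``20502020``."""
        return "".join(
            f"{round(100 * v):02d}"
            for v in (
                self.unshare_berkson,
                self.share_berkson,
                self.unshare_class,
                self.share_class,
            )
        )


@dataclass(frozen=True)
class TrueModel:
    """True linear-quadratic ERR model and the fixed number of cases per ensemble.

    The probability of an individual with true dose D being one of the
    ``n_cases`` cancers is proportional to 1 + alpha*D + beta*D^2.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    n_cases: int = DEFAULT_N_CASES

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")

    def relative_risk(self, dose: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(dose, dtype=float)
        rr = 1.0 + self.alpha * d + self.beta * d * d
        return rr if rr.ndim else float(rr)

    def validate_positive(self, doses: Sequence[float]) -> None:
        rr = self.relative_risk(np.asarray(doses, dtype=float))
        if np.any(np.asarray(rr) <= 0):
            raise ValueError("relative risk non-positive at some dose")


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario: cohort, error magnitudes, true model, MC design."""

    cohort: Cohort
    gsds: ErrorGSDs
    model: TrueModel = field(default_factory=TrueModel)
    m_ensembles: int = DEFAULT_M_ENSEMBLES
    n_realisations: int = DEFAULT_N_REALISATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_ensembles < 1:
            raise ValueError("m_ensembles must be >= 1")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be >= 1")
        self.model.validate_positive(self.cohort.central_doses)

    def label(self) -> str:
        return self.gsds.label()


def default_cohort() -> Cohort:
    """The five-group LSS-like cohort fixture (3471 persons in total)."""
    return Cohort(
        tuple(
            DoseGroup(index=i + 1, central_dose=d, persons=n)
            for i, (d, n) in enumerate(DEFAULT_GROUPS)
        )
    )


def default_model() -> TrueModel:
    return TrueModel()


def default_scenario(gsds: ErrorGSDs | None = None, *, seed: int = 0, **kwargs) -> Scenario:
    """Scenario with the default cohort and true model; ``kwargs`` override design fields."""
    return Scenario(
        cohort=default_cohort(),
        gsds=gsds if gsds is not None else ErrorGSDs(),
        seed=seed,
        **kwargs,
    )


def scenario_grid(
    *,
    seed: int = 0,
    m_ensembles: int = DEFAULT_M_ENSEMBLES,
    n_realisations: int = DEFAULT_N_REALISATIONS,
) -> list[Scenario]:
    """The 20-scenario study grid.

    Four classical-only rows (Berkson GSDs zero, classical GSDs in
    {0.2, 0.5}^2) followed by all 16 combinations of the four GSDs over
    {0.2, 0.5}, ordered as in the study tables: unshared Berkson, shared
    Berkson, unshared classical, shared classical, each varying slowest to
    fastest.
    """
    cohort = default_cohort()
    model = TrueModel()
    levels = (0.2, 0.5)
    grid: list[Scenario] = []

    def add(ub: float, sb: float, uc: float, sc: float) -> None:
        grid.append(
            Scenario(
                cohort=cohort,
                gsds=ErrorGSDs(
                    share_berkson=sb,
                    unshare_berkson=ub,
                    share_class=sc,
                    unshare_class=uc,
                ),
                model=model,
                m_ensembles=m_ensembles,
                n_realisations=n_realisations,
                seed=seed,
            )
        )

    for uc in levels:
        for sc in levels:
            add(0.0, 0.0, uc, sc)
    for ub in levels:
        for sb in levels:
            for uc in levels:
                for sc in levels:
                    add(ub, sb, uc, sc)
    return grid


# ---------------------------------------------------------------------------
# Config (steering-file analogue): YAML serialisation of scenarios
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "cohort": [
            {"index": g.index, "central_dose": g.central_dose, "persons": g.persons}
            for g in scenario.cohort.groups
        ],
        "gsds": {
            "share_berkson": scenario.gsds.share_berkson,
            "unshare_berkson": scenario.gsds.unshare_berkson,
            "share_class": scenario.gsds.share_class,
            "unshare_class": scenario.gsds.unshare_class,
        },
        "model": {
            "alpha": scenario.model.alpha,
            "beta": scenario.model.beta,
            "n_cases": scenario.model.n_cases,
        },
        "m_ensembles": scenario.m_ensembles,
        "n_realisations": scenario.n_realisations,
        "seed": scenario.seed,
    }


def scenario_from_dict(data: dict) -> Scenario:
    cohort = Cohort(
        tuple(
            DoseGroup(index=g["index"], central_dose=g["central_dose"], persons=g["persons"])
            for g in data["cohort"]
        )
    )
    return Scenario(
        cohort=cohort,
        gsds=ErrorGSDs(**data["gsds"]),
        model=TrueModel(**data["model"]),
        m_ensembles=data["m_ensembles"],
        n_realisations=data["n_realisations"],
        seed=data["seed"],
    )


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True))


def load_scenario(path: str | Path) -> Scenario:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))
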