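import numpy as np
import pytest

from sharederr import (
    Cohort,
    DoseGroup,
    ErrorGSDs,
    TrueModel,
    default_cohort,
    default_model,
)


@pytest.fixture(scope="session")
def cohort() -> Cohort:
    return default_cohort()


@pytest.fixture(scope="session")
def model() -> TrueModel:
    return default_model()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Three small groups, including a zero-dose group."""
    return Cohort(
        (
            DoseGroup(index=1, central_dose=0.0, persons=50),
            DoseGroup(index=2, central_dose=1.0, persons=30),
            DoseGroup(index=3, central_dose=2.0, persons=20),
        )
    )


def berkson_settings() -> list[ErrorGSDs]:
    """The distinct (unshared, shared) Berkson GSD pairs of the study grid;
    classical components are irrelevant for true-dose behaviour."""
    return [
        ErrorGSDs(unshare_berkson=u, share_berkson=s)
        for u in (0.2, 0.5)
        for s in (0.2, 0.5)
    ]
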