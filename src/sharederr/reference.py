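"""Published reference values for the 20-scenario study, for self-checks.

The packaged CSV holds the reported coverage probabilities, mean fitted
coefficients and interindividual true-dose correlations for every row of
the study grid.  ``self-check`` compares a fresh run against these at the
built-in tolerances (coverage +-3 percentage points, mean alpha +-0.05,
mean beta +-0.5 — looser for beta given the skew of its estimates,
correlation +-0.03), which reflect Monte-Carlo error at m = 500.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterator

import numpy as np
import pandas as pd

from .cohort import Scenario
from .study import METHODS

COVERAGE_TOL = 3.0  # percentage points
ALPHA_TOL = 0.05  # ERR/Gy
BETA_TOL = 0.5  # ERR/Gy^2
CORR_TOL = 0.03

_GSD_COLS = ["unshare_berkson", "share_berkson", "unshare_class", "share_class"]


def load_reference() -> pd.DataFrame:
    with resources.files("sharederr.data").joinpath("reference_tables.csv").open() as fh:
        return pd.read_csv(fh)


def reference_row(scenario: Scenario, reference: pd.DataFrame | None = None) -> pd.Series:
    if reference is None:
        reference = load_reference()
    g = scenario.gsds
    match = reference[
        (reference["unshare_berkson"] == g.unshare_berkson)
        & (reference["share_berkson"] == g.share_berkson)
        & (reference["unshare_class"] == g.unshare_class)
        & (reference["share_class"] == g.share_class)
    ]
    if len(match) != 1:
        raise KeyError(f"no reference row for GSDs {g.label()}")
    return match.iloc[0]


def check_summary(
    scenario: Scenario,
    cov_row: dict,
    mean_row: dict,
    reference: pd.DataFrame | None = None,
) -> Iterator[str]:
    """Yield PASS/FAIL lines comparing a scenario summary to the reference."""
    ref = reference_row(scenario, reference)

    def line(name: str, got: float, want: float, tol: float) -> str:
        ok = abs(got - want) <= tol
        return (
            f"{'PASS' if ok else 'FAIL'} {scenario.label()} {name}: "
            f"got {got:.3f}, reference {want:.3f} (tol {tol})"
        )

    corr = cov_row.get("interindividual_corr", float("nan"))
    if not (np.isnan(corr) or pd.isna(ref["corr"])):
        yield line("interindividual_corr", corr, ref["corr"], CORR_TOL)
    for method in METHODS:
        for coef, tol in (("alpha", ALPHA_TOL), ("beta", BETA_TOL)):
            key = f"{method}_coverage_{coef}"
            if key in cov_row:
                yield line(key, cov_row[key], ref[key], COVERAGE_TOL)
            key = f"{method}_{coef}"
            if key in mean_row:
                yield line(key, mean_row[key], ref[key], tol)
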