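"""Deterministic RNG stream derivation.

Each scenario carries one master seed; independent child streams are
derived per random component (realisation set, per-ensemble true doses,
per-ensemble case allocation, per-ensemble surrogate doses).  The streams
that feed true doses and case allocation are keyed on the Berkson GSDs
only, and the surrogate stream on the classical GSDs only, so scenarios
that differ only in classical error magnitudes share identical true doses,
cases and realisation sets.  This reproduces the block structure of the
study tables, where the calibration-based estimators are invariant to the
classical error magnitudes.
"""

from __future__ import annotations

import numpy as np

from .cohort import ErrorGSDs

_REALISATION, _TRUE, _CASES, _SURROGATE, _CORRELATION = 0, 1, 2, 3, 4


def _generator(key: tuple[int, ...]) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(key)))


def realisation_rng(seed: int, gsds: ErrorGSDs) -> np.random.Generator:
    """Stream for the scenario's realisation set (Berkson-keyed)."""
    return _generator((seed, _REALISATION, *gsds.berkson_key))


def true_dose_rng(seed: int, gsds: ErrorGSDs, ensemble: int) -> np.random.Generator:
    """Stream for ensemble ``ensemble``'s true-dose draw (Berkson-keyed)."""
    return _generator((seed, _TRUE, *gsds.berkson_key, ensemble))


def case_rng(seed: int, gsds: ErrorGSDs, ensemble: int) -> np.random.Generator:
    """Stream for ensemble ``ensemble``'s case allocation (Berkson-keyed)."""
    return _generator((seed, _CASES, *gsds.berkson_key, ensemble))


def surrogate_rng(seed: int, gsds: ErrorGSDs, ensemble: int) -> np.random.Generator:
    """Stream for ensemble ``ensemble``'s surrogate-dose draw (classical-keyed)."""
    return _generator((seed, _SURROGATE, *gsds.classical_key, ensemble))


def correlation_rng(seed: int, gsds: ErrorGSDs) -> np.random.Generator:
    """Stream for the interindividual-correlation estimate (Berkson-keyed)."""
    return _generator((seed, _CORRELATION, *gsds.berkson_key))
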