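"""Seeded stratified fold assignment shared by the CV layers.

Within each stratum the members are shuffled and dealt round-robin into
k folds, so fold sizes within a stratum differ by at most one and small
strata still spread across folds.
"""

from __future__ import annotations

import numpy as np

from .core import ValidationError


def stratified_assign(strata, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each element a fold label in [0, k) stratified by ``strata``."""
    if k < 2:
        raise ValidationError(f"number of folds must be >= 2, got {k}")
    strata = np.asarray(strata)
    folds = np.empty(strata.shape[0], dtype=np.int64)
    start = 0  # rotate the dealing start so tiny strata do not pile on fold 0
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        rng.shuffle(idx)
        folds[idx] = (start + np.arange(idx.size)) % k
        start = (start + idx.size) % k
    return folds
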