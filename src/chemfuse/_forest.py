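"""Access to per-tree out-of-bag sample indices of a fitted forest."""

from __future__ import annotations

import inspect

import numpy as np
from sklearn.ensemble._forest import _generate_unsampled_indices

_NEEDS_WEIGHT = "sample_weight" in inspect.signature(
    _generate_unsampled_indices).parameters


def oob_indices(estimator, n_samples: int) -> np.ndarray:
    """Indices of the samples a given tree never saw during bootstrap."""
    if _NEEDS_WEIGHT:
        return _generate_unsampled_indices(
            estimator.random_state, n_samples, n_samples, None)
    return _generate_unsampled_indices(
        estimator.random_state, n_samples, n_samples)
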