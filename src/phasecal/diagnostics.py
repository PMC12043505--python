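"""Convergence diagnostics: split R-hat and effective sample size.

Thin wrappers over arviz so every sampler in the package reports the same
(rank-normalised) statistics on arrays shaped (chains, draws).
"""

from __future__ import annotations

import warnings

import numpy as np


def split_rhat(samples: np.ndarray) -> float:
    """Rank-normalised split R-hat for an array of shape (chains, draws)."""
    import arviz as az

    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected (chains, draws)")
    if arr.shape[0] < 2 or np.allclose(arr, arr.flat[0]):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = az.rhat(az.convert_to_dataset(arr[:, :, None]))["x"].values
        return float(np.asarray(v).reshape(-1)[0])


def effective_sample_size(samples: np.ndarray) -> float:
    """Bulk effective sample size for an array of shape (chains, draws)."""
    import arviz as az

    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected (chains, draws)")
    if np.allclose(arr, arr.flat[0]):
        return float(arr.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = az.ess(az.convert_to_dataset(arr[:, :, None]))["x"].values
        return float(np.asarray(v).reshape(-1)[0])
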