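"""Shared temporal-ICA wrapper (fixed-point, tanh contrast)."""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning


def run_temporal_ica(
    rows: np.ndarray, k: int, seed: int, max_iter: int = 1000, tol: float = 1e-6
) -> np.ndarray:
    """One temporal ICA run: sources are independent along time.

    ``rows`` is (n_rows, T); returns (k, T) source estimates.  Samples
    are time points, features are rows, so the unmixing acts on the
    time axis.  Non-convergence is tolerated per run: the ICASSO
    clustering downweights unstable estimates.
    """
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(rows.T)  # (T, k)
    return sources.T
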