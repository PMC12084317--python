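"""Trilinear (tensor) ICA of one subject's multi-echo dataset.

The data array (voxels x echoes x time) is unfolded to an
(echo*time) x voxel matrix, whitened by PCA to an MDL-selected model
order, decomposed by spatial fixed-point ICA (tanh contrast, symmetric
decorrelation), and each component's mixing column is split into an
echo-time loading and a time course by its leading rank-1
factorization.  The TE loading is what downstream classification uses
to separate BOLD from non-BOLD components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synthetic_data import MultiEchoDataset

__all__ = [
    "TensorComponent",
    "DecompositionResult",
    "estimate_order_mdl",
    "default_mask",
    "rank1_split",
    "tensor_pica",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TensorComponent:
    """(spatial map, time course, TE loading) triple for one component."""

    spatial_map: np.ndarray  # per masked voxel, unit norm
    timecourse: np.ndarray  # length T, unit variance
    te_loading: np.ndarray  # length n_echoes, mean >= 0
    variance_explained: float
    rank1_residual: float = 0.0  # fraction of mixing energy beyond rank 1


@dataclass
class DecompositionResult:
    components: list[TensorComponent]
    model_order: int
    mask: np.ndarray  # boolean voxel inclusion map (grid shape)
    diagnostics: dict = field(default_factory=dict)


def estimate_order_mdl(eigenvalues: np.ndarray, n_samples: int) -> int:
    """Minimum description length model order from a PCA spectrum.

    Wax-Kailath form: for k retained components,
    ``MDL(k) = -n (p-k) log(geoMean(lam_{k+1..p}) / arithMean(lam_{k+1..p}))
    + 0.5 k (2p - k) log n``; the estimate is the argmin over k = 0..p-1.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.ndim != 1 or len(lam) < 2:
        raise ValueError("need a 1-D spectrum with at least 2 eigenvalues")
    if np.any(lam <= 0):
        raise ValueError("eigenvalues must be positive")
    if np.any(np.diff(lam) > 1e-12 * lam[0]):
        raise ValueError("eigenvalues must be in descending order")
    p = len(lam)
    if n_samples <= p:
        raise ValueError("n_samples must exceed the number of eigenvalues")
    log_lam = np.log(lam)
    mdl = np.empty(p)
    for k in range(p):
        tail = lam[k:]
        geo = np.exp(log_lam[k:].mean())
        arith = tail.mean()
        mdl[k] = -n_samples * (p - k) * np.log(geo / arith) + 0.5 * k * (2 * p - k) * np.log(
            n_samples
        )
    return int(np.argmin(mdl))


def default_mask(dataset: MultiEchoDataset, threshold: float = 0.2) -> np.ndarray:
    """Voxels whose mean signal exceeds ``threshold`` x robust max.

    The robust max is the 98th percentile of the per-voxel mean over
    echoes and time.
    """
    mean_img = dataset.data.mean(axis=(-2, -1))
    robust_max = np.percentile(mean_img, 98)
    return mean_img > threshold * robust_max


def _smooth_volumes(data: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Gaussian-smooth each (echo, time) volume in-plane-and-through-plane."""
    sigma = fwhm_vox * FWHM_TO_SIGMA
    out = np.empty_like(data, dtype=float)
    for e in range(data.shape[-2]):
        for t in range(data.shape[-1]):
            out[..., e, t] = gaussian_filter(data[..., e, t].astype(float), sigma=sigma)
    return out


def _run_fastica(
    X: np.ndarray, k: int, seed: int, max_restarts: int, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Spatial FastICA with restarts on non-convergence.

    Each restart uses a new random start and a 10x relaxed tolerance:
    the symmetric tanh update can oscillate indefinitely on the
    near-Gaussian tail dimensions of the whitened data, while the
    super-Gaussian source components settle within the first iterations.
    ``X`` is (echo*time) x voxels; returns (sources voxels x k,
    mixing (echo*time) x k, seed used, tolerance used).
    """
    last_err: Optional[str] = None
    for attempt in range(max_restarts):
        run_seed = seed + attempt
        run_tol = tol * 10**attempt
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=run_tol,
            random_state=run_seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(X.T)  # voxels x k
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged:
            return sources, ica.mixing_, run_seed, run_tol
        last_err = f"seed {run_seed}"
    raise RuntimeError(
        f"ICA did not converge after {max_restarts} restarts (last {last_err})"
    )


def rank1_split(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Leading rank-1 factorization of an echo x time mixing matrix.

    Returns (te_loading, timecourse, residual) where residual is the
    fraction of the matrix energy beyond the leading singular triple
    (0 for an exactly rank-1 matrix).
    """
    U, svals, Vt = np.linalg.svd(M, full_matrices=False)
    te_loading = U[:, 0] * svals[0]
    tc = Vt[0]
    resid = float(1.0 - svals[0] ** 2 / (svals**2).sum())
    return te_loading, tc, resid


def tensor_pica(
    dataset: MultiEchoDataset,
    k: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
    smooth_fwhm_vox: float = 2.0,
    max_order: int = 40,
    seed: int = 0,
    max_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> DecompositionResult:
    """Decompose a multi-echo dataset into spatial/temporal/TE triples.

    Steps: mask, optional Gaussian smoothing, per-voxel-per-echo
    de-meaning, unfolding to (echo*time) x voxel, MDL order selection on
    the PCA spectrum (when ``k`` is None), spatial fixed-point ICA, and a
    leading rank-1 SVD of each mixing column into TE loading x time
    course.  Components are sign-fixed (TE loading mean >= 0, spatial
    map skew >= 0) and ordered by variance explained.
    """
    if mask is None:
        mask = default_mask(dataset)
    E, T = dataset.n_echoes, dataset.n_timepoints

    def unfold(data: np.ndarray) -> np.ndarray:
        # masked voxels x echo x time, de-meaned along time per voxel/echo
        V = data[mask].astype(float)
        V = V - V.mean(axis=-1, keepdims=True)
        return V.transpose(1, 2, 0).reshape(E * T, -1)  # (E*T) x voxels

    n_vox = int(mask.sum())
    if k is None:
        # Order selection on the UNSMOOTHED spectrum: smoothing correlates the
        # voxel samples and invalidates the iid assumption behind MDL.
        X0 = unfold(dataset.data)
        svals0 = np.linalg.svd(X0, compute_uv=False)
        eig0 = (svals0**2) / n_vox
        eig0 = eig0[eig0 > 1e-12 * eig0[0]]
        spectrum = eig0[: min(len(eig0), n_vox - 1)]
        k = estimate_order_mdl(spectrum, n_samples=n_vox)
        k = int(np.clip(k, 1, max_order))

    data = dataset.data
    if smooth_fwhm_vox > 0:
        data = _smooth_volumes(data, smooth_fwhm_vox)
    X = unfold(data)
    svals = np.linalg.svd(X, compute_uv=False)
    eig = (svals**2) / n_vox
    eig = eig[eig > 1e-12 * eig[0]]
    if k > len(eig):
        raise ValueError(f"requested order k={k} exceeds data rank {len(eig)}")

    sources, mixing, used_seed, used_tol = _run_fastica(X, k, seed, max_restarts, max_iter, tol)

    total_energy = float((X**2).sum())
    components: list[TensorComponent] = []
    for c in range(k):
        s_c = sources[:, c]
        a_c = mixing[:, c]
        comp_energy = float((s_c**2).sum() * (a_c**2).sum())
        var_exp = comp_energy / total_energy if total_energy > 0 else 0.0

        te_loading, tc, resid = rank1_split(a_c.reshape(E, T))

        # sign conventions: te_loading mean >= 0; spatial map skew >= 0
        if te_loading.mean() < 0:
            te_loading = -te_loading
            tc = -tc
        smap = s_c / np.linalg.norm(s_c)
        if np.sum(smap**3) < 0:
            smap = -smap
            tc = -tc
        sd = tc.std()
        tc = (tc - tc.mean()) / sd if sd > 0 else tc
        components.append(
            TensorComponent(
                spatial_map=smap,
                timecourse=tc,
                te_loading=te_loading,
                variance_explained=var_exp,
                rank1_residual=resid,
            )
        )
    components.sort(key=lambda comp: comp.variance_explained, reverse=True)
    diagnostics = {
        "demeaning": "per voxel per echo",
        "seed_used": used_seed,
        "ica_tol_used": used_tol,
        "n_masked_voxels": int(n_vox),
        "smooth_fwhm_vox": smooth_fwhm_vox,
        "eigenvalues": eig[: min(len(eig), 50)].tolist(),
    }
    return DecompositionResult(
        components=components, model_order=k, mask=mask, diagnostics=diagnostics
    )
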