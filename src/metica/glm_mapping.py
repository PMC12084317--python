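"""Echo combination, per-subject GLM, and permutation cluster inference.

Echoes are combined by a fixed weighted sum ([1 2 2 2] normalized) for
BOLD sensitivity, leading dummy volumes are discarded, all group
temporal components enter one first-level OLS design simultaneously
(plus intercept and linear drift), and second-level one-/two-sample
t-maps are thresholded voxelwise (p < 0.001 two-sided) with
family-wise-error control on cluster extent by a max-statistic
permutation scheme (group-label permutations, or sign flips for the
one-sample case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .synthetic_data import MultiEchoDataset
from .tensor_ica import FWHM_TO_SIGMA

__all__ = [
    "EchoCombinedSeries",
    "BetaMaps",
    "Cluster",
    "ClusterResult",
    "combine_echoes",
    "smooth_maps",
    "first_level_glm",
    "second_level_ttest",
    "cluster_fwe_permutation",
    "extract_peak_betas",
]

DEFAULT_ECHO_WEIGHTS = (1.0, 2.0, 2.0, 2.0)


@dataclass
class EchoCombinedSeries:
    data: np.ndarray  # (*grid, T - n_discarded)
    weights: np.ndarray  # per-echo, nonnegative, sum 1
    n_discarded: int
    tr_s: float
    subject_id: str
    group_label: str


@dataclass
class BetaMaps:
    betas: np.ndarray  # (n_regressors, *grid)
    regressor_names: list[str]
    design: np.ndarray  # full design matrix incl. nuisance
    subject_id: str = ""
    group_label: str = ""


@dataclass
class Cluster:
    peak_voxel: tuple[int, int, int]
    extent: int
    peak_t: float
    fwe_p: float
    label_id: int = 0  # value in ClusterResult.labeled_map


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    voxel_thresh_p: float
    n_permutations: int
    t_map: np.ndarray = field(repr=False, default=None)
    labeled_map: np.ndarray = field(repr=False, default=None)  # 0 = background
    df: int = 0

    def cluster_mask(self, cluster: Cluster) -> np.ndarray:
        return self.labeled_map == cluster.label_id


def combine_echoes(
    dataset: MultiEchoDataset,
    weights: tuple[float, ...] = DEFAULT_ECHO_WEIGHTS,
    n_discard: int = 10,
) -> EchoCombinedSeries:
    """Weighted echo sum (weights normalized to 1), dummies discarded."""
    w = np.asarray(weights, dtype=float)
    if len(w) != dataset.n_echoes:
        raise ValueError(f"{len(w)} weights for {dataset.n_echoes} echoes")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    if n_discard >= dataset.n_timepoints:
        raise ValueError("n_discard must be smaller than the number of volumes")
    w = w / w.sum()
    combined = np.tensordot(dataset.data, w, axes=([-2], [0]))
    return EchoCombinedSeries(
        data=combined[..., n_discard:],
        weights=w,
        n_discarded=n_discard,
        tr_s=dataset.tr_s,
        subject_id=dataset.subject_id,
        group_label=dataset.group_label,
    )


def smooth_maps(volume: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Gaussian smoothing of a 3-D map or a (*grid, T) series."""
    sigma = fwhm_vox * FWHM_TO_SIGMA
    if volume.ndim == 3:
        return ndimage.gaussian_filter(volume.astype(float), sigma)
    out = np.empty(volume.shape, dtype=float)
    for t in range(volume.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(volume[..., t].astype(float), sigma)
    return out


def first_level_glm(
    series: EchoCombinedSeries,
    gtc_regressors: np.ndarray,
    regressor_names: Optional[list[str]] = None,
    mask: Optional[np.ndarray] = None,
) -> BetaMaps:
    """Voxelwise OLS with all GTC regressors entered simultaneously.

    Nuisance terms are an intercept and a linear drift.  Regressors must
    already be trimmed to the post-discard series length.
    """
    G = np.atleast_2d(np.asarray(gtc_regressors, dtype=float))
    if G.shape[0] == series.data.shape[-1]:
        G = G.T  # accept (T, k) too
    k, T = G.shape
    if T != series.data.shape[-1]:
        raise ValueError(
            f"regressor length {T} != series length {series.data.shape[-1]} "
            "(trim GTCs by the same number of discarded volumes)"
        )
    names = regressor_names or [f"gtc_{i + 1}" for i in range(k)]
    drift = np.linspace(-1, 1, T)
    X = np.column_stack([G.T, np.ones(T), drift])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        u, s, vt = np.linalg.svd(X)
        null_cols = np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0]
        raise ValueError(f"rank-deficient design; collinear columns: {null_cols.tolist()}")

    grid = series.data.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    Y = series.data[mask].T  # T x voxels
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    betas = np.zeros((k,) + grid)
    for i in range(k):
        betas[i][mask] = coef[i]
    return BetaMaps(
        betas=betas,
        regressor_names=names,
        design=X,
        subject_id=series.subject_id,
        group_label=series.group_label,
    )


def _one_sample_t(B: np.ndarray) -> tuple[np.ndarray, int]:
    n = B.shape[0]
    sd = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B.mean(axis=0) / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t, n - 1


def _two_sample_t(B: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, int]:
    n1, n2 = g1.sum(), g2.sum()
    m1, m2 = B[g1].mean(axis=0), B[g2].mean(axis=0)
    v1 = B[g1].var(axis=0, ddof=1)
    v2 = B[g2].var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t[sp2 == 0] = np.nan
    return t, n1 + n2 - 2


def second_level_ttest(
    betas: np.ndarray, groups: Optional[list[str]] = None
) -> tuple[np.ndarray, int]:
    """Voxelwise one-sample t (groups=None) or pooled two-sample t.

    ``betas`` is (n_subjects, *grid).  Two-sample contrast is
    group1 - group2 with groups in sorted label order (so relabeling
    subjects negates the map).  Zero-variance voxels are NaN (masked
    out downstream).
    """
    B = np.asarray(betas, dtype=float).reshape(betas.shape[0], -1)
    if groups is None:
        if betas.shape[0] < 3:
            raise ValueError("need >= 3 subjects")
        t, df = _one_sample_t(B)
    else:
        names = sorted(set(groups))
        if len(names) != 2:
            raise ValueError("groups must contain exactly 2 levels")
        g1 = np.array([g == names[0] for g in groups])
        g2 = ~g1
        if g1.sum() < 3 or g2.sum() < 3:
            raise ValueError("need >= 3 subjects per group")
        t, df = _two_sample_t(B, g1, g2)
    return t.reshape(betas.shape[1:]), df


def _cluster_extents(
    t_map: np.ndarray, t_crit: float, structure: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray]:
    supra = np.abs(np.nan_to_num(t_map)) > t_crit
    labeled, n = ndimage.label(supra, structure=structure)
    return labeled, n, supra


def cluster_fwe_permutation(
    betas: np.ndarray,
    groups: Optional[list[str]] = None,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
) -> ClusterResult:
    """Cluster-extent FWE by the max-statistic permutation method.

    The observed |t| map is thresholded at the two-sided ``voxel_p``
    critical value; clusters use 26-connectivity by default.  The null
    distribution of the maximum cluster extent comes from group-label
    permutations (two-sample) or random sign flips (one-sample); each
    cluster's FWE p is ``(1 + #null >= extent) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n_subjects = betas.shape[0]
    grid = betas.shape[1:]
    structure = (
        np.ones((3, 3, 3), dtype=bool) if connectivity == 26 else ndimage.generate_binary_structure(3, 1)
    )

    t_map, df = second_level_ttest(betas, groups)
    t_crit = stats.t.ppf(1 - voxel_p / 2, df)
    labeled, n_clusters, _ = _cluster_extents(t_map, t_crit, structure)

    if groups is not None:
        names = sorted(set(groups))
        g_arr = np.array(groups)
        n1 = int((g_arr == names[0]).sum())
        n_distinct = comb(n_subjects, n1)
    else:
        n_distinct = 2**n_subjects
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct relabelings; capping permutations"
        )
        n_perm = n_distinct

    B = betas.reshape(n_subjects, -1)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        if groups is not None:
            perm_groups = list(rng.permutation(groups))
            t_p, _ = second_level_ttest(betas, perm_groups)
        else:
            signs = rng.choice([-1.0, 1.0], size=n_subjects)
            t_flat, _ = _one_sample_t(B * signs[:, None])
            t_p = t_flat.reshape(grid)
        lab_p, n_p, _ = _cluster_extents(t_p, t_crit, structure)
        if n_p:
            null_max[i] = np.max(ndimage.sum_labels(np.ones(grid), lab_p, np.arange(1, n_p + 1)))

    clusters = []
    for c in range(1, n_clusters + 1):
        sel = labeled == c
        extent = int(sel.sum())
        abs_t = np.where(sel, np.abs(np.nan_to_num(t_map)), -np.inf)
        peak = np.unravel_index(np.argmax(abs_t), grid)
        fwe = (1 + np.sum(null_max >= extent)) / (1 + n_perm)
        clusters.append(
            Cluster(
                peak_voxel=tuple(int(x) for x in peak),
                extent=extent,
                peak_t=float(t_map[peak]),
                fwe_p=float(fwe),
                label_id=c,
            )
        )
    clusters.sort(key=lambda cl: cl.fwe_p)
    return ClusterResult(
        clusters=clusters,
        voxel_thresh_p=voxel_p,
        n_permutations=n_perm,
        t_map=t_map,
        labeled_map=labeled,
        df=df,
    )


def extract_peak_betas(
    betas: np.ndarray, peaks: list[tuple[int, int, int]], subject_ids: Optional[list[str]] = None
) -> "pd.DataFrame":
    """Per-subject beta values at cluster peak voxels (subjects x peaks)."""
    import pandas as pd

    grid = betas.shape[1:]
    for pk in peaks:
        if any(not 0 <= pk[d] < grid[d] for d in range(3)):
            raise ValueError(f"peak {pk} outside volume of shape {grid}")
    cols = {f"peak_{i + 1}": betas[:, pk[0], pk[1], pk[2]] for i, pk in enumerate(peaks)}
    index = subject_ids or [f"sub-{i + 1:02d}" for i in range(betas.shape[0])]
    return pd.DataFrame(cols, index=index)
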