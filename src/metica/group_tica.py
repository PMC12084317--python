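"""Group temporal ICA over concatenated BOLD component time courses.

Each subject's BOLD-labeled component time courses are smoothed with a
moving average, z-scored, and stacked into one matrix (rows =
component time series).  Temporal ICA (independent sources along time)
is run repeatedly from random starts; the pooled estimates are
clustered by absolute correlation (ICASSO-style) and each cluster's
best exemplar becomes a group temporal component (GTC) with a stability
index (mean intra-cluster similarity minus mean extra-cluster
similarity, in [-1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .bold_classifier import BoldLabel
from .tensor_ica import DecompositionResult, estimate_order_mdl
from ._ica import run_temporal_ica

__all__ = [
    "GroupTimecourseMatrix",
    "GroupTemporalComponent",
    "moving_average",
    "build_group_matrix",
    "number_of_components",
    "marchenko_pastur_order",
    "run_icasso",
]


@dataclass
class GroupTimecourseMatrix:
    rows: np.ndarray  # (n_rows, T), each row unit variance
    row_index: list[tuple[str, int]]  # (subject_id, component index)

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def T(self) -> int:
        return self.rows.shape[1]


@dataclass
class GroupTemporalComponent:
    id: int
    timecourse: np.ndarray  # length T, unit variance
    mixing: np.ndarray  # per-row regression weights
    stability_iq: float
    explained_variance: float


def moving_average(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges.

    Output length equals input length so smoothed time courses stay
    aligned with stimulus regressors.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(series) < window:
        raise ValueError("series shorter than window")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    n = len(series)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def build_group_matrix(
    decompositions: dict[str, DecompositionResult],
    labels: dict[str, list[BoldLabel]],
    window: int = 5,
) -> GroupTimecourseMatrix:
    """Stack all BOLD-labeled time courses, smoothed then z-scored."""
    rows = []
    row_index = []
    contributing = 0
    for subject_id, decomp in decompositions.items():
        subject_rows = 0
        for c_idx, (comp, label) in enumerate(zip(decomp.components, labels[subject_id])):
            if not label.is_bold:
                continue
            tc = moving_average(comp.timecourse, window)
            sd = tc.std()
            if sd == 0:
                raise ValueError(
                    f"constant time course for {subject_id} component {c_idx}"
                )
            rows.append((tc - tc.mean()) / sd)
            row_index.append((subject_id, c_idx))
            subject_rows += 1
        contributing += subject_rows > 0
    if not rows:
        raise ValueError("no BOLD-labeled components across the cohort")
    if contributing < 2:
        raise ValueError("need BOLD components from at least 2 subjects")
    return GroupTimecourseMatrix(rows=np.array(rows), row_index=row_index)


def marchenko_pastur_order(matrix: GroupTimecourseMatrix) -> int:
    """Signal dimensionality: eigenvalues above the Marchenko-Pastur edge.

    For p z-scored noise rows over T samples the sample eigenvalues are
    bounded by ``(1 + sqrt(p/T))**2``; eigenvalues above that edge
    indicate shared structure.  Unlike MDL this stays calibrated when
    p/T is not small, which is the regime of concatenated cohort rows.
    Best applied to unsmoothed rows (smoothing colors the noise floor).
    """
    p, T = matrix.rows.shape
    eig = np.linalg.eigvalsh(matrix.rows @ matrix.rows.T / T)[::-1]
    edge = (1 + np.sqrt(p / T)) ** 2
    return max(int((eig > edge).sum()), 1)


def number_of_components(matrix: GroupTimecourseMatrix) -> int:
    """MDL model order on the eigenvalues of the row-space covariance."""
    R = matrix.rows
    cov = R @ R.T / matrix.T
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = eig[eig > 1e-12 * eig[0]]
    if len(eig) < 2:  # identical rows: covariance is rank 1
        return 1
    k = estimate_order_mdl(eig, n_samples=matrix.T)
    return max(k, 1)


def run_icasso(
    matrix: GroupTimecourseMatrix,
    k: int | str = "mdl",
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> list[GroupTemporalComponent]:
    """Stable group temporal components by clustering repeated ICA runs.

    Temporal ICA is run ``n_runs`` times from different random starts;
    all pooled source estimates are clustered (average linkage on
    1 - |Pearson r|) into ``k`` clusters.  Each GTC is the cluster
    member with the highest mean within-cluster similarity; its
    stability index is mean intra-cluster minus mean extra-cluster
    similarity.  GTCs are ordered by explained variance of the group
    matrix and numbered from 1.
    """
    if k == "mdl":
        k = number_of_components(matrix)
    elif k == "mp":
        k = marchenko_pastur_order(matrix)
    k = int(k)
    rank = min(matrix.n_rows, matrix.T)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")

    estimates = []  # pooled unit-variance time sources
    rng = np.random.default_rng(seed)
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        sources = run_temporal_ica(matrix.rows, k, run_seed, max_iter, tol)  # (k, T)
        for s in sources:
            estimates.append((s - s.mean()) / s.std())
    est = np.array(estimates)  # (n_runs*k, T)

    sim = np.abs(np.corrcoef(est))
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(assignment)) < k:
        raise ValueError(f"could not form {k} clusters from pooled estimates")

    gtcs = []
    n_est = est.shape[0]
    for cluster_id in np.unique(assignment):
        members = np.where(assignment == cluster_id)[0]
        outside = np.where(assignment != cluster_id)[0]
        sub = sim[np.ix_(members, members)]
        if len(members) == 1:
            intra = 1.0
            exemplar = members[0]
        else:
            off_diag = sub[~np.eye(len(members), dtype=bool)]
            intra = float(off_diag.mean())
            exemplar = members[np.argmax(sub.mean(axis=1))]
        extra = float(sim[np.ix_(members, outside)].mean()) if len(outside) else 0.0
        iq = intra - extra

        tc = est[exemplar]
        if np.sum(tc**3) < 0:  # fix the arbitrary ICA sign by positive skew
            tc = -tc
        mixing = matrix.rows @ tc / matrix.T  # per-row covariance (rows z-scored)
        exp_var = float(np.mean(mixing**2))
        gtcs.append(
            GroupTemporalComponent(
                id=0,
                timecourse=tc,
                mixing=mixing,
                stability_iq=iq,
                explained_variance=exp_var,
            )
        )
    gtcs.sort(key=lambda g: g.explained_variance, reverse=True)
    for i, g in enumerate(gtcs):
        g.id = i + 1
    return gtcs
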