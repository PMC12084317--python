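"""End-to-end orchestration on a simulated cohort.

Chains the full analysis: simulate a multi-echo cohort, decompose each
subject with tensor ICA, keep BOLD-labeled components by TE profile,
extract stable group temporal components (GTCs), correlate them with
stimulus regressors, map them voxelwise with a first-level GLM on
echo-combined data, and test group differences with permutation
cluster-extent FWE control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import bold_classifier, correlation, glm_mapping, group_tica, tensor_ica
from .stimulus_features import canonical_hrf, make_regressor
from .synthetic_data import (
    GroundTruth,
    MultiEchoDataset,
    SimulationConfig,
    simulate_cohort,
)

__all__ = [
    "PipelineResult",
    "match_timecourses",
    "planted_deficit_detected",
    "stimulus_regressors",
    "run_pipeline",
]


@dataclass
class PipelineResult:
    truth: GroundTruth
    decompositions: dict[str, tensor_ica.DecompositionResult]
    labels: dict[str, list[bold_classifier.BoldLabel]]
    group_matrix: group_tica.GroupTimecourseMatrix
    gtcs: list[group_tica.GroupTemporalComponent]
    corr: correlation.CorrelationTable
    betas: np.ndarray  # (n_subjects, n_gtcs, *grid)
    group_labels: list[str]
    cluster_results: dict[int, glm_mapping.ClusterResult] = field(default_factory=dict)
    gtc_to_source: dict[int, tuple[int, float]] = field(default_factory=dict)


def planted_deficit_detected(
    result: PipelineResult, alpha: float = 0.05, dilate: int = 1
) -> tuple[bool, bool]:
    """Did any FWE-significant cluster overlap the planted source support?

    Returns (detected_at_planted_location, any_significant_elsewhere);
    "elsewhere" means a significant cluster disjoint from the planted
    support dilated by ``dilate`` voxels (smoothing spreads true effects
    slightly beyond the support).
    """
    from scipy import ndimage

    cfg = result.truth.config
    support = result.truth.source_maps[cfg.planted_effect.source_index] > 0
    dilated = ndimage.binary_dilation(support, iterations=dilate) if dilate else support
    detected = False
    elsewhere = False
    for cres in result.cluster_results.values():
        for cl in cres.clusters:
            if cl.fwe_p >= alpha:
                continue
            cmask = cres.cluster_mask(cl)
            if (cmask & support).any():
                detected = True
            elif not (cmask & dilated).any():
                elsewhere = True
    return detected, elsewhere


def match_timecourses(estimates: np.ndarray, references: np.ndarray) -> list[tuple[int, float]]:
    """Greedy one-to-one matching of rows by maximal absolute correlation.

    Returns, per estimate row, the matched reference index and |r|.
    """
    est = np.atleast_2d(estimates)
    ref = np.atleast_2d(references)
    r = np.abs(np.corrcoef(est, ref)[: len(est), len(est):])
    matches: list[Optional[tuple[int, float]]] = [None] * len(est)
    used: set[int] = set()
    flat = [(-r[i, j], i, j) for i in range(len(est)) for j in range(len(ref))]
    for negr, i, j in sorted(flat):
        if matches[i] is None and j not in used:
            matches[i] = (j, -negr)
            used.add(j)
    # more estimates than references: fall back to best available |r|
    for i in range(len(est)):
        if matches[i] is None:
            j = int(np.argmax(r[i]))
            matches[i] = (j, float(r[i, j]))
    return matches


def stimulus_regressors(truth: GroundTruth, trim: int = 0) -> pd.DataFrame:
    """HRF-convolved per-TR regressors for every binary annotation track."""
    hrf = canonical_hrf(truth.config.tr_s)
    T = truth.config.n_timepoints
    cols = {}
    for name in truth.stimulus_tracks.binary.columns:
        per_tr = truth.stimulus_tracks.per_tr(name)[:T]
        cols[name] = make_regressor(per_tr, hrf, name=name).values[trim:]
    return pd.DataFrame(cols)


def run_pipeline(
    config: SimulationConfig,
    seed: int = 0,
    subject_k: Optional[int] = None,
    group_k: int | str = "mp",
    n_icasso_runs: int = 20,
    n_perm: int = 500,
    voxel_p: float = 0.001,
    glm_smooth_fwhm_vox: float = 2.0,
    map_group_difference: str = "planted",
    datasets: Optional[list[MultiEchoDataset]] = None,
    truth: Optional[GroundTruth] = None,
) -> PipelineResult:
    """Run simulate -> tensor ICA -> classify -> group ICA -> GLM -> clusters.

    ``map_group_difference`` selects which GTCs get the permutation
    cluster test: "planted" (the GTC best matched to the planted
    source), "all", or "none".
    """
    if datasets is None or truth is None:
        datasets, truth = simulate_cohort(config)
    te = np.asarray(config.te_ms)

    decomps: dict[str, tensor_ica.DecompositionResult] = {}
    labels: dict[str, list[bold_classifier.BoldLabel]] = {}
    for i, ds in enumerate(datasets):
        decomp = tensor_ica.tensor_pica(ds, k=subject_k, seed=seed + 1000 * i)
        decomps[ds.subject_id] = decomp
        labels[ds.subject_id] = [
            lab for _, lab in bold_classifier.classify_components(decomp, te)
        ]

    matrix = group_tica.build_group_matrix(decomps, labels)
    if group_k == "mp":
        # order from unsmoothed rows: the moving average colors the noise
        # floor that the Marchenko-Pastur edge calibrates against
        raw = group_tica.build_group_matrix(decomps, labels, window=1)
        group_k = group_tica.marchenko_pastur_order(raw)
    gtcs = group_tica.run_icasso(matrix, k=group_k, n_runs=n_icasso_runs, seed=seed)

    gtc_tc = np.array([g.timecourse for g in gtcs])
    regs = stimulus_regressors(truth)
    corr = correlation.flag_table(
        correlation.correlate_table(
            pd.DataFrame(gtc_tc.T, columns=[g.id for g in gtcs]), regs
        )
    )

    matches = match_timecourses(gtc_tc, truth.source_timecourses)
    gtc_to_source = {g.id: matches[i] for i, g in enumerate(gtcs)}

    n_discard = config.n_dummy
    trimmed = gtc_tc[:, n_discard:]
    grid = config.grid_shape
    betas = np.zeros((len(datasets), len(gtcs)) + grid)
    group_labels = [ds.group_label for ds in datasets]
    for s, ds in enumerate(datasets):
        series = glm_mapping.combine_echoes(ds, n_discard=n_discard)
        if glm_smooth_fwhm_vox > 0:
            series.data = glm_mapping.smooth_maps(series.data, glm_smooth_fwhm_vox)
        bm = glm_mapping.first_level_glm(
            series, trimmed, mask=decomps[ds.subject_id].mask
        )
        betas[s] = bm.betas

    cluster_results: dict[int, glm_mapping.ClusterResult] = {}
    if map_group_difference != "none":
        if map_group_difference == "planted":
            planted_src = config.planted_effect.source_index
            candidates = [
                i
                for i, g in enumerate(gtcs)
                if gtc_to_source[g.id][0] == planted_src
            ]
        else:
            candidates = list(range(len(gtcs)))
        for i in candidates:
            cluster_results[gtcs[i].id] = glm_mapping.cluster_fwe_permutation(
                betas[:, i],
                groups=group_labels,
                voxel_p=voxel_p,
                n_perm=n_perm,
                seed=seed + 77,
            )

    return PipelineResult(
        truth=truth,
        decompositions=decomps,
        labels=labels,
        group_matrix=matrix,
        gtcs=gtcs,
        corr=corr,
        betas=betas,
        group_labels=group_labels,
        cluster_results=cluster_results,
        gtc_to_source=gtc_to_source,
    )
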