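"""File interfaces: NIfTI volumes, TSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .group_tica import GroupTemporalComponent
from .synthetic_data import GroundTruth, MultiEchoDataset, StimulusTracks
from .tensor_ica import DecompositionResult

__all__ = [
    "write_multi_echo_nifti",
    "read_multi_echo_nifti",
    "write_cohort",
    "write_tracks_tsv",
    "write_covariates_tsv",
    "write_decomposition",
    "write_gtcs",
    "write_cluster_table",
]


def write_multi_echo_nifti(dataset: MultiEchoDataset, outdir: str | Path) -> list[Path]:
    """One 4-D NIfTI per echo, suffixed ``_echo-{i}``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in range(dataset.n_echoes):
        img = nib.Nifti1Image(dataset.data[..., e, :], affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr_s))
        p = outdir / f"{dataset.subject_id}_echo-{e + 1}_bold.nii.gz"
        nib.save(img, p)
        paths.append(p)
    sidecar = {
        "te_ms": dataset.te_ms.tolist(),
        "tr_s": dataset.tr_s,
        "group_label": dataset.group_label,
    }
    (outdir / f"{dataset.subject_id}_bold.json").write_text(json.dumps(sidecar, indent=1))
    return paths


def read_multi_echo_nifti(
    paths: list[str | Path],
    te_ms: np.ndarray,
    tr_s: float,
    subject_id: str = "sub-01",
    group_label: str = "",
) -> MultiEchoDataset:
    vols = [np.asarray(nib.load(str(p)).dataobj) for p in paths]
    data = np.stack(vols, axis=-2)
    return MultiEchoDataset(
        data=data, te_ms=te_ms, tr_s=tr_s, subject_id=subject_id, group_label=group_label
    )


def write_tracks_tsv(tracks: StimulusTracks, path: str | Path) -> None:
    """All per-frame tracks in one TSV with an ``onset_frame`` column."""
    df = pd.concat([tracks.binary, tracks.continuous], axis=1)
    df.insert(0, "onset_frame", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def write_covariates_tsv(truth: GroundTruth, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(len(truth.group_labels))],
            "group": truth.group_labels,
            "bdi": truth.symptom_scores,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_cohort(datasets: list[MultiEchoDataset], truth: GroundTruth, outdir: str | Path) -> None:
    """Per-subject per-echo NIfTI, tracks/covariates TSV, truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_multi_echo_nifti(ds, outdir / ds.subject_id)
    write_tracks_tsv(truth.stimulus_tracks, outdir / "stimulus_tracks.tsv")
    write_covariates_tsv(truth, outdir / "covariates.tsv")
    np.savez_compressed(
        outdir / "ground_truth.npz",
        source_maps=truth.source_maps,
        source_timecourses=truth.source_timecourses,
        te_profiles=truth.te_profiles,
        subject_amplitudes=truth.subject_amplitudes,
        symptom_scores=truth.symptom_scores,
    )
    meta = {
        "labels": truth.labels,
        "group_labels": truth.group_labels,
        "source_stimulus": {str(k): v for k, v in truth.source_stimulus.items()},
        "noise_sd": truth.noise_sd,
        "te_ms": list(truth.config.te_ms),
        "tr_s": truth.config.tr_s,
        "seed": truth.config.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=1))


def write_decomposition(result: DecompositionResult, outdir: str | Path) -> None:
    """Spatial maps as 4-D NIfTI, time courses/TE loadings as TSV, JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = result.mask.shape
    maps4d = np.zeros(grid + (len(result.components),))
    for i, comp in enumerate(result.components):
        vol = np.zeros(grid)
        vol[result.mask] = comp.spatial_map
        maps4d[..., i] = vol
    nib.save(nib.Nifti1Image(maps4d, affine=np.eye(4)), outdir / "component_maps.nii.gz")
    pd.DataFrame({f"comp_{i + 1}": c.timecourse for i, c in enumerate(result.components)}).to_csv(
        outdir / "timecourses.tsv", sep="\t", index=False
    )
    pd.DataFrame({f"comp_{i + 1}": c.te_loading for i, c in enumerate(result.components)}).to_csv(
        outdir / "te_loadings.tsv", sep="\t", index=False
    )
    diag = dict(result.diagnostics)
    diag["model_order"] = result.model_order
    diag["variance_explained"] = [c.variance_explained for c in result.components]
    (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=1))


def write_gtcs(gtcs: list[GroupTemporalComponent], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({f"gtc_{g.id}": g.timecourse for g in gtcs}).to_csv(
        outdir / "gtc_timecourses.tsv", sep="\t", index=False
    )
    meta = {
        f"gtc_{g.id}": {
            "stability_iq": g.stability_iq,
            "explained_variance": g.explained_variance,
        }
        for g in gtcs
    }
    (outdir / "gtc_stability.json").write_text(json.dumps(meta, indent=1))


def write_cluster_table(clusters, path: str | Path) -> None:
    """Cluster table: blank region label, peak coordinate, extent, T, FWE p."""
    rows = [
        {
            "region": "",
            "x": c.peak_voxel[0],
            "y": c.peak_voxel[1],
            "z": c.peak_voxel[2],
            "T": c.peak_t,
            "k_E": c.extent,
            "p_FWE": c.fwe_p,
        }
        for c in clusters
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
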