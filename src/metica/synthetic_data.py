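"""Synthetic multi-echo fMRI cohorts with known ground truth.

The generator emulates a naturalistic-viewing multi-echo acquisition:
4 echoes (13/28/43/57 ms), TR = 1 s, a two-group cohort (healthy
controls vs patients), spatially compact latent sources whose echo-time
loading is either BOLD-like (bell-shaped, ``TE * exp(-TE/T2*)``) or
artifactual (monotone decay or TE-constant), stimulus-locked time
courses built from annotation tracks, a planted regional amplitude
deficit in the patient group, and symptom scores correlated with the
planted amplitude.

Every downstream stage of the pipeline (tensor ICA, TE classification,
group temporal ICA, GLM mapping, clinical statistics) is testable
against the returned :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .stimulus_features import canonical_hrf, make_regressor

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "StimulusTracks",
    "GroundTruth",
    "MultiEchoDataset",
    "simulate_stimulus_tracks",
    "simulate_cohort",
]

BINARY_TRACK_NAMES = ("language", "face", "music", "negative_face")
CONTINUOUS_TRACK_NAMES = ("motion_energy", "loudness")


@dataclass
class PlantedEffect:
    """A group amplitude deficit on one source.

    The patient group's loading on ``source_index`` is multiplied by
    ``amplitude_ratio`` (1.0 = no effect).  ``voxel_mask`` optionally
    restricts the deficit to a sub-region of the source map; by default
    the whole source is affected.
    """

    source_index: int = 0
    amplitude_ratio: float = 0.5
    voxel_mask: Optional[np.ndarray] = None


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    n_timepoints: int = 310  # includes n_dummy leading volumes
    tr_s: float = 1.0
    te_ms: tuple[float, ...] = (13.0, 28.0, 43.0, 57.0)
    n_subjects_per_group: int = 8
    n_bold_sources: int = 4
    n_nonbold_sources: int = 3
    t2star_range_ms: tuple[float, float] = (30.0, 48.0)
    snr: float = 2.0  # source amplitude SD / thermal noise SD
    planted_effect: PlantedEffect = field(default_factory=PlantedEffect)
    symptom_effect_r: float = -0.4
    n_dummy: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if te.ndim != 1 or len(te) < 2:
            raise ValueError("te_ms must list at least two echo times")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_ms must be strictly increasing and positive")
        if any(g <= 0 for g in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        n_sources = self.n_bold_sources + self.n_nonbold_sources
        if int(np.prod(self.grid_shape)) < 8 * n_sources:
            raise ValueError("grid too small: need >= 8 voxels per source")
        if self.n_timepoints <= 0 or self.tr_s <= 0:
            raise ValueError("n_timepoints and tr_s must be positive")
        if self.n_subjects_per_group <= 0:
            raise ValueError("n_subjects_per_group must be positive")
        if not np.isinf(self.snr) and self.snr <= 0:
            raise ValueError("snr must be positive (or inf for noiseless)")
        if not 0 < self.planted_effect.amplitude_ratio <= 1:
            raise ValueError("planted amplitude_ratio must be in (0, 1]")
        if not 0 <= self.planted_effect.source_index < n_sources:
            raise ValueError(
                f"planted source index {self.planted_effect.source_index} out of "
                f"range for {n_sources} sources"
            )
        lo, hi = self.t2star_range_ms
        if not 0 < lo < hi:
            raise ValueError("t2star_range_ms must be a positive increasing interval")

    @property
    def n_sources(self) -> int:
        return self.n_bold_sources + self.n_nonbold_sources


@dataclass
class StimulusTracks:
    """Per-frame annotation and feature tracks for one stimulus run."""

    binary: pd.DataFrame  # frames x binary tracks (0/1)
    continuous: pd.DataFrame  # frames x continuous positive tracks
    fps: float
    tr_s: float

    @property
    def n_frames(self) -> int:
        return len(self.binary)

    def per_tr(self, name: str) -> np.ndarray:
        """Within-TR mean of a track (fraction active for binary tracks)."""
        frames_per_tr = int(round(self.fps * self.tr_s))
        df = self.binary if name in self.binary.columns else self.continuous
        vals = df[name].to_numpy()
        n_tr = len(vals) // frames_per_tr
        return vals[: n_tr * frames_per_tr].reshape(n_tr, frames_per_tr).mean(axis=1)


@dataclass
class GroundTruth:
    source_maps: np.ndarray  # (n_sources, *grid_shape), nonneg, max 1
    source_timecourses: np.ndarray  # (n_sources, T), unit variance
    te_profiles: np.ndarray  # (n_sources, n_echoes), max 1
    labels: list[str]  # "BOLD" | "non-BOLD" per source
    subject_amplitudes: np.ndarray  # (n_subjects, n_sources), planted effect applied
    symptom_scores: np.ndarray  # (n_subjects,)
    group_labels: list[str]  # "HC" | "MDD" per subject
    t2star_ms: np.ndarray  # per-source T2* (nan for TE-constant profiles)
    stimulus_tracks: StimulusTracks
    source_stimulus: dict[int, str]  # source index -> driving track name
    noise_sd: float
    config: SimulationConfig


@dataclass
class MultiEchoDataset:
    """One subject's 4-D voxel grid x echo x time signal."""

    data: np.ndarray  # (*grid_shape, n_echoes, T)
    te_ms: np.ndarray
    tr_s: float
    subject_id: str
    group_label: str

    def __post_init__(self) -> None:
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.data.shape[-2] != len(self.te_ms):
            raise ValueError("echo axis length must equal len(te_ms)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[-2]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]


def simulate_stimulus_tracks(
    n_timepoints: int,
    fps: float = 25.0,
    tr_s: float = 1.0,
    seed: int = 0,
    on_seconds: tuple[float, float] = (1.0, 30.0),
    off_seconds: tuple[float, float] = (1.0, 30.0),
) -> StimulusTracks:
    """Generate blockwise binary annotation tracks and continuous tracks.

    Binary tracks (language, face, music, negative face) alternate
    active/inactive runs with durations drawn uniformly from
    ``on_seconds`` / ``off_seconds``.  Continuous tracks are smooth and
    strictly positive.  Frame count = ``n_timepoints * tr_s * fps``.
    """
    if fps < 1:
        raise ValueError("fps must be >= 1")
    if n_timepoints < 32:
        raise ValueError("n_timepoints must be >= 32")
    for fieldname, (lo, hi) in (("on_seconds", on_seconds), ("off_seconds", off_seconds)):
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"{fieldname} durations must be positive with hi >= lo")
    rng = np.random.default_rng(seed)
    n_frames = int(round(n_timepoints * tr_s * fps))

    binary = {}
    for name in BINARY_TRACK_NAMES:
        track = np.zeros(n_frames, dtype=float)
        pos = 0
        state = bool(rng.integers(0, 2))
        while pos < n_frames:
            lo, hi = on_seconds if state else off_seconds
            run = int(round(rng.uniform(lo, hi) * fps))
            run = max(run, 1)
            if state:
                track[pos : pos + run] = 1.0
            pos += run
            state = not state
        binary[name] = track

    continuous = {}
    for name in CONTINUOUS_TRACK_NAMES:
        raw = gaussian_filter1d(rng.standard_normal(n_frames), sigma=fps / 2.0)
        continuous[name] = np.exp(raw / max(raw.std(), 1e-12))  # positive, lognormal-like
    return StimulusTracks(
        binary=pd.DataFrame(binary),
        continuous=pd.DataFrame(continuous),
        fps=fps,
        tr_s=tr_s,
    )


def _brain_mask_and_baseline(grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal brain mask and a smooth positive mean image inside it."""
    axes = [np.linspace(-1, 1, n) for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    rho2 = (xx / 0.9) ** 2 + (yy / 0.9) ** 2 + (zz / 0.9) ** 2
    mask = rho2 <= 1.0
    baseline = 100.0 * np.exp(-0.5 * rho2) * mask
    return mask, baseline


def _compact_source_maps(
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    n_sources: int,
    rng: np.random.Generator,
    sigma_vox: float = 1.3,
    support_radius: float = 3.0,
) -> np.ndarray:
    """Gaussian blobs with compact connected support, max value 1."""
    coords = np.argwhere(mask)
    # keep centers away from the mask boundary so supports stay inside
    interior = coords[
        (coords[:, 0] > 1)
        & (coords[:, 0] < grid_shape[0] - 2)
        & (coords[:, 1] > 1)
        & (coords[:, 1] < grid_shape[1] - 2)
        & (coords[:, 2] > 0)
        & (coords[:, 2] < grid_shape[2] - 1)
    ]
    centers: list[np.ndarray] = []
    min_sep = 2 * support_radius * 0.8
    for _ in range(5000):
        if len(centers) == n_sources:
            break
        cand = interior[rng.integers(len(interior))]
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < n_sources:
        # grid too crowded for full separation: relax to best effort
        while len(centers) < n_sources:
            centers.append(interior[rng.integers(len(interior))])
    grids = np.indices(grid_shape).reshape(3, -1).T
    maps = np.zeros((n_sources,) + grid_shape)
    for s, c in enumerate(centers):
        d2 = ((grids - c) ** 2).sum(axis=1).reshape(grid_shape)
        blob = np.exp(-d2 / (2 * sigma_vox**2))
        blob[np.sqrt(d2) > support_radius] = 0.0
        blob *= mask
        maps[s] = blob / blob.max()
    return maps


def _stimulus_locked_timecourse(
    tracks: StimulusTracks, name: str, n_timepoints: int, hrf: np.ndarray
) -> np.ndarray:
    per_tr = tracks.per_tr(name)[:n_timepoints]
    reg = make_regressor(per_tr, hrf, name=name)
    return reg.values


def _orthogonalized_random_timecourse(
    existing: list[np.ndarray], n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth bursty random series residualized against existing sources.

    Cubing the smoothed Gaussian gives the heavy-tailed (super-Gaussian)
    marginal typical of spontaneous activity bursts; independent
    component estimation is only identifiable for non-Gaussian sources.
    """
    raw = gaussian_filter1d(rng.standard_normal(n_timepoints), sigma=1.5)
    raw = raw**3
    if existing:
        basis = np.column_stack(existing)
        beta, *_ = np.linalg.lstsq(basis, raw, rcond=None)
        raw = raw - basis @ beta
    raw = raw - raw.mean()
    return raw / raw.std()


def _source_timecourses(
    config: SimulationConfig, tracks: StimulusTracks, rng: np.random.Generator
) -> tuple[np.ndarray, dict[int, str]]:
    """Unit-variance time courses, near-orthogonal by construction.

    The first half of the BOLD sources are HRF-convolved annotation
    tracks (regenerating offending tracks keeps pairwise |r| < 0.2);
    remaining sources are smooth noise residualized against all earlier
    time courses.
    """
    T = config.n_timepoints
    hrf = canonical_hrf(config.tr_s)
    n_stim = min(config.n_bold_sources // 2 + config.n_bold_sources % 2, len(BINARY_TRACK_NAMES))
    courses: list[np.ndarray] = []
    source_stimulus: dict[int, str] = {}
    for i in range(n_stim):
        name = BINARY_TRACK_NAMES[i]
        tc = _stimulus_locked_timecourse(tracks, name, T, hrf)
        for attempt in range(50):
            if not courses or max(abs(np.corrcoef(np.array(courses + [tc]))[-1, :-1])) < 0.2:
                break
            alt = simulate_stimulus_tracks(
                config.n_timepoints, tracks.fps, config.tr_s, seed=int(rng.integers(2**31))
            )
            tc = _stimulus_locked_timecourse(alt, name, T, hrf)
            tracks.binary[name] = alt.binary[name].to_numpy()
        courses.append(tc)
        source_stimulus[i] = name
    while len(courses) < config.n_sources:
        courses.append(_orthogonalized_random_timecourse(courses, T, rng))
    return np.array(courses), source_stimulus


def _te_profiles(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], np.ndarray]:
    te = np.asarray(config.te_ms)
    profiles = np.zeros((config.n_sources, len(te)))
    labels: list[str] = []
    t2stars = np.full(config.n_sources, np.nan)
    lo, hi = config.t2star_range_ms
    for s in range(config.n_bold_sources):
        t2 = rng.uniform(lo, hi)
        prof = te * np.exp(-te / t2)
        profiles[s] = prof / prof.max()
        labels.append("BOLD")
        t2stars[s] = t2
    for j in range(config.n_nonbold_sources):
        s = config.n_bold_sources + j
        if config.n_nonbold_sources >= 2 and j == config.n_nonbold_sources - 1:
            profiles[s] = np.ones(len(te))  # TE-constant artifact variant
        else:
            t2 = rng.uniform(20.0, 60.0)
            prof = np.exp(-te / t2)
            profiles[s] = prof / prof.max()
            t2stars[s] = t2
        labels.append("non-BOLD")
    return profiles, labels, t2stars


def _symptom_scores(
    planted_amp: np.ndarray, target_r: float, rng: np.random.Generator
) -> np.ndarray:
    """BDI-like scores with exact sample correlation ``target_r`` to the
    planted amplitude (noise residualized against the amplitude)."""
    z = (planted_amp - planted_amp.mean()) / planted_amp.std()
    eps = rng.standard_normal(len(z))
    eps = eps - z * (eps @ z) / (z @ z)
    eps = eps - eps.mean()
    eps = eps / eps.std()
    score_z = target_r * z + np.sqrt(1 - target_r**2) * eps
    return 15.0 + 10.0 * score_z


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[MultiEchoDataset], GroundTruth]:
    """Simulate a two-group multi-echo cohort from the forward model

    ``signal(v, e, t) = baseline(v, e)
    + sum_c a_sc * m_c(v) * b_c(TE_e) * s_c(t) + drift + noise``

    with subject amplitudes ``a``, compact nonnegative maps ``m``,
    TE profiles ``b`` and unit-variance time courses ``s``.  The planted
    effect multiplies the patient group's loading on one source; symptom
    scores correlate with that loading at the configured r.
    """
    rng = np.random.default_rng(config.seed)
    n_subjects = 2 * config.n_subjects_per_group
    noise_sd = 0.0 if np.isinf(config.snr) else 1.0 / config.snr

    mask, baseline = _brain_mask_and_baseline(config.grid_shape)
    maps = _compact_source_maps(config.grid_shape, mask, config.n_sources, rng)
    tracks = simulate_stimulus_tracks(
        config.n_timepoints, tr_s=config.tr_s, seed=int(rng.integers(2**31))
    )
    courses, source_stimulus = _source_timecourses(config, tracks, rng)
    profiles, labels, t2stars = _te_profiles(config, rng)

    group_labels = ["HC"] * config.n_subjects_per_group + ["MDD"] * config.n_subjects_per_group
    amplitudes = np.exp(0.2 * rng.standard_normal((n_subjects, config.n_sources)))
    planted = config.planted_effect
    is_mdd = np.array([g == "MDD" for g in group_labels])
    if planted.voxel_mask is None:
        amplitudes[is_mdd, planted.source_index] *= planted.amplitude_ratio

    symptom = _symptom_scores(amplitudes[:, planted.source_index], config.symptom_effect_r, rng)

    te = np.asarray(config.te_ms)
    baseline_e = baseline[..., None] * np.exp(-te / 40.0)  # (grid, E)
    T = config.n_timepoints
    t_lin = np.linspace(-1, 1, T)
    t_quad = (3 * t_lin**2 - 1) / 2.0
    t_lin = t_lin / t_lin.std()
    t_quad = t_quad / t_quad.std()

    datasets: list[MultiEchoDataset] = []
    for s_idx in range(n_subjects):
        data = np.broadcast_to(baseline_e[..., None], config.grid_shape + (len(te), T)).astype(
            np.float64
        ).copy()
        for c in range(config.n_sources):
            m = maps[c]
            if (
                c == planted.source_index
                and planted.voxel_mask is not None
                and is_mdd[s_idx]
            ):
                m = np.where(planted.voxel_mask, m * planted.amplitude_ratio, m)
            term = amplitudes[s_idx, c] * (
                m[..., None, None] * profiles[c][:, None] * courses[c][None, :]
            )
            data += term
        if noise_sd > 0:
            data += noise_sd * rng.standard_normal(data.shape)
            drift_coef = 0.3 * noise_sd * rng.standard_normal(config.grid_shape + (len(te), 2))
            data += drift_coef[..., 0:1] * t_lin + drift_coef[..., 1:2] * t_quad
        datasets.append(
            MultiEchoDataset(
                data=data.astype(np.float32),
                te_ms=te,
                tr_s=config.tr_s,
                subject_id=f"sub-{s_idx + 1:02d}",
                group_label=group_labels[s_idx],
            )
        )

    truth = GroundTruth(
        source_maps=maps,
        source_timecourses=courses,
        te_profiles=profiles,
        labels=labels,
        subject_amplitudes=amplitudes,
        symptom_scores=symptom,
        group_labels=group_labels,
        t2star_ms=t2stars,
        stimulus_tracks=tracks,
        source_stimulus=source_stimulus,
        noise_sd=noise_sd,
        config=config,
    )
    return datasets, truth
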