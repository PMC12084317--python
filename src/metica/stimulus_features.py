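"""Audio/visual stimulus features and HRF-convolved regressors.

Basic per-frame video features (luminance, temporal contrast, local
contrast) and windowed audio features (sound pressure level, envelope)
are computed from raw arrays, aggregated into per-TR series, and turned
into regressors by convolution with a canonical double-gamma hemodynamic
response function followed by z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.stats import gamma as gamma_dist

__all__ = [
    "FrameSeries",
    "FeatureTrack",
    "FeatureRegressor",
    "extract_video_features",
    "extract_audio_features",
    "aggregate_to_tr",
    "canonical_hrf",
    "make_regressor",
]

AGGREGATE_STATS = ("mean", "std", "msq")


@dataclass
class FrameSeries:
    """Time-ordered stack of grayscale frames with intensities in [0, 1]."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, height, width) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.fps < 1:
            raise ValueError("fps must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class FeatureTrack:
    """A named per-sample feature series with its sampling rate (Hz)."""

    name: str
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class FeatureRegressor:
    """Per-TR regressor; z-scored, optionally HRF-convolved.

    ``constant_input`` marks degenerate (all-constant) inputs whose
    regressor is identically zero rather than undefined.
    """

    name: str
    values: np.ndarray
    convolved: bool = True
    constant_input: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def extract_video_features(frames: FrameSeries) -> dict[str, FeatureTrack]:
    """Compute luminance, temporal contrast and local contrast per frame.

    luminance[t]
        mean pixel intensity of frame t.
    temporal_contrast[t]
        mean absolute frame-to-frame intensity difference (0 for the
        first frame).
    local_contrast[t]
        mean over pixels of the mean absolute difference between each
        pixel and its 8-connected neighbors; edge pixels use only the
        neighbors that exist.
    """
    if frames.n_frames < 2:
        raise ValueError("need at least 2 frames")
    f = frames.frames
    luminance = f.mean(axis=(1, 2))

    temporal = np.zeros(frames.n_frames)
    temporal[1:] = np.abs(np.diff(f, axis=0)).mean(axis=(1, 2))

    local = _local_contrast(f)
    return {
        "luminance": FeatureTrack("luminance", luminance, frames.fps),
        "temporal_contrast": FeatureTrack("temporal_contrast", temporal, frames.fps),
        "local_contrast": FeatureTrack("local_contrast", local, frames.fps),
    }


def _local_contrast(f: np.ndarray) -> np.ndarray:
    """Mean over pixels of mean |pixel - 8-neighbor| with shrinking edges."""
    n, h, w = f.shape
    diff_sum = np.zeros_like(f)
    count = np.zeros((h, w))
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for di, dj in shifts:
        src_i = slice(max(0, -di), h - max(0, di))
        src_j = slice(max(0, -dj), w - max(0, dj))
        dst_i = slice(max(0, di), h - max(0, -di))
        dst_j = slice(max(0, dj), w - max(0, -dj))
        diff_sum[:, dst_i, dst_j] += np.abs(f[:, dst_i, dst_j] - f[:, src_i, src_j])
        count[dst_i, dst_j] += 1
    per_pixel = diff_sum / count[None, :, :]
    return per_pixel.mean(axis=(1, 2))


def extract_audio_features(
    waveform: np.ndarray,
    sample_rate: float,
    window_s: float,
    spl_floor_db: float = -100.0,
    envelope_on: str = "spl",
) -> dict[str, FeatureTrack]:
    """Windowed sound pressure level (dB re full scale) and envelope.

    SPL per non-overlapping window is ``20*log10(RMS / 1.0)`` with a
    floor of ``spl_floor_db`` for silence.  The envelope is the squared
    magnitude of the analytic signal of the SPL series
    (``envelope_on="spl"``); set ``envelope_on="waveform"`` for the
    conventional waveform-based variant (squared analytic magnitude of
    the waveform, averaged per window).
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    n_win_samples = int(round(window_s * sample_rate))
    if n_win_samples < 8:
        raise ValueError("window_s * sample_rate must be >= 8 samples")
    if envelope_on not in ("spl", "waveform"):
        raise ValueError(f"unknown envelope_on {envelope_on!r}")

    n_windows = waveform.size // n_win_samples
    if n_windows < 1:
        raise ValueError("waveform shorter than one window")
    trimmed = waveform[: n_windows * n_win_samples].reshape(n_windows, n_win_samples)

    rms = np.sqrt((trimmed**2).mean(axis=1))
    with np.errstate(divide="ignore"):
        spl = 20.0 * np.log10(rms)
    spl = np.maximum(spl, spl_floor_db)

    rate = 1.0 / window_s
    if envelope_on == "spl":
        envelope = np.abs(hilbert(spl)) ** 2
    else:
        analytic_sq = np.abs(hilbert(waveform[: n_windows * n_win_samples])) ** 2
        envelope = analytic_sq.reshape(n_windows, n_win_samples).mean(axis=1)

    return {
        "spl_db": FeatureTrack("spl_db", spl, rate),
        "envelope": FeatureTrack("envelope", envelope, rate),
    }


def aggregate_to_tr(track: FeatureTrack, tr_s: float, stat: str = "mean") -> np.ndarray:
    """Summarize a feature track per TR window [k*TR, (k+1)*TR).

    ``stat`` is one of ``mean``, ``std`` (population) or ``msq`` (mean
    of squares).  Only complete TR windows are emitted.
    """
    if stat not in AGGREGATE_STATS:
        raise ValueError(f"unknown stat {stat!r}; expected one of {AGGREGATE_STATS}")
    samples_per_tr = track.rate * tr_s
    if samples_per_tr < 1:
        raise ValueError("track rate * tr_s must be >= 1 sample per TR")
    n = len(track.values)
    times = np.arange(n) / track.rate
    n_tr = int(np.floor(n / samples_per_tr))
    out = np.empty(n_tr)
    for k in range(n_tr):
        sel = (times >= k * tr_s) & (times < (k + 1) * tr_s)
        vals = track.values[sel]
        if stat == "mean":
            out[k] = vals.mean()
        elif stat == "std":
            out[k] = vals.std()
        else:
            out[k] = np.mean(vals**2)
    return out


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, peak-normalized to 1.

    Difference of two gamma densities: response peak delay 6 s,
    undershoot delay 16 s, both dispersions 1 s, response:undershoot
    amplitude ratio 6.  The kernel spans ``duration_s`` seconds.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    peak_delay, under_delay, disp, ratio = 6.0, 16.0, 1.0, 6.0
    if duration_s < 2 * peak_delay:
        raise ValueError("duration_s must be at least twice the response delay (12 s)")
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    h = gamma_dist.pdf(t, peak_delay / disp, scale=disp) - gamma_dist.pdf(
        t, under_delay / disp, scale=disp
    ) / ratio
    return h / h.max()


def make_regressor(
    track: np.ndarray, kernel: np.ndarray, name: str = "regressor", convolve: bool = True
) -> FeatureRegressor:
    """HRF-convolve a per-TR track (truncated to its length) and z-score.

    An all-constant track yields an all-zero regressor flagged
    ``constant_input`` (with a warning) instead of a 0/0 z-score.
    """
    track = np.asarray(track, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if len(track) < len(kernel):
        raise ValueError("track must be at least as long as the kernel")
    if track.std() == 0:
        warnings.warn(f"constant input for regressor {name!r}; emitting zeros")
        return FeatureRegressor(name, np.zeros_like(track), convolve, constant_input=True)
    values = np.convolve(track, kernel)[: len(track)] if convolve else track.copy()
    sd = values.std()
    if sd == 0:
        warnings.warn(f"constant input for regressor {name!r}; emitting zeros")
        return FeatureRegressor(name, np.zeros_like(values), convolve, constant_input=True)
    return FeatureRegressor(name, (values - values.mean()) / sd, convolve)
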