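import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from metica.stimulus_features import (
    FeatureTrack,
    FrameSeries,
    aggregate_to_tr,
    canonical_hrf,
    extract_audio_features,
    extract_video_features,
    make_regressor,
)


class TestVideoFeatures:
    def test_constant_frames_give_constant_luminance_and_zero_contrast(self):
        frames = FrameSeries(np.full((5, 8, 8), 0.5), fps=25)
        feats = extract_video_features(frames)
        assert np.allclose(feats["luminance"].values, 0.5)
        assert np.allclose(feats["temporal_contrast"].values, 0.0)
        assert np.allclose(feats["local_contrast"].values, 0.0)

    def test_alternating_black_white_frames_have_unit_temporal_contrast(self):
        f = np.zeros((6, 4, 4))
        f[1::2] = 1.0
        feats = extract_video_features(FrameSeries(f, fps=25))
        assert feats["temporal_contrast"].values[0] == 0.0
        assert np.allclose(feats["temporal_contrast"].values[1:], 1.0)

    def test_local_contrast_matches_exhaustive_neighbor_loop(self, rng):
        frames = rng.random((3, 5, 6))
        feats = extract_video_features(FrameSeries(frames, fps=25))
        for t in range(3):
            f = frames[t]
            per_pixel = []
            for i in range(5):
                for j in range(6):
                    diffs = [
                        abs(f[i, j] - f[i + di, j + dj])
                        for di in (-1, 0, 1)
                        for dj in (-1, 0, 1)
                        if (di, dj) != (0, 0)
                        and 0 <= i + di < 5
                        and 0 <= j + dj < 6
                    ]
                    per_pixel.append(np.mean(diffs))
            assert feats["local_contrast"].values[t] == pytest.approx(np.mean(per_pixel))

    def test_features_invariant_to_translation_of_periodic_pattern(self, rng):
        base = np.tile(rng.random((4, 4)), (3, 3))  # 12x12 periodic
        rolled = np.roll(np.roll(base, 2, axis=0), 3, axis=1)
        f1 = extract_video_features(FrameSeries(np.stack([base, base]), fps=25))
        f2 = extract_video_features(FrameSeries(np.stack([rolled, rolled]), fps=25))
        assert f1["luminance"].values == pytest.approx(f2["luminance"].values)
        # local contrast: interior statistics identical for periodic shifts is
        # only exact without edges, so compare means loosely
        assert f1["local_contrast"].values == pytest.approx(
            f2["local_contrast"].values, rel=0.15
        )

    def test_frame_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FrameSeries(np.zeros((3, 4)), fps=25)


class TestAudioFeatures:
    def test_full_scale_square_wave_is_zero_db(self):
        wave = np.tile([1.0, -1.0], 256)
        feats = extract_audio_features(wave, sample_rate=64, window_s=1.0)
        assert np.allclose(feats["spl_db"].values, 0.0)

    def test_silence_hits_floor_and_stays_finite(self):
        feats = extract_audio_features(np.zeros(512), sample_rate=64, window_s=1.0)
        assert np.all(feats["spl_db"].values == -100.0)
        assert np.all(np.isfinite(feats["envelope"].values))

    def test_sine_spl_matches_direct_rms(self, rng):
        sr, A = 1000, 0.3
        t = np.arange(8 * sr) / sr
        wave = A * np.sin(2 * np.pi * 50 * t)
        feats = extract_audio_features(wave, sample_rate=sr, window_s=1.0)
        expected = 20 * np.log10(np.sqrt(np.mean(wave[:sr] ** 2)))
        assert feats["spl_db"].values == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(20 * np.log10(A / np.sqrt(2)), abs=1e-3)

    def test_scaling_waveform_by_10_shifts_spl_by_20_db(self, rng):
        wave = 0.05 * rng.standard_normal(2048)
        f1 = extract_audio_features(wave, 256, 1.0)
        f2 = extract_audio_features(10 * wave, 256, 1.0)
        assert f2["spl_db"].values - f1["spl_db"].values == pytest.approx(20.0)

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_audio_features(np.array([]), 100, 1.0)


class TestAggregateToTr:
    def test_constant_track_std_is_zero(self):
        track = FeatureTrack("x", np.full(20, 3.0), rate=4)
        assert np.allclose(aggregate_to_tr(track, tr_s=1.0, stat="std"), 0.0)

    def test_mean_of_two_samples_per_tr(self):
        track = FeatureTrack("x", np.array([1.0, 2, 3, 4]), rate=2)
        assert aggregate_to_tr(track, 1.0, "mean") == pytest.approx([1.5, 3.5])

    def test_msq_equals_direct_loop(self, rng):
        vals = rng.random(30)
        track = FeatureTrack("x", vals, rate=5)
        out = aggregate_to_tr(track, 1.0, "msq")
        expected = [np.mean(vals[k * 5:(k + 1) * 5] ** 2) for k in range(6)]
        assert out == pytest.approx(expected)

    def test_unknown_stat_rejected(self):
        with pytest.raises(ValueError, match="stat"):
            aggregate_to_tr(FeatureTrack("x", np.ones(8), rate=2), 1.0, "median")


class TestCanonicalHrf:
    def test_peak_near_five_seconds(self):
        # dense-grid evaluation of the double-gamma difference as oracle
        t = np.linspace(0, 32, 32001)
        dense = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6
        t_peak = t[np.argmax(dense)]
        h = canonical_hrf(tr_s=1.0)
        assert abs(np.argmax(h) * 1.0 - t_peak) <= 1.0

    def test_zero_at_time_zero_and_peak_normalized(self):
        h = canonical_hrf(1.0)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_exactly_one_sign_change(self):
        h = canonical_hrf(0.5)
        signs = np.sign(h[np.abs(h) > 1e-12])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(1.0, duration_s=10)


class TestMakeRegressor:
    def test_impulse_reproduces_kernel(self):
        h = canonical_hrf(1.0)
        track = np.zeros(40)
        track[0] = 1.0
        conv = np.convolve(track, h)[:40]
        reg = make_regressor(track, h)
        assert np.corrcoef(reg.values, conv)[0, 1] == pytest.approx(1.0)

    def test_superposition_of_two_impulses(self):
        h = canonical_hrf(1.0)
        t1 = np.zeros(64); t1[3] = 1
        t2 = np.zeros(64); t2[20] = 1
        both = np.convolve(t1 + t2, h)[:64]
        single = np.convolve(t1, h)[:64] + np.convolve(t2, h)[:64]
        assert both == pytest.approx(single)

    def test_boxcar_matches_quadratic_loop_convolution(self, rng):
        h = canonical_hrf(1.0)
        track = np.zeros(50)
        track[5:15] = 1.0
        expected = np.zeros(50)
        for i in range(50):
            for j in range(len(h)):
                if 0 <= i - j < 50:
                    expected[i] += track[i - j] * h[j]
        raw = np.convolve(track, h)[:50]
        assert raw == pytest.approx(expected)
        reg = make_regressor(track, h)
        assert reg.values == pytest.approx((expected - expected.mean()) / expected.std())

    def test_constant_track_yields_flagged_zero_regressor(self):
        h = canonical_hrf(1.0)
        with pytest.warns(UserWarning, match="constant"):
            reg = make_regressor(np.ones(40), h)
        assert reg.constant_input
        assert np.all(reg.values == 0)

    def test_convolution_linearity_before_zscoring(self, rng):
        h = canonical_hrf(1.0)
        x, y = rng.random(60), rng.random(60)
        lhs = np.convolve(2 * x + 3 * y, h)[:60]
        rhs = 2 * np.convolve(x, h)[:60] + 3 * np.convolve(y, h)[:60]
        assert lhs == pytest.approx(rhs)
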