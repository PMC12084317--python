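import numpy as np
import pytest
from scipy import stats

from metica.clinical_stats import pooled_t_from_summary
from metica.glm_mapping import (
    EchoCombinedSeries,
    cluster_fwe_permutation,
    combine_echoes,
    extract_peak_betas,
    first_level_glm,
    second_level_ttest,
    smooth_maps,
)
from metica.synthetic_data import MultiEchoDataset

TE = np.array([13.0, 28.0, 43.0, 57.0])


def _dataset(data):
    return MultiEchoDataset(data=data, te_ms=TE, tr_s=1.0, subject_id="s", group_label="HC")


def _series(data, tr=1.0, group="HC", sid="s"):
    return EchoCombinedSeries(
        data=data, weights=np.full(4, 0.25), n_discarded=0, tr_s=tr, subject_id=sid, group_label=group
    )


class TestCombineEchoes:
    def test_identical_echoes_reduce_to_single_echo(self, rng):
        single = rng.random((4, 4, 2, 30))
        data = np.repeat(single[..., None, :], 4, axis=-2)
        out = combine_echoes(_dataset(data), n_discard=5)
        assert out.data == pytest.approx(single[..., 5:])

    def test_default_weights_normalize_to_sevenths(self, rng):
        data = rng.random((3, 3, 2, 4, 20))
        out = combine_echoes(_dataset(data), n_discard=0)
        assert out.weights == pytest.approx([1 / 7, 2 / 7, 2 / 7, 2 / 7])

    def test_full_run_length_after_dummy_discard(self):
        data = np.zeros((2, 2, 1, 1220), dtype=np.float32)
        out = combine_echoes(_dataset(np.repeat(data[..., None, :], 4, axis=-2)), n_discard=10)
        assert out.data.shape[-1] == 1210

    def test_discarding_everything_rejected(self, rng):
        data = rng.random((2, 2, 1, 8, 4)).transpose(0, 1, 2, 4, 3)
        with pytest.raises(ValueError):
            combine_echoes(_dataset(data), n_discard=8)


class TestFirstLevelGlm:
    def test_exact_recovery_in_noiseless_voxel(self, rng):
        T = 80
        g1 = np.sin(np.arange(T))
        g2 = np.cos(np.arange(T) / 3)
        g1, g2 = g1 - g1.mean(), g2 - g2.mean()
        g2 = g2 - g1 * (g2 @ g1) / (g1 @ g1)  # orthogonal design
        data = np.zeros((2, 1, 1, T))
        data[0, 0, 0] = 2.5 * g1 + 7.0
        data[1, 0, 0] = -1.0 * g2
        bm = first_level_glm(_series(data), np.vstack([g1, g2]))
        assert bm.betas[0, 0, 0, 0] == pytest.approx(2.5, abs=1e-9)
        assert bm.betas[1, 0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert bm.betas[1, 1, 0, 0] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_normal_equations_on_toy(self, rng):
        T, n_vox = 40, 5
        G = rng.standard_normal((2, T))
        Y = rng.standard_normal((n_vox, T))
        data = Y.reshape(5, 1, 1, T)
        bm = first_level_glm(_series(data), G)
        X = np.column_stack([G.T, np.ones(T), np.linspace(-1, 1, T)])
        expected = np.linalg.solve(X.T @ X, X.T @ Y.T)[:2]
        assert bm.betas[:, :, 0, 0] == pytest.approx(expected, abs=1e-9)

    def test_rank_deficient_design_rejected(self, rng):
        T = 30
        g = rng.standard_normal(T)
        data = rng.random((2, 2, 1, T))
        with pytest.raises(ValueError, match="collinear"):
            first_level_glm(_series(data), np.vstack([g, 2 * g]))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            first_level_glm(_series(rng.random((2, 2, 1, 30))), rng.standard_normal((1, 25)))


class TestSecondLevelTtest:
    def test_null_two_sample_t_centered_on_zero(self):
        # voxel t values within one cohort share the subject draw, so average
        # over independent replicate cohorts and bound by the empirical SE
        local = np.random.default_rng(77)
        groups = ["HC"] * 10 + ["MDD"] * 10
        means = []
        for _ in range(50):
            t, df = second_level_ttest(local.standard_normal((20, 6, 6, 3)), groups)
            assert df == 18
            means.append(np.nanmean(t))
        assert abs(np.mean(means)) < 3 * np.std(means) / np.sqrt(len(means))

    def test_matches_summary_statistics_formula(self, rng):
        betas = rng.standard_normal((12, 2, 2, 2))
        groups = ["HC"] * 5 + ["MDD"] * 7
        t, df = second_level_ttest(betas, groups)
        b = betas.reshape(12, -1)
        v = 3
        t_ref, df_ref, _ = pooled_t_from_summary(
            b[:5, v].mean(), b[:5, v].std(ddof=1), 5,
            b[5:, v].mean(), b[5:, v].std(ddof=1), 7,
        )
        assert t.ravel()[v] == pytest.approx(t_ref)
        assert df == df_ref

    def test_group_label_flip_negates_t_map(self, rng):
        betas = rng.standard_normal((10, 3, 3, 2))
        g1 = ["A"] * 5 + ["B"] * 5
        g2 = ["B"] * 5 + ["A"] * 5
        t1, _ = second_level_ttest(betas, g1)
        t2, _ = second_level_ttest(betas, g2)
        assert t1 == pytest.approx(-t2)

    def test_one_sample_matches_scipy(self, rng):
        betas = rng.standard_normal((9, 2, 2, 1)) + 0.4
        t, df = second_level_ttest(betas)
        ref = stats.ttest_1samp(betas.reshape(9, -1), 0.0)
        assert t.ravel() == pytest.approx(ref.statistic)
        assert df == 8

    def test_scaling_data_leaves_t_unchanged(self, rng):
        betas = rng.standard_normal((8, 4, 4, 2))
        t1, _ = second_level_ttest(betas)
        t2, _ = second_level_ttest(3.7 * betas)
        assert t1 == pytest.approx(t2)


class TestClusterFwePermutation:
    def test_permutation_p_has_floor(self, rng):
        betas = smooth_maps_batch(rng, n=12, effect=2.0)
        groups = ["HC"] * 6 + ["MDD"] * 6
        res = cluster_fwe_permutation(betas, groups, n_perm=100, seed=0)
        assert all(c.fwe_p >= 1 / 101 for c in res.clusters)

    def test_planted_group_difference_detected(self, rng):
        betas = smooth_maps_batch(rng, n=16, effect=3.0)
        groups = ["HC"] * 8 + ["MDD"] * 8
        res = cluster_fwe_permutation(betas, groups, n_perm=200, seed=1)
        sig = [c for c in res.clusters if c.fwe_p < 0.05]
        assert sig
        assert res.cluster_mask(sig[0])[4:8, 4:8, 2:4].any()

    def test_exhausted_relabelings_capped_with_warning(self, rng):
        betas = rng.standard_normal((4, 5, 5, 3))
        with pytest.warns(UserWarning, match="relabelings"):
            cluster_fwe_permutation(betas, n_perm=100, seed=0)


def smooth_maps_batch(rng, n, effect):
    """Smoothed null betas with a group deficit planted in a central block."""
    betas = np.stack([smooth_maps(rng.standard_normal((12, 12, 6)), 1.5) for _ in range(n)])
    betas[n // 2:, 4:8, 4:8, 2:4] += effect * betas.std()
    return betas


class TestExtractPeakBetas:
    def test_single_voxel_indexing_and_shape(self, rng):
        betas = rng.standard_normal((7, 4, 4, 2))
        df = extract_peak_betas(betas, [(1, 2, 0), (3, 3, 1)])
        assert df.shape == (7, 2)
        assert df.iloc[2, 0] == betas[2, 1, 2, 0]

    def test_peak_outside_volume_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            extract_peak_betas(rng.standard_normal((3, 2, 2, 2)), [(5, 0, 0)])


def test_scaling_data_scales_betas_linearly(rng):
    T = 50
    g = rng.standard_normal((1, T))
    data = rng.random((3, 3, 2, T))
    b1 = first_level_glm(_series(data), g).betas
    b2 = first_level_glm(_series(10 * data), g).betas
    assert b2 == pytest.approx(10 * b1)
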