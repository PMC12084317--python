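import numpy as np
import pytest

from metica.synthetic_data import SimulationConfig, simulate_cohort

TE_MS = np.array([13.0, 28.0, 43.0, 57.0])


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort shared by tests that only read it."""
    cfg = SimulationConfig(seed=7)
    datasets, truth = simulate_cohort(cfg)
    return cfg, datasets, truth


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale config for cheap Monte-Carlo loops (no dependence of the
    checked quantity on grid size)."""
    return dict(
        grid_shape=(10, 10, 6),
        n_timepoints=160,
        n_subjects_per_group=5,
        n_bold_sources=3,
        n_nonbold_sources=2,
        n_dummy=5,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def make_rank2_dataset(grid=(10, 10, 5), T=200, noise=0.0, seed=0):
    """Noiseless (or low-noise) 2-source multi-echo tensor with known triples."""
    from metica.synthetic_data import MultiEchoDataset

    rng = np.random.default_rng(seed)
    maps = np.zeros((2,) + grid)
    maps[0, 2:5, 2:5, 1:3] = rng.random((3, 3, 2)) + 0.5
    maps[1, 6:9, 6:9, 2:4] = rng.random((3, 3, 2)) + 0.5
    tcs = rng.standard_normal((2, T)) ** 3
    tcs = (tcs - tcs.mean(1, keepdims=True)) / tcs.std(1, keepdims=True)
    profiles = np.array([TE_MS * np.exp(-TE_MS / 35), np.exp(-TE_MS / 30)])
    profiles /= profiles.max(1, keepdims=True)
    data = np.full(grid + (4, T), 100.0)
    for c in range(2):
        data += maps[c][..., None, None] * profiles[c][:, None] * tcs[c][None, :]
    if noise:
        data += noise * rng.standard_normal(data.shape)
    ds = MultiEchoDataset(
        data=data, te_ms=TE_MS, tr_s=1.0, subject_id="sub-01", group_label="HC"
    )
    return ds, maps, tcs, profiles


@pytest.fixture(scope="session")
def rank2_dataset_factory():
    return make_rank2_dataset
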