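import numpy as np
import pytest

from pssmap import CohortConfig, PSSVolume, TestConfig, extract_pss, generate_cohort
from pssmap.grid import VoxelGrid
from pssmap.synthetic import Ellipsoid


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid(shape=(10, 10, 10))


def make_pss(grid: VoxelGrid, voxels, method: str = "test") -> PSSVolume:
    """PSSVolume from an explicit list of (i, j, k) voxels."""
    mask = grid.empty_mask()
    for v in voxels:
        mask[tuple(v)] = True
    return PSSVolume(mask=mask, grid=grid, method=method)


def scaled_pd_config(seed: int = 3, n_patients: int = 12, **overrides) -> CohortConfig:
    """PD-like cohort shrunk onto a 16^3 grid (shorter trajectory, tighter
    jitter and ground truth so the geometry stays feasible)."""
    grid = VoxelGrid(shape=(16, 16, 16))
    defaults = dict(
        trajectory_span=10.0,
        trajectory_jitter_sd=1.0,
        trajectory_z_jitter_sd=0.5,
        ground_truth=Ellipsoid(center=(7.5, 7.5, 7.5), semi_axes=(3.0, 3.0, 4.0)),
    )
    defaults.update(overrides)
    return CohortConfig.pd_like(seed=seed, grid=grid, n_patients=n_patients, **defaults)


@pytest.fixture(scope="session")
def strong_signal_cohort():
    """Noise-free full-size PD-like cohort: 36 patients, 12-22 stimulations
    each on a 32^3 grid, scores driven purely by sweet-spot overlap."""
    cfg = CohortConfig.pd_like(seed=7, score_noise_sd=0.0)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovered_pss(strong_signal_cohort):
    """Sweet spots recovered from the strong-signal cohort by all three
    statistical engines at their default settings."""
    cfg, cohort = strong_signal_cohort
    out = {}
    for method in ("bayes", "wfdr", "wperm"):
        out[method] = extract_pss(cohort, TestConfig(method=method, seed=1))
    return cfg, out


def dice_vs_mask(pss: PSSVolume, reference_mask: np.ndarray) -> float:
    inter = int(np.count_nonzero(pss.mask & reference_mask))
    denom = pss.n_voxels + int(np.count_nonzero(reference_mask))
    return 200.0 * inter / denom if denom else float("nan")
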