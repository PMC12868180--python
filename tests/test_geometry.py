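"""Pairwise PSS metrics and the successive-comparison curve logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pssmap import CohortConfig, DatasetGrid, SamplingPlan, generate_cohort
from pssmap.geometry import (
    centr_dist,
    centroid,
    combined_metric,
    diameter,
    dice,
    successive_comparisons,
    vol_diff,
    volume,
)
from pssmap.grid import VoxelGrid
from pssmap.mapping import PSSVolume
from pssmap.resampling import DatasetKey

from conftest import make_pss

GRID = VoxelGrid(shape=(10, 10, 10))
HALF_GRID = VoxelGrid(shape=(10, 10, 10), voxel_size=(0.5, 0.5, 0.5))
EMPTY = make_pss(GRID, [])


voxel_sets = st.sets(
    st.tuples(*[st.integers(0, 9)] * 3), min_size=1, max_size=20
)


class TestScalarDescriptors:
    def test_volume_counts_voxels(self):
        assert volume(EMPTY) == 0.0
        assert volume(make_pss(HALF_GRID, [(i, 0, 0) for i in range(10)])) == pytest.approx(1.25)

    def test_centroid_examples(self):
        single = make_pss(GRID, [(3, 4, 5)])
        np.testing.assert_allclose(centroid(single), [3, 4, 5])
        pair = make_pss(GRID, [(2, 2, 2), (4, 6, 8)])
        np.testing.assert_allclose(centroid(pair), [3, 4, 5])
        with pytest.raises(ValueError):
            centroid(EMPTY)

    @given(voxel_sets)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_centroid_matches_brute_force(self, voxels):
        pss = make_pss(GRID, voxels)
        ref = np.mean([GRID.world_coords([v])[0] for v in voxels], axis=0)
        np.testing.assert_allclose(centroid(pss), ref)

    def test_diameter_closed_form(self):
        # 1000 unit voxels -> V = 1000 mm^3 -> d = (6000/pi)^(1/3)
        cube = make_pss(GRID, [(i, j, k) for i in range(10) for j in range(10) for k in range(10)])
        assert diameter(cube) == pytest.approx((6000 / math.pi) ** (1 / 3))
        assert diameter(cube) == pytest.approx(12.407, abs=1e-3)

    def test_diameter_scales_with_cbrt_volume(self):
        a = make_pss(GRID, [(0, 0, 0)])
        b = make_pss(GRID, [(0, 0, 0), (0, 0, 1)])
        assert diameter(b) / diameter(a) == pytest.approx(2 ** (1 / 3))


class TestPairwiseMetrics:
    def test_vol_diff_examples(self):
        a = make_pss(GRID, [(i, 0, 0) for i in range(10)])
        b = make_pss(GRID, [(i, 0, 1) for i in range(5)])
        assert vol_diff(a, b) == pytest.approx(50.0)
        assert vol_diff(a, a) == 0.0
        assert vol_diff(EMPTY, EMPTY) == 0.0
        assert vol_diff(a, EMPTY) == 100.0

    def test_dice_examples(self):
        a = make_pss(GRID, [(i, 0, 0) for i in range(8)])
        half = make_pss(GRID, [(i, 0, 0) for i in range(4)] + [(i, 5, 5) for i in range(4)])
        assert dice(a, half) == pytest.approx(50.0)  # |a|=|b|=8, overlap 4
        assert dice(a, a) == 100.0
        disjoint = make_pss(GRID, [(0, 9, 9)])
        assert dice(a, disjoint) == 0.0
        assert math.isnan(dice(EMPTY, EMPTY))
        assert dice(a, EMPTY) == 0.0

    def test_centr_dist_single_voxels_three_mm_apart(self):
        a = make_pss(GRID, [(1, 1, 1)])
        b = make_pss(GRID, [(4, 1, 1)])
        expected = 100.0 * 3.0 / (6 / math.pi) ** (1 / 3)
        assert centr_dist(a, b) == pytest.approx(expected)
        assert expected > 100  # normalized distance may exceed 100 %
        assert centr_dist(a, a) == 0.0
        assert math.isnan(centr_dist(a, EMPTY))

    @given(voxel_sets, voxel_sets)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry(self, va, vb):
        a, b = make_pss(GRID, va), make_pss(GRID, vb)
        assert vol_diff(a, b) == pytest.approx(vol_diff(b, a))
        assert dice(a, b) == pytest.approx(dice(b, a))
        assert centr_dist(a, b) == pytest.approx(centr_dist(b, a))
        assert 0 <= dice(a, b) <= 100
        assert 0 <= vol_diff(a, b) <= 100

    @given(voxel_sets, voxel_sets, voxel_sets)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_centroid_distance_triangle_inequality(self, va, vb, vc):
        a, b, c = (make_pss(GRID, v) for v in (va, vb, vc))
        ab = np.linalg.norm(centroid(a) - centroid(b))
        bc = np.linalg.norm(centroid(b) - centroid(c))
        ac = np.linalg.norm(centroid(a) - centroid(c))
        assert ac <= ab + bc + 1e-9


@pytest.fixture(scope="module")
def tiny_grid():
    cohort = generate_cohort(
        CohortConfig.pd_like(seed=4, n_patients=8, stims_per_patient=(4, 6))
    )
    plan = SamplingPlan(n_patient_reps=2, stim_counts=(4,), n_stim_reps=2)
    return DatasetGrid(cohort, plan, master_seed=0)


class TestSuccessiveComparisons:
    def test_identical_pss_give_flat_curves(self, tiny_grid):
        ref = make_pss(tiny_grid.cohort.grid, [(5, 5, 5), (5, 5, 6)], method="bayes")
        pss = {k: ref for k in tiny_grid.keys()}
        curves = successive_comparisons(pss, tiny_grid)
        assert (curves[curves["metric"] == "dice"]["mean"] == 100.0).all()
        assert (curves[curves["metric"] == "vol_diff"]["mean"] == 0.0).all()
        assert (curves[curves["metric"] == "centr_dist"]["mean"] == 0.0).all()
        assert (curves["sd"] == 0.0).all()

    def test_cross_pair_count_and_hand_average(self, tiny_grid):
        # different volume per (n_pat, rep, stim_rep): vol_diff computable by hand
        sizes = {}
        pss = {}
        for key in tiny_grid.keys():
            nv = 1 + (key.n_pat + key.patient_rep + key.stim_rep) % 3
            pss[key] = make_pss(
                tiny_grid.cohort.grid, [(0, 0, z) for z in range(nv)], method="bayes"
            )
            sizes[key] = nv
        curves = successive_comparisons(pss, tiny_grid)
        vd = curves[curves["metric"] == "vol_diff"].set_index("n_pat")
        # point at the larger size of each pair; full plan: 2 reps x (2x2) pairs
        assert set(vd.index) == {6, 8}
        # hand-compute the n_pat = 6 point (pairs 4 -> 6 within each chain)
        chain_means = []
        for rep in (1, 2):
            vals = []
            for i in (1, 2):
                for j in (1, 2):
                    va = sizes[DatasetKey(4, rep, 4, i)]
                    vb = sizes[DatasetKey(6, rep, 4, j)]
                    vals.append(100.0 * abs(va - vb) / max(va, vb))
            chain_means.append(np.mean(vals))
        assert vd.loc[6, "mean"] == pytest.approx(np.mean(chain_means))
        assert vd.loc[6, "n_pairs"] == 8

    def test_missing_pss_pairs_skipped(self, tiny_grid):
        ref = make_pss(tiny_grid.cohort.grid, [(5, 5, 5)], method="bayes")
        pss = {k: ref for k in tiny_grid.keys()}
        dropped = DatasetKey(4, 1, 4, 1)
        del pss[dropped]
        curves = successive_comparisons(pss, tiny_grid)
        vd = curves[(curves["metric"] == "dice") & (curves["n_pat"] == 6)]
        assert vd["n_pairs"].iloc[0] == 6  # chain 1 lost 2 of its 4 cross-pairs


class TestCombinedMetric:
    def test_pointwise_mean(self, small_grid):
        import pandas as pd

        rows = []
        for metric, val in [("vol_diff", 0.0), ("dice", 100.0), ("centr_dist", 0.0)]:
            rows.append({"method": "bayes", "metric": metric, "n_stim": 4,
                         "n_pat": 6, "mean": val, "sd": 0.0, "n_pairs": 9})
        curves = pd.DataFrame(rows)
        comb = combined_metric(curves)
        assert comb["mean"].iloc[0] == pytest.approx(100.0 / 3.0)

    def test_undefined_component_propagates(self):
        import pandas as pd

        rows = [
            {"method": "m", "metric": "vol_diff", "n_stim": 4, "n_pat": 6,
             "mean": 10.0, "sd": 0.0, "n_pairs": 9},
            {"method": "m", "metric": "dice", "n_stim": 4, "n_pat": 6,
             "mean": float("nan"), "sd": 0.0, "n_pairs": 9},
            {"method": "m", "metric": "centr_dist", "n_stim": 4, "n_pat": 6,
             "mean": 5.0, "sd": 0.0, "n_pairs": 9},
        ]
        comb = combined_metric(pd.DataFrame(rows))
        assert math.isnan(comb["mean"].iloc[0])
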