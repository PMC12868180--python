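"""Voxel-wise mapping pipeline: occurrence maps, corrections, filters."""

import itertools

import numpy as np
import pytest

from pssmap import (
    TestConfig,
    apply_occurrence_filters,
    compute_occurrence_maps,
    extract_pss,
    psm_bayes,
    psm_wfdr,
    psm_wperm,
    remove_small_clusters,
    voxel_scores,
)
from pssmap.dataset import Stimulation, StimulationDataset
from pssmap.grid import VoxelGrid
from pssmap.mapping import OccurrenceMaps
from pssmap.stats import signed_rank_z_matrix


def _stim(grid, pid, sid, voxels, score):
    mask = grid.empty_mask()
    for v in voxels:
        mask[v] = True
    return Stimulation(patient_id=pid, stim_id=sid, mask=mask, amplitude=1.0, score=score)


@pytest.fixture
def line_grid():
    return VoxelGrid(shape=(3, 1, 1))


@pytest.fixture
def random_fixture():
    """5 patients x 3 stimulations with random blob masks."""
    grid = VoxelGrid(shape=(6, 6, 6))
    rng = np.random.default_rng(17)
    stims = []
    for p in range(5):
        for s in range(3):
            mask = rng.random((6, 6, 6)) < 0.3
            mask[rng.integers(6), rng.integers(6), rng.integers(6)] = True
            stims.append(
                Stimulation(f"P{p}", f"P{p}_S{s}", mask, 1.0, float(rng.choice([0, 25, 50, 75, 100])))
            )
    return StimulationDataset(grid, stims)


class TestOccurrenceMaps:
    def test_same_patient_counts_once_in_npatmap(self, line_grid):
        d = StimulationDataset(
            line_grid,
            [
                _stim(line_grid, "A", "A1", [(0, 0, 0)], 50),
                _stim(line_grid, "A", "A2", [(0, 0, 0)], 75),
            ],
        )
        occ = compute_occurrence_maps(d)
        assert occ.nmap[0, 0, 0] == 2
        assert occ.npatmap[0, 0, 0] == 1

    def test_matches_brute_force(self, random_fixture):
        occ = compute_occurrence_maps(random_fixture)
        nmap = np.zeros(random_fixture.grid.shape, dtype=int)
        npat = np.zeros(random_fixture.grid.shape, dtype=int)
        for v in np.ndindex(*random_fixture.grid.shape):
            pats = set()
            for s in random_fixture.stimulations:
                if s.mask[v]:
                    nmap[v] += 1
                    pats.add(s.patient_id)
            npat[v] = len(pats)
        np.testing.assert_array_equal(occ.nmap, nmap)
        np.testing.assert_array_equal(occ.npatmap, npat)
        assert np.all(occ.npatmap <= occ.nmap)

    def test_voxel_scores_conservation(self, random_fixture):
        total = sum(
            len(voxel_scores(random_fixture, v))
            for v in np.ndindex(*random_fixture.grid.shape)
        )
        assert total == sum(s.mask.sum() for s in random_fixture.stimulations)

    def test_uncovered_voxel_empty(self, line_grid):
        d = StimulationDataset(line_grid, [_stim(line_grid, "A", "A1", [(0, 0, 0)], 50)])
        assert voxel_scores(d, (2, 0, 0)) == []
        assert voxel_scores(d, (0, 0, 0)) == [50]


def bh_stepup(p, alpha):
    """Hand-coded Benjamini-Hochberg oracle: rejection set + adjusted p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    k = np.nonzero(below)[0].max() + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    return reject, p_adj


class TestWFDR:
    def test_bh_agrees_with_hand_oracle_on_random_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=900), rng.uniform(0, 0.01, size=100)])
        reject_ref, padj_ref = bh_stepup(p, 0.05)
        reject, padj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, reject_ref)
        np.testing.assert_allclose(padj, padj_ref, atol=1e-12)

    def test_three_pvalue_example(self):
        reject, _ = bh_stepup([0.01, 0.02, 0.04], 0.05)
        assert reject.all()  # largest k with p_(k) <= k*alpha/m is k = 3

    def test_single_voxel_equals_raw_threshold(self, line_grid):
        # with one tested voxel BH reduces to plain p < alpha
        stims = [
            _stim(line_grid, f"P{i}", f"S{i}", [(1, 0, 0)], 100.0) for i in range(6)
        ]
        d = StimulationDataset(line_grid, stims)
        res = psm_wfdr(d, TestConfig(method="wfdr", min_observations=5))
        assert res.tested.sum() == 1
        assert res.statistic[0] == pytest.approx(res.raw_p[0])
        assert res.significant[1, 0, 0] == (res.raw_p[0] < 0.05)

    def test_all_scores_at_threshold_not_significant(self, line_grid):
        stims = [_stim(line_grid, f"P{i}", f"S{i}", [(0, 0, 0)], 50.0) for i in range(8)]
        d = StimulationDataset(line_grid, stims)
        res = psm_wfdr(d, TestConfig(method="wfdr"))
        assert not res.significant.any()


class TestWPERM:
    @pytest.fixture
    def small_fixture(self, line_grid):
        coverage = [
            [(0, 0, 0), (2, 0, 0)],
            [(0, 0, 0), (1, 0, 0)],
            [(0, 0, 0), (1, 0, 0), (2, 0, 0)],
            [(0, 0, 0), (1, 0, 0)],
            [(1, 0, 0), (2, 0, 0)],
            [(1, 0, 0), (2, 0, 0)],
        ]
        scores = [100.0, 75.0, 62.5, 25.0, 87.5, 50.0]
        stims = [
            _stim(line_grid, f"P{i}", f"S{i}", cov, sc)
            for i, (cov, sc) in enumerate(zip(coverage, scores))
        ]
        return StimulationDataset(line_grid, stims)

    def test_agrees_with_exhaustive_enumeration(self, small_fixture):
        cfg = TestConfig(method="wperm", min_observations=2, n_permutations=10_000, seed=4)
        res = psm_wperm(small_fixture, cfg)
        assert res.tested.sum() == 3

        # oracle: every ordering of the 6 scores, exact max-statistic null
        scores = small_fixture.scores()
        stack = small_fixture.mask_stack()[:, res.tested]  # (6, 3)
        max_n = stack.sum(axis=0).max()
        idx = np.full((3, max_n), -1)
        for v in range(3):
            members = np.nonzero(stack[:, v])[0]
            idx[v, : members.size] = members
        def z_of(score_vec):
            S = np.where(idx >= 0, np.asarray(score_vec)[np.clip(idx, 0, None)], np.nan)
            return signed_rank_z_matrix(S, 50.0)
        z_obs = z_of(scores)
        exceed = np.zeros(3)
        n_perm = 0
        for perm in itertools.permutations(scores):
            exceed += z_of(perm).max() >= z_obs
            n_perm += 1
        p_exact = exceed / n_perm
        mc_se = np.sqrt(p_exact * (1 - p_exact) / cfg.n_permutations)
        np.testing.assert_array_less(
            np.abs(res.statistic - p_exact), 3 * mc_se + 2 / cfg.n_permutations
        )

    def test_corrected_p_monotone_in_observed_statistic(self, small_fixture):
        cfg = TestConfig(method="wperm", min_observations=2, n_permutations=500, seed=0)
        res = psm_wperm(small_fixture, cfg)
        scores = small_fixture.scores()
        stack = small_fixture.mask_stack()[:, res.tested]
        idx = np.full((3, int(stack.sum(0).max())), -1)
        for v in range(3):
            members = np.nonzero(stack[:, v])[0]
            idx[v, : members.size] = members
        S = np.where(idx >= 0, scores[np.clip(idx, 0, None)], np.nan)
        z_obs = signed_rank_z_matrix(S, 50.0)
        order = np.argsort(z_obs)
        assert np.all(np.diff(res.statistic[order]) <= 1e-12)

    def test_constant_scores_never_significant(self, line_grid):
        stims = [_stim(line_grid, f"P{i}", f"S{i}", [(0, 0, 0)], 75.0) for i in range(8)]
        d = StimulationDataset(line_grid, stims)
        res = psm_wperm(d, TestConfig(method="wperm", n_permutations=100, seed=1))
        # every permutation is identical, so corrected p = 1 everywhere
        assert not res.significant.any()
        assert np.all(res.statistic == 1.0)


class TestOccurrenceFilters:
    def _occ(self, shape, nmap_val, npat_val, at):
        nmap = np.zeros(shape, dtype=int)
        npat = np.zeros(shape, dtype=int)
        nmap[at] = nmap_val
        npat[at] = npat_val
        # another voxel holds the nMap maximum
        nmap[0, 0, 0] = 20
        npat[0, 0, 0] = 10
        return OccurrenceMaps(nmap, npat)

    def test_patient_fraction_rule(self):
        sig = np.ones((3, 3, 3), dtype=bool)
        occ = self._occ((3, 3, 3), nmap_val=20, npat_val=2, at=(1, 1, 1))
        out = apply_occurrence_filters(sig, occ, n_patients=10)
        assert not out[1, 1, 1]  # 2/10 patients < 25 %

    def test_stim_fraction_rule(self):
        sig = np.ones((3, 3, 3), dtype=bool)
        occ = self._occ((3, 3, 3), nmap_val=1, npat_val=10, at=(1, 1, 1))
        out = apply_occurrence_filters(sig, occ, n_patients=10)
        assert not out[1, 1, 1]  # 1/20 stimulations < 10 % of max nMap

    def test_boundary_values_retained(self):
        sig = np.ones((3, 3, 3), dtype=bool)
        occ = self._occ((3, 3, 3), nmap_val=2, npat_val=3, at=(1, 1, 1))
        # thresholds: npat >= 0.25*10 = 2.5 -> 3 passes; nmap >= 2 passes
        out = apply_occurrence_filters(sig, occ, n_patients=10)
        assert out[1, 1, 1]

    def test_never_adds_voxels(self):
        rng = np.random.default_rng(0)
        sig = rng.random((4, 4, 4)) < 0.5
        occ = OccurrenceMaps(
            rng.integers(0, 10, (4, 4, 4)), rng.integers(0, 5, (4, 4, 4))
        )
        out = apply_occurrence_filters(sig, occ, n_patients=8)
        assert not np.any(out & ~sig)


class TestClusterFilter:
    def test_sub_millimeter_cluster_removed(self):
        grid = VoxelGrid(shape=(10, 10, 10), voxel_size=(0.5, 0.5, 0.5))
        mask = grid.empty_mask()
        # 7-voxel face-connected plus sign: 7 * 0.125 = 0.875 mm^3 < 1
        c = (5, 5, 5)
        mask[c] = True
        for d in range(3):
            for off in (-1, 1):
                v = list(c)
                v[d] += off
                mask[tuple(v)] = True
        assert mask.sum() == 7
        out = remove_small_clusters(mask, grid, min_volume=1.0)
        assert not out.any()

    def test_exactly_one_cubic_millimeter_kept(self):
        grid = VoxelGrid(shape=(10, 10, 10), voxel_size=(0.5, 0.5, 0.5))
        mask = grid.empty_mask()
        mask[2:4, 2:4, 2:4] = True  # 8 voxels = 1.0 mm^3, "smaller than" is strict
        out = remove_small_clusters(mask, grid, min_volume=1.0)
        np.testing.assert_array_equal(out, mask)

    def test_unit_grid_unchanged(self):
        grid = VoxelGrid(shape=(6, 6, 6))
        rng = np.random.default_rng(2)
        mask = rng.random((6, 6, 6)) < 0.2
        out = remove_small_clusters(mask, grid, min_volume=1.0)
        np.testing.assert_array_equal(out, mask)

    def test_connectivity_matters(self):
        grid = VoxelGrid(shape=(6, 6, 6), voxel_size=(0.5, 0.5, 0.5))
        mask = grid.empty_mask()
        mask[1:3, 1:3, 1:3] = True  # 8 voxels, 1 mm^3
        mask[3, 3, 3] = True  # diagonal neighbor: separate under 6-connectivity
        out6 = remove_small_clusters(mask, grid, min_volume=1.0, connectivity=6)
        assert out6.sum() == 8
        out26 = remove_small_clusters(mask, grid, min_volume=1.0, connectivity=26)
        assert out26.sum() == 9


class TestExtractPss:
    def test_zero_scores_give_empty_pss(self, line_grid):
        stims = [_stim(line_grid, f"P{i}", f"S{i}", [(0, 0, 0), (1, 0, 0)], 0.0) for i in range(8)]
        d = StimulationDataset(line_grid, stims)
        for method in ("wfdr", "wperm", "bayes"):
            cfg = TestConfig(method=method, n_permutations=50,
                             num_samples=200, warmup_steps=100, seed=0)
            assert extract_pss(d, cfg).is_empty

    def test_bayes_deterministic_given_seed(self, line_grid):
        rng = np.random.default_rng(1)
        stims = [
            _stim(line_grid, f"P{i}", f"S{i}", [(0, 0, 0), (1, 0, 0)],
                  float(rng.choice([50, 75, 100])))
            for i in range(10)
        ]
        d = StimulationDataset(line_grid, stims)
        cfg = TestConfig(method="bayes", num_samples=300, warmup_steps=100, seed=5)
        a = extract_pss(d, cfg)
        b = extract_pss(d, cfg)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_filtered_mask_subset_of_significance(self, recovered_pss):
        _, pss_by_method = recovered_pss
        for pss in pss_by_method.values():
            assert pss.provenance["n_final"] <= pss.provenance["n_after_occurrence"]
            assert pss.provenance["n_after_occurrence"] <= pss.provenance["n_significant"]
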