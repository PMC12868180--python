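"""Probabilistic sweet-spot (PSS) extraction from a stimulation dataset.

The pipeline mirrors the standard probabilistic-mapping workflow: build
voxel-wise occurrence maps, run a voxel-wise one-sample test of improvement
against a clinical threshold with one of three engines —

* ``wfdr``  — Wilcoxon signed-rank + Benjamini-Hochberg FDR correction,
* ``wperm`` — Wilcoxon signed-rank + max-statistic permutation correction
  (improvement scores shuffled across all stimulations, masks fixed),
* ``bayes`` — Bayesian one-sample test, voxels kept at Bayes factor >= 10,

then discard voxels stimulated in fewer than 25% of patients or with fewer
than 10% of the maximum stimulation occurrence, and finally drop connected
clusters smaller than 1 mm^3.  The surviving voxels form the PSS volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .bayes import NormalPrior, bayes_factor_directional, posterior_mu_matrix
from .dataset import StimulationDataset
from .grid import VoxelGrid
from .stats import signed_rank_z_matrix, wilcoxon_p_matrix

__all__ = [
    "OccurrenceMaps",
    "TestConfig",
    "VoxelStatisticMap",
    "PSSVolume",
    "compute_occurrence_maps",
    "voxel_scores",
    "psm_wfdr",
    "psm_wperm",
    "psm_bayes",
    "apply_occurrence_filters",
    "remove_small_clusters",
    "extract_pss",
]

METHODS = ("bayes", "wfdr", "wperm")


@dataclass
class OccurrenceMaps:
    """Voxel-wise coverage counts.

    ``nmap`` counts covering stimulations, ``npatmap`` distinct patients
    with at least one covering stimulation.
    """

    nmap: np.ndarray
    npatmap: np.ndarray


@dataclass
class TestConfig:
    """Settings for one voxel-wise statistical run.

    ``improvement_threshold`` is the clinical cut between "responder" and
    "non-responder" scores: 50% for rigidity-type ratings, 75% for tremor.
    """

    method: str = "bayes"
    improvement_threshold: float = 50.0
    alpha: float = 0.05
    n_permutations: int = 200
    bf_threshold: float = 10.0
    prior: NormalPrior | None = None  # None: Normal(theta, 25^2), HalfNormal(25)
    num_samples: int = 2000
    warmup_steps: int = 1000
    min_observations: int = 5
    cluster_min_volume: float = 1.0  # mm^3
    connectivity: int = 6  # 6 | 18 | 26
    patient_frac: float = 0.25
    stim_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}, expected one of {METHODS}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.improvement_threshold < 100.0):
            raise ValueError("improvement threshold must be in (0, 100)")
        if self.bf_threshold <= 1.0:
            raise ValueError("bf_threshold must be > 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def resolved_prior(self) -> NormalPrior:
        return self.prior or NormalPrior(mu_loc=self.improvement_threshold)


@dataclass
class VoxelStatisticMap:
    """Per-voxel statistic over the tested-voxel family.

    ``statistic`` holds, per tested voxel, the method's decision statistic:
    a corrected p-value for the Wilcoxon engines, a Bayes factor for the
    Bayesian one.  ``significant`` is the thresholded decision before the
    occurrence and cluster filters.
    """

    method: str
    tested: np.ndarray  # 3D bool: the correction family
    statistic: np.ndarray  # 1D, aligned with tested.nonzero()
    significant: np.ndarray  # 3D bool
    raw_p: np.ndarray | None = None  # 1D, Wilcoxon engines only

    def statistic_volume(self, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.tested.shape, fill)
        out[self.tested] = self.statistic
        return out


@dataclass
class PSSVolume:
    """Binary sweet-spot volume with provenance."""

    mask: np.ndarray
    grid: VoxelGrid
    method: str
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    def centroid(self) -> np.ndarray | None:
        """World-coordinate centroid of member voxel centers; None if empty."""
        if self.is_empty:
            return None
        idx = np.argwhere(self.mask)
        return self.grid.world_coords(idx).mean(axis=0)


def compute_occurrence_maps(dataset: StimulationDataset) -> OccurrenceMaps:
    """nMap (stimulation counts) and nPatMap (patient counts) per voxel."""
    if dataset.n_stimulations == 0:
        raise ValueError("dataset has no stimulations")
    nmap = np.zeros(dataset.grid.shape, dtype=np.int32)
    npatmap = np.zeros(dataset.grid.shape, dtype=np.int32)
    for stims in dataset.by_patient().values():
        patient_any = np.zeros(dataset.grid.shape, dtype=bool)
        for s in stims:
            nmap += s.mask
            patient_any |= s.mask
        npatmap += patient_any
    return OccurrenceMaps(nmap=nmap, npatmap=npatmap)


def voxel_scores(dataset: StimulationDataset, voxel) -> list[float]:
    """Scores of all stimulations covering one voxel, in dataset order."""
    i, j, k = voxel
    return [s.score for s in dataset.stimulations if s.mask[i, j, k]]


def _coverage_matrix(dataset: StimulationDataset, tested: np.ndarray):
    """Index matrix (n_tested, max_n) into the score vector, -1 padded."""
    stack = dataset.mask_stack()  # (n_stims, *grid)
    cov = stack[:, tested]  # (n_stims, n_tested)
    counts = cov.sum(axis=0)
    max_n = int(counts.max()) if counts.size else 0
    idx = np.full((tested.sum(), max_n), -1, dtype=np.int64)
    for v in range(cov.shape[1]):
        members = np.nonzero(cov[:, v])[0]
        idx[v, : members.size] = members
    return idx


def _score_matrix(scores: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Padded per-voxel score matrix (NaN padding) from an index matrix."""
    S = np.where(idx >= 0, scores[np.clip(idx, 0, None)], np.nan)
    return S


def _tested_family(dataset: StimulationDataset, config: TestConfig, occ: OccurrenceMaps):
    """Voxels entering the multiple-comparison family.

    Wilcoxon engines require ``min_observations`` non-zero differences
    (scores != theta); the Bayesian engine ``min_observations`` covering
    scores.  Correcting over never-tested voxels would only inflate the
    family size.
    """
    if config.method == "bayes":
        return occ.nmap >= config.min_observations
    scores = dataset.scores()
    nonzero = scores != config.improvement_threshold
    stack = dataset.mask_stack()
    nz_count = stack[nonzero].sum(axis=0) if nonzero.any() else np.zeros(dataset.grid.shape)
    return nz_count >= config.min_observations


def psm_wfdr(dataset: StimulationDataset, config: TestConfig) -> VoxelStatisticMap:
    """Wilcoxon + Benjamini-Hochberg FDR over the tested-voxel family."""
    occ = compute_occurrence_maps(dataset)
    tested = _tested_family(dataset, config, occ)
    sig = np.zeros(dataset.grid.shape, dtype=bool)
    if not tested.any():
        return VoxelStatisticMap("wfdr", tested, np.empty(0), sig, raw_p=np.empty(0))
    scores = dataset.scores()
    idx = _coverage_matrix(dataset, tested)
    S = _score_matrix(scores, idx)
    raw_p = wilcoxon_p_matrix(S, config.improvement_threshold)
    reject, p_corr, _, _ = multipletests(raw_p, alpha=config.alpha, method="fdr_bh")
    sig[tested] = reject & (p_corr < config.alpha)
    return VoxelStatisticMap("wfdr", tested, p_corr, sig, raw_p=raw_p)


def psm_wperm(dataset: StimulationDataset, config: TestConfig) -> VoxelStatisticMap:
    """Wilcoxon + max-statistic permutation correction (family-wise).

    Scores are shuffled across all stimulations while masks stay fixed;
    each voxel's corrected p is the proportion of permutations — the
    observed arrangement included — whose family-maximum standardized
    statistic reaches its observed statistic.
    """
    occ = compute_occurrence_maps(dataset)
    tested = _tested_family(dataset, config, occ)
    sig = np.zeros(dataset.grid.shape, dtype=bool)
    if not tested.any():
        return VoxelStatisticMap("wperm", tested, np.empty(0), sig, raw_p=np.empty(0))
    scores = dataset.scores()
    idx = _coverage_matrix(dataset, tested)
    theta = config.improvement_threshold
    z_obs = signed_rank_z_matrix(_score_matrix(scores, idx), theta)
    rng = np.random.default_rng(config.seed)
    exceed = np.ones(z_obs.shape[0], dtype=np.int64)  # observed arrangement counts
    for _ in range(config.n_permutations):
        perm = rng.permutation(scores)
        z_perm = signed_rank_z_matrix(_score_matrix(perm, idx), theta)
        z_max = z_perm.max() if z_perm.size else -np.inf
        exceed += z_max >= z_obs
    p_corr = exceed / (config.n_permutations + 1)
    raw = wilcoxon_p_matrix(_score_matrix(scores, idx), theta)
    sig[tested] = p_corr < config.alpha
    return VoxelStatisticMap("wperm", tested, p_corr, sig, raw_p=raw)


def psm_bayes(dataset: StimulationDataset, config: TestConfig) -> VoxelStatisticMap:
    """Bayesian one-sample test; voxels kept at BF >= ``bf_threshold``."""
    occ = compute_occurrence_maps(dataset)
    tested = _tested_family(dataset, config, occ)
    sig = np.zeros(dataset.grid.shape, dtype=bool)
    if not tested.any():
        return VoxelStatisticMap("bayes", tested, np.empty(0), sig)
    scores = dataset.scores()
    idx = _coverage_matrix(dataset, tested)
    S = _score_matrix(scores, idx)
    valid = np.isfinite(S)
    n = valid.sum(axis=1).astype(float)
    s1 = np.nansum(S, axis=1)
    s2 = np.nansum(S**2, axis=1)
    prior = config.resolved_prior()
    rng = np.random.default_rng(config.seed)
    draws = posterior_mu_matrix(
        n, s1, s2, prior, num_samples=config.num_samples,
        warmup_steps=config.warmup_steps, rng=rng,
    )
    theta = config.improvement_threshold
    ok = np.all(np.isfinite(draws), axis=1)  # non-finite chains: not significant
    bf = np.zeros(draws.shape[0])
    for v in np.nonzero(ok)[0]:
        bf[v] = bayes_factor_directional(draws[v], prior, theta)
    sig[tested] = ok & (bf >= config.bf_threshold)
    return VoxelStatisticMap("bayes", tested, bf, sig)


def apply_occurrence_filters(
    significance: np.ndarray,
    occ: OccurrenceMaps,
    n_patients: int,
    patient_frac: float = 0.25,
    stim_frac: float = 0.10,
) -> np.ndarray:
    """Discard under-sampled voxels.

    A voxel survives only if it was stimulated in at least ``patient_frac``
    of the patients *and* its stimulation count reaches ``stim_frac`` of the
    maximum nMap value.  Comparisons are >= on the exact fractional
    thresholds.
    """
    keep = significance.copy()
    keep &= occ.npatmap >= patient_frac * n_patients
    keep &= occ.nmap >= stim_frac * occ.nmap.max()
    return keep


_CONN_RANK = {6: 1, 18: 2, 26: 3}


def remove_small_clusters(
    mask: np.ndarray,
    grid: VoxelGrid,
    min_volume: float = 1.0,
    connectivity: int = 6,
) -> np.ndarray:
    """Drop connected components strictly smaller than ``min_volume`` mm^3."""
    if connectivity not in _CONN_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])
    labels, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())[1:]  # skip background
    small = np.nonzero(counts * grid.voxel_volume < min_volume)[0] + 1
    out = mask.copy()
    out[np.isin(labels, small)] = False
    return out


_ENGINES = {"wfdr": psm_wfdr, "wperm": psm_wperm, "bayes": psm_bayes}


def extract_pss(dataset: StimulationDataset, config: TestConfig) -> PSSVolume:
    """Full pipeline: voxel-wise test -> occurrence filters -> cluster filter."""
    occ = compute_occurrence_maps(dataset)
    stat_map = _ENGINES[config.method](dataset, config)
    filtered = apply_occurrence_filters(
        stat_map.significant, occ, dataset.n_patients,
        patient_frac=config.patient_frac, stim_frac=config.stim_frac,
    )
    final = remove_small_clusters(
        filtered, dataset.grid,
        min_volume=config.cluster_min_volume, connectivity=config.connectivity,
    )
    provenance = {
        "method": config.method,
        "improvement_threshold": config.improvement_threshold,
        "seed": config.seed,
        "n_patients": dataset.n_patients,
        "n_stimulations": dataset.n_stimulations,
        "n_tested": int(stat_map.tested.sum()),
        "n_significant": int(stat_map.significant.sum()),
        "n_after_occurrence": int(filtered.sum()),
        "n_final": int(final.sum()),
    }
    return PSSVolume(mask=final, grid=dataset.grid, method=config.method, provenance=provenance)
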