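"""Synthetic DBS stimulation cohorts with a known sweet spot.

Generates cohorts carrying the statistical structure the mapping pipeline
assumes, so every downstream stage can be exercised and validated without
clinical data:

* a ground-truth "sweet spot" ellipsoid in the shared grid space,
* per-patient electrode trajectories (two parallel tracks, positions
  spanning a fixed extent at 1 mm steps) along which VTAs are placed,
* VTAs modeled as axis-aligned ellipsoids whose radii grow monotonically
  with stimulation amplitude (a stand-in for electric-field thresholding),
* improvement scores driven by each VTA's overlap with the ground truth,
  with mode-specific marginal distributions: a PD-like mode (wide, mean
  near 50) and an ET-like mode (skewed high, mean near 70).

Scores are quantized to the clinical 0/25/50/75/100 rating scale
(half-steps allowed, i.e. multiples of 12.5) unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import Stimulation, StimulationDataset
from .grid import VoxelGrid

__all__ = [
    "Ellipsoid",
    "CohortConfig",
    "generate_vta",
    "score_stimulation",
    "generate_cohort",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in world (mm) coordinates."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        """Boolean mask of voxels whose centers fall inside the ellipsoid."""
        xs, ys, zs = grid.axis_centers()
        c = self.center
        a = self.semi_axes
        dx2 = ((xs - c[0]) / a[0]) ** 2
        dy2 = ((ys - c[1]) / a[1]) ** 2
        dz2 = ((zs - c[2]) / a[2]) ** 2
        return (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= 1.0


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort.

    The two mode presets (:meth:`pd_like`, :meth:`et_like`) encode the study
    conditions: 36 PD-like patients with 12-22 intra-operative stimulations
    each and a wide score distribution centered near 50; 61 ET-like patients
    with exactly 4 stimulations each and scores skewed toward high values
    with mean near 70.
    """

    n_patients: int
    stims_per_patient: tuple[int, int]
    grid: VoxelGrid
    mode: str  # "pd" | "et"
    ground_truth: Ellipsoid
    trajectory_span: float = 14.0  # mm explored along each track
    trajectory_step: float = 1.0  # mm between stimulation positions
    track_separation: float = 2.0  # mm between the two parallel tracks
    trajectory_jitter_sd: float = 1.5  # mm, per-patient entry-point scatter (x, y)
    trajectory_z_jitter_sd: float = 1.0  # mm, per-patient scatter along the track axis
    amplitude_range: tuple[float, float] = (0.2, 3.0)  # mA
    vta_base_radius: float = 0.5  # mm, radius at zero amplitude
    vta_growth: float = 1.5  # mm per sqrt(mA)
    score_gamma: float = 1.0  # overlap -> score shape, score = 100 * f**gamma
    score_noise_sd: float = 10.0  # percent
    quantization: float | None = 12.5  # percent, None = continuous
    position_concentration: float | None = None  # mm; None = uniform along track
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stims_per_patient
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid stims_per_patient range {self.stims_per_patient}")
        if self.score_noise_sd < 0:
            raise ValueError("score noise sd must be >= 0")
        c = np.asarray(self.ground_truth.center)
        a = np.asarray(self.ground_truth.semi_axes)
        for corner in (c - a, c + a):
            if not self.grid.contains_point(corner):
                raise ValueError("ground-truth ellipsoid extends outside the grid")

    @classmethod
    def pd_like(cls, seed: int = 0, grid: VoxelGrid | None = None, **overrides) -> "CohortConfig":
        """PD-like cohort: 36 patients, 12-22 stimulations, scores ~ mean 50."""
        grid = grid or VoxelGrid(shape=(32, 32, 32))
        center = tuple(
            float(c)
            for c in 0.5 * (np.asarray(grid.shape) - 1) * np.asarray(grid.voxel_size)
            + np.asarray(grid.origin)
        )
        cfg = cls(
            n_patients=36,
            stims_per_patient=(12, 22),
            grid=grid,
            mode="pd",
            ground_truth=Ellipsoid(center=center, semi_axes=(3.5, 3.5, 5.0)),
            score_gamma=0.50,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def et_like(cls, seed: int = 0, grid: VoxelGrid | None = None, **overrides) -> "CohortConfig":
        """ET-like cohort: 61 patients, exactly 4 stimulations, scores ~ mean 70."""
        grid = grid or VoxelGrid(shape=(32, 32, 32))
        center = tuple(
            float(c)
            for c in 0.5 * (np.asarray(grid.shape) - 1) * np.asarray(grid.voxel_size)
            + np.asarray(grid.origin)
        )
        cfg = cls(
            n_patients=61,
            stims_per_patient=(4, 4),
            grid=grid,
            mode="et",
            ground_truth=Ellipsoid(center=center, semi_axes=(3.5, 3.5, 5.0)),
            score_gamma=0.40,
            position_concentration=3.0,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg


def generate_vta(
    grid: VoxelGrid,
    center,
    amplitude: float,
    base_radius: float = 0.5,
    growth: float = 1.5,
) -> np.ndarray:
    """Binary VTA as an axis-aligned ellipsoid around ``center``.

    Radii grow monotonically with amplitude, ``r = base_radius +
    growth * sqrt(amplitude)``, mimicking how the activated volume expands
    with stimulation current.  The voxel nearest to ``center`` is always
    included, so the mask is never empty.
    """
    if amplitude <= 0:
        raise ValueError(f"amplitude must be > 0, got {amplitude}")
    if not grid.contains_point(center):
        raise ValueError(f"VTA center {tuple(center)} outside grid extent")
    r = base_radius + growth * float(np.sqrt(amplitude))
    mask = Ellipsoid(center=tuple(center), semi_axes=(r, r, r)).mask(grid)
    mask[grid.nearest_voxel(center)] = True
    return mask


def score_stimulation(
    mask: np.ndarray,
    ground_truth_mask: np.ndarray,
    gamma: float = 1.0,
    noise_sd: float = 0.0,
    quantization: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Improvement score (percent) from VTA / sweet-spot overlap.

    The noiseless score is ``100 * f ** gamma`` with ``f`` the fraction of
    the VTA inside the ground truth (``gamma=1`` is the identity map).
    Gaussian noise is added, the result clipped to [0, 100] and optionally
    snapped to the rating grid.
    """
    mask = np.asarray(mask, dtype=bool)
    f = np.count_nonzero(mask & ground_truth_mask) / np.count_nonzero(mask)
    base = 100.0 * f**gamma if f > 0 else 0.0
    score = base
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        score += rng.normal(0.0, noise_sd)
    score = float(np.clip(score, 0.0, 100.0))
    if quantization is not None:
        score = float(np.clip(np.round(score / quantization) * quantization, 0.0, 100.0))
    return score


def _patient_candidates(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Candidate stimulation centers for one patient: two parallel tracks.

    Tracks run along z through a jittered entry point near the ground-truth
    center; positions span ``trajectory_span`` mm at ``trajectory_step`` mm
    steps.  Returns (n_candidates, 3) world coordinates.
    """
    c = np.asarray(cfg.ground_truth.center)
    base_xy = c[:2] + rng.normal(0.0, cfg.trajectory_jitter_sd, size=2)
    base_z = c[2] + rng.normal(0.0, cfg.trajectory_z_jitter_sd)
    offsets = np.arange(
        -cfg.trajectory_span / 2, cfg.trajectory_span / 2 + 1e-9, cfg.trajectory_step
    )
    pts = []
    for dx in (-cfg.track_separation / 2, cfg.track_separation / 2):
        for dz in offsets:
            pts.append([base_xy[0] + dx, base_xy[1], base_z + dz])
    return np.asarray(pts)


def generate_cohort(cfg: CohortConfig) -> StimulationDataset:
    """Generate a full synthetic cohort, reproducible for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    gt_mask = cfg.ground_truth.mask(cfg.grid)
    stims: list[Stimulation] = []
    pad = len(str(cfg.n_patients))
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:0{pad}d}"
        cand = _patient_candidates(cfg, rng)
        inside = np.array([cfg.grid.contains_point(pt) for pt in cand])
        if not inside.all():
            raise ValueError(
                f"trajectory for patient {pid} leaves the grid; enlarge the grid "
                "or reduce trajectory span/jitter"
            )
        lo, hi = cfg.stims_per_patient
        n_stims = int(rng.integers(lo, hi + 1))
        if n_stims > len(cand):
            raise ValueError(
                f"patient {pid}: {n_stims} stimulations requested but only "
                f"{len(cand)} trajectory positions available"
            )
        if cfg.position_concentration is not None:
            # bias positions toward the sweet spot, emulating chronic-contact
            # screening where only promising positions are programmed
            dz = np.abs(cand[:, 2] - cfg.ground_truth.center[2])
            w = np.exp(-dz / cfg.position_concentration)
            w /= w.sum()
            chosen = rng.choice(len(cand), size=n_stims, replace=False, p=w)
        else:
            chosen = rng.choice(len(cand), size=n_stims, replace=False)
        for s, ci in enumerate(chosen):
            amp = float(rng.uniform(*cfg.amplitude_range))
            mask = generate_vta(
                cfg.grid, cand[ci], amp, base_radius=cfg.vta_base_radius, growth=cfg.vta_growth
            )
            score = score_stimulation(
                mask,
                gt_mask,
                gamma=cfg.score_gamma,
                noise_sd=cfg.score_noise_sd,
                quantization=cfg.quantization,
                rng=rng if cfg.score_noise_sd > 0 else None,
            )
            stims.append(
                Stimulation(
                    patient_id=pid,
                    stim_id=f"{pid}_S{s + 1:02d}",
                    mask=mask,
                    amplitude=amp,
                    score=score,
                )
            )
    return StimulationDataset(cfg.grid, stims)
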