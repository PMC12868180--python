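"""Stimulation data containers.

A *stimulation* is the atomic observation of intra-/post-operative DBS
testing: one binary volume of tissue activated (VTA) on the shared grid,
labeled with the clinician-rated symptom improvement score (percent).  A
*dataset* is a cohort subset — selected patients and selected stimulations —
on one :class:`~pssmap.grid.VoxelGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

__all__ = ["Stimulation", "StimulationDataset"]


@dataclass
class Stimulation:
    """One VTA with its improvement label.

    ``mask`` is a boolean array on the dataset grid; ``score`` is the
    improvement in percent (0 = no improvement, 100 = excellent).
    """

    patient_id: str
    stim_id: str
    mask: np.ndarray
    amplitude: float
    score: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"stimulation {self.stim_id}: empty mask")
        if not (0.0 <= self.score <= 100.0):
            raise ValueError(f"stimulation {self.stim_id}: score {self.score} outside [0, 100]")


@dataclass
class StimulationDataset:
    """A cohort subset of stimulations on a shared voxel grid."""

    grid: VoxelGrid
    stimulations: list[Stimulation]

    def __post_init__(self) -> None:
        for s in self.stimulations:
            if tuple(s.mask.shape) != self.grid.shape:
                raise ValueError(
                    f"stimulation {s.stim_id}: mask shape {s.mask.shape} "
                    f"does not match grid shape {self.grid.shape}"
                )

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.stimulations:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_stimulations(self) -> int:
        return len(self.stimulations)

    def by_patient(self) -> dict[str, list[Stimulation]]:
        out: dict[str, list[Stimulation]] = {}
        for s in self.stimulations:
            out.setdefault(s.patient_id, []).append(s)
        return out

    def subset_patients(self, patient_ids) -> "StimulationDataset":
        """Dataset restricted to the given patients (order preserved)."""
        wanted = set(patient_ids)
        stims = [s for s in self.stimulations if s.patient_id in wanted]
        missing = wanted - {s.patient_id for s in stims}
        if missing:
            raise KeyError(f"patients not in dataset: {sorted(missing)}")
        return StimulationDataset(self.grid, stims)

    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.stimulations], dtype=float)

    def mask_stack(self) -> np.ndarray:
        """(n_stims, *grid.shape) boolean stack of all masks."""
        return np.stack([s.mask for s in self.stimulations])

    def equals(self, other: "StimulationDataset") -> bool:
        """Bit-exact equality of grids, ordering, masks, scores and ids."""
        if self.grid != other.grid or self.n_stimulations != other.n_stimulations:
            return False
        for a, b in zip(self.stimulations, other.stimulations):
            if (
                a.patient_id != b.patient_id
                or a.stim_id != b.stim_id
                or a.amplitude != b.amplitude
                or a.score != b.score
                or not np.array_equal(a.mask, b.mask)
            ):
                return False
        return True
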