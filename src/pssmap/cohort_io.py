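"""Reading and writing stimulation cohorts.

On disk a cohort is a directory with one uint8 NIfTI mask per stimulation
under ``masks/`` and a ``cohort.csv`` table with columns ``patient_id,
stim_id, mask_file, amplitude, score``.  The round trip is lossless: masks
bit-exact, amplitudes and scores to full float precision.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dataset import Stimulation, StimulationDataset
from .grid import VoxelGrid

__all__ = ["write_cohort", "read_cohort", "CohortFormatError"]

TABLE_NAME = "cohort.csv"
MASK_DIR = "masks"
_COLUMNS = ["patient_id", "stim_id", "mask_file", "amplitude", "score"]


class CohortFormatError(ValueError):
    """Malformed cohort directory: bad table, missing mask, or grid mismatch."""


def write_cohort(dataset: StimulationDataset, directory) -> Path:
    """Write a dataset to ``directory``; returns the table path."""
    directory = Path(directory)
    (directory / MASK_DIR).mkdir(parents=True, exist_ok=True)
    affine = dataset.grid.affine
    rows = []
    for s in dataset.stimulations:
        fname = f"{MASK_DIR}/{s.stim_id}.nii.gz"
        img = nib.Nifti1Image(s.mask.astype(np.uint8), affine)
        nib.save(img, directory / fname)
        rows.append(
            {
                "patient_id": s.patient_id,
                "stim_id": s.stim_id,
                "mask_file": fname,
                "amplitude": repr(float(s.amplitude)),
                "score": repr(float(s.score)),
            }
        )
    table = directory / TABLE_NAME
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(table, index=False)
    return table


def _grid_from_image(img: nib.Nifti1Image, path: Path) -> VoxelGrid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise CohortFormatError(f"{path.name}: non-axis-aligned affine unsupported")
    return VoxelGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size=tuple(float(v) for v in np.diag(aff[:3, :3])),
        origin=tuple(float(o) for o in aff[:3, 3]),
    )


def read_cohort(directory) -> StimulationDataset:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    table = directory / TABLE_NAME
    if not table.exists():
        raise CohortFormatError(f"missing table {table}")
    df = pd.read_csv(
        table,
        dtype={"patient_id": str, "stim_id": str, "mask_file": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"{table.name}: missing columns {missing_cols}")
    grid: VoxelGrid | None = None
    stims: list[Stimulation] = []
    for i, row in df.iterrows():
        mask_path = directory / row["mask_file"]
        if not mask_path.exists():
            raise CohortFormatError(
                f"{table.name} row {i} (stim_id={row['stim_id']}): "
                f"mask file {row['mask_file']} not found"
            )
        img = nib.load(mask_path)
        g = _grid_from_image(img, mask_path)
        if grid is None:
            grid = g
        elif g != grid:
            raise CohortFormatError(
                f"{mask_path.name}: grid {g.shape}/{g.voxel_size} does not match "
                f"cohort grid {grid.shape}/{grid.voxel_size}"
            )
        mask = np.asarray(img.dataobj) > 0
        stims.append(
            Stimulation(
                patient_id=str(row["patient_id"]),
                stim_id=str(row["stim_id"]),
                mask=mask,
                amplitude=float(row["amplitude"]),
                score=float(row["score"]),
            )
        )
    if grid is None:
        raise CohortFormatError(f"{table.name}: no stimulations")
    return StimulationDataset(grid, stims)
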