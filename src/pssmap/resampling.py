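"""Patient- and stimulation-level subsampling for the stability analysis.

Patient subgroups follow an additive, without-replacement scheme: a chain
starts from ``start_size`` randomly chosen patients and grows by ``step``
randomly chosen remaining patients per level, so consecutive levels are
nested.  Ten independent chains (by default) plus the shared full cohort
give the patient datasets; each is then expanded by drawing a fixed number
of stimulations per patient (4, 6, 8, 10, 12 by default), three independent
draws per combination.  With the default plan on a 36-patient cohort this
yields 160 subgroup datasets + the full cohort = 161, and 161 x 5 x 3 =
2415 datasets overall.

Every dataset is regenerable from ``(master_seed, key)`` alone — nothing
needs to be stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .dataset import StimulationDataset

__all__ = [
    "SamplingPlan",
    "DatasetKey",
    "additive_patient_chains",
    "subsample_stimulations",
    "DatasetGrid",
]

FULL_COHORT_REP = 0  # patient_rep value marking the shared full-cohort dataset


@dataclass(frozen=True)
class SamplingPlan:
    start_size: int = 4
    step: int = 2
    n_patient_reps: int = 10
    stim_counts: tuple[int, ...] = (4, 6, 8, 10, 12)
    n_stim_reps: int = 3
    include_full_cohort: bool = True

    def __post_init__(self) -> None:
        if self.start_size < 2 or self.step < 1:
            raise ValueError("start_size must be >= 2 and step >= 1")
        if self.n_patient_reps < 1 or self.n_stim_reps < 1:
            raise ValueError("repetition counts must be >= 1")
        if any(c < 1 for c in self.stim_counts):
            raise ValueError("stim_counts must all be >= 1")

    def subgroup_sizes(self, n_patients: int) -> list[int]:
        """Chain levels: start, start+step, ... strictly below the cohort size."""
        if n_patients < self.start_size:
            raise ValueError(
                f"cohort of {n_patients} patients smaller than start size {self.start_size}"
            )
        return list(range(self.start_size, n_patients, self.step))


class DatasetKey(NamedTuple):
    """Unique identifier of one generated dataset.

    ``patient_rep`` 0 denotes the shared full cohort; chains are 1-based.
    """

    n_pat: int
    patient_rep: int
    n_stim: int
    stim_rep: int


def _chain_rng(master_seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, 101, rep)))


def _stim_rng(master_seed: int, key: DatasetKey) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((master_seed, 202, key.n_pat, key.patient_rep,
                                key.n_stim, key.stim_rep))
    )


def additive_patient_chains(
    patient_ids: list[str], plan: SamplingPlan, master_seed: int = 0
) -> list[list[tuple[str, ...]]]:
    """Independent nested chains of patient subsets.

    Each chain is a list of tuples of sizes ``start, start+step, ...`` (all
    below the cohort size); level ``k`` is a prefix-extension of level
    ``k-1``, i.e. earlier patients are never dropped.
    """
    sizes = plan.subgroup_sizes(len(patient_ids))
    chains = []
    for rep in range(1, plan.n_patient_reps + 1):
        order = list(_chain_rng(master_seed, rep).permutation(patient_ids))
        chains.append([tuple(order[:s]) for s in sizes])
    return chains


def subsample_stimulations(
    dataset: StimulationDataset, n_stim: int, rng: np.random.Generator
) -> StimulationDataset:
    """Retain exactly ``n_stim`` stimulations per patient, drawn without
    replacement; masks and scores untouched."""
    kept = []
    for pid, stims in dataset.by_patient().items():
        if len(stims) < n_stim:
            raise ValueError(
                f"patient {pid} has {len(stims)} stimulations, cannot sample {n_stim}"
            )
        chosen = rng.choice(len(stims), size=n_stim, replace=False)
        kept.extend(stims[i] for i in sorted(chosen))
    return StimulationDataset(dataset.grid, kept)


@dataclass
class DatasetGrid:
    """Lazy collection of all (patient subset x stimulation subsample) datasets.

    Datasets are materialized on demand from ``(master_seed, key)``; the
    full cohort (``patient_rep = 0``) is one shared patient set that
    terminates every chain's curve.
    """

    cohort: StimulationDataset
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    master_seed: int = 0

    def __post_init__(self) -> None:
        self._chains = additive_patient_chains(
            self.cohort.patient_ids, self.plan, self.master_seed
        )
        self._full = tuple(self.cohort.patient_ids)

    @property
    def subgroup_sizes(self) -> list[int]:
        return self.plan.subgroup_sizes(self.cohort.n_patients)

    def patient_sets(self) -> dict[tuple[int, int], tuple[str, ...]]:
        """(n_pat, patient_rep) -> patient-id tuple, full cohort included."""
        out = {}
        for rep, chain in enumerate(self._chains, start=1):
            for subset in chain:
                out[(len(subset), rep)] = subset
        if self.plan.include_full_cohort:
            out[(len(self._full), FULL_COHORT_REP)] = self._full
        return out

    @property
    def n_patient_datasets(self) -> int:
        return len(self.patient_sets())

    @property
    def n_datasets(self) -> int:
        return self.n_patient_datasets * len(self.plan.stim_counts) * self.plan.n_stim_reps

    def keys(self) -> Iterator[DatasetKey]:
        for (n_pat, rep) in self.patient_sets():
            for n_stim in self.plan.stim_counts:
                for stim_rep in range(1, self.plan.n_stim_reps + 1):
                    yield DatasetKey(n_pat, rep, n_stim, stim_rep)

    def patient_dataset(self, n_pat: int, patient_rep: int) -> StimulationDataset:
        subset = self.patient_sets()[(n_pat, patient_rep)]
        return self.cohort.subset_patients(subset)

    def dataset(self, key: DatasetKey) -> StimulationDataset:
        base = self.patient_dataset(key.n_pat, key.patient_rep)
        return subsample_stimulations(base, key.n_stim, _stim_rng(self.master_seed, key))
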