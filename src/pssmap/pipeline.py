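"""End-to-end orchestration: simulate -> map -> curves -> stability -> boundary.

A :class:`RunConfig` bundles every stage's settings; :func:`run_pipeline`
executes the stages in order, caching each sweet-spot volume on disk keyed
by a hash of the configuration so interrupted or repeated runs only
recompute what is missing.  All outputs are CSV/JSON; volumes are cached
as compressed numpy archives and can be exported to NIfTI on demand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .boundary import evaluate_model, fit_boundary_model, minimum_stim_boundary
from .bayes import NormalPrior
from .dataset import StimulationDataset
from .grid import VoxelGrid
from .mapping import PSSVolume, TestConfig, extract_pss
from .resampling import DatasetGrid, DatasetKey, SamplingPlan
from .stability import build_stability_dataset, stability_points_table
from .synthetic import CohortConfig, Ellipsoid, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "compute_pss_grid", "prior_sensitivity_sweep"]

log = logging.getLogger("pssmap")


@dataclass
class RunConfig:
    """Full pipeline configuration with the study-condition defaults."""

    cohort: CohortConfig
    methods: tuple[str, ...] = ("bayes", "wfdr", "wperm")
    test: TestConfig = field(default_factory=TestConfig)
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    stability_tolerance: float = 5.0
    boundary_prior_sd: float = 10.0
    boundary_num_samples: int = 2000
    boundary_warmup: int = 1000
    probe_n_pat: tuple[int, int] = (4, 100)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohort_raw = dict(raw["cohort"])
        mode = cohort_raw.pop("mode", "pd")
        grid_raw = cohort_raw.pop("grid", None)
        grid = VoxelGrid(**grid_raw) if grid_raw else None
        gt_raw = cohort_raw.pop("ground_truth", None)
        if gt_raw:
            cohort_raw["ground_truth"] = Ellipsoid(
                center=tuple(gt_raw["center"]), semi_axes=tuple(gt_raw["semi_axes"])
            )
        maker = CohortConfig.pd_like if mode == "pd" else CohortConfig.et_like
        cohort = maker(grid=grid, **cohort_raw)
        kwargs: dict = {"cohort": cohort}
        if "test" in raw:
            test_raw = dict(raw["test"])
            if "prior" in test_raw:
                test_raw["prior"] = NormalPrior(**test_raw["prior"])
            kwargs["test"] = TestConfig(**test_raw)
        if "plan" in raw:
            plan_raw = dict(raw["plan"])
            if "stim_counts" in plan_raw:
                plan_raw["stim_counts"] = tuple(plan_raw["stim_counts"])
            kwargs["plan"] = SamplingPlan(**plan_raw)
        for key in (
            "methods", "stability_tolerance", "boundary_prior_sd",
            "boundary_num_samples", "boundary_warmup", "probe_n_pat", "master_seed",
        ):
            if key in raw:
                val = raw[key]
                kwargs[key] = tuple(val) if isinstance(val, list) else val
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _key_name(method: str, key: DatasetKey) -> str:
    return f"{method}_p{key.n_pat:03d}r{key.patient_rep:02d}_s{key.n_stim:02d}x{key.stim_rep}"


def compute_pss_grid(
    dsgrid: DatasetGrid,
    config: TestConfig,
    method: str,
    cache_dir: Path | None = None,
) -> dict[DatasetKey, PSSVolume]:
    """Sweet spot for every dataset key, using the on-disk cache if given."""
    out: dict[DatasetKey, PSSVolume] = {}
    cfg = dataclasses.replace(config, method=method)
    for key in dsgrid.keys():
        cache_file = cache_dir / f"{_key_name(method, key)}.npz" if cache_dir else None
        if cache_file is not None and cache_file.exists():
            with np.load(cache_file, allow_pickle=False) as npz:
                mask = npz["mask"].astype(bool)
                provenance = json.loads(str(npz["provenance"]))
            out[key] = PSSVolume(mask, dsgrid.cohort.grid, method, provenance)
            continue
        pss = extract_pss(dsgrid.dataset(key), cfg)
        log.info(
            "PSS %s %s: tested=%d significant=%d final=%d",
            method, key, pss.provenance["n_tested"],
            pss.provenance["n_significant"], pss.provenance["n_final"],
        )
        if cache_file is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(
                cache_file,
                mask=pss.mask.astype(np.uint8),
                provenance=np.array(json.dumps(pss.provenance)),
            )
        out[key] = pss
    return out


def run_pipeline(config: RunConfig, output_dir) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    cache_dir = output_dir / "cache" / chash
    manifest: dict = {"config_hash": chash, "master_seed": config.master_seed, "artifacts": []}

    log.info("generating cohort (mode=%s, %d patients)", config.cohort.mode, config.cohort.n_patients)
    cohort = generate_cohort(config.cohort)
    dsgrid = DatasetGrid(cohort, config.plan, config.master_seed)
    log.info("dataset grid: %d datasets", dsgrid.n_datasets)

    all_curves, all_records, boundaries, evaluations = [], [], [], {}
    for method in config.methods:
        pss = compute_pss_grid(dsgrid, config.test, method, cache_dir)
        curves = geometry.successive_comparisons(pss, dsgrid)
        curves = pd.concat([curves, geometry.combined_metric(curves)], ignore_index=True)
        all_curves.append(curves)
        records = build_stability_dataset(
            curves[curves["metric"].isin(geometry.PAIR_METRICS)], config.stability_tolerance
        )
        all_records.append(records)
        post = fit_boundary_model(
            records,
            prior_sd=config.boundary_prior_sd,
            num_samples=config.boundary_num_samples,
            warmup_steps=config.boundary_warmup,
            seed=config.master_seed,
        )
        curve = minimum_stim_boundary(post, range(config.probe_n_pat[0], config.probe_n_pat[1] + 1))
        curve.insert(0, "method", method)
        curve.insert(1, "metric_set", "all")
        boundaries.append(curve)
        if not post.degenerate and records["label"].nunique() == 2 and \
                min(np.bincount(records["label"], minlength=2)) >= 2:
            evaluations[method] = evaluate_model(records, seed=config.master_seed)
        else:
            evaluations[method] = {"degenerate": True}

    curves_df = pd.concat(all_curves, ignore_index=True)
    records_df = pd.concat(all_records, ignore_index=True)
    points_df = stability_points_table(
        curves_df, config.stability_tolerance
    )
    non_empty = [b for b in boundaries if not b.empty]
    boundary_df = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else pd.DataFrame(columns=["method", "metric_set", "n_pat", "mean",
                                   "ci_low", "ci_high", "censored_frac"])
    )

    outputs = {
        "curves.csv": curves_df,
        "stability_points.csv": points_df,
        "stability_records.csv": records_df,
        "boundary.csv": boundary_df,
    }
    for name, df in outputs.items():
        path = output_dir / name
        df.to_csv(path, index=False)
        manifest["artifacts"].append({"stage": name.split(".")[0], "path": name})
    (output_dir / "evaluation.json").write_text(json.dumps(evaluations, indent=2))
    manifest["artifacts"].append({"stage": "evaluation", "path": "evaluation.json"})
    manifest["n_datasets"] = dsgrid.n_datasets
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def prior_sensitivity_sweep(
    dataset: StimulationDataset,
    config: TestConfig,
    priors: list[NormalPrior],
) -> pd.DataFrame:
    """Re-extract the Bayesian sweet spot under each prior on a fixed dataset.

    Reports per prior: surviving voxel count, volume, centroid, and Dice
    against the first prior's sweet spot (the reference).
    """
    if not priors:
        raise ValueError("prior sweep grid is empty")
    rows = []
    reference: PSSVolume | None = None
    for prior in priors:
        cfg = dataclasses.replace(config, method="bayes", prior=prior)
        pss = extract_pss(dataset, cfg)
        if reference is None:
            reference = pss
        c = pss.centroid()
        rows.append(
            {
                "mu_loc": prior.mu_loc,
                "mu_scale": prior.mu_scale,
                "sigma_scale": prior.sigma_scale,
                "n_voxels": pss.n_voxels,
                "volume_mm3": pss.volume_mm3,
                "centroid_x": np.nan if c is None else c[0],
                "centroid_y": np.nan if c is None else c[1],
                "centroid_z": np.nan if c is None else c[2],
                "dice_vs_reference": geometry.dice(pss, reference),
            }
        )
    return pd.DataFrame(rows)
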