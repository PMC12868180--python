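"""Geometric variability of sweet-spot volumes.

Pairwise metrics between two PSS volumes, all expressed in percent so they
are comparable across cohorts and grids:

* ``vol_diff``   — volume difference normalized by the larger volume,
* ``dice``       — Dice overlap coefficient,
* ``centr_dist`` — centroid distance normalized by the larger
  equivalent-sphere diameter (may exceed 100 for well-separated volumes).

Undefined values (e.g. Dice of two empty volumes, centroid distance when a
volume is empty) are represented as NaN and excluded from averages.  The
``successive_comparisons`` routine implements the curve construction: for
each chain and each pair of consecutive patient sample sizes, all cross
pairs of stimulation re-draws are compared, averaged, and then averaged
across chains, indexed at the larger size of each pair.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .mapping import PSSVolume
from .resampling import FULL_COHORT_REP, DatasetGrid, DatasetKey

__all__ = [
    "volume",
    "centroid",
    "diameter",
    "vol_diff",
    "dice",
    "centr_dist",
    "successive_comparisons",
    "combined_metric",
    "PAIR_METRICS",
]

PAIR_METRICS = ("vol_diff", "dice", "centr_dist")


def volume(pss: PSSVolume) -> float:
    """Volume in mm^3 (0 for an empty PSS)."""
    return pss.volume_mm3


def centroid(pss: PSSVolume) -> np.ndarray:
    """Unweighted mean of member voxel-center world coordinates."""
    c = pss.centroid()
    if c is None:
        raise ValueError("centroid of an empty PSS is undefined")
    return c


def diameter(pss: PSSVolume) -> float:
    """Equivalent-sphere diameter (6V/pi)^(1/3) in mm."""
    v = pss.volume_mm3
    if v <= 0:
        raise ValueError("diameter of an empty PSS is undefined")
    return (6.0 * v / math.pi) ** (1.0 / 3.0)


def vol_diff(a: PSSVolume, b: PSSVolume) -> float:
    """100 * |V(a) - V(b)| / max(V(a), V(b)); 0 if both empty, 100 if one is."""
    va, vb = a.volume_mm3, b.volume_mm3
    if va == 0 and vb == 0:
        return 0.0
    return 100.0 * abs(va - vb) / max(va, vb)


def dice(a: PSSVolume, b: PSSVolume) -> float:
    """100 * 2|A n B| / (|A| + |B|); NaN if both empty, 0 if exactly one is."""
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        return float("nan")
    if na == 0 or nb == 0:
        return 0.0
    inter = int(np.count_nonzero(a.mask & b.mask))
    return 100.0 * 2.0 * inter / (na + nb)


def centr_dist(a: PSSVolume, b: PSSVolume) -> float:
    """Centroid distance as percent of the larger equivalent-sphere diameter.

    NaN if either volume is empty (no position to compare).
    """
    if a.is_empty or b.is_empty:
        return float("nan")
    d = float(np.linalg.norm(centroid(a) - centroid(b)))
    return 100.0 * d / max(diameter(a), diameter(b))


_METRIC_FUNCS = {"vol_diff": vol_diff, "dice": dice, "centr_dist": centr_dist}


def successive_comparisons(
    pss_by_key: dict[DatasetKey, PSSVolume],
    grid: DatasetGrid,
    metrics: tuple[str, ...] = PAIR_METRICS,
) -> pd.DataFrame:
    """Metric curves from PSS volumes of all sampled datasets (one method).

    Returns a tidy frame with columns ``method, metric, n_stim, n_pat,
    mean, sd, n_pairs``: for each chain and consecutive size pair
    (s -> s'), every cross pair of stimulation re-draws is compared and
    averaged; values are then averaged across chains and indexed at s'.
    ``sd`` is the across-chain standard deviation, ``n_pairs`` the total
    number of defined pairwise comparisons behind the point.
    """
    plan = grid.plan
    sizes = grid.subgroup_sizes
    method = next(iter(pss_by_key.values())).method if pss_by_key else "?"
    rows = []
    for metric in metrics:
        func = _METRIC_FUNCS[metric]
        for n_stim in plan.stim_counts:
            # per chain: list of (target size, value over stim cross-pairs)
            chain_points: dict[int, list[tuple[int, float, int]]] = {}
            for rep in range(1, plan.n_patient_reps + 1):
                levels: list[tuple[int, int]] = [(s, rep) for s in sizes]
                if plan.include_full_cohort:
                    levels.append((grid.cohort.n_patients, FULL_COHORT_REP))
                pts = []
                for (s_lo, rep_lo), (s_hi, rep_hi) in zip(levels[:-1], levels[1:]):
                    vals = []
                    for i, j in itertools.product(
                        range(1, plan.n_stim_reps + 1), repeat=2
                    ):
                        ka = DatasetKey(s_lo, rep_lo, n_stim, i)
                        kb = DatasetKey(s_hi, rep_hi, n_stim, j)
                        if ka not in pss_by_key or kb not in pss_by_key:
                            continue
                        vals.append(func(pss_by_key[ka], pss_by_key[kb]))
                    defined = [v for v in vals if not math.isnan(v)]
                    pts.append(
                        (s_hi, float(np.mean(defined)) if defined else float("nan"),
                         len(defined))
                    )
                chain_points[rep] = pts
            n_levels = len(next(iter(chain_points.values())))
            for lvl in range(n_levels):
                n_pat = chain_points[1][lvl][0]
                vals = [chain_points[r][lvl][1] for r in chain_points]
                counts = sum(chain_points[r][lvl][2] for r in chain_points)
                defined = [v for v in vals if not math.isnan(v)]
                rows.append(
                    {
                        "method": method,
                        "metric": metric,
                        "n_stim": n_stim,
                        "n_pat": n_pat,
                        "mean": float(np.mean(defined)) if defined else float("nan"),
                        "sd": float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0,
                        "n_pairs": counts,
                    }
                )
    return pd.DataFrame(rows)


def combined_metric(curves: pd.DataFrame) -> pd.DataFrame:
    """Point-wise unweighted mean of vol_diff, dice and centr_dist curves.

    A point is undefined (NaN) whenever any component is undefined.
    Returns rows with ``metric = "m_comb"``.
    """
    need = set(PAIR_METRICS)
    have = set(curves["metric"].unique())
    if not need <= have:
        raise ValueError(f"combined metric needs curves for {sorted(need)}, got {sorted(have)}")
    sub = curves[curves["metric"].isin(PAIR_METRICS)]
    rows = []
    for (method, n_stim, n_pat), g in sub.groupby(["method", "n_stim", "n_pat"]):
        if len(g) != len(PAIR_METRICS):
            continue
        vals = g["mean"].to_numpy()
        rows.append(
            {
                "method": method,
                "metric": "m_comb",
                "n_stim": n_stim,
                "n_pat": n_pat,
                "mean": float("nan") if np.isnan(vals).any() else float(vals.mean()),
                "sd": float(g["sd"].mean()),
                "n_pairs": int(g["n_pairs"].min()),
            }
        )
    return pd.DataFrame(rows).sort_values(["method", "n_stim", "n_pat"]).reset_index(drop=True)
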