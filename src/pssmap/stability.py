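"""Stability points on metric curves and the binary stability dataset.

A metric curve (variability vs number of patients, for one statistical
method and stimulation count) is *stable* from the earliest support point
after which every later point stays within ``tolerance`` percentage points
of the curve's final value (the full-cohort point).  A stability point
that would coincide with the final point only, or a curve whose tail
contains undefined values, yields NOT-EXISTING (None).

Each curve point then becomes a binary record — 1 if its patient count is
at or beyond the stability point, 0 otherwise (all 0 for NOT-EXISTING) —
with the total stimulation count ``n_pat * n_stim`` as the feature used by
the boundary model.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "find_stability_point",
    "stability_points_table",
    "build_stability_dataset",
    "assemble_all_metrics",
]

DEFAULT_TOLERANCE = 5.0  # percentage points on the metric scale


def find_stability_point(
    n_pat, values, tolerance: float = DEFAULT_TOLERANCE
) -> int | None:
    """Earliest n_pat from which the curve stays within tolerance of its end.

    ``values`` may contain NaN for undefined points; an undefined point in
    the tail vetoes stability for everything before it.  Returns the n_pat
    of the stability point, or None (NOT-EXISTING).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    n_pat = np.asarray(n_pat)
    values = np.asarray(values, dtype=float)
    if n_pat.size != values.size:
        raise ValueError("n_pat and values must align")
    order = np.argsort(n_pat)
    n_pat, values = n_pat[order], values[order]
    defined = ~np.isnan(values)
    if defined.sum() < 2:
        return None
    last = values.size - 1
    if not defined[last]:
        return None
    final = values[last]
    i = last
    for j in range(last - 1, -1, -1):
        if not defined[j] or abs(values[j] - final) >= tolerance:
            break
        i = j
    if i == last:
        return None
    return int(n_pat[i])


def stability_points_table(
    curves: pd.DataFrame, tolerance: float = DEFAULT_TOLERANCE
) -> pd.DataFrame:
    """Stability point per (method, metric, n_stim); NaN marks NOT-EXISTING."""
    rows = []
    for (method, metric, n_stim), g in curves.groupby(["method", "metric", "n_stim"]):
        pt = find_stability_point(g["n_pat"].to_numpy(), g["mean"].to_numpy(), tolerance)
        rows.append(
            {
                "method": method,
                "metric": metric,
                "n_stim": n_stim,
                "n_pat_stable": float("nan") if pt is None else pt,
            }
        )
    return pd.DataFrame(rows)


def build_stability_dataset(
    curves: pd.DataFrame, tolerance: float = DEFAULT_TOLERANCE
) -> pd.DataFrame:
    """Binary stability records, one per curve support point.

    Columns: method, metric, n_pat, n_stim, total_stims, label.  Labels are
    1 iff ``n_pat >= n_pat_stable`` for that curve; all 0 when the curve has
    no stability point.
    """
    points = stability_points_table(curves, tolerance)
    lookup = {
        (r.method, r.metric, r.n_stim): r.n_pat_stable for r in points.itertuples()
    }
    rows = []
    for r in curves.itertuples():
        stable_at = lookup[(r.method, r.metric, r.n_stim)]
        label = 0 if math.isnan(stable_at) else int(r.n_pat >= stable_at)
        rows.append(
            {
                "method": r.method,
                "metric": r.metric,
                "n_pat": int(r.n_pat),
                "n_stim": int(r.n_stim),
                "total_stims": int(r.n_pat) * int(r.n_stim),
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def assemble_all_metrics(per_metric_records: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool stability records across metrics for one statistical method.

    Metric provenance is retained in the ``metric`` column; mixing methods
    is an error (the boundary model stays method-specific).
    """
    pooled = pd.concat(per_metric_records, ignore_index=True)
    methods = pooled["method"].unique()
    if len(methods) != 1:
        raise ValueError(f"records mix methods {sorted(methods)}; pool per method")
    return pooled
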