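"""One-sample, one-sided Wilcoxon signed-rank testing.

The voxel-wise hypotheses are H0: improvement < theta vs H1: improvement
>= theta, tested on the signed ranks of (score - theta).  Zero differences
are discarded before ranking (classic signed-rank convention).  Because
clinical ratings are heavily tied (multiples of 12.5), the exact null is
computed *conditionally on the observed tie pattern* via a
generating-function convolution over sign assignments; above ``exact_max``
observations a tie-corrected normal approximation with continuity
correction is used.

The module also provides fully vectorized variants over a padded score
matrix (one row per voxel), which the permutation-correction engine relies
on: recomputing thousands of voxel statistics per permutation must not pay
per-voxel Python overhead.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["wilcoxon_one_sided", "signed_rank_z_matrix", "wilcoxon_p_matrix"]

EXACT_MAX_DEFAULT = 25


def _exact_sf(ranks2: np.ndarray, w2_obs: int) -> float:
    """P(W+ >= w_obs) under random signs, from doubled ranks (integers).

    ``ranks2`` are 2x the (possibly midrank) ranks of |differences|, so all
    entries are integers even under ties.  The null distribution of
    2*W+ = sum of a random subset of ``ranks2`` is built by polynomial
    convolution; exact up to float renormalization at the end.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[:-r] if r > 0 else counts
    return float(counts[w2_obs:].sum() / counts.sum())


def wilcoxon_one_sided(
    scores, theta: float, exact_max: int = EXACT_MAX_DEFAULT
) -> float:
    """Raw one-sided p-value for H1: location >= theta.

    Returns 1.0 when every score equals ``theta`` (no usable differences,
    hence no evidence against H0).
    """
    d = np.asarray(scores, dtype=float) - theta
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    ranks = sps.rankdata(absd)  # midranks
    w_plus = ranks[d > 0].sum()
    if n <= exact_max:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        return _exact_sf(ranks2, int(np.rint(2 * w_plus)))
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(ranks) / 48.0
    if var <= 0:
        return 1.0 if w_plus <= mean else 0.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(sps.norm.sf(z))


def _tie_term(ranks: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t), from midranks of one sample."""
    # element-wise: a group of size t contributes t*(t^2-1) = sum_i (c_i^2 - 1)
    r_min = sps.rankdata(ranks, method="min")
    r_max = sps.rankdata(ranks, method="max")
    c = r_max - r_min + 1
    return float(np.sum(c**2 - 1))


def _prepare_matrix(score_matrix: np.ndarray, theta: float):
    """Differences, validity mask and midranks for a padded score matrix.

    ``score_matrix`` is (n_rows, max_n) with NaN padding.  Zero differences
    and padding are pushed to +inf so they take the largest ranks and do not
    disturb the ranks of usable entries.
    """
    d = score_matrix - theta
    valid = np.isfinite(d) & (d != 0)
    absd = np.where(valid, np.abs(d), np.inf)
    ranks = sps.rankdata(absd, axis=1)
    r_min = sps.rankdata(absd, axis=1, method="min")
    r_max = sps.rankdata(absd, axis=1, method="max")
    c = np.where(valid, r_max - r_min + 1, 0.0)
    tie_term = np.sum(c**2 - np.where(valid, 1.0, 0.0), axis=1)
    n = valid.sum(axis=1)
    w_plus = np.where(valid & (d > 0), ranks, 0.0).sum(axis=1)
    return d, valid, ranks, n, w_plus, tie_term


def signed_rank_z_matrix(score_matrix: np.ndarray, theta: float) -> np.ndarray:
    """Tie-corrected standardized W+ per row; -inf for rows with no data.

    This is the voxel statistic used for max-statistic permutation
    correction: standardization makes rows with different sample sizes
    comparable, and larger z means stronger evidence for H1.
    """
    _, _, _, n, w_plus, tie_term = _prepare_matrix(score_matrix, theta)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w_plus - mean) / np.sqrt(var)
    z = np.where((n == 0) | (var <= 0), -np.inf, z)
    return z


def wilcoxon_p_matrix(
    score_matrix: np.ndarray, theta: float, exact_max: int = EXACT_MAX_DEFAULT
) -> np.ndarray:
    """Raw one-sided p per row of a padded score matrix.

    Rows with <= ``exact_max`` usable differences get the exact conditional
    null; larger rows the tie-corrected normal approximation.  Rows with no
    usable differences get p = 1.
    """
    d, valid, ranks, n, w_plus, tie_term = _prepare_matrix(score_matrix, theta)
    p = np.ones(score_matrix.shape[0], dtype=float)
    approx = n > exact_max
    if approx.any():
        na = n[approx]
        mean = na * (na + 1) / 4.0
        var = na * (na + 1) * (2 * na + 1) / 24.0 - tie_term[approx] / 48.0
        z = (w_plus[approx] - mean - 0.5) / np.sqrt(np.maximum(var, 1e-12))
        p[approx] = sps.norm.sf(z)
    exact_rows = np.nonzero((n > 0) & ~approx)[0]
    for i in exact_rows:
        ranks2 = np.rint(2 * ranks[i, valid[i]]).astype(np.int64)
        p[i] = _exact_sf(ranks2, int(np.rint(2 * w_plus[i])))
    return p
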