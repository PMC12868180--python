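"""Bayesian logistic stability boundary in the nPat-nStim plane.

The probability that a sweet-spot map is geometrically stable is modeled
as ``P(stable) = logistic(b0 + b1 * total_stims)`` where ``total_stims =
n_pat * n_stim`` captures the joint contribution of cohort size and
per-patient stimulation count.  Posterior draws of (b0, b1) under
weakly-informative Normal(0, 10^2) priors (feature standardized
internally) are obtained by random-walk Metropolis calibrated with a
Laplace approximation at the posterior mode.

For each patient count the minimum number of stimulations per patient
reaching ``P(stable) >= p*`` is computed per draw as ``ceil(T / n_pat)``
with ``T = (logit(p*) - b0) / b1`` the threshold total; draws with
non-positive slope are censored at a cap so credible intervals keep their
meaning.  The resulting mean boundary decays like 1/n_pat — convex and
non-increasing in the patient count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import train_test_split

__all__ = [
    "BoundaryPosterior",
    "fit_boundary_model",
    "stability_probability",
    "minimum_stim_boundary",
    "evaluate_model",
]

PRIOR_SD_DEFAULT = 10.0


@dataclass
class BoundaryPosterior:
    """Posterior draws of the logistic parameters on the raw total-stims scale."""

    beta0: np.ndarray
    beta1: np.ndarray
    degenerate: bool = False  # single-class training data
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta0.size


def _log_posterior(b, xs, y, prior_sd):
    eta = b[0] + b[1] * xs
    # log sigmoid / log(1 - sigmoid), numerically stable
    loglik = np.sum(y * -np.logaddexp(0.0, -eta) + (1.0 - y) * -np.logaddexp(0.0, eta))
    return loglik - (b[0] ** 2 + b[1] ** 2) / (2.0 * prior_sd**2)


def fit_boundary_model(
    records: pd.DataFrame,
    prior_sd: float = PRIOR_SD_DEFAULT,
    num_samples: int = 2000,
    warmup_steps: int = 1000,
    seed: int = 0,
) -> BoundaryPosterior:
    """Fit the Bayesian logistic regression on (total_stims, label) records.

    Returns a degenerate posterior (no draws) when the records contain a
    single class — there is no boundary to estimate and downstream curves
    report NOT-EXISTING.
    """
    x = records["total_stims"].to_numpy(dtype=float)
    y = records["label"].to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        return BoundaryPosterior(
            beta0=np.empty(0), beta1=np.empty(0), degenerate=True,
            diagnostics={"reason": f"single-class data (label={classes.tolist()})"},
        )
    m, s = x.mean(), x.std()
    s = s if s > 0 else 1.0
    xs = (x - m) / s

    neg = lambda b: -_log_posterior(b, xs, y, prior_sd)
    res = optimize.minimize(neg, x0=np.zeros(2), method="BFGS")
    mode = res.x
    # Laplace covariance from the analytic Hessian of the negative log posterior
    p = expit(mode[0] + mode[1] * xs)
    w = p * (1.0 - p)
    X = np.column_stack([np.ones_like(xs), xs])
    hess = X.T @ (X * w[:, None]) + np.eye(2) / prior_sd**2
    cov = np.linalg.inv(hess)
    prop_chol = np.linalg.cholesky(cov * 2.4**2 / 2.0)

    rng = np.random.default_rng(seed)
    b = mode.copy()
    lp = _log_posterior(b, xs, y, prior_sd)
    draws = np.empty((num_samples, 2))
    accepted = 0
    for it in range(warmup_steps + num_samples):
        prop = b + prop_chol @ rng.standard_normal(2)
        lp_prop = _log_posterior(prop, xs, y, prior_sd)
        if math.log(rng.uniform()) < lp_prop - lp:
            b, lp = prop, lp_prop
            accepted += 1
        if it >= warmup_steps:
            draws[it - warmup_steps] = b
    beta1 = draws[:, 1] / s
    beta0 = draws[:, 0] - draws[:, 1] * m / s
    return BoundaryPosterior(
        beta0=beta0,
        beta1=beta1,
        diagnostics={
            "accept_rate": accepted / (warmup_steps + num_samples),
            "feature_mean": m,
            "feature_sd": s,
        },
    )


def stability_probability(posterior: BoundaryPosterior, total_stims: float) -> np.ndarray:
    """Per-draw probability of stability at a given total stimulation count."""
    if posterior.degenerate:
        raise ValueError("degenerate posterior: no draws")
    return expit(posterior.beta0 + posterior.beta1 * float(total_stims))


def minimum_stim_boundary(
    posterior: BoundaryPosterior,
    n_pat_range=range(4, 101),
    p_star: float = 0.5,
    cap: int = 100,
    integer: bool = True,
) -> pd.DataFrame:
    """Minimum stimulations per patient for P(stable) >= p*, per patient count.

    Columns: ``n_pat, mean, ci_low, ci_high, censored_frac``.  Draws with
    non-positive slope cannot reach p* at any total and are censored at
    ``cap``; an all-censored posterior (or a degenerate one) yields an
    empty frame — the NOT-EXISTING boundary.

    With ``integer=False`` the per-draw threshold ``T / n_pat`` is reported
    without the ceiling: stimulation counts are no longer whole numbers,
    but the mean curve is exactly convex in n_pat (ceiling quantizes the
    1/n_pat decay into a staircase that is convex only up to +-1).
    """
    if posterior.degenerate or posterior.n_draws == 0:
        return pd.DataFrame(columns=["n_pat", "mean", "ci_low", "ci_high", "censored_frac"])
    b0, b1 = posterior.beta0, posterior.beta1
    pos = b1 > 0
    if not pos.any():
        return pd.DataFrame(columns=["n_pat", "mean", "ci_low", "ci_high", "censored_frac"])
    thr_total = np.where(pos, (logit(p_star) - b0) / np.where(pos, b1, 1.0), np.inf)
    rows = []
    for n_pat in n_pat_range:
        per_draw = thr_total / n_pat
        if integer:
            per_draw = np.ceil(per_draw)
        vals = np.where(
            pos, np.minimum(cap, np.maximum(1, per_draw)), cap
        ).astype(float)
        rows.append(
            {
                "n_pat": int(n_pat),
                "mean": float(vals.mean()),
                "ci_low": float(np.percentile(vals, 2.5)),
                "ci_high": float(np.percentile(vals, 97.5)),
                "censored_frac": float(1.0 - pos.mean()),
            }
        )
    return pd.DataFrame(rows)


def evaluate_model(
    records: pd.DataFrame,
    test_size: float = 0.30,
    seed: int = 0,
    prior_sd: float = PRIOR_SD_DEFAULT,
    num_samples: int = 1000,
    warmup_steps: int = 500,
) -> dict:
    """Train/test evaluation of the stability classifier.

    Stratified 70/30 split; test records are classified by posterior-mean
    probability >= 0.5.  Returns accuracy and F1 (positive class = stable).
    """
    y = records["label"].to_numpy()
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least two records per class for evaluation")
    train, test = train_test_split(
        records, test_size=test_size, random_state=seed, stratify=y
    )
    post = fit_boundary_model(
        train, prior_sd=prior_sd, num_samples=num_samples,
        warmup_steps=warmup_steps, seed=seed,
    )
    probs = np.array(
        [stability_probability(post, t).mean() for t in test["total_stims"]]
    )
    pred = (probs >= 0.5).astype(int)
    return {
        "accuracy": float(accuracy_score(test["label"], pred)),
        "f1": float(f1_score(test["label"], pred, zero_division=0)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
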