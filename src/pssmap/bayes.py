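"""Bayesian one-sample test for voxel-wise improvement scores.

Model per voxel: ``score_i ~ Normal(mu, sigma^2)`` with priors
``mu ~ Normal(mu_loc, mu_scale^2)`` and ``sigma ~ HalfNormal(sigma_scale)``.
The evidence statistic is a directional Bayes factor contrasting
H1: mu >= theta against H0: mu < theta,

    BF = [P(mu >= theta | data) / P(mu < theta | data)]
         / [P(mu >= theta) / P(mu < theta)],

with posterior masses estimated from MCMC draws of mu and prior masses
analytic.  With the default prior centered at theta the prior odds are 1
and the BF equals the posterior odds.

Sampling is Metropolis-within-Gibbs, vectorized across voxels: the mu-step
is an exact conjugate normal draw given sigma, the sigma-step a random-walk
Metropolis update on log(sigma).  Because the Gaussian likelihood depends
on the data only through (n, sum x, sum x^2), each sweep costs O(n_voxels)
regardless of how many scores cover each voxel.  With ``sigma_fixed`` set,
the sampler reduces to exact i.i.d. draws from the conjugate posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["NormalPrior", "bayes_posterior", "bayes_factor_directional", "posterior_mu_matrix"]


@dataclass(frozen=True)
class NormalPrior:
    """Prior hyperparameters on the 0-100 improvement scale.

    ``mu_scale`` of 25 spans one step of the clinical rating scale;
    ``sigma_scale`` likewise.  ``sigma_fixed`` pins the noise sd (conjugate
    special case, mainly for validation against the closed form).
    """

    mu_loc: float = 50.0
    mu_scale: float = 25.0
    sigma_scale: float = 25.0
    sigma_fixed: float | None = None
    # truncation of sigma's support; the floor (0.5 on the percent scale,
    # well below the rating resolution) keeps voxels whose covering scores
    # are all identical from collapsing the chain to sigma = 0
    sigma_floor: float = 0.5
    sigma_ceil: float = 1e3

    def __post_init__(self) -> None:
        if self.mu_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be > 0")
        if self.sigma_fixed is not None and self.sigma_fixed <= 0:
            raise ValueError("sigma_fixed must be > 0")


def posterior_mu_matrix(
    n: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    prior: NormalPrior,
    num_samples: int = 2000,
    warmup_steps: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior draws of mu for many voxels at once.

    Parameters are per-voxel sufficient statistics: count ``n``, sum ``s1``
    and sum of squares ``s2`` of the covering scores.  Returns an array of
    shape ``(n_voxels, num_samples)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = np.asarray(n, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(n < 1):
        raise ValueError("every voxel needs at least one observation")
    n_vox = n.shape[0]
    xbar = s1 / n
    if prior.sigma_fixed is not None:
        sigma = np.full(n_vox, float(prior.sigma_fixed))
        update_sigma = False
    else:
        var0 = np.maximum(s2 / n - xbar**2, prior.sigma_floor**2)
        sigma = np.sqrt(var0)
        update_sigma = True
    log_sigma = np.log(sigma)
    step = np.clip(2.4 / np.sqrt(2.0 * n), 0.05, 1.0)
    mu = xbar.copy()
    out = np.empty((n_vox, num_samples))
    m0, s0 = prior.mu_loc, prior.mu_scale
    for it in range(warmup_steps + num_samples):
        # conjugate mu | sigma
        prec = n / sigma**2 + 1.0 / s0**2
        mean = (s1 / sigma**2 + m0 / s0**2) / prec
        mu = mean + rng.standard_normal(n_vox) / np.sqrt(prec)
        if update_sigma:
            # random-walk Metropolis on log sigma | mu
            prop = log_sigma + step * rng.standard_normal(n_vox)
            sig_p = np.exp(prop)
            ss = s2 - 2.0 * mu * s1 + n * mu**2  # sum (x - mu)^2
            def logpost(ls, sg):
                return (
                    -n * ls
                    - ss / (2.0 * sg**2)
                    - sg**2 / (2.0 * prior.sigma_scale**2)
                    + ls  # Jacobian of the log transform
                )
            log_acc = logpost(prop, sig_p) - logpost(log_sigma, sigma)
            in_bounds = (sig_p >= prior.sigma_floor) & (sig_p <= prior.sigma_ceil)
            accept = in_bounds & (np.log(rng.uniform(size=n_vox)) < log_acc)
            log_sigma = np.where(accept, prop, log_sigma)
            sigma = np.exp(log_sigma)
        if it >= warmup_steps:
            out[:, it - warmup_steps] = mu
    return out


def bayes_posterior(
    scores,
    prior: NormalPrior,
    num_samples: int = 2000,
    warmup_steps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Posterior draws of mu for a single voxel's scores."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("scores must be non-empty")
    rng = np.random.default_rng(seed)
    draws = posterior_mu_matrix(
        np.array([x.size]),
        np.array([x.sum()]),
        np.array([np.sum(x**2)]),
        prior,
        num_samples=num_samples,
        warmup_steps=warmup_steps,
        rng=rng,
    )
    return draws[0]


def bayes_factor_directional(
    mu_samples: np.ndarray,
    prior: NormalPrior,
    theta: float,
    cap: float | None = None,
) -> float:
    """Directional Bayes factor for H1: mu >= theta vs H0: mu < theta.

    Capped at ``cap`` (default ``2 * n_samples + 1``) when no posterior
    sample falls below theta; returns 0 when none falls at or above it.
    """
    mu_samples = np.asarray(mu_samples, dtype=float)
    if mu_samples.size == 0:
        raise ValueError("need at least one posterior sample")
    if cap is None:
        cap = 2.0 * mu_samples.size + 1.0
    prior_hi = float(sps.norm.sf(theta, loc=prior.mu_loc, scale=prior.mu_scale))
    prior_lo = 1.0 - prior_hi
    if prior_hi <= 0.0 or prior_lo <= 0.0:
        raise ValueError("prior places zero mass on one side of theta")
    k = int(np.count_nonzero(mu_samples >= theta))
    m = mu_samples.size
    if k == m:
        return float(cap)
    if k == 0:
        return 0.0
    post_odds = k / (m - k)
    return float(min(cap, post_odds * prior_lo / prior_hi))
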