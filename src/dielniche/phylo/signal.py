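"""Phylogenetic signal statistics: Pagel's lambda and Blomberg's K.

Pagel's lambda scales the off-diagonal entries of the Brownian covariance;
its ML value measures how much phylogenetic structure the trait carries
(0 = none, 1 = pure Brownian motion).  Blomberg's K compares observed to
Brownian-expected partitioning of trait variance over the tree; K = 1 is
the Brownian expectation, K < 1 means less signal than Brownian motion.
The multivariate K (as used for the full 48-bin speed profiles) sums
squared deviations over trait columns before taking the same ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .tree import Phylogeny

__all__ = ["SignalResult", "pagel_lambda", "blomberg_k"]


@dataclass
class SignalResult:
    statistic: str        # "lambda", "K" or "K_mult"
    value: float
    log_likelihood: float | None = None
    log_likelihood_0: float | None = None   # lambda = 0 reference
    p: float | None = None                  # permutation p (K) or LRT p (lambda)
    boundary: bool = False


def _bm_profile_loglik(y: np.ndarray, C: np.ndarray) -> float:
    """Gaussian log-likelihood with mean and rate profiled out."""
    n = len(y)
    cf = linalg.cho_factor(C, lower=True)
    one = np.ones(n)
    Ci1 = linalg.cho_solve(cf, one)
    mu = float(Ci1 @ y) / float(Ci1 @ one)
    r = y - mu
    q = float(r @ linalg.cho_solve(cf, r))
    sigma2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(tree: Phylogeny, trait, tip_labels=None) -> SignalResult:
    """ML estimate of Pagel's lambda for one continuous trait.

    Maximizes the Brownian likelihood with covariance sigma^2 * C(lambda)
    over lambda in [0, lambda_max], with sigma^2 and the root state
    profiled out.  lambda_max is the largest value keeping C(lambda)
    positive-definite.  A likelihood-ratio p-value against lambda = 0 is
    reported.
    """
    y = np.asarray(trait, dtype=float)
    if len(y) < 4:
        raise ValueError("need >= 4 tips")
    order = tree.tip_index(tip_labels) if tip_labels is not None else np.arange(len(y))
    C = tree.mrca_depths()[np.ix_(order, order)]
    off = C - np.diag(np.diag(C))
    d = np.diag(C)
    lam_max = tree.lambda_max()

    def nll(lam):
        try:
            return -_bm_profile_loglik(y, lam * off + np.diag(d))
        except linalg.LinAlgError:
            return np.inf

    # coarse grid then local polish; the profile likelihood in lambda is
    # one-dimensional but can be flat or bimodal on small trees
    grid = np.linspace(0.0, lam_max, 21)
    vals = np.array([nll(g) for g in grid])
    best = grid[int(np.argmin(vals))]
    lo = max(0.0, best - (grid[1] - grid[0]))
    hi = min(lam_max, best + (grid[1] - grid[0]))
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = float(res.x)
    ll = -float(res.fun)
    ll0 = _bm_profile_loglik(y, np.diag(d))
    if ll0 > ll:  # boundary optimum at 0
        lam_hat, ll = 0.0, ll0
    from scipy import stats

    lrt = 2.0 * (ll - ll0)
    p = stats.chi2.sf(max(lrt, 0.0), 1)
    boundary = lam_hat <= 1e-8 or lam_hat >= lam_max - 1e-8
    return SignalResult("lambda", lam_hat, log_likelihood=ll,
                        log_likelihood_0=ll0, p=float(p), boundary=boundary)


def blomberg_k(
    tree: Phylogeny,
    trait,
    tip_labels=None,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K (or multivariate K for an (n, p) trait matrix).

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected, where MSE0 uses raw
    deviations from the phylogenetic (GLS) mean, MSE uses C^-1-weighted
    deviations, and the expectation under Brownian motion is
    (tr C - n / sum(C^-1)) / (n - 1).  For a trait matrix the squared
    deviations are summed across columns (the multivariate extension used
    for profile data).  A permutation p-value shuffles trait rows across
    tips.
    """
    Y = np.asarray(trait, dtype=float)
    multi = Y.ndim == 2 and Y.shape[1] > 1
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need >= 4 tips")
    if np.allclose(Y.var(axis=0), 0):
        raise ValueError("trait has zero variance")
    order = tree.tip_index(tip_labels) if tip_labels is not None else np.arange(n)
    C = tree.mrca_depths()[np.ix_(order, order)]
    cf = linalg.cho_factor(C, lower=True)
    Ci1 = linalg.cho_solve(cf, np.ones(n))
    expected = (np.trace(C) - n / float(Ci1.sum())) / (n - 1)

    def stat(Yrows):
        mu = (Ci1 @ Yrows) / float(Ci1.sum())
        R = Yrows - mu
        mse0 = float((R**2).sum())
        mse = float(np.einsum("ij,ij->", R, linalg.cho_solve(cf, R)))
        return (mse0 / mse) / expected

    k_obs = stat(Y)
    p = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 1
        for _ in range(n_perm):
            k_p = stat(Y[rng.permutation(n)])
            if k_p >= k_obs:
                count += 1
        p = count / (n_perm + 1.0)
    return SignalResult("K_mult" if multi else "K", float(k_obs), p=p)
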