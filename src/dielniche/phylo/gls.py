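"""Phylogenetic regression and related tests.

All routines share one idea: under Brownian motion the residuals of a
cross-species regression are correlated with covariance proportional to the
shared-branch-length matrix C.  Pre-multiplying data by the inverse Cholesky
factor of C ("whitening") turns the problem back into ordinary least
squares, which is how pGLS, the phylogenetic ANOVA null and the
phylogenetically corrected two-block PLS are implemented below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .tree import Phylogeny

__all__ = ["PglsFit", "pgls", "phylo_anova", "two_block_pls"]


def _chol_whitener(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor L of C; solve against it to whiten."""
    return linalg.cholesky(C, lower=True)


def phylo_weights(C: np.ndarray) -> np.ndarray:
    """GLS weights for the phylogenetic mean: C^-1 1 / (1' C^-1 1)."""
    w = linalg.solve(C, np.ones(len(C)), assume_a="pos")
    return w / w.sum()


@dataclass
class PglsFit:
    """Result of a (phylogenetic) generalized least-squares regression."""

    params: np.ndarray          # intercept first
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    log_likelihood: float
    sigma2: float               # ML rate estimate
    df_resid: int
    names: list = field(default_factory=list)


def pgls(
    y,
    X,
    tree: Phylogeny | None = None,
    tip_labels=None,
    C: np.ndarray | None = None,
    add_intercept: bool = True,
) -> PglsFit:
    """Regression of ``y`` on ``X`` with Brownian residual covariance.

    ``X`` may be a vector (single predictor) or an (n, p) matrix.  When
    ``tree`` is None (or the covariance is the identity) the fit reduces to
    ordinary least squares.  Tips are aligned by ``tip_labels`` when given,
    otherwise rows are assumed already in ``tree.tip_labels`` order.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if C is None:
        if tree is not None:
            order = (
                tree.tip_index(tip_labels)
                if tip_labels is not None
                else np.arange(n)
            )
            C = tree.mrca_depths()[np.ix_(order, order)]
        else:
            C = np.eye(n)
    L = _chol_whitener(C)
    yw = linalg.solve_triangular(L, y, lower=True)
    D = np.column_stack([np.ones(n), X]) if add_intercept else X
    Dw = linalg.solve_triangular(L, D, lower=True)

    p = Dw.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(Dw, yw, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("singular design matrix")
    resid = yw - Dw @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2_hat = rss / df if df > 0 else np.nan
    XtX_inv = np.linalg.inv(Dw.T @ Dw)
    bse = np.sqrt(np.diag(XtX_inv) * sigma2_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df) if df > 0 else np.full(p, np.nan)

    # R^2 against the GLS mean-only model
    onew = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float(onew @ yw) / float(onew @ onew) if add_intercept else 0.0
    tss = float((yw - mu * onew) @ (yw - mu * onew))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    sigma2_ml = rss / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    return PglsFit(
        params=beta,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        r_squared=r2,
        log_likelihood=ll,
        sigma2=sigma2_ml,
        df_resid=df,
        names=(["intercept"] + [f"x{i}" for i in range(p - 1)]) if add_intercept else [f"x{i}" for i in range(p)],
    )


# ----------------------------------------------------------- phylo ANOVA
def _anova_f(y: np.ndarray, groups_onehot: np.ndarray) -> float:
    return float(_anova_f_many(y[:, None], groups_onehot)[0])


def _anova_f_many(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Classical one-way ANOVA F for each column of Y; G is (n, k) one-hot."""
    n, k = G.shape
    counts = G.sum(axis=0)
    means = (G.T @ Y) / counts[:, None]
    grand = Y.mean(axis=0)
    ssb = (counts[:, None] * (means - grand) ** 2).sum(axis=0)
    resid = Y - G @ means
    ssw = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / (k - 1)) / (ssw / (n - k))


def phylo_anova(
    trait,
    groups,
    tree: Phylogeny,
    tip_labels=None,
    n_sim: int = 1000,
    seed: int | None = None,
):
    """Phylogenetic ANOVA: classical F, null distribution from BM simulation.

    The observed F statistic is the ordinary one-way ANOVA F.  Its null
    distribution is obtained by simulating Brownian traits on the tree
    (rate set to the ML estimate from the data under a single-mean BM
    model) and recomputing F; the reported p-value is the fraction of
    simulated statistics at least as large as the observed one.
    """
    y = np.asarray(trait, dtype=float)
    groups = np.asarray(groups)
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    n = len(y)
    order = tree.tip_index(tip_labels) if tip_labels is not None else np.arange(n)
    C = tree.mrca_depths()[np.ix_(order, order)]
    G = np.zeros((n, len(levels)))
    G[np.arange(n), codes] = 1.0

    f_obs = _anova_f(y, G)

    # BM rate from the data (GLS, mean-only model)
    w = phylo_weights(C)
    mu = float(w @ y)
    r = y - mu
    sigma2 = float(r @ linalg.solve(C, r, assume_a="pos")) / n

    rng = np.random.default_rng(seed)
    L = _chol_whitener(sigma2 * C)
    Ysim = L @ rng.standard_normal((n, n_sim))
    f_sim = _anova_f_many(Ysim, G)
    p = (1.0 + np.sum(f_sim >= f_obs)) / (n_sim + 1.0)
    return {"F": f_obs, "p": p, "df": (len(levels) - 1, n - len(levels)),
            "sigma2": sigma2, "group_levels": list(levels)}


# ------------------------------------------------------- two-block PLS
def two_block_pls(
    block1,
    block2,
    tree: Phylogeny | None = None,
    tip_labels=None,
    n_perm: int = 999,
    seed: int | None = None,
):
    """Phylogenetically corrected two-block partial least squares.

    Both blocks are whitened by the Cholesky factor of the tree covariance
    (identity when ``tree`` is None), centred on the GLS mean, and the
    cross-covariance between them is decomposed by SVD.  ``r_pls`` is the
    correlation of the paired first singular-vector scores; adjusted R^2 is
    reported for each regression direction of the scores; the permutation
    p-value shuffles the tip assignment of the second block.
    """
    Y1 = np.atleast_2d(np.asarray(block1, dtype=float).T).T
    Y2 = np.atleast_2d(np.asarray(block2, dtype=float).T).T
    n = Y1.shape[0]
    if tree is not None:
        order = tree.tip_index(tip_labels) if tip_labels is not None else np.arange(n)
        C = tree.mrca_depths()[np.ix_(order, order)]
    else:
        C = np.eye(n)
    L = _chol_whitener(C)
    w = phylo_weights(C)

    def _stat(Y2_rows):
        E1 = linalg.solve_triangular(L, Y1 - w @ Y1, lower=True)
        E2 = linalg.solve_triangular(L, Y2_rows - w @ Y2_rows, lower=True)
        S12 = E1.T @ E2 / (n - 1)
        if not np.any(S12):
            raise ValueError("rank-0 cross-covariance between blocks")
        U, sv, Vt = np.linalg.svd(S12, full_matrices=False)
        s1 = E1 @ U[:, 0]
        s2 = E2 @ Vt[0]
        r = np.corrcoef(s1, s2)[0, 1]
        return abs(float(r)), s1, s2

    r_obs, s1, s2 = _stat(Y2)

    def _adj_r2(a, b):
        fit = np.polyfit(b, a, 1)
        res = a - np.polyval(fit, b)
        r2 = 1 - (res @ res) / ((a - a.mean()) @ (a - a.mean()))
        return 1 - (1 - r2) * (n - 1) / (n - 2)

    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p, _, _ = _stat(Y2[perm])
        if r_p >= r_obs:
            count += 1
    return {
        "r_pls": r_obs,
        "scores1": s1,
        "scores2": s2,
        "adj_r2_1on2": _adj_r2(s1, s2),
        "adj_r2_2on1": _adj_r2(s2, s1),
        "p": count / (n_perm + 1.0),
    }
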