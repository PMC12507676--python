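"""Continuous trait-evolution models on trees: BM, OU and early-burst.

Each model implies a tip covariance matrix; fitting is Gaussian ML with
the root state and rate profiled out analytically, leaving at most a
one-dimensional search (OU: the pull strength alpha; EB: the rate-decay
exponent).  Model comparison uses AICc.  Ancestral states are the joint
ML (= conditional-mean) states given the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .signal import _bm_profile_loglik
from .tree import Phylogeny

__all__ = ["ContinuousFit", "fit_continuous", "ou_ancestral", "compare_aic"]

_K_PARAMS = {"BM": 2, "OU": 3, "EB": 3}


@dataclass
class ContinuousFit:
    model: str
    sigma2: float
    z0: float
    log_likelihood: float
    aicc: float
    n: int
    alpha: float | None = None   # OU pull strength
    rate: float | None = None    # EB exponent (<= 0)

    @property
    def aic(self) -> float:  # for generic ranking
        return self.aicc


def _aicc(ll: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def ou_shape(T: np.ndarray, d: np.ndarray, alpha: float) -> np.ndarray:
    """Root-conditioned OU covariance shape (sigma^2 factored out).

    ``T`` holds MRCA depths, ``d`` node depths.  As alpha -> 0 this tends
    to the Brownian shape T.
    """
    if alpha <= 0:
        return T.copy()
    dd = d[:, None] + d[None, :] - 2.0 * T
    # (1 - e^{-2 a t}) / (2 a), stable at small alpha
    var_term = -np.expm1(-2.0 * alpha * T) / (2.0 * alpha)
    return np.exp(-alpha * dd) * var_term


def eb_shape(T: np.ndarray, rate: float) -> np.ndarray:
    """Early-burst covariance shape: shared path t -> (e^{r t} - 1) / r."""
    if rate == 0:
        return T.copy()
    return np.expm1(rate * T) / rate


def _profile_fit(y: np.ndarray, V: np.ndarray):
    """Profile out root state and rate; return (loglik, sigma2, z0)."""
    n = len(y)
    cf = linalg.cho_factor(V, lower=True)
    one = np.ones(n)
    Vi1 = linalg.cho_solve(cf, one)
    z0 = float(Vi1 @ y) / float(Vi1 @ one)
    r = y - z0
    q = float(r @ linalg.cho_solve(cf, r))
    sigma2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, sigma2, z0


def fit_continuous(
    tree: Phylogeny,
    trait,
    model: str = "BM",
    tip_labels=None,
) -> ContinuousFit:
    """ML fit of a BM, OU or EB model to one continuous trait."""
    model = model.upper()
    if model not in _K_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need >= 5 tips")
    order = tree.tip_index(tip_labels) if tip_labels is not None else np.arange(n)
    T = tree.mrca_depths()[np.ix_(order, order)]
    d = np.diag(T).copy()
    depth = float(d.max())

    if model == "BM":
        ll, s2, z0 = _profile_fit(y, T)
        return ContinuousFit("BM", s2, z0, ll, _aicc(ll, 2, n), n)

    if model == "OU":
        def nll(log_a):
            try:
                ll, _, _ = _profile_fit(y, ou_shape(T, d, np.exp(log_a)))
                return -ll
            except linalg.LinAlgError:
                return np.inf

        lo, hi = np.log(1e-8 / depth), np.log(500.0 / depth)
        grid = np.linspace(lo, hi, 40)
        vals = [nll(g) for g in grid]
        best = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            nll, bounds=(max(lo, best - 1.0), min(hi, best + 1.0)),
            method="bounded", options={"xatol": 1e-10})
        alpha = float(np.exp(res.x))
        ll, s2, z0 = _profile_fit(y, ou_shape(T, d, alpha))
        ll_bm, s2_bm, z0_bm = _profile_fit(y, T)
        if ll_bm >= ll:  # boundary: alpha -> 0 degenerates to BM
            alpha, ll, s2, z0 = 0.0, ll_bm, s2_bm, z0_bm
        return ContinuousFit("OU", s2, z0, ll, _aicc(ll, 3, n), n, alpha=alpha)

    # EB
    def nll(r):
        try:
            ll, _, _ = _profile_fit(y, eb_shape(T, r))
            return -ll
        except linalg.LinAlgError:
            return np.inf

    rmin = -10.0 / depth  # ~ geiger's default lower bound scale
    grid = np.linspace(rmin, 0.0, 40)
    vals = [nll(g) for g in grid]
    best = grid[int(np.argmin(vals))]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        nll, bounds=(max(rmin, best - step), min(0.0, best + step)),
        method="bounded", options={"xatol": 1e-12})
    r_hat = float(min(res.x, 0.0))
    ll, s2, z0 = _profile_fit(y, eb_shape(T, r_hat))
    ll0, s20, z00 = _profile_fit(y, T)
    if ll0 >= ll:
        r_hat, ll, s2, z0 = 0.0, ll0, s20, z00
    return ContinuousFit("EB", s2, z0, ll, _aicc(ll, 3, n), n, rate=r_hat)


def ou_ancestral(
    tree: Phylogeny,
    trait,
    fit: ContinuousFit | None = None,
    tip_labels=None,
) -> dict[int, float]:
    """Joint ML ancestral states under a fitted OU model.

    Returns a mapping from internal-node index to reconstructed state.
    The states are the conditional means of the internal nodes given the
    tips under the fitted Gaussian model (which for a multivariate normal
    coincide with the joint ML states).  When the fitted alpha sits at the
    zero boundary the reconstruction falls back to Brownian motion, with a
    warning.
    """
    y = np.asarray(trait, dtype=float)
    if fit is None:
        fit = fit_continuous(tree, y, "OU", tip_labels=tip_labels)
    alpha = fit.alpha if fit.model == "OU" else 0.0
    if fit.model == "OU" and (alpha is None or alpha <= 1e-10):
        warnings.warn("alpha at the zero boundary; reconstructing under BM")
        alpha = 0.0

    M = tree.mrca_depths(include_internal=True)
    d = tree.depths
    V = ou_shape(M, d, alpha) if alpha > 0 else M
    nt = tree.n_tips
    order = tree.tip_index(tip_labels) if tip_labels is not None else np.arange(nt)
    tips = np.asarray(order)
    internal = np.arange(nt, tree.n_nodes)
    Vtt = V[np.ix_(tips, tips)]
    Vat = V[np.ix_(internal, tips)]
    # root has zero marginal variance under the root-conditioned model, so
    # regularize only through the solve on the tip block
    resid = linalg.solve(Vtt, y - fit.z0, assume_a="pos")
    anc = fit.z0 + Vat @ resid
    return {int(i): float(v) for i, v in zip(internal, anc)}


def compare_aic(fits) -> list[dict]:
    """Rank model fits by their information criterion.

    Accepts any objects exposing ``model`` (or ``pattern``) and ``aicc``
    or ``aic``.  Returns a list of dicts sorted best-first with a
    ``delta`` column relative to the best model.  All fits must refer to
    the same data (same ``n`` where available).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    ns = {getattr(f, "n", None) for f in fits} - {None}
    if len(ns) > 1:
        raise ValueError("fits computed on different data (different n)")

    def score(f):
        return getattr(f, "aicc", None) if getattr(f, "aicc", None) is not None else f.aic

    def name(f):
        return getattr(f, "model", None) or getattr(f, "pattern", "?")

    rows = sorted(
        ({"model": name(f), "aic": float(score(f)),
          "log_likelihood": float(f.log_likelihood)} for f in fits),
        key=lambda r: (r["aic"], r["model"]),
    )
    best = rows[0]["aic"]
    for r in rows:
        r["delta"] = r["aic"] - best
    return rows
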