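"""Mk models of discrete character evolution, including "bridge" constraints.

A continuous-time Markov chain with rate matrix Q runs along the branches;
the likelihood of tip states is computed with Felsenstein's pruning
algorithm.  Rate patterns: ER (one rate), SYM (symmetric pairs), ARD (all
rates different), and the bridge-constrained variants bridge-SYM and
bridge-ARD, which forbid direct transitions between the diurnal and
nocturnal states — the discrete-model formulation of the crepuscular
bridge hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .tree import Phylogeny

__all__ = ["MkModel", "fit_mk", "mk_loglik", "build_rate_matrix",
           "pattern_free_params", "DIEL_STATES"]

DIEL_STATES = ("diurnal", "nocturnal", "crepuscular", "cathemeral")
PATTERNS = ("ER", "SYM", "ARD", "bridge-SYM", "bridge-ARD")


@dataclass
class MkModel:
    states: tuple
    pattern: str
    Q: np.ndarray
    rates: np.ndarray           # free rate parameters
    log_likelihood: float
    aic: float
    k_free: int
    root_prior: str = "flat"
    n: int | None = None
    model: str = field(init=False)

    def __post_init__(self):
        self.model = self.pattern


def _pattern_map(states, pattern, forbidden=None):
    """Map off-diagonal cells to free-parameter indices; -1 = fixed at 0."""
    k = len(states)
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    if forbidden is None and pattern.startswith("bridge"):
        if "diurnal" not in states or "nocturnal" not in states:
            raise ValueError("bridge patterns need diurnal and nocturnal states")
        forbidden = [("diurnal", "nocturnal")]
    forb = set()
    for a, b in forbidden or []:
        ia, ib = states.index(a), states.index(b)
        forb.add((ia, ib))
        forb.add((ib, ia))
    base = pattern.split("-")[-1] if pattern.startswith("bridge") else pattern
    pmap = np.full((k, k), -1, dtype=int)
    nxt = 0
    pair_idx = {}
    for i in range(k):
        for j in range(k):
            if i == j or (i, j) in forb:
                continue
            if base == "ER":
                pmap[i, j] = 0
            elif base == "SYM":
                key = (min(i, j), max(i, j))
                if key not in pair_idx:
                    pair_idx[key] = nxt
                    nxt += 1
                pmap[i, j] = pair_idx[key]
            else:  # ARD
                pmap[i, j] = nxt
                nxt += 1
    n_free = 1 if base == "ER" else nxt
    return pmap, n_free


def pattern_free_params(n_states: int, pattern: str, forbidden=None) -> int:
    """Number of free rate parameters for a pattern on ``n_states`` states."""
    states = DIEL_STATES[:n_states] if n_states <= 4 else tuple(map(str, range(n_states)))
    return _pattern_map(tuple(states), pattern, forbidden)[1]


def build_rate_matrix(states, pattern, rates, forbidden=None) -> np.ndarray:
    """Assemble Q from free rates; rows sum to zero."""
    pmap, n_free = _pattern_map(tuple(states), pattern, forbidden)
    rates = np.asarray(rates, dtype=float)
    if len(rates) != n_free:
        raise ValueError(f"pattern {pattern} needs {n_free} rates, got {len(rates)}")
    Q = np.where(pmap >= 0, rates[np.clip(pmap, 0, None)], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _branch_transition_mats(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """exp(Q * t_i) for every branch, via one eigendecomposition of Q."""
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) > 1e8:
            raise np.linalg.LinAlgError
        E = np.exp(np.multiply.outer(t, w))             # (m, k)
        P = np.einsum("ab,mb,bc->mac", U, E, Uinv)
        P = np.real_if_close(P, tol=1e6).real
    except np.linalg.LinAlgError:
        P = np.stack([linalg.expm(Q * ti) for ti in t])
    np.clip(P, 0.0, None, out=P)
    # renormalize tiny numerical drift
    P /= P.sum(axis=2, keepdims=True)
    return P


def mk_loglik(tree: Phylogeny, tip_state_idx, Q: np.ndarray,
              root_prior="flat") -> float:
    """Felsenstein pruning log-likelihood of tip states under Q.

    ``tip_state_idx`` maps tip order to state indices; -1 denotes a
    missing/ambiguous tip.  ``root_prior``: "flat", "stationary" or
    "fitzjohn".
    """
    k = Q.shape[0]
    P = _branch_transition_mats(Q, tree.branch_lengths)
    partial = np.zeros((tree.n_nodes, k))
    logscale = 0.0
    for v in tree.postorder:
        if not tree.children[v]:
            s = tip_state_idx[v]
            if s < 0:
                partial[v] = 1.0
            else:
                partial[v, s] = 1.0
        else:
            prod = np.ones(k)
            for c in tree.children[v]:
                prod *= P[c] @ partial[c]
            m = prod.max()
            if m <= 0:
                return -np.inf
            partial[v] = prod / m
            logscale += np.log(m)
    pr = partial[tree.root_index]
    if isinstance(root_prior, str):
        if root_prior == "flat":
            pi = np.full(k, 1.0 / k)
        elif root_prior == "stationary":
            A = np.vstack([Q.T, np.ones(k)])
            b = np.zeros(k + 1)
            b[-1] = 1.0
            pi, *_ = np.linalg.lstsq(A, b, rcond=None)
            pi = np.clip(pi, 0, None)
            pi /= pi.sum()
        elif root_prior == "fitzjohn":
            tot = pr.sum()
            pi = pr / tot if tot > 0 else np.full(k, 1.0 / k)
        else:
            raise ValueError(f"unknown root prior {root_prior!r}")
    else:
        pi = np.asarray(root_prior, dtype=float)
    lik = float(pi @ pr)
    if lik <= 0:
        return -np.inf
    return np.log(lik) + logscale


def fit_mk(
    tree: Phylogeny,
    tip_states,
    pattern: str = "ER",
    states=None,
    tip_labels=None,
    forbidden=None,
    root_prior: str = "flat",
    n_restarts: int = 5,
    seed: int | None = None,
) -> MkModel:
    """ML fit of an Mk model with the given rate-constraint pattern.

    ``tip_states`` are state names aligned to ``tip_labels`` (or to
    ``tree.tip_labels``).  AIC = -2 logL + 2 k_free.  The optimizer runs
    bounded quasi-Newton on log-rates with seeded random restarts, since
    richly parameterized patterns can be multimodal on small trees.
    """
    tip_states = list(tip_states)
    if states is None:
        observed = [s for s in tip_states if s is not None]
        states = tuple(s for s in DIEL_STATES if s in observed) or tuple(
            sorted(set(observed)))
    states = tuple(states)
    state_idx = {s: i for i, s in enumerate(states)}
    order = (tree.tip_index(tip_labels) if tip_labels is not None
             else np.arange(tree.n_tips))
    tip_arr = np.full(tree.n_tips, -1, dtype=int)
    for pos, s in zip(order, tip_states):
        tip_arr[pos] = -1 if s is None else state_idx[s]

    pmap, n_free = _pattern_map(states, pattern, forbidden)
    depth = tree.depth
    lo, hi = np.log(1e-5 / depth), np.log(200.0 / depth)

    def nll(x):
        Q = build_rate_matrix(states, pattern, np.exp(x), forbidden)
        ll = mk_loglik(tree, tip_arr, Q, root_prior)
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    x0s = [np.full(n_free, np.log(1.0 / depth))]
    x0s += [np.log(1.0 / depth) + rng.normal(0, 1.5, n_free)
            for _ in range(max(0, n_restarts - 1))]
    best = None
    for x0 in x0s:
        res = optimize.minimize(
            nll, np.clip(x0, lo + 1e-6, hi - 1e-6), method="L-BFGS-B",
            bounds=[(lo, hi)] * n_free)
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    Q = build_rate_matrix(states, pattern, rates, forbidden)
    ll = -float(best.fun)
    if not np.isfinite(ll):
        raise RuntimeError("non-finite Mk likelihood at optimum")
    aic = -2.0 * ll + 2.0 * n_free
    return MkModel(states, pattern, Q, rates, ll, aic, n_free,
                   root_prior=root_prior, n=tree.n_tips)
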