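"""Simulated phylogenies, continuous traits and discrete-state histories.

Trees are pure-birth (Yule) and therefore ultrametric; continuous traits
are multivariate-normal draws under BM, OU or early-burst covariance;
discrete states evolve by a continuous-time Markov chain simulated
branch-by-branch (Gillespie), with the full transition history retained
as ground truth — e.g. to verify that no history simulated under a
bridge-constrained model ever jumps straight between the diurnal and
nocturnal states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..phylo.continuous import eb_shape, ou_shape
from ..phylo.tree import Phylogeny

__all__ = ["simulate_tree", "simulate_continuous", "simulate_discrete",
           "DiscreteHistory"]


def simulate_tree(n_tips: int, seed: int | None = None,
                  depth: float = 1.0) -> Phylogeny:
    """Pure-birth ultrametric tree with ``n_tips`` tips, rescaled to ``depth``.

    Tip labels are six-character codes ``sp0001 ...`` mirroring the
    six-letter species codes used for real data.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    # grow lineages: start from the root split, wait Exp(k) between events
    # node = (birth_time); build child lists bottom-up at the end
    births = {0: 0.0, 1: 0.0}
    parent = {0: -1, 1: -1}
    active = [0, 1]
    nxt = 2
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        births[nxt] = t
        births[nxt + 1] = t
        parent[nxt] = node
        parent[nxt + 1] = node
        active += [nxt, nxt + 1]
        nxt += 2
    t_end = t + rng.exponential(1.0 / len(active))

    # assemble Newick recursively
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    scale = depth / t_end
    counter = [0]

    def nwk(node):
        if node in children:
            inner = ",".join(nwk(c) for c in children[node])
            end = min(b for b in (births[c] for c in children[node]))
            length = (end - births[node]) * scale
            return f"({inner}):{length:.10f}"
        counter[0] += 1
        length = (t_end - births[node]) * scale
        return f"sp{counter[0]:04d}:{length:.10f}"

    root_inner = ",".join(nwk(c) for c in children[-1])
    newick = f"({root_inner});"
    return Phylogeny.from_newick(newick)


def simulate_continuous(
    tree: Phylogeny,
    model: str = "BM",
    params: dict | None = None,
    seed: int | None = None,
    n_traits: int = 1,
):
    """Draw tip trait values under BM, OU or EB on the tree.

    ``params``: ``sigma2`` (> 0, all models), ``z0`` (root state),
    ``alpha`` (OU, >= 0), ``rate`` (EB, <= 0).  Returns an (n_tips,) array
    (or (n_tips, n_traits) when ``n_traits`` > 1) in ``tree.tip_labels``
    order.
    """
    import warnings

    model = model.upper()
    p = {"sigma2": 1.0, "z0": 0.0, "alpha": 1.0, "rate": -1.0, **(params or {})}
    if p["sigma2"] <= 0:
        raise ValueError("sigma2 must be > 0")
    T = tree.mrca_depths()
    d = np.diag(T).copy()
    if model == "BM":
        V = T
    elif model == "OU":
        if p["alpha"] < 0:
            raise ValueError("alpha must be >= 0")
        if not tree.is_ultrametric():
            warnings.warn("OU simulation on a non-ultrametric tree")
        V = ou_shape(T, d, p["alpha"])
    elif model == "EB":
        if p["rate"] > 0:
            raise ValueError("EB rate must be <= 0")
        V = eb_shape(T, p["rate"])
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(p["sigma2"] * V + 1e-12 * np.eye(len(V)))
    Z = rng.standard_normal((len(V), n_traits))
    Y = p["z0"] + L @ Z
    return Y[:, 0] if n_traits == 1 else Y


@dataclass
class DiscreteHistory:
    """Ground truth of a discrete-character simulation."""

    tip_states: dict            # label -> state name
    node_states: dict           # node index -> state at node
    transitions: list           # (node index, time along branch, from, to)

    def has_direct_transition(self, a: str, b: str) -> bool:
        return any({fr, to} == {a, b} for _, _, fr, to in self.transitions)


def simulate_discrete(
    tree: Phylogeny,
    Q: np.ndarray,
    states,
    root_state,
    seed: int | None = None,
) -> DiscreteHistory:
    """Continuous-time Markov simulation of a discrete character.

    ``Q`` rows must sum to zero with non-negative off-diagonals (an
    absorbing state — an all-zero row — is valid).  The transition
    history along every branch is retained.
    """
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("Q rows must sum to 0")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be >= 0")
    states = tuple(states)
    idx = {s: i for i, s in enumerate(states)}
    rng = np.random.default_rng(seed)

    node_states = {tree.root_index: idx[root_state]}
    transitions = []
    for v in tree.postorder[::-1]:     # preorder
        if v == tree.root_index:
            continue
        s = node_states[tree.parent[v]]
        t, t_end = 0.0, tree.branch_lengths[v]
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                break
            probs = np.clip(Q[s], 0, None)
            probs[s] = 0.0
            probs /= probs.sum()
            s_new = int(rng.choice(len(states), p=probs))
            transitions.append((int(v), float(t), states[s], states[s_new]))
            s = s_new
        node_states[v] = s
    tips = {lab: states[node_states[i]] for i, lab in enumerate(tree.tip_labels)}
    return DiscreteHistory(tips, {k: states[v] for k, v in node_states.items()},
                           transitions)
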