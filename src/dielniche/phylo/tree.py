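"""Rooted time-calibrated phylogenies and their trait covariance structure.

The comparative machinery in this package works on a light array-based view
of a rooted tree: node indices, parent pointers, branch lengths and a
postorder.  Newick parsing, writing and taxon pruning are delegated to
dendropy; everything numerical is computed here.

Node numbering convention: tips are ``0 .. n_tips-1`` in ``tip_labels``
order, internal nodes follow in postorder, the root is the last node.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_tree"]


class Phylogeny:
    """A rooted tree with branch lengths in time units.

    Parameters
    ----------
    dtree:
        A rooted :class:`dendropy.Tree`.  Unifurcations are suppressed and
        taxon labels become tip labels.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        self._dtree = dtree

        tips = [lf for lf in dtree.leaf_node_iter()]
        self.tip_labels: list[str] = [
            (lf.taxon.label if lf.taxon is not None else str(i))
            for i, lf in enumerate(tips)
        ]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        self.n_tips = len(tips)

        # assign indices: tips first (taxon order as encountered), then
        # internal nodes in postorder
        index = {}
        for i, lf in enumerate(tips):
            index[id(lf)] = i
        nxt = self.n_tips
        postorder_nodes = list(dtree.postorder_node_iter())
        for nd in postorder_nodes:
            if not nd.is_leaf():
                index[id(nd)] = nxt
                nxt += 1
        self.n_nodes = nxt
        self.root_index = index[id(dtree.seed_node)]

        parent = np.full(self.n_nodes, -1, dtype=np.intp)
        blen = np.zeros(self.n_nodes)
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        postorder = []
        for nd in postorder_nodes:
            i = index[id(nd)]
            postorder.append(i)
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                el = nd.edge.length
                blen[i] = 0.0 if el is None else float(el)
        if np.any(blen[np.arange(self.n_nodes) != self.root_index] < 0):
            raise ValueError("negative branch length")
        self.parent = parent
        self.branch_lengths = blen
        self.children = children
        self.postorder = np.asarray(postorder, dtype=np.intp)

        depth = np.zeros(self.n_nodes)
        for i in self.postorder[::-1]:  # preorder
            p = parent[i]
            depth[i] = blen[i] + (depth[p] if p >= 0 else 0.0)
        self.depths = depth

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted"
        )
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = io.StringIO()
        self._dtree.write(
            file=s,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------- queries
    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.depths[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths[: self.n_tips]
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))

    def tip_index(self, labels) -> np.ndarray:
        lut = {l: i for i, l in enumerate(self.tip_labels)}
        try:
            return np.asarray([lut[l] for l in labels], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown tip label {e.args[0]!r}") from None

    def prune(self, keep) -> "Phylogeny":
        """Restrict to a subset of tips, preserving path lengths."""
        keep = list(keep)
        missing = set(keep) - set(self.tip_labels)
        if missing:
            raise KeyError(f"unknown tip labels: {sorted(missing)}")
        dtree = self._dtree.clone(depth=1)
        dtree.retain_taxa_with_labels(keep)
        return Phylogeny(dtree)

    # ---------------------------------------------------------- covariance
    def mrca_depths(self, include_internal: bool = False) -> np.ndarray:
        """Matrix of most-recent-common-ancestor depths.

        With ``include_internal=False`` this is the Brownian-motion trait
        covariance (up to sigma^2): ``C[i, j]`` is the shared root-to-MRCA
        path length of tips i and j, and the diagonal holds tip depths.
        """
        n = self.n_nodes if include_internal else self.n_tips
        M = np.zeros((n, n))
        sets: dict[int, np.ndarray] = {}
        for v in self.postorder:
            if not self.children[v]:
                mine = [v] if (include_internal or v < self.n_tips) else []
            else:
                groups = [sets.pop(c) for c in self.children[v]]
                dv = self.depths[v]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        M[np.ix_(groups[a], groups[b])] = dv
                        M[np.ix_(groups[b], groups[a])] = dv
                mine = list(np.concatenate(groups)) if groups else []
                if include_internal:
                    if mine:
                        M[v, mine] = dv
                        M[mine, v] = dv
                    mine = mine + [v]
            if mine:
                sets[v] = np.asarray(mine, dtype=np.intp)
        idx = np.arange(n)
        M[idx, idx] = self.depths[:n] if include_internal else self.depths[: self.n_tips]
        return M

    def vcv(self, lam: float | None = None) -> np.ndarray:
        """Brownian trait covariance ``C``; optional Pagel's lambda transform.

        ``lam`` multiplies the off-diagonal entries, leaving tip depths
        untouched (lambda = 0 gives a star-tree/diagonal covariance).
        """
        C = self.mrca_depths()
        if lam is not None:
            if lam < 0:
                raise ValueError("lambda must be >= 0")
            D = np.diag(np.diag(C).copy())
            C = lam * (C - np.diag(np.diag(C))) + D
            # positive-definiteness is the caller-visible contract
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                raise ValueError(f"lambda={lam} leaves C non positive-definite")
        return C

    def lambda_max(self, cap: float = 1.5) -> float:
        """Largest lambda keeping the transformed covariance positive-definite."""
        C = self.mrca_depths()
        off = C - np.diag(np.diag(C))
        d = np.diag(C)

        def pd(lam):
            try:
                np.linalg.cholesky(lam * off + np.diag(d))
                return True
            except np.linalg.LinAlgError:
                return False

        if pd(cap):
            return cap
        lo, hi = 1.0, cap
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if pd(mid):
                lo = mid
            else:
                hi = mid
        return lo


def read_tree(path_or_newick) -> Phylogeny:
    """Read a rooted tree from a Newick file path or literal string."""
    s = str(path_or_newick)
    if s.lstrip().startswith("("):
        return Phylogeny.from_newick(s)
    return Phylogeny.from_file(s)
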