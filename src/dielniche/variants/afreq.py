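"""Posterior allele frequencies from genotype likelihoods.

For each species (two diploid individuals in the study design) the
alternative-allele frequency f is estimated by maximizing

    sum_ind log sum_g L(g) * HW(g | f),

with the Hardy-Weinberg prior HW(g|f) = {(1-f)^2, 2f(1-f), f^2}, by EM.
At the EM fixed point the ML frequency equals the posterior-mean allele
dosage over individuals divided by the chromosome count, which is the
reported frequency; the MAP genotype-based count is also emitted.  The
estimate is exactly equivariant under ref/alt swap (f -> 1 - f).
"""

from __future__ import annotations

import numpy as np

__all__ = ["af_posterior", "af_table", "scale_af"]


def _gl_from_pl(pl: np.ndarray) -> np.ndarray:
    return np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)


def af_posterior(pl_triples: np.ndarray, tol: float = 1e-10,
                 max_iter: int = 200) -> dict:
    """EM estimate of the allele frequency for one species at one site.

    ``pl_triples``: (n_ind, 3) Phred-scaled genotype likelihoods.  Rows
    that are entirely flat (all-equal PLs) carry no information; if every
    row is flat the frequency is 0.5 and flagged.
    """
    pl = np.atleast_2d(np.asarray(pl_triples, dtype=float))
    # canonical orientation makes ref/alt-swap equivariance exact in
    # floating point: the flipped panel reuses the same EM trajectory
    flipped = pl[:, ::-1]
    if tuple(flipped.ravel()) < tuple(pl.ravel()):
        res = af_posterior(flipped, tol=tol, max_iter=max_iter)
        return {"f": 1.0 - res["f"], "f_map": 1.0 - res["f_map"],
                "flagged": res["flagged"], "n_iter": res["n_iter"]}
    gl = _gl_from_pl(pl)
    informative = ~np.all(np.isclose(gl, gl[:, :1]), axis=1)
    if not informative.any():
        return {"f": 0.5, "f_map": 0.5, "flagged": True, "n_iter": 0}
    f = 0.5
    g_vals = np.arange(3)
    for it in range(max_iter):
        hw = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        w = gl * hw
        w /= w.sum(axis=1, keepdims=True)
        f_new = float((w @ g_vals).sum() / (2.0 * len(gl)))
        if abs(f_new - f) < tol:
            f = f_new
            break
        f = f_new
    hw = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    post = gl * hw
    post /= post.sum(axis=1, keepdims=True)
    f_map = float(post.argmax(axis=1).sum() / (2.0 * len(gl)))
    return {"f": f, "f_map": f_map, "flagged": False, "n_iter": it + 1}


def af_table(pl: np.ndarray, species: list, n_per_species: int = 2,
             tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """(n_sites, n_species) posterior allele frequencies from panel PLs.

    Vectorized EM over every (site, species) cell; identical model to
    :func:`af_posterior`, including the canonical-orientation trick that
    makes ref/alt-swap equivariance exact.
    """
    pl = np.asarray(pl, dtype=float)
    n_sites = pl.shape[0]
    S = len(species)
    if n_sites == 0:
        return np.empty((0, S))
    cells = pl.reshape(n_sites, S, n_per_species, 3)

    # canonical orientation per cell: flip when the reversed PL block is
    # lexicographically smaller than the original
    flat = cells.reshape(n_sites, S, -1)
    flipped = cells[..., ::-1].reshape(n_sites, S, -1)
    cmp = flipped != flat
    first = cmp.argmax(axis=-1)
    any_diff = cmp.any(axis=-1)
    ii, jj = np.indices(first.shape)
    flip = any_diff & (np.take_along_axis(flipped, first[..., None], -1)[..., 0]
                       < np.take_along_axis(flat, first[..., None], -1)[..., 0])
    work = np.where(flip[..., None, None], cells[..., ::-1], cells)

    gl = _gl_from_pl(work)                       # (sites, S, ind, 3)
    flat_cell = np.all(np.isclose(gl, gl[..., :1]), axis=(-2, -1))
    f = np.full((n_sites, S), 0.5)
    g_vals = np.arange(3.0)
    for _ in range(max_iter):
        hw = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
        w = gl * hw[:, :, None, :]
        w /= w.sum(axis=-1, keepdims=True)
        f_new = (w @ g_vals).sum(axis=-1) / (2.0 * n_per_species)
        done = not (np.abs(f_new - f) >= tol).any()
        f = f_new
        if done:
            break
    f = np.where(flat_cell, 0.5, f)
    return np.where(flip, 1.0 - f, f)


def scale_af(f: np.ndarray) -> np.ndarray:
    """Linear scaling of allele frequencies from [0, 1] to [-1, 1]."""
    return 2.0 * np.asarray(f, dtype=float) - 1.0
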