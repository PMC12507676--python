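"""Diel-niche classification from species daily-speed profiles.

Each species is summarized by its z-scored 48-bin daily speed profile.
PCA is run with the 48 time bins as observations and species as features,
so the bin *scores* separate day from night time points on PC1 and pull
the dawn/dusk ramp bins out on PC2, while the species *loadings* measure
diurnal-nocturnal preference (PC1) and crepuscularity (PC2).  Ward
clustering of the (PC1, PC2) loadings cuts the species into three groups
(diurnal / crepuscular / nocturnal, named by centroid position); species
whose mean profile varies less than twice the mean per-bin standard
deviation are overridden to cathemeral.  The bridge-shaped relationship
between the two loadings is quantified with a quadratic fit (OLS and
pGLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .activity import N_BINS, SpeciesProfile
from .phylo import Phylogeny, pgls
from .synth.schedule import LightSchedule, make_light_schedule

__all__ = ["ActivityPCA", "DielClassification", "zscore_profiles",
           "activity_pca", "cluster_loadings", "cathemeral_rule",
           "quadratic_bridge_fit", "classify_cohort"]

GUILDS = ("diurnal", "nocturnal", "crepuscular", "cathemeral")


@dataclass
class ActivityPCA:
    scores: np.ndarray              # (48, n_components): time-bin scores
    loadings: np.ndarray            # (n_species, n_components)
    explained_variance_ratio: np.ndarray
    species: list
    n_components: int


@dataclass
class DielClassification:
    species: list
    pc1: np.ndarray
    pc2: np.ndarray
    guild: list                     # one of GUILDS per species
    cathemeral: np.ndarray          # bool: variability override applied

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "PC1_loading": self.pc1,
                             "PC2_loading": self.pc2, "guild": self.guild})


def zscore_profiles(profiles: dict[str, np.ndarray] | list[SpeciesProfile]) -> pd.DataFrame:
    """48 x S matrix of per-species z-scored daily mean-speed profiles.

    Each species column is standardized over its own 48 bins (mean 0,
    SD 1).  Constant profiles are rejected.
    """
    if not isinstance(profiles, dict):
        profiles = {p.species: p.mean for p in profiles}
    cols = {}
    for sp, v in profiles.items():
        v = np.asarray(v, dtype=float)
        if v.shape != (N_BINS,):
            raise ValueError(f"{sp}: profile must have {N_BINS} bins")
        sd = v.std()
        if sd == 0:
            raise ValueError(f"{sp}: zero-variance profile cannot be z-scored")
        cols[sp] = (v - v.mean()) / sd
    return pd.DataFrame(cols)


def activity_pca(matrix: pd.DataFrame, n_components: int = 10,
                 schedule: LightSchedule | None = None) -> ActivityPCA:
    """PCA of the z-scored bin x species matrix (bins are observations).

    The sign of each component is arbitrary; it is fixed so that night
    bins score positive on PC1 (nocturnal species then get positive PC1
    loadings) and the dawn/dusk ramp bins score positive on PC2
    (crepuscular species get positive PC2 loadings).
    """
    X = np.asarray(matrix, dtype=float)
    species = list(matrix.columns)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 species")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T                       # (S, n_components)

    if schedule is None:
        schedule = make_light_schedule()
    bin_state = schedule.bin_states()
    night = bin_state == "night"
    ramp = (bin_state == "dawn-ramp") | (bin_state == "dusk-ramp")
    flips = np.ones(n_components)
    if night.any() and scores[night, 0].mean() < 0:
        flips[0] = -1.0
    if n_components > 1 and ramp.any() and scores[ramp, 1].mean() < 0:
        flips[1] = -1.0
    scores = scores * flips
    loadings = loadings * flips
    return ActivityPCA(scores, loadings, pca.explained_variance_ratio_.copy(),
                       species, n_components)


def cluster_loadings(pc1, pc2, species=None) -> dict:
    """Ward clustering of (PC1, PC2) loadings cut at three groups.

    Cluster names follow centroid position: most-negative mean PC1 is
    diurnal, most-positive is nocturnal, the remaining group is
    crepuscular.  Species order does not affect the assignment; input
    rows are sorted by species code before linkage to make tie-breaks
    reproducible.
    """
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.asarray(pc2, dtype=float)
    n = len(pc1)
    if n < 3:
        raise ValueError("need >= 3 species to form three clusters")
    if species is None:
        species = [f"s{i}" for i in range(n)]
    order = np.argsort(np.asarray(species, dtype=object))
    pts = np.column_stack([pc1, pc2])[order]
    Z = linkage(pts, method="ward")
    lab_sorted = fcluster(Z, t=3, criterion="maxclust")
    labels = np.empty(n, dtype=int)
    labels[order] = lab_sorted
    cents = {c: pc1[labels == c].mean() for c in np.unique(labels)}
    by_pc1 = sorted(cents, key=cents.get)
    name_of = {by_pc1[0]: "diurnal", by_pc1[-1]: "nocturnal"}
    for c in by_pc1[1:-1]:
        name_of[c] = "crepuscular"
    return {"labels": np.array([name_of[c] for c in labels], dtype=object),
            "cluster_id": labels}


def cathemeral_rule(mean_profile, per_bin_sd, factor: float = 2.0) -> bool:
    """Variability override: flat profile relative to individual scatter.

    True (cathemeral) when the min-to-max range of the species mean
    profile is strictly smaller than ``factor`` times the across-bin mean
    of the per-bin SD.
    """
    v = np.asarray(mean_profile, dtype=float)
    sd = np.asarray(per_bin_sd, dtype=float)
    return bool(np.ptp(v) < factor * sd.mean())


def classify_cohort(profiles: list[SpeciesProfile],
                    schedule: LightSchedule | None = None,
                    n_components: int = 10,
                    sd_source: str = "individuals"):
    """Full diel classification: z-score -> PCA -> Ward -> cathemeral rule.

    ``sd_source`` selects whether the cathemeral rule uses the per-bin SD
    across individuals (default) or across days.
    """
    profiles = sorted(profiles, key=lambda p: p.species)
    Z = zscore_profiles(profiles)
    n_components = min(n_components, len(profiles) - 1, N_BINS)
    res = activity_pca(Z, n_components=n_components, schedule=schedule)
    pc1, pc2 = res.loadings[:, 0], res.loadings[:, 1]
    clust = cluster_loadings(pc1, pc2, species=res.species)
    guild = clust["labels"].copy()
    cath = np.zeros(len(profiles), dtype=bool)
    for i, p in enumerate(profiles):
        sd = p.sd_individuals if sd_source == "individuals" else p.sd_days
        if p.n_individuals < 2:
            sd = p.sd_days
        cath[i] = cathemeral_rule(p.mean, sd)
    guild[cath] = "cathemeral"
    cls = DielClassification(res.species, pc1, pc2, list(guild), cath)
    return cls, res


def quadratic_bridge_fit(pc1, pc2, tree: Phylogeny | None = None,
                         species=None) -> dict:
    """PC2 ~ PC1 + PC1^2 by OLS and (when a tree is given) by pGLS.

    A parabola opening downward with its ridge near PC1 = 0 is the
    signature of the crepuscular bridge: strongly diurnal or nocturnal
    species have low crepuscularity, intermediate species high.
    """
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.asarray(pc2, dtype=float)
    if len(pc1) < 5:
        raise ValueError("need >= 5 species")
    X = np.column_stack([pc1, pc1**2])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(pc1)), X])) < 3:
        raise ValueError("collinear design (PC1 and PC1^2 not distinguishable)")
    ols = pgls(pc2, X, tree=None)
    out = {"ols": ols}
    if tree is not None:
        out["pgls"] = pgls(pc2, X, tree=tree, tip_labels=species)
    return out
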