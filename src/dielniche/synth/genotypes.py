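"""Phylogenetically structured allele frequencies with genotype likelihoods.

Species-level alternative-allele frequencies evolve by Brownian motion on
the logit scale along the tree, which keeps them in (0, 1) while inducing
the between-species correlation a phylogenetic GWAS must absorb.  A small
number of planted sites carry frequencies correlated with a species-level
trait; for those sites the trait satisfies

    trait ~ beta * (2 f - 1) + Brownian noise,

so ``beta`` is a signal-to-noise ratio.  Two diploid individuals per
species (as in a species-level resequencing panel) receive Hardy-Weinberg
genotypes, Poisson read depths, binomially sampled alleles with per-read
error, and exact GATK-style diploid genotype likelihoods.  Per-site INFO
annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, DP) are drawn with a
known pass/fail label so the filtering stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..phylo.tree import Phylogeny
from .trees import simulate_continuous

__all__ = ["GenotypePanel", "simulate_genotype_likelihoods"]

N_DIPLOIDS_PER_SPECIES = 2

# GATK-style hard-filter thresholds the synthetic annotations are scored
# against (fail when QD < 2, FS > 60, MQ < 40, MQRankSum < -12.5,
# ReadPosRankSum < -8); depth gate 900 <= DP <= 1900 summed over samples.
QUALITY_FAIL_FRACTION = 0.08
DEPTH_FAIL_FRACTION = 0.05


@dataclass
class GenotypePanel:
    """Synthetic variant panel plus full ground truth."""

    sites: pd.DataFrame          # chrom,pos,ref,alt + INFO fields + labels
    pl: np.ndarray               # (n_sites, n_ind, 3) Phred genotype likelihoods
    genotypes: np.ndarray        # (n_sites, n_ind) alt-allele dosage 0/1/2
    true_af: np.ndarray          # (n_sites, n_species)
    trait: np.ndarray            # species-level trait
    species: list = field(default_factory=list)
    individuals: list = field(default_factory=list)
    assoc_sites: np.ndarray = None   # indices of planted sites


def _gatk_pl(alt_reads, ref_reads, err):
    """Phred-scaled diploid genotype likelihoods from read counts."""
    a = np.asarray(alt_reads, dtype=float)
    r = np.asarray(ref_reads, dtype=float)
    p_alt = np.array([err, 0.5, 1.0 - err])           # P(alt read | g)
    with np.errstate(divide="ignore"):
        ll = (a[..., None] * np.log(p_alt) + r[..., None] * np.log(1.0 - p_alt))
    pl = -10.0 / np.log(10.0) * (ll - ll.max(axis=-1, keepdims=True))
    return np.round(pl).astype(int)


def simulate_genotype_likelihoods(
    tree: Phylogeny,
    n_sites: int = 2000,
    n_assoc: int = 0,
    beta: float = 2.0,
    mean_depth: float = 10.0,
    base_error: float = 0.01,
    sigma_logit: float = 1.5,
    seed: int | None = None,
    contaminate: bool = True,
    trait: np.ndarray | None = None,
) -> GenotypePanel:
    """Simulate a species-level variant panel on a tree.

    When ``contaminate`` is true, extra labelled failure modes are mixed
    in: quality-annotation failures, depth failures, indels, multiallelic
    records, unplaced-scaffold records and singleton minor alleles —
    everything the site-selection stage is supposed to remove.
    """
    rng = np.random.default_rng(seed)
    species = list(tree.tip_labels)
    S = len(species)
    n_ind = S * N_DIPLOIDS_PER_SPECIES
    if n_assoc > n_sites:
        raise ValueError("n_assoc > n_sites")

    # species trait: standardized BM draw unless a measured trait is given
    if trait is None:
        trait_bm = simulate_continuous(tree, "BM", {"sigma2": 1.0},
                                       seed=int(rng.integers(2**31)))
    else:
        trait_bm = np.asarray(trait, dtype=float)
        if len(trait_bm) != S:
            raise ValueError("trait length must match tree tips")
    t_std = (trait_bm - trait_bm.mean()) / trait_bm.std()

    # null allele frequencies: logit-BM around a site-specific base
    base = rng.uniform(-1.5, 1.5, n_sites)
    C = tree.mrca_depths()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(S))
    logit = base[:, None] + sigma_logit * (L @ rng.standard_normal((S, n_sites))).T
    af = 1.0 / (1.0 + np.exp(-logit))

    assoc = rng.choice(n_sites, size=n_assoc, replace=False) if n_assoc else np.empty(0, int)
    if n_assoc:
        # plant sites whose scaled frequency x = 2f-1 tracks the trait with
        # slope consistent with trait = beta * x + unit BM noise
        rho = beta / np.sqrt(1.0 + beta**2)
        for k, s in enumerate(assoc):
            noise = L @ rng.standard_normal(S)
            noise = (noise - noise.mean()) / noise.std()
            x = np.clip(rho * t_std + np.sqrt(1 - rho**2) * noise * 0.4, -0.96, 0.96)
            af[s] = (x + 1.0) / 2.0

    genotypes = rng.binomial(2, np.repeat(af, N_DIPLOIDS_PER_SPECIES, axis=1))
    depth = rng.poisson(mean_depth, size=genotypes.shape)
    p_alt = np.array([base_error, 0.5, 1.0 - base_error])[genotypes]
    alt_reads = rng.binomial(depth, p_alt)
    pl = _gatk_pl(alt_reads, depth - alt_reads, base_error)
    # no reads -> flat likelihoods
    pl[depth == 0] = 0

    dp = depth.sum(axis=1)

    # INFO annotations with planted failures
    qd = rng.uniform(15.0, 35.0, n_sites)
    fs = rng.uniform(0.0, 10.0, n_sites)
    mq = rng.uniform(50.0, 60.0, n_sites)
    mqrs = rng.normal(0.0, 1.0, n_sites)
    rprs = rng.normal(0.0, 1.0, n_sites)
    quality_fail = np.zeros(n_sites, dtype=bool)
    depth_fail = ~((dp >= 900) & (dp <= 1900))
    is_indel = np.zeros(n_sites, dtype=bool)
    multiallelic = np.zeros(n_sites, dtype=bool)
    unplaced = np.zeros(n_sites, dtype=bool)
    if contaminate:
        bad = rng.random(n_sites) < QUALITY_FAIL_FRACTION
        which = rng.integers(0, 5, n_sites)
        qd[bad & (which == 0)] = rng.uniform(0.0, 1.99, (bad & (which == 0)).sum())
        fs[bad & (which == 1)] = rng.uniform(60.01, 200.0, (bad & (which == 1)).sum())
        mq[bad & (which == 2)] = rng.uniform(10.0, 39.99, (bad & (which == 2)).sum())
        mqrs[bad & (which == 3)] = rng.uniform(-20.0, -12.51, (bad & (which == 3)).sum())
        rprs[bad & (which == 4)] = rng.uniform(-15.0, -8.01, (bad & (which == 4)).sum())
        quality_fail = bad
        # structural labels on a disjoint slice of sites
        other = rng.random(n_sites)
        is_indel = (other >= 0.95) & ~bad
        multiallelic = (other >= 0.92) & (other < 0.95) & ~bad
        unplaced = (other >= 0.90) & (other < 0.92) & ~bad
        forced_low = rng.random(n_sites) < DEPTH_FAIL_FRACTION

        dp = dp.astype(float)
        dp[forced_low] = rng.integers(100, 899, forced_low.sum())
        dp = dp.astype(int)
        depth_fail = ~((dp >= 900) & (dp <= 1900))

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = np.array([bases[(list(bases).index(r) + 1 + rng.integers(0, 3)) % 4]
                    for r in ref])
    alt_field = alt.astype(object)
    ref_field = ref.astype(object)
    alt_field[is_indel] = [a + "T" for a in alt[is_indel]]
    alt_field[multiallelic] = [f"{a},{bases[(list(bases).index(a) + 1) % 4]}"
                               for a in alt[multiallelic]]

    chrom = np.where(unplaced, "scaffold_un_1", "chr1").astype(object)
    pos = np.sort(rng.choice(np.arange(1, n_sites * 50), n_sites, replace=False))

    # singleton labels from the drawn genotypes (minor allele in one individual)
    alt_count = genotypes.sum(axis=1)
    minor = np.minimum(alt_count, 2 * n_ind - alt_count)
    carriers_alt = (genotypes > 0).sum(axis=1)
    carriers_ref = (genotypes < 2).sum(axis=1)
    singleton = np.where(alt_count <= 2 * n_ind - alt_count,
                         carriers_alt <= 1, carriers_ref <= 1)
    monomorphic = minor == 0

    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref_field, "alt": alt_field,
        "QD": qd, "FS": fs, "MQ": mq, "MQRankSum": mqrs,
        "ReadPosRankSum": rprs, "DP": dp,
        "true_quality_fail": quality_fail, "true_depth_fail": depth_fail,
        "true_indel": is_indel, "true_multiallelic": multiallelic,
        "true_unplaced": unplaced, "true_singleton": singleton,
        "true_monomorphic": monomorphic,
        "true_assoc": np.isin(np.arange(n_sites), assoc),
    })
    individuals = [f"{sp}_{i}" for sp in species
                   for i in range(N_DIPLOIDS_PER_SPECIES)]
    return GenotypePanel(sites, pl, genotypes, af, trait_bm, species,
                         individuals, assoc)
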