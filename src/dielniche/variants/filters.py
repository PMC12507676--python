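"""Site filtering for the species-level variant panel.

Quality masking follows the GATK hard-filter expression
``QD < 2.0 || FS > 60.0 || MQ < 40.0 || MQRankSum < -12.5 ||
ReadPosRankSum < -8.0`` (a site fails when any clause is true; a missing
annotation passes its clause, the GATK VariantFiltration convention).
The depth gate keeps sites whose summed read depth across all samples is
between 900 and 1900 inclusive.  Site selection then keeps biallelic
SNPs on placed scaffolds (optionally inside a mappability BED) whose
minor allele is carried by at least two individuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["quality_mask", "depth_mask", "site_selection"]

_QUALITY_CLAUSES = (
    ("QD", "lt", 2.0),
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
)


def _get(site, key):
    v = site.get(key) if hasattr(site, "get") else getattr(site, key, None)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def quality_mask(site) -> bool:
    """True (pass) unless any hard-filter clause fires.

    All boundaries are exclusive, exactly as the printed inequalities:
    QD = 2.0, FS = 60.0, MQ = 40.0, MQRankSum = -12.5 and
    ReadPosRankSum = -8.0 all pass.
    """
    for key, op, cut in _QUALITY_CLAUSES:
        v = _get(site, key)
        if v is None:
            continue          # missing annotation passes its clause
        if (op == "lt" and v < cut) or (op == "gt" and v > cut):
            return False
    return True


def depth_mask(site, low: float = 900.0, high: float = 1900.0) -> bool:
    """Pass iff the summed depth satisfies low <= DP <= high."""
    dp = _get(site, "DP")
    if dp is None:
        return False
    return low <= dp <= high


def _best_genotypes(pl: np.ndarray) -> np.ndarray:
    """Best-guess genotype per individual from Phred likelihood triples."""
    return np.argmin(pl, axis=-1)


def site_selection(
    sites: pd.DataFrame,
    pl: np.ndarray | None = None,
    mappability_bed: pd.DataFrame | None = None,
    placed_prefix: str = "chr",
    min_minor_carriers: int = 2,
    apply_quality: bool = True,
    apply_depth: bool = True,
) -> np.ndarray:
    """Boolean keep-vector over the site table.

    Removes quality/depth failures, indels, multiallelic records, sites
    on unplaced scaffolds, sites outside the mappability mask (when one
    is given; BED intervals are 0-based half-open), and sites whose minor
    allele is observed (by best genotype from the PL triples) in fewer
    than ``min_minor_carriers`` individuals.
    """
    n = len(sites)
    keep = np.ones(n, dtype=bool)
    if apply_quality:
        fail = np.zeros(n, dtype=bool)
        for key, op, cut in _QUALITY_CLAUSES:
            if key not in sites:
                continue
            v = pd.to_numeric(sites[key], errors="coerce").to_numpy()
            with np.errstate(invalid="ignore"):
                hit = (v < cut) if op == "lt" else (v > cut)
            fail |= np.where(np.isnan(v), False, hit)
        keep &= ~fail
    if apply_depth:
        dp = pd.to_numeric(sites.get("DP"), errors="coerce").to_numpy() \
            if "DP" in sites else np.full(n, np.nan)
        keep &= np.where(np.isnan(dp), False, (dp >= 900) & (dp <= 1900))

    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    snp = (ref.str.len() == 1) & (alt.str.len() == 1) & ~alt.str.contains(",")
    keep &= snp.to_numpy()
    keep &= sites["chrom"].astype(str).str.startswith(placed_prefix).to_numpy()

    if mappability_bed is not None:
        inside = np.zeros(n, dtype=bool)
        pos0 = sites["pos"].to_numpy() - 1          # VCF is 1-based
        chroms = sites["chrom"].to_numpy()
        for _, iv in mappability_bed.iterrows():
            inside |= ((chroms == iv["chrom"]) & (pos0 >= iv["start"])
                       & (pos0 < iv["end"]))
        keep &= inside

    if pl is not None:
        g = _best_genotypes(np.asarray(pl))
        n_ind = g.shape[1]
        alt_count = g.sum(axis=1)
        alt_minor = alt_count <= 2 * n_ind - alt_count
        carriers = np.where(alt_minor, (g > 0).sum(axis=1), (g < 2).sum(axis=1))
        minor_count = np.minimum(alt_count, 2 * n_ind - alt_count)
        keep &= (minor_count > 0) & (carriers >= min_minor_carriers)
    return keep
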