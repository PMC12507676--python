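"""VCF 4.2 reading and writing for the species-level variant panel.

Records carry PL genotype-likelihood triples per diploid individual and
the INFO annotations the filtering stage consumes (QD, FS, MQ, MQRankSum,
ReadPosRankSum, DP).  pysam does the parsing and serialization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

__all__ = ["write_vcf", "read_vcf", "read_bed"]

_INFO_FIELDS = (
    ("QD", "Float", "Variant confidence / depth"),
    ("FS", "Float", "Phred-scaled strand-bias Fisher p"),
    ("MQ", "Float", "RMS mapping quality"),
    ("MQRankSum", "Float", "Mapping-quality rank-sum Z"),
    ("ReadPosRankSum", "Float", "Read-position rank-sum Z"),
    ("DP", "Integer", "Combined depth across samples"),
)


def write_vcf(path, sites: pd.DataFrame, pl: np.ndarray, individuals: list,
              contigs=None) -> None:
    """Write the site table + PL array to an uncompressed VCF."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    if contigs is None:
        contigs = list(dict.fromkeys(sites["chrom"].astype(str)))
    maxpos = int(sites["pos"].max()) + 1000
    for c in contigs:
        header.contigs.add(c, length=maxpos)
    for name, typ, desc in _INFO_FIELDS:
        header.info.add(name, 1, typ, desc)
    header.formats.add("GT", 1, "String", "Best-guess genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    for ind in individuals:
        header.add_sample(ind)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, (_, row) in enumerate(sites.iterrows()):
            alts = tuple(str(row["alt"]).split(","))
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]),) + alts)
            for name, typ, _ in _INFO_FIELDS:
                if name in row and pd.notna(row[name]):
                    rec.info[name] = (int(row[name]) if typ == "Integer"
                                      else float(row[name]))
            n_alleles = 1 + len(alts)
            n_geno = n_alleles * (n_alleles + 1) // 2
            for j, ind in enumerate(individuals):
                trip = [int(v) for v in pl[i, j]]
                g = int(np.argmin(trip))
                rec.samples[ind]["GT"] = ((0, 0), (0, 1), (1, 1))[g]
                # genotypes involving alleles beyond the first alt get a
                # large (implausible) Phred likelihood
                rec.samples[ind]["PL"] = trip + [255] * (n_geno - 3)
            vf.write(rec)


def read_vcf(path):
    """Read a panel VCF back into (sites DataFrame, PL array, individuals)."""
    rows = []
    pls = []
    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        for rec in vf:
            info = {k: rec.info.get(k) for k, _, _ in _INFO_FIELDS}
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": ",".join(rec.alts or ()), **info})
            trip = np.zeros((len(individuals), 3), dtype=int)
            for j, ind in enumerate(individuals):
                v = rec.samples[ind].get("PL")
                if v is not None and len(v) >= 3 and all(
                        x is not None for x in v[:3]):
                    trip[j] = v[:3]
            pls.append(trip)
    sites = pd.DataFrame(rows)
    return sites, np.asarray(pls), individuals


def read_bed(path) -> pd.DataFrame:
    """Mappability mask: 0-based half-open intervals."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end"],
                       usecols=[0, 1, 2])
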