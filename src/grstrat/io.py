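"""Flat-file input/output: dosage TSV, phenotype TSV and VCF.

TSV is the primary interchange format (dosage matrix with ``NA`` missing,
phenotype table with a documented header).  VCF support writes one sample
per individual with a GT field and reads through ``cyvcf2``, orienting
dosages to the panel's risk allele.  Strand harmonisation is the caller's
responsibility.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, VariantPanel


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_vcf(genotypes: GenotypeMatrix, panel: VariantPanel, path) -> None:
    """Write dosages as a minimal VCF 4.2 (GT only, 1-based positions).

    REF is the panel's ``other_allele`` and ALT the risk allele, so the ALT
    allele count equals the stored dosage.  Missing dosage becomes ``./.``.
    """
    recs = {r.rsid: r for r in panel.records}
    missing = [r for r in genotypes.rsids if r not in recs]
    if missing:
        raise KeyError(f"variants not in panel: {missing}")
    order = sorted(genotypes.rsids, key=lambda r: (str(recs[r].chrom), recs[r].pos))
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in genotypes.sample_ids) + "\n")
        for rsid in order:
            rec = recs[rsid]
            col = genotypes.column(rsid)
            gts = "\t".join("./." if np.isnan(d) else gt_of[d] for d in col)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.rsid}\t{rec.other_allele}\t"
                     f"{rec.risk_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, panel: VariantPanel) -> GenotypeMatrix:
    """Read GT fields from a VCF, counting copies of the panel risk allele.

    Variants are matched by rsid; sites whose rsid is not in the panel are
    skipped.  If the risk allele is the REF allele the dosage is flipped.
    """
    from cyvcf2 import VCF  # lazy: optional backend

    recs = {r.rsid: r for r in panel.records}
    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    rsids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        rsid = var.ID
        if rsid not in recs:
            continue
        rec = recs[rsid]
        # gt_types with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        alt_dosage = np.asarray(var.gt_types, dtype=float)
        alt_dosage[alt_dosage == 3] = np.nan
        if var.ALT and rec.risk_allele == var.ALT[0]:
            dos = alt_dosage
        elif rec.risk_allele == var.REF:
            dos = 2.0 - alt_dosage
        else:
            raise ValueError(
                f"{rsid}: risk allele {rec.risk_allele!r} matches neither "
                f"REF {var.REF!r} nor ALT {var.ALT!r}")
        rsids.append(rsid)
        cols.append(dos)
    vcf.close()
    if not rsids:
        raise ValueError("no panel variants found in VCF")
    # restore panel order for the variants present
    order = [r for r in (rec.rsid for rec in panel.records) if r in set(rsids)]
    idx = {r: i for i, r in enumerate(rsids)}
    dosage = np.column_stack([cols[idx[r]] for r in order])
    return GenotypeMatrix(samples, np.asarray(order, dtype=object), dosage)
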