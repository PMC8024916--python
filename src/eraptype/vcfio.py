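"""Optional phased-VCF ingestion.

Genotype calls carry nucleotide alleles, while allotype catalogs are
residue strings, so a site annotation table (position, ref_residue,
alt_residue) translates each phased GT into a residue per haplotype.
Only fully phased records ("|" separators) are accepted; genotype
phasing or imputation is out of scope.

Requires ``cyvcf2`` (the ``vcf`` extra).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .popgen import PhasedPanel


def read_phased_vcf(
    path: str,
    annotation: pd.DataFrame,
    populations: Mapping[str, str] | None = None,
) -> PhasedPanel:
    """Build a phased panel from a VCF of coding SNPs.

    ``annotation`` must provide ``position``, ``ref_residue`` and
    ``alt_residue`` columns; VCF records are matched to annotation rows
    by POS and taken in annotation (canonical) order.  ``populations``
    optionally maps sample name to population label (default ``ALL``).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "phased-VCF ingestion requires cyvcf2 (install the 'vcf' extra)"
        ) from exc

    ann = annotation.set_index("position")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    hap_alleles: dict[int, tuple[list[int], list[int]]] = {}
    for variant in vcf:
        if variant.POS not in ann.index:
            continue
        a0, a1 = [], []
        for gt in variant.genotypes:
            allele_a, allele_b, phased = gt[0], gt[1], gt[-1]
            if not phased:
                raise ValueError(
                    f"unphased genotype at POS {variant.POS}; phased input required"
                )
            a0.append(allele_a)
            a1.append(allele_b)
        hap_alleles[variant.POS] = (a0, a1)

    missing = [p for p in ann.index if p not in hap_alleles]
    if missing:
        raise ValueError(f"VCF lacks records for positions {missing}")

    def residue(pos: int, allele: int) -> str:
        row = ann.loc[pos]
        if allele == 0:
            return str(row["ref_residue"])
        if allele == 1:
            return str(row["alt_residue"])
        raise ValueError(f"multi-allelic genotype at position {pos}")

    hap1, hap2 = [], []
    for i in range(len(samples)):
        hap1.append("".join(residue(p, hap_alleles[p][0][i]) for p in ann.index))
        hap2.append("".join(residue(p, hap_alleles[p][1][i]) for p in ann.index))
    pops = [populations.get(s, "ALL") if populations else "ALL" for s in samples]
    return PhasedPanel(samples=samples, populations=pops, hap1=hap1, hap2=hap2)
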