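"""Packaged reference data: the 16-allotype ERAP1 catalog with reference
population frequencies, the polymorphic-site annotations used for VCF
ingestion, and 1000 Genomes phase-3 population sizes."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .popgen import AllotypeCatalog, Site, SiteSet

#: 1000 Genomes phase 3 sample counts per super-population (2504 total).
POPULATION_SAMPLES = {"AFR": 661, "AMR": 347, "EAS": 504, "EUR": 503, "SAS": 489}

#: Columns of the shipped frequency table.
POPULATIONS = ("ALL", "AFR", "AMR", "EUR", "EAS", "SAS")

#: Conventional label groups: the ten common allotypes characterised
#: enzymatically, and the six rarer population-restricted ones.
DEFAULT_GROUPS = {
    "1-10": tuple(str(i) for i in range(1, 11)),
    "11-16": tuple(str(i) for i in range(11, 17)),
}


def _data_path(name: str):
    return resources.files("eraptype.data").joinpath(name)


def load_catalog_frame() -> pd.DataFrame:
    """Raw shipped catalog: allotype label, 9-residue haplotype, and
    percent frequency per population."""
    with resources.as_file(_data_path("erap1_allotype_catalog.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype={"allotype": str})
    return frame


def load_catalog() -> AllotypeCatalog:
    """The 16-entry ERAP1 allotype catalog (haplotype -> label)."""
    frame = load_catalog_frame()
    return AllotypeCatalog(
        entries=dict(zip(frame["haplotype"], frame["allotype"]))
    )


def reference_frequencies() -> pd.DataFrame:
    """Published percent frequencies indexed by allotype label, one
    column per population (ALL, AFR, AMR, EUR, EAS, SAS)."""
    frame = load_catalog_frame().set_index("allotype")
    return frame[list(POPULATIONS)]


def erap1_sites() -> SiteSet:
    """The nine canonical ERAP1 polymorphic positions with allele sets."""
    with resources.as_file(_data_path("erap1_sites.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    sites = tuple(
        Site(int(r.position), (r.ref_residue, r.alt_residue), maf=float(r.maf))
        for r in frame.itertuples()
    )
    return SiteSet("ERAP1", sites)


def erap2_sites() -> SiteSet:
    """The two ERAP2 tag SNPs (rs2549782, rs2248374), nucleotide alleles."""
    with resources.as_file(_data_path("erap2_sites.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    sites = tuple(
        Site(int(r.position), (r.ref_allele, r.alt_allele), maf=float(r.maf))
        for r in frame.itertuples()
    )
    return SiteSet("ERAP2", sites)


def site_annotation() -> pd.DataFrame:
    """Position -> residue-change annotation used to translate VCF
    ref/alt genotypes into haplotype residue strings."""
    with resources.as_file(_data_path("erap1_sites.tsv")) as path:
        return pd.read_csv(path, sep="\t")
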