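"""Allotype calling and population statistics for ERAP1/ERAP2.

ERAP1 allotypes are defined as 9-site haplotypes of coding missense
polymorphisms (amino-acid positions 56, 127, 276, 346, 349, 528, 575,
725 and 730).  Given a phased panel — two haplotype strings per sample —
each chromosome is assigned an allotype label by exact lookup in a
catalog, and population frequencies, diplotype (unordered allotype pair)
tables and cross-gene contingency tables are derived from the calls.

ERAP2 is handled through its two tag SNPs, rs2549782 and rs2248374: the
[G,A] haplotype is allotype A, [T,G] is allotype B, and the rs2248374 G
allele abolishes protein expression, so B/B individuals are
expression-null.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: Canonical order of the ERAP1 polymorphic amino-acid positions.
ERAP1_POSITIONS = (56, 127, 276, 346, 349, 528, 575, 725, 730)


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    """One polymorphic site: an amino-acid (or nucleotide) position with
    its observed allele set and, optionally, a global minor-allele
    frequency."""

    position: int
    alleles: tuple[str, ...]
    maf: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.alleles)) < 2:
            raise ValueError(
                f"site {self.position} needs >=2 alleles, got {self.alleles!r}"
            )


@dataclass(frozen=True)
class SiteSet:
    """Ordered set of polymorphic sites for one gene."""

    gene: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"positions not strictly increasing: {positions}")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)

    def validate_haplotype(self, hap: str) -> None:
        """Raise ``ValueError`` if ``hap`` has the wrong length or carries a
        residue outside a site's allele set."""
        if len(hap) != len(self.sites):
            raise ValueError(
                f"haplotype {hap!r} has length {len(hap)}, expected {len(self.sites)}"
            )
        for residue, site in zip(hap, self.sites):
            if residue not in site.alleles:
                raise ValueError(
                    f"residue {residue!r} not in allele set {site.alleles} "
                    f"at position {site.position}"
                )


def filter_polymorphic_sites(
    allele_freqs: Mapping[int, float],
    cutoff: float = 0.01,
    excluded_positions: Iterable[int] = (),
    *,
    alleles: Mapping[int, Sequence[str]],
    gene: str = "ERAP1",
) -> SiteSet:
    """Select polymorphic sites by minor-allele-frequency cutoff.

    A coding missense variant qualifies as a polymorphism when its global
    frequency reaches ``cutoff`` (default 1%).  Positions in
    ``excluded_positions`` are dropped regardless of frequency — for ERAP1
    this removes position 12, which lies in the signal peptide and is
    absent from the mature protein.  Input order is preserved.
    """
    excluded = set(excluded_positions)
    sites = []
    for pos, freq in allele_freqs.items():
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"frequency {freq} at position {pos} outside [0, 1]")
        if freq >= cutoff and pos not in excluded:
            sites.append(Site(pos, tuple(alleles[pos]), maf=freq))
    if not sites:
        raise ValueError("no polymorphic sites")
    return SiteSet(gene, tuple(sites))


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllotypeCatalog:
    """Mapping from haplotype residue strings to allotype labels.

    Haplotypes absent from the catalog classify as ``unassigned_label``.
    """

    entries: Mapping[str, str]
    unassigned_label: str = UNASSIGNED

    def __post_init__(self) -> None:
        labels = list(self.entries.values())
        if len(set(labels)) != len(labels):
            raise ValueError("allotype labels not unique")
        lengths = {len(h) for h in self.entries}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent haplotype lengths: {lengths}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.entries.values())

    @property
    def haplotype_length(self) -> int:
        return len(next(iter(self.entries)))

    def haplotype(self, label: str) -> str:
        for hap, lab in self.entries.items():
            if lab == label:
                return hap
        raise KeyError(f"no allotype labelled {label!r}")


def classify_haplotype(
    hap: str,
    catalog: AllotypeCatalog,
    sites: SiteSet | None = None,
) -> str:
    """Assign an allotype label to one haplotype by exact catalog lookup.

    Returns the catalog's unassigned label for any haplotype not in the
    catalog; raises only on malformed input (wrong length, or — when
    ``sites`` is given — a residue outside that site's allele set).
    """
    if len(hap) != catalog.haplotype_length:
        raise ValueError(
            f"haplotype {hap!r} has length {len(hap)}, "
            f"catalog expects {catalog.haplotype_length}"
        )
    if sites is not None:
        sites.validate_haplotype(hap)
    return catalog.entries.get(hap, catalog.unassigned_label)


def _label_sort_key(label: str):
    """Numeric-aware ordering: '2' < '10' < 'unassigned'."""
    return (0, int(label)) if label.isdigit() else (1, label)


# ---------------------------------------------------------------------------
# Phased panels
# ---------------------------------------------------------------------------

@dataclass
class PhasedPanel:
    """Phased diploid panel: two haplotype strings per sample."""

    samples: list[str]
    populations: list[str]
    hap1: list[str]
    hap2: list[str]

    def __post_init__(self) -> None:
        n = len(self.samples)
        if not (len(self.populations) == len(self.hap1) == len(self.hap2) == n):
            raise ValueError("panel columns have unequal lengths")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_chromosomes(self) -> int:
        return 2 * len(self.samples)

    def chromosomes(self) -> Iterable[tuple[str, str]]:
        """Yield (population, haplotype) for every chromosome."""
        for pop, h1, h2 in zip(self.populations, self.hap1, self.hap2):
            yield pop, h1
            yield pop, h2

    def validate(self, sites: SiteSet) -> None:
        for hap in (*self.hap1, *self.hap2):
            sites.validate_haplotype(hap)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "population": self.populations,
                "hap1": self.hap1,
                "hap2": self.hap2,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhasedPanel":
        required = {"sample", "population", "hap1", "hap2"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        return cls(
            samples=frame["sample"].astype(str).tolist(),
            populations=frame["population"].astype(str).tolist(),
            hap1=frame["hap1"].astype(str).tolist(),
            hap2=frame["hap2"].astype(str).tolist(),
        )


def read_panel_tsv(path) -> PhasedPanel:
    return PhasedPanel.from_frame(pd.read_csv(path, sep="\t"))


def write_panel_tsv(panel: PhasedPanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Per-population allotype chromosome counts and frequencies.

    ``counts`` is indexed by allotype label with one column per population
    plus an ``ALL`` column; ``chromosomes`` holds the per-column totals.
    Display output is rounded to 1 decimal percent; internal arithmetic
    stays at full precision.
    """

    counts: pd.DataFrame
    chromosomes: pd.Series
    groups: Mapping[str, Sequence[str]] | None = None

    def fractions(self) -> pd.DataFrame:
        return self.counts / self.chromosomes

    def percent(self, decimals: int = 1) -> pd.DataFrame:
        return (100.0 * self.fractions()).round(decimals)

    def subtotals(self, decimals: int = 1) -> pd.DataFrame:
        """Percent subtotal per label group (e.g. allotypes 1-10)."""
        if not self.groups:
            raise ValueError("no label groups defined")
        rows = {}
        for name, labels in self.groups.items():
            present = [lab for lab in labels if lab in self.counts.index]
            frac = self.counts.loc[present].sum() / self.chromosomes
            rows[name] = (100.0 * frac).round(decimals)
        return pd.DataFrame(rows).T

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        out = self.percent(decimals)
        out.index.name = "allotype"
        return out


def allotype_frequencies(
    panel: PhasedPanel,
    catalog: AllotypeCatalog,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> FrequencyTable:
    """Tabulate allotype frequencies per population and overall.

    Frequency = chromosomes carrying the allotype / total chromosomes,
    within each population column and in the pooled ``ALL`` column.
    """
    if panel.n_samples == 0:
        raise ValueError("empty panel")
    counts: Counter = Counter()
    for pop, hap in panel.chromosomes():
        counts[(pop, classify_haplotype(hap, catalog))] += 1

    pops = sorted({pop for pop, _ in counts})
    labels = sorted({lab for _, lab in counts}, key=_label_sort_key)
    table = pd.DataFrame(0, index=labels, columns=pops, dtype=int)
    for (pop, lab), n in counts.items():
        table.loc[lab, pop] = n
    table["ALL"] = table.sum(axis=1)
    chromosomes = table.sum(axis=0)
    return FrequencyTable(counts=table, chromosomes=chromosomes, groups=groups)


# ---------------------------------------------------------------------------
# Diplotypes
# ---------------------------------------------------------------------------

@dataclass
class DiplotypeTable:
    """Counts of unordered allotype pairs across samples."""

    counts: dict[tuple[str, str], int]
    n_samples: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_samples:
            raise ValueError("diplotype counts do not sum to sample count")

    def frequency(self, pair: tuple[str, str]) -> float:
        """Fraction of samples carrying the unordered pair."""
        return self.counts.get(pair_key(*pair), 0) / self.n_samples

    def percents(self) -> dict[tuple[str, str], float]:
        return {k: 100.0 * v / self.n_samples for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "allotype_a": a,
                "allotype_b": b,
                "count": n,
                "percent": 100.0 * n / self.n_samples,
            }
            for (a, b), n in sorted(
                self.counts.items(),
                key=lambda kv: (_label_sort_key(kv[0][0]), _label_sort_key(kv[0][1])),
            )
        ]
        return pd.DataFrame(rows)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair key, sorted numerically where possible."""
    return tuple(sorted((a, b), key=_label_sort_key))  # type: ignore[return-value]


def diplotype_table(panel: PhasedPanel, catalog: AllotypeCatalog) -> DiplotypeTable:
    """Count unordered allotype combinations carried by each sample."""
    if panel.n_samples == 0:
        raise ValueError("empty panel")
    counts: Counter = Counter()
    for h1, h2 in zip(panel.hap1, panel.hap2):
        key = pair_key(
            classify_haplotype(h1, catalog), classify_haplotype(h2, catalog)
        )
        counts[key] += 1
    return DiplotypeTable(counts=dict(counts), n_samples=panel.n_samples)


def expected_cooccurrence(
    p: float, q: float, mode: str = "hwe", *, identical: bool = False
) -> float:
    """Expected frequency of an allotype pair under random pairing.

    ``mode="hwe"`` is the unordered-genotype expectation: ``2pq`` for two
    distinct allotypes, ``p**2`` for a homozygous pair.  ``mode="product"``
    returns the plain product ``p*q`` (a commonly quoted arithmetic shortcut
    kept for comparison).  Frequencies are fractions in [0, 1].
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    if mode == "product":
        return p * q
    if mode == "hwe":
        return p * p if identical else 2.0 * p * q
    raise ValueError(f"unknown mode {mode!r}")


def random_pairing_simulation(
    freqs: Mapping[str, float], n_samples: int, seed: int
) -> DiplotypeTable:
    """Pair 2n haplotypes drawn i.i.d. from ``freqs`` and tabulate the
    unordered allotype combinations.  Reproducible under a fixed seed."""
    labels = list(freqs)
    probs = np.asarray([freqs[lab] for lab in labels], dtype=float)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"frequencies sum to {total}, expected ~1")
    probs = probs / total
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(labels), size=(n_samples, 2), p=probs)
    counts: Counter = Counter()
    for i, j in draws:
        counts[pair_key(labels[i], labels[j])] += 1
    return DiplotypeTable(counts=dict(counts), n_samples=n_samples)


# ---------------------------------------------------------------------------
# ERAP2
# ---------------------------------------------------------------------------

#: Haplotypes over (rs2549782, rs2248374): [G,A] is allotype A, [T,G] is B.
ERAP2_HAPLOTYPE_LABELS = {"GA": "A", "TG": "B"}
ERAP2_OTHER = "other"
#: The rs2248374 G allele (second site) abolishes ERAP2 expression.
_ERAP2_NULL_ALLELE = "G"


@dataclass
class Erap2Calls:
    """Per-sample ERAP2 allotype calls and expression-null flags."""

    samples: list[str]
    calls: list[tuple[str, str]]  # unordered (A/B/other) pair per sample
    expression_null: list[bool]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def haplotype_frequencies(self) -> dict[str, float]:
        """Fraction of chromosomes per ERAP2 allotype label."""
        counts: Counter = Counter()
        for a, b in self.calls:
            counts[a] += 1
            counts[b] += 1
        total = 2 * self.n_samples
        return {lab: n / total for lab, n in sorted(counts.items())}

    def null_fraction(self) -> float:
        """Fraction of samples with no expressed ERAP2 allele."""
        return sum(self.expression_null) / self.n_samples

    def diplotype_classes(self) -> dict[str, str]:
        """Sample -> 'A/A', 'A/B', ... class string."""
        return {
            s: "/".join(call) for s, call in zip(self.samples, self.calls)
        }


def call_erap2(panel: PhasedPanel) -> Erap2Calls:
    """Call ERAP2 allotypes from two-site (rs2549782, rs2248374) haplotypes.

    [G,A] maps to allotype A and [T,G] to allotype B; any other
    combination is labelled ``other``.  A sample is expression-null iff
    both its haplotypes carry G at rs2248374.
    """
    calls: list[tuple[str, str]] = []
    nulls: list[bool] = []
    for h1, h2 in zip(panel.hap1, panel.hap2):
        for h in (h1, h2):
            if len(h) != 2:
                raise ValueError(f"ERAP2 haplotype {h!r} must have 2 sites")
        lab1 = ERAP2_HAPLOTYPE_LABELS.get(h1, ERAP2_OTHER)
        lab2 = ERAP2_HAPLOTYPE_LABELS.get(h2, ERAP2_OTHER)
        calls.append(pair_key(lab1, lab2))
        nulls.append(h1[1] == _ERAP2_NULL_ALLELE and h2[1] == _ERAP2_NULL_ALLELE)
    return Erap2Calls(samples=list(panel.samples), calls=calls, expression_null=nulls)


# ---------------------------------------------------------------------------
# Cross-tabulation
# ---------------------------------------------------------------------------

@dataclass
class CrossTab:
    """ERAP1 diplotype distribution conditional on ERAP2 diplotype class.

    ``percent`` has one row per ERAP1 pair, one column per ERAP2 class
    plus a whole-population ``ALL`` marginal; every column sums to 100.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame


def cross_tabulate(
    erap1_pairs: Mapping[str, tuple[str, str]],
    erap2_classes: Mapping[str, str],
) -> CrossTab:
    """Distribution of ERAP1 allotype combinations within each group of
    individuals carrying a particular ERAP2 diplotype, next to the
    whole-population marginal."""
    if set(erap1_pairs) != set(erap2_classes):
        raise ValueError("ERAP1 and ERAP2 calls cover different sample sets")
    counts: Counter = Counter()
    for sample, pair in erap1_pairs.items():
        key = "/".join(pair_key(*pair))
        counts[(key, erap2_classes[sample])] += 1

    rows = sorted({k for k, _ in counts})
    cols = sorted({c for _, c in counts})
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (row, col), n in counts.items():
        table.loc[row, col] = n
    table["ALL"] = table.sum(axis=1)
    percent = 100.0 * table / table.sum(axis=0)
    return CrossTab(counts=table, percent=percent)
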