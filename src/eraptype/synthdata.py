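"""Seeded generators for every input the pipeline consumes.

The generators emulate the study designs the analysis modules expect:
phased genotype panels with configurable haplotype frequencies (and
optional cross-gene diplotype coupling), enzyme-assay rate and
time-course datasets from Michaelis–Menten or Hill ground truths,
inhibitor titrations from four-parameter-logistic ground truths with
high/low control wells, and sequential-trimming time courses from the
shared-enzyme competitive cascade model.

Default kinetic ground truths encode reported fold relationships only
— the 9mer catalytic-efficiency ratio of 60 between allotypes 2 and 10,
the Leu-AMC efficiency ratio of 18 between allotypes 3 and 10, a
roughly twofold activity band across allotypes 1-9 with allotype 10's
turnover tenfold below the median, and a KM spread within sixfold.
Absolute values are configuration, chosen once at plausible magnitudes
for an ER aminopeptidase.

Every generator is a pure function of (spec, seed).  Noise is
multiplicative log-normal by default (plate-reader-like), parameterised
by its coefficient of variation and mean-corrected so E[noise] = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .catalog import POPULATION_SAMPLES, load_catalog, reference_frequencies
from .kinetics import KineticDataset, StandardCurve
from .popgen import AllotypeCatalog, PhasedPanel, pair_key
from .trimming import OVALBUMIN_SPECIES, TrimmingSeries, integrate_cascade

#: Alphabet-valid 9-residue haplotype that matches no catalog entry;
#: used to carry the small "unassigned" remainder of exact-count panels.
FILLER_HAPLOTYPE = "EPIGMKDRE"

ERAP2_LABEL_TO_HAP = {"A": "GA", "B": "TG"}


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def largest_remainder(weights: Mapping[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` integer counts proportionally to ``weights``
    (largest-remainder method, deterministic tie-break)."""
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    quota = w / w.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.lexsort((np.arange(len(keys)), -(quota - counts)))
    counts[order[:short]] += 1
    return dict(zip(keys, counts.tolist()))


# ---------------------------------------------------------------------------
# Phased panels
# ---------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """Recipe for one population's phased panel.

    ``freqs`` maps haplotype strings to frequencies (summing to ~1).  In
    ``exact`` mode chromosome counts are round(freq x 2n) with
    largest-remainder correction so the total is exactly 2n; in
    ``sample`` mode chromosomes are drawn i.i.d.  ``joint``, if given,
    fixes the number of samples per unordered haplotype pair (cross-
    chromosome coupling) instead of random pairing.
    """

    freqs: Mapping[str, float]
    n_samples: int
    population: str = "ALL"
    mode: str = "exact"
    joint: Mapping[tuple[str, str], int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.freqs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")
        if self.mode not in ("exact", "sample"):
            raise ValueError(f"unknown mode {self.mode!r}")


def gen_phased_panel(spec: PanelSpec, seed: int | None = None) -> PhasedPanel:
    """Generate a phased diploid panel from a :class:`PanelSpec`."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_samples
    haps = list(spec.freqs)

    if spec.joint is not None:
        if sum(spec.joint.values()) != n:
            raise ValueError("joint diplotype counts do not sum to sample count")
        marginal: dict[str, int] = {}
        pairs = []
        for (a, b), count in spec.joint.items():
            marginal[a] = marginal.get(a, 0) + count
            marginal[b] = marginal.get(b, 0) + count
            pairs.extend([(a, b)] * count)
        expected = largest_remainder(spec.freqs, 2 * n)
        for hap, got in marginal.items():
            want = expected.get(hap, 0)
            if abs(got - want) > max(2, 0.01 * 2 * n):
                raise ValueError(
                    f"joint distribution marginal for {hap!r} ({got}) "
                    f"inconsistent with frequencies ({want})"
                )
        rng.shuffle(pairs)
        hap1 = [a for a, _ in pairs]
        hap2 = [b for _, b in pairs]
    elif spec.mode == "exact":
        counts = largest_remainder(spec.freqs, 2 * n)
        pool = np.repeat(
            np.arange(len(haps)), [counts[h] for h in haps]
        )
        rng.shuffle(pool)
        hap1 = [haps[i] for i in pool[:n]]
        hap2 = [haps[i] for i in pool[n:]]
    else:  # sample
        probs = np.asarray([spec.freqs[h] for h in haps], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(haps), size=(n, 2), p=probs)
        hap1 = [haps[i] for i in draws[:, 0]]
        hap2 = [haps[i] for i in draws[:, 1]]

    samples = [f"{spec.population}{i:05d}" for i in range(n)]
    return PhasedPanel(
        samples=samples,
        populations=[spec.population] * n,
        hap1=hap1,
        hap2=hap2,
    )


def reference_panel_spec(
    population: str = "ALL",
    n_samples: int | None = None,
    catalog: AllotypeCatalog | None = None,
) -> PanelSpec:
    """Exact-count PanelSpec from the shipped catalog frequency column.

    Percentages that do not sum to 100 leave a remainder carried by an
    alphabet-valid, catalog-absent filler haplotype, so those
    chromosomes classify as unassigned.
    """
    catalog = catalog or load_catalog()
    percents = reference_frequencies()[population]
    if n_samples is None:
        n_samples = (
            2504 if population == "ALL" else POPULATION_SAMPLES[population]
        )
    freqs = {
        catalog.haplotype(label): pct / 100.0
        for label, pct in percents.items()
        if pct > 0
    }
    rest = 1.0 - sum(freqs.values())
    if rest > 1e-12:
        freqs[FILLER_HAPLOTYPE] = rest
    return PanelSpec(freqs=freqs, n_samples=n_samples, population=population)


def gen_reference_panel(
    population: str = "ALL", seed: int = 0, n_samples: int | None = None
) -> PhasedPanel:
    """Exact-count fixture panel for one shipped frequency column."""
    return gen_phased_panel(reference_panel_spec(population, n_samples), seed=seed)


def gen_coupled_erap_panels(
    joint: Mapping[tuple[tuple[str, str], tuple[str, str]], int],
    seed: int = 0,
    catalog: AllotypeCatalog | None = None,
) -> tuple[PhasedPanel, PhasedPanel]:
    """Paired ERAP1/ERAP2 panels with a prescribed joint diplotype table.

    ``joint`` maps ((erap1_a, erap1_b), (erap2_a, erap2_b)) allotype-label
    pairs to sample counts; ERAP2 labels are A/B.  Sample order is
    shuffled but identical across the two returned panels.
    """
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(seed)
    rows = []
    for (e1_pair, e2_pair), count in joint.items():
        h1 = tuple(catalog.haplotype(lab) for lab in e1_pair)
        h2 = tuple(ERAP2_LABEL_TO_HAP[lab] for lab in e2_pair)
        rows.extend([(h1, h2)] * count)
    rng.shuffle(rows)
    samples = [f"S{i:05d}" for i in range(len(rows))]
    pops = ["ALL"] * len(rows)
    erap1 = PhasedPanel(
        samples=samples,
        populations=pops,
        hap1=[r[0][0] for r in rows],
        hap2=[r[0][1] for r in rows],
    )
    erap2 = PhasedPanel(
        samples=samples,
        populations=pops,
        hap1=[r[1][0] for r in rows],
        hap2=[r[1][1] for r in rows],
    )
    return erap1, erap2


# ---------------------------------------------------------------------------
# Kinetic ground truths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMTruth:
    kcat: float  # 1/s
    km: float  # molar

    @property
    def efficiency(self) -> float:
        return self.kcat / self.km

    def rate(self, enzyme_conc: float, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.kcat * enzyme_conc * s / (self.km + s)


@dataclass(frozen=True)
class HillTruth:
    vmax: float  # molar/s
    k_half: float  # molar
    h: float

    def rate(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.vmax * s**self.h / (self.k_half**self.h + s**self.h)


#: 9mer (YTAFTIPSI) ground truths.  Allotypes 1-9 span ~2-fold in kcat
#: with allotypes 1 and 2 the tightest binders; allotype 10's kcat is
#: 10-fold below the 1-9 median and its kcat/KM is 60-fold below
#: allotype 2.  KM values stay within a 6-fold band.
NINEMER_TRUTHS: dict[str, MMTruth] = {
    "1": MMTruth(5.5, 32e-6),
    "2": MMTruth(6.0, 30e-6),
    "3": MMTruth(4.5, 60e-6),
    "4": MMTruth(4.0, 90e-6),
    "5": MMTruth(3.6, 110e-6),
    "6": MMTruth(4.2, 80e-6),
    "7": MMTruth(3.8, 120e-6),
    "8": MMTruth(4.8, 55e-6),
    "9": MMTruth(3.0, 150e-6),
    "10": MMTruth(0.42, 126e-6),
}

#: Leu-AMC catalytic efficiencies (1/(M s)).  Allotype 3 is the most
#: active and allotype 10 is 18-fold below it; 1-9 span ~2-fold.  The
#: rate stays linear in S well past the assayed 150 uM, represented by
#: a common large KM (1.5 mM) so the efficiency is the only live
#: parameter.
LEU_AMC_EFFICIENCIES: dict[str, float] = {
    "1": 7.0e4,
    "2": 8.0e4,
    "3": 9.0e4,
    "4": 5.0e4,
    "5": 5.5e4,
    "6": 6.0e4,
    "7": 4.8e4,
    "8": 6.5e4,
    "9": 4.6e4,
    "10": 5.0e3,
}

LEU_AMC_KM = 1.5e-3  # molar; keeps v linear in S up to 150 uM


def leu_amc_truth(allotype: str) -> MMTruth:
    eff = LEU_AMC_EFFICIENCIES[allotype]
    return MMTruth(kcat=eff * LEU_AMC_KM, km=LEU_AMC_KM)


#: Leu-pNA allosteric (Hill) truths for allotypes 1-9.  Allotype 10 is
#: deliberately absent: its hydrolysis is too slow for a reliable fit
#: and the pipeline must surface a flagged non-result instead.
LEU_PNA_TRUTHS: dict[str, HillTruth] = {
    "1": HillTruth(3.2e-7, 220e-6, 1.5),
    "2": HillTruth(3.6e-7, 200e-6, 1.5),
    "3": HillTruth(4.0e-7, 260e-6, 1.4),
    "4": HillTruth(2.2e-7, 300e-6, 1.6),
    "5": HillTruth(2.5e-7, 330e-6, 1.5),
    "6": HillTruth(2.8e-7, 280e-6, 1.5),
    "7": HillTruth(2.1e-7, 350e-6, 1.4),
    "8": HillTruth(3.0e-7, 240e-6, 1.5),
    "9": HillTruth(1.9e-7, 380e-6, 1.6),
}


def gen_rate_dataset(
    truth: MMTruth | HillTruth,
    s_grid: Sequence[float],
    enzyme_conc: float,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rate-vs-substrate dataset (columns ``s``, ``rate``) from a ground
    truth, with seeded multiplicative noise."""
    rng = np.random.default_rng(seed)
    s = np.asarray(s_grid, dtype=float)
    if isinstance(truth, MMTruth):
        v = truth.rate(enzyme_conc, s)
    else:
        v = truth.rate(s)
    v = v * _noise(rng, noise_cv, v.shape)
    return pd.DataFrame({"s": s, "rate": v})


def gen_assay_timecourses(
    truth: MMTruth | HillTruth,
    s_grid: Sequence[float],
    times: Sequence[float],
    enzyme_conc: float,
    noise_cv: float = 0.0,
    seed: int | None = None,
    substrate: str = "",
    curve: StandardCurve | None = None,
) -> KineticDataset:
    """Product-formation time courses over a substrate grid.

    Progress curves come from integrating dP/dt = v(S0 - P).  When a
    :class:`StandardCurve` is supplied an extra ``signal`` column
    re-encodes the product concentration as raw instrument signal.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    rows = []
    for s0 in np.asarray(s_grid, dtype=float):

        def dpdt(_t, p):
            s = max(s0 - p[0], 0.0)
            if isinstance(truth, MMTruth):
                return [truth.rate(enzyme_conc, s)]
            return [truth.rate(s)]

        sol = solve_ivp(
            dpdt,
            (0.0, float(times.max())),
            [0.0],
            t_eval=times,
            method="LSODA",
            rtol=1e-9,
            atol=1e-12 * max(s0, 1e-9),
        )
        product = np.clip(sol.y[0], 0.0, None)
        product = product * _noise(rng, noise_cv, product.shape)
        for t, p in zip(times, product):
            row = {"s0": s0, "time": t, "product": p}
            if curve is not None:
                row["signal"] = float(curve.apply(p))
            rows.append(row)
    return KineticDataset(
        substrate=substrate, enzyme_conc=enzyme_conc, data=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# Trimming cascades
# ---------------------------------------------------------------------------

@dataclass
class CascadeSpec:
    """Ground truth for one sequential digestion.

    One (kcat, KM) pair per trimming step; the terminal species is not
    consumed.  Defaults mirror the ovalbumin-precursor design: 25 uM
    14mer, 10 nM enzyme, two-hour time course.
    """

    species: tuple[str, ...] = OVALBUMIN_SPECIES
    kcats: tuple[float, ...] = (1.5, 0.8, 0.4, 0.9, 1.2, 2.0)  # 1/s
    kms: tuple[float, ...] = (100e-6,) * 6  # molar
    enzyme_conc: float = 10e-9
    s0: float = 25e-6
    times: tuple[float, ...] = tuple(np.linspace(0.0, 7200.0, 13))
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kcats) != len(self.species) - 1:
            raise ValueError("need one kcat per step (species - 1)")
        if len(self.kms) != len(self.kcats):
            raise ValueError("kcats and kms must have equal length")
        if any(k <= 0 for k in (*self.kcats, *self.kms)):
            raise ValueError("rates must be positive")

    @property
    def efficiencies(self) -> np.ndarray:
        return np.asarray(self.kcats) / np.asarray(self.kms)


def simulate_cascade(spec: CascadeSpec, seed: int | None = None) -> TrimmingSeries:
    """Integrate the competitive-cascade ground truth, with optional
    seeded multiplicative noise.  Noiseless output conserves total
    peptide exactly (one product per cleavage, terminal not consumed)."""
    conc = integrate_cascade(
        spec.kcats, spec.kms, spec.enzyme_conc, spec.s0, spec.times
    )
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        conc = conc * _noise(rng, spec.noise_cv, conc.shape)
    return TrimmingSeries(
        species=spec.species,
        times=np.asarray(spec.times),
        conc=conc,
        enzyme_conc=spec.enzyme_conc,
    )


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourPLTruth:
    """4PL ground truth; ``r0`` is the zero-dose response (% activity)
    and ``r_inf`` the saturating-dose response."""

    r0: float
    r_inf: float
    pxc50: float
    slope: float = 1.0

    def response(self, dose) -> np.ndarray:
        x = np.asarray(dose, dtype=float)
        xc50 = 10.0 ** (-self.pxc50)
        return self.r_inf + (self.r0 - self.r_inf) / (
            1.0 + (x / xc50) ** self.slope
        )


#: Active-site inhibitor: potent, narrow pIC50 band across allotypes.
DG013A_TRUTHS: dict[str, FourPLTruth] = {
    "1": FourPLTruth(100.0, 0.0, 7.4),
    "2": FourPLTruth(100.0, 0.0, 7.5),
    "3": FourPLTruth(100.0, 0.0, 7.6),
    "4": FourPLTruth(100.0, 0.0, 7.3),
    "5": FourPLTruth(100.0, 0.0, 7.2),
    "6": FourPLTruth(100.0, 0.0, 7.4),
    "7": FourPLTruth(100.0, 0.0, 7.3),
    "8": FourPLTruth(100.0, 0.0, 7.5),
    "9": FourPLTruth(100.0, 0.0, 7.2),
    "10": FourPLTruth(100.0, 0.0, 7.2),
}

#: Regulatory-site binder on the dipeptide substrate: an apparent
#: activator whose potency (pXC50) spans 4.8-6.5 and whose maximal
#: enhancement grows with potency (the Fig-4F-style coupling).
_GSK849_PXC50 = {
    "1": 6.5, "2": 6.4, "3": 6.2, "4": 5.8, "5": 5.6,
    "6": 5.9, "7": 5.4, "8": 6.0, "9": 5.2, "10": 4.8,
}
GSK849_LEU_AMC_TRUTHS: dict[str, FourPLTruth] = {
    lab: FourPLTruth(100.0, 100.0 + 25.0 * (p - 4.5), p)
    for lab, p in _GSK849_PXC50.items()
}

#: The same compound inhibits 9mer hydrolysis; potency tracks allotype
#: activity (most potent against the most active allotypes).
GSK849_NINEMER_TRUTHS: dict[str, FourPLTruth] = {
    lab: FourPLTruth(100.0, 0.0, 5.0 + 1.5 * eff / 9.0e4)
    for lab, eff in LEU_AMC_EFFICIENCIES.items()
}


@dataclass
class SynthTitration:
    """Raw titration wells plus high/low controls for one curve."""

    compound: str
    allotype: str
    doses: np.ndarray
    raw: np.ndarray
    high_wells: np.ndarray  # uninhibited controls
    low_wells: np.ndarray  # fully inhibited controls


def gen_titration(
    truths: Mapping[str, FourPLTruth],
    doses: Sequence[float],
    compound: str,
    noise_cv: float = 0.0,
    seed: int | None = None,
    *,
    raw_low: float = 2000.0,
    raw_span: float = 50000.0,
    n_control_wells: int = 8,
) -> dict[str, SynthTitration]:
    """Titration curves on an arbitrary raw-signal scale.

    Raw signal is affine in percent activity, so
    :func:`~eraptype.inhibition.normalize_activity` against the control
    wells recovers the ground-truth responses.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    out = {}
    for allotype, truth in truths.items():
        pct = truth.response(doses)
        raw = (raw_low + raw_span * pct / 100.0) * _noise(
            rng, noise_cv, pct.shape
        )
        high = (raw_low + raw_span) * _noise(rng, noise_cv, n_control_wells)
        low = raw_low * _noise(rng, noise_cv, n_control_wells)
        out[allotype] = SynthTitration(
            compound=compound,
            allotype=allotype,
            doses=doses,
            raw=raw,
            high_wells=high,
            low_wells=low,
        )
    return out


#: Threefold dilution series spanning the titration transitions, molar.
DEFAULT_DOSES = tuple(1e-4 / 3.0**i for i in range(10))
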