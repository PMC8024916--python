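"""Enzyme-kinetic analysis of aminopeptidase assays.

Raw plate-reader or MS signals are converted to product concentration
through linear standard curves; initial rates are taken from the early,
linear region of each time course (by default the window where no more
than 10% of the substrate has been consumed); and rate-versus-substrate
data are summarised either by the Michaelis–Menten model

    v = kcat * E * S / (KM + S),

by the allosteric (Hill) variant

    v = Vmax * S**h / (K_half**h + S**h),

or — for substrates assayed only well below KM — by the slope of the
linear regime, which estimates the catalytic efficiency kcat/KM
directly.  Units are molar and seconds throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Standard curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Linear signal-vs-concentration calibration for one analyte."""

    analyte: str
    slope: float  # signal per molar
    intercept: float  # signal at zero concentration
    residual_sd: float = 0.0

    def apply(self, conc):
        """Concentration -> expected signal."""
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def invert(self, signal):
        """Signal -> concentration."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


def fit_standard_curve(
    conc: Sequence[float], signal: Sequence[float], analyte: str = ""
) -> StandardCurve:
    """Least-squares line through calibration points.

    Requires at least two distinct concentrations and a positive slope
    (signal must increase with analyte amount).
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("standard curve needs >=2 distinct concentrations")
    slope, intercept = np.polyfit(conc, signal, 1)
    if slope <= 0:
        raise ValueError(f"standard curve slope {slope} is not positive")
    resid = signal - (slope * conc + intercept)
    dof = max(len(conc) - 2, 1)
    return StandardCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


# ---------------------------------------------------------------------------
# Datasets and rates
# ---------------------------------------------------------------------------

@dataclass
class KineticDataset:
    """Replicated product-formation time courses over a substrate grid.

    ``data`` columns: ``s0`` (initial substrate, M), ``time`` (s) and
    ``product`` (M); an optional ``replicate`` column separates repeats.
    """

    substrate: str
    enzyme_conc: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")
        missing = {"s0", "time", "product"} - set(self.data.columns)
        if missing:
            raise ValueError(f"kinetic data missing columns: {sorted(missing)}")

    def rates(self, max_fraction: float = 0.10) -> pd.DataFrame:
        """Initial rate per substrate level (columns s, rate, specific_activity)."""
        keys = ["s0"] + (["replicate"] if "replicate" in self.data.columns else [])
        rows = []
        for key, grp in self.data.groupby(keys):
            s0 = key[0] if isinstance(key, tuple) else key
            est = initial_rate(
                grp["time"].to_numpy(),
                grp["product"].to_numpy(),
                s0=s0,
                max_fraction=max_fraction,
            )
            rows.append(
                {
                    "s": s0,
                    "rate": est.rate,
                    "specific_activity": specific_activity(
                        est.rate, self.enzyme_conc
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class InitialRate:
    rate: float  # molar / s
    intercept: float
    n_points: int
    t_max: float  # last time point inside the linear window


def initial_rate(
    times: Sequence[float],
    product: Sequence[float],
    *,
    s0: float | None = None,
    max_fraction: float = 0.10,
    min_points: int = 4,
) -> InitialRate:
    """Slope of the early, linear region of a product time course.

    When ``s0`` is given, the fit is restricted to points where
    accumulated product does not exceed ``max_fraction`` of the initial
    substrate, keeping the constant-substrate assumption explicit.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(product, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    if s0 is not None:
        mask = p <= max_fraction * s0
    else:
        mask = np.ones_like(t, dtype=bool)
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} points within the {max_fraction:.0%} "
            f"turnover window (need {min_points})"
        )
    slope, intercept = np.polyfit(t[mask], p[mask], 1)
    return InitialRate(
        rate=float(slope),
        intercept=float(intercept),
        n_points=int(mask.sum()),
        t_max=float(t[mask].max()),
    )


def specific_activity(rate: float, enzyme_conc: float) -> float:
    """Rate normalised to enzyme concentration (units 1/s)."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    return rate / enzyme_conc


# ---------------------------------------------------------------------------
# Linear-regime efficiency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearEfficiency:
    """kcat/KM from the low-substrate linear regime (v/E = (kcat/KM) * S)."""

    efficiency: float  # 1 / (M s)
    se: float
    r_squared: float
    nonlinear: bool


def efficiency_from_linear_regime(
    s: Sequence[float],
    v_over_e: Sequence[float],
    *,
    r2_threshold: float = 0.98,
    through_origin: bool = True,
    strict: bool = False,
) -> LinearEfficiency:
    """Estimate kcat/KM as the slope of specific activity vs substrate.

    Valid only while the rate stays proportional to S (S well below KM);
    curvature is detected as R² below ``r2_threshold`` and either flagged
    or, in strict mode, raised.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v_over_e, dtype=float)
    if len(s) < 3:
        raise ValueError("need >=3 substrate levels")
    if through_origin:
        slope = float(s @ v / (s @ s))
        fitted = slope * s
        dof = max(len(s) - 1, 1)
        resid = v - fitted
        se = float(np.sqrt((resid @ resid / dof) / (s @ s)))
    else:
        (slope, intercept), cov = np.polyfit(s, v, 1, cov=True)
        fitted = slope * s + intercept
        resid = v - fitted
        se = float(np.sqrt(cov[0, 0]))
        slope = float(slope)
    tss = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    nonlinear = r2 < r2_threshold
    if nonlinear and strict:
        raise ValueError(
            f"rate vs substrate is nonlinear (R²={r2:.4f} < {r2_threshold})"
        )
    if nonlinear:
        logger.warning("linear-regime fit flagged nonlinear (R²=%.4f)", r2)
    return LinearEfficiency(efficiency=slope, se=se, r_squared=r2, nonlinear=nonlinear)


# ---------------------------------------------------------------------------
# Michaelis-Menten and Hill fits
# ---------------------------------------------------------------------------

def _aic(rss: float, n: int, n_params: int) -> float:
    # Gaussian log-likelihood AIC; +1 for the residual variance.
    return n * np.log(rss / n) + 2 * (n_params + 1)


@dataclass(frozen=True)
class MMFitResult:
    kcat: float  # 1/s
    km: float  # molar
    kcat_se: float
    km_se: float
    efficiency: float  # kcat/KM, 1/(M s)
    efficiency_se: float
    converged: bool
    aic: float
    rss: float
    n: int


@dataclass(frozen=True)
class AllostericFitResult:
    vmax: float  # molar/s
    k_half: float  # molar
    h: float
    vmax_se: float
    k_half_se: float
    h_se: float
    converged: bool
    aic: float
    rss: float
    n: int
    kcat: float = float("nan")  # vmax / E when enzyme concentration known


def fit_mm(
    s: Sequence[float], v: Sequence[float], enzyme_conc: float
) -> MMFitResult:
    """Nonlinear least-squares Michaelis–Menten fit of rate vs substrate.

    Non-convergence yields a flagged (``converged=False``) result with
    NaN parameters rather than an exception.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(s) < 5:
        raise ValueError("need >=5 substrate levels for a Michaelis-Menten fit")
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")

    # fit in nondimensional units (rates are O(1e-9) M/s, KM O(1e-5) M;
    # raw scales stall the optimiser)
    s_ref = float(np.median(s))
    v_ref = float(np.max(np.abs(v)))

    def model(x, a, b):  # a = kcat*E/v_ref, b = km/s_ref
        return a * x / (b + x)

    try:
        popt, pcov = curve_fit(
            model, s / s_ref, v / v_ref, p0=(1.0, 1.0),
            bounds=(0, np.inf), maxfev=20000,
        )
    except RuntimeError:
        nan = float("nan")
        return MMFitResult(nan, nan, nan, nan, nan, nan, False, nan, nan, len(s))
    jac = np.diag([v_ref / enzyme_conc, s_ref])  # back to physical units
    pcov = jac @ pcov @ jac
    kcat = popt[0] * v_ref / enzyme_conc
    km = popt[1] * s_ref
    resid = v - v_ref * model(s / s_ref, *popt)
    rss = float(resid @ resid)
    kcat_se, km_se = np.sqrt(np.diag(pcov))
    eff = kcat / km
    # delta method for kcat/KM, including the kcat-KM covariance
    grad = np.array([1.0 / km, -kcat / km**2])
    eff_var = float(grad @ pcov @ grad)
    return MMFitResult(
        kcat=float(kcat),
        km=float(km),
        kcat_se=float(kcat_se),
        km_se=float(km_se),
        efficiency=float(eff),
        efficiency_se=float(np.sqrt(max(eff_var, 0.0))),
        converged=True,
        aic=float(_aic(rss, len(s), 2)),
        rss=rss,
        n=len(s),
    )


def fit_hill(
    s: Sequence[float],
    v: Sequence[float],
    enzyme_conc: float | None = None,
    *,
    fix_h: float | None = None,
) -> AllostericFitResult:
    """Allosteric (Hill) fit v = Vmax * S^h / (K_half^h + S^h).

    With ``fix_h=1`` the model reduces exactly to Michaelis–Menten and
    the fit matches :func:`fit_mm` on the same data.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    min_levels = 5 if fix_h is not None else 6
    if len(s) < min_levels:
        raise ValueError(f"need >={min_levels} substrate levels for a Hill fit")

    s_ref = float(np.median(s))
    v_ref = float(np.max(np.abs(v)))

    if fix_h is None:

        def model(x, a, b, h):  # a = vmax/v_ref, b = k_half/s_ref
            return a * x**h / (b**h + x**h)

        p0 = (1.0, 1.0, 1.0)
        n_params = 3
    else:

        def model(x, a, b):
            return a * x**fix_h / (b**fix_h + x**fix_h)

        p0 = (1.0, 1.0)
        n_params = 2

    try:
        popt, pcov = curve_fit(
            model, s / s_ref, v / v_ref, p0=p0, bounds=(0, np.inf), maxfev=20000
        )
    except RuntimeError:
        nan = float("nan")
        return AllostericFitResult(
            nan, nan, nan, nan, nan, nan, False, nan, nan, len(s)
        )
    scale = np.array([v_ref, s_ref, 1.0][: len(popt)])
    ses = np.sqrt(np.diag(pcov)) * scale
    if fix_h is None:
        vmax, k_half, h = popt * scale
        vmax_se, k_half_se, h_se = ses
    else:
        vmax, k_half = popt * scale
        h = float(fix_h)
        vmax_se, k_half_se = ses
        h_se = 0.0
    resid = v - v_ref * model(s / s_ref, *popt)
    rss = float(resid @ resid)
    return AllostericFitResult(
        vmax=float(vmax),
        k_half=float(k_half),
        h=float(h),
        vmax_se=float(vmax_se),
        k_half_se=float(k_half_se),
        h_se=float(h_se),
        converged=True,
        aic=float(_aic(rss, len(s), n_params)),
        rss=rss,
        n=len(s),
        kcat=float(vmax / enzyme_conc) if enzyme_conc else float("nan"),
    )


@dataclass(frozen=True)
class ModelSelection:
    chosen: str  # "mm" or "hill"
    delta_aic: float  # AIC(mm) - AIC(hill); positive favours Hill
    table: pd.DataFrame


def model_select(
    mm: MMFitResult, hill: AllostericFitResult, *, parsimony_delta: float = 2.0
) -> ModelSelection:
    """Choose between MM and Hill by AIC.

    The extra Hill parameter must buy more than ``parsimony_delta`` AIC
    units, otherwise the simpler Michaelis–Menten model is kept.
    """
    delta = mm.aic - hill.aic
    chosen = "hill" if (hill.converged and delta > parsimony_delta) else "mm"
    table = pd.DataFrame(
        {
            "model": ["mm", "hill"],
            "aic": [mm.aic, hill.aic],
            "rss": [mm.rss, hill.rss],
            "n_params": [2, 3],
        }
    )
    return ModelSelection(chosen=chosen, delta_aic=float(delta), table=table)


# ---------------------------------------------------------------------------
# Activity profiles and fold ratios
# ---------------------------------------------------------------------------

@dataclass
class ActivityProfile:
    """Per-allotype, per-substrate activity values (specific activity in
    1/s or catalytic efficiency in 1/(M s)) with uncertainties.

    Missing entries (e.g. an allotype too slow to fit on a substrate) are
    simply absent or NaN — never extrapolated.
    """

    table: pd.DataFrame  # columns: allotype, substrate, value, se

    def __post_init__(self) -> None:
        missing = {"allotype", "substrate", "value"} - set(self.table.columns)
        if missing:
            raise ValueError(f"profile missing columns: {sorted(missing)}")
        if "se" not in self.table.columns:
            self.table = self.table.assign(se=np.nan)

    def values_for(self, substrate: str) -> pd.Series:
        sub = self.table[self.table["substrate"] == substrate]
        return sub.set_index("allotype")["value"].dropna()

    def get(self, allotype: str, substrate: str) -> float:
        series = self.values_for(substrate)
        if allotype not in series.index:
            raise KeyError(
                f"no activity for allotype {allotype!r} on substrate {substrate!r}"
            )
        return float(series.loc[allotype])


@dataclass(frozen=True)
class FoldRatios:
    matrix: pd.DataFrame  # ratio[i, j] = value_i / value_j
    spread: float  # max / min
    excluded: tuple[str, ...]


def fold_ratios(profile: ActivityProfile, substrate: str) -> FoldRatios:
    """Pairwise activity ratios between allotypes for one substrate."""
    values = profile.values_for(substrate)
    all_labels = profile.table.loc[
        profile.table["substrate"] == substrate, "allotype"
    ]
    excluded = tuple(sorted(set(all_labels) - set(values.index)))
    if excluded:
        logger.info(
            "fold_ratios(%s): excluding allotypes without values: %s",
            substrate,
            excluded,
        )
    if len(values) < 2:
        raise ValueError("need >=2 allotypes with values")
    matrix = pd.DataFrame(
        np.outer(values.to_numpy(), 1.0 / values.to_numpy()),
        index=values.index,
        columns=values.index,
    )
    return FoldRatios(
        matrix=matrix,
        spread=float(values.max() / values.min()),
        excluded=excluded,
    )
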