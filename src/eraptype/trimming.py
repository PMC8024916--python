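"""Sequential peptide-trimming analysis.

An aminopeptidase shortens a precursor peptide one N-terminal residue at
a time, so a digestion of a 14mer produces a ladder of co-present
intermediates down to a terminal product that the enzyme no longer
consumes.  This module quantifies such time courses from
internal-standard-normalised MS signals, computes the descriptive
intermediate-accumulation statistics (fraction-of-total trajectories and
per-species maxima), and — as a model-based extension — fits a
shared-enzyme competitive Michaelis–Menten cascade to recover per-step
catalytic efficiencies.

In the cascade model every species still carrying a scissile N-terminus
competes for the same enzyme:

    v_i = kcat_i * E * (S_i / KM_i) / (1 + sum_j S_j / KM_j)

and d[S_i]/dt = v_{i-1} - v_i, with the terminal species only produced.
Total peptide is conserved because each cleavage converts one peptide
into exactly one shorter peptide (free amino acids are not tracked).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .kinetics import StandardCurve

logger = logging.getLogger(__name__)

#: The seven ovalbumin-epitope species, 14mer precursor down to the
#: mature 8mer SIINFEKL.
OVALBUMIN_SPECIES = (
    "GLEQLESIINFEKL",
    "LEQLESIINFEKL",
    "EQLESIINFEKL",
    "QLESIINFEKL",
    "LESIINFEKL",
    "ESIINFEKL",
    "SIINFEKL",
)


@dataclass
class TrimmingSeries:
    """Concentration of each species over time for one digestion.

    ``conc`` has shape (n_times, n_species); species are ordered longest
    first.  Enzyme concentration is carried explicitly because slow
    variants are assayed at higher enzyme (summaries normalise per
    enzyme).
    """

    species: tuple[str, ...]
    times: np.ndarray  # seconds
    conc: np.ndarray  # molar
    enzyme_conc: float
    replicate: str = "1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.conc.shape != (len(self.times), len(self.species)):
            raise ValueError(
                f"conc shape {self.conc.shape} does not match "
                f"({len(self.times)}, {len(self.species)})"
            )
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")

    def totals(self) -> np.ndarray:
        return self.conc.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.conc, columns=list(self.species))
        frame.insert(0, "time", self.times)
        return frame


# ---------------------------------------------------------------------------
# Quantification from raw MS signals
# ---------------------------------------------------------------------------

def quantify_species(
    signals: pd.DataFrame,
    is_signal: Sequence[float],
    curves: Mapping[str, StandardCurve],
    enzyme_conc: float,
    replicate: str = "1",
) -> TrimmingSeries:
    """Convert per-species MS signals to concentrations.

    Each species signal is divided by the co-measured internal-standard
    signal, then inverted through that species' calibration curve.
    ``signals`` is a time-indexed frame with one column per species.
    """
    times = signals.index.to_numpy(dtype=float)
    is_signal = np.asarray(is_signal, dtype=float)
    bad = np.nonzero(is_signal <= 0)[0]
    if bad.size:
        raise ValueError(
            f"internal-standard signal <= 0 at time point t={times[bad[0]]}"
        )
    conc = np.column_stack(
        [
            curves[sp].invert(signals[sp].to_numpy(dtype=float) / is_signal)
            for sp in signals.columns
        ]
    )
    return TrimmingSeries(
        species=tuple(signals.columns),
        times=times,
        conc=conc,
        enzyme_conc=enzyme_conc,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class AccumulationSummary:
    """Fraction-of-total trajectories and per-species maxima."""

    fractions: pd.DataFrame  # time x species, rows sum to 1
    maxima: pd.DataFrame  # species x [max_conc, time_of_max_conc, ...]


def fraction_of_total(series: TrimmingSeries) -> pd.DataFrame:
    """Per-time-point fraction of the total peptide pool per species."""
    totals = series.totals()
    zero = np.nonzero(totals <= 0)[0]
    if zero.size:
        raise ValueError(f"total peptide is zero at t={series.times[zero[0]]}")
    frame = pd.DataFrame(
        series.conc / totals[:, None],
        index=pd.Index(series.times, name="time"),
        columns=list(series.species),
    )
    return frame


def max_accumulation(series: TrimmingSeries) -> pd.DataFrame:
    """Maximal accumulation of each species over the sampled time grid.

    Reported both in concentration and as fraction-of-total, each with
    the time at which the sampled maximum occurs (no interpolation).
    """
    if len(series.times) < 2:
        raise ValueError("need >=2 time points")
    fractions = fraction_of_total(series).to_numpy()
    i_conc = series.conc.argmax(axis=0)
    i_frac = fractions.argmax(axis=0)
    idx = np.arange(len(series.species))
    return pd.DataFrame(
        {
            "max_conc": series.conc[i_conc, idx],
            "time_of_max_conc": series.times[i_conc],
            "max_fraction": fractions[i_frac, idx],
            "time_of_max_fraction": series.times[i_frac],
        },
        index=pd.Index(series.species, name="species"),
    )


def summarize(series: TrimmingSeries) -> AccumulationSummary:
    return AccumulationSummary(
        fractions=fraction_of_total(series), maxima=max_accumulation(series)
    )


def lowess_smooth(
    t: Sequence[float], y: Sequence[float], span: float = 0.5
) -> np.ndarray:
    """Tricube-weighted local linear (LOWESS) smoother, evaluated at the
    input abscissae.  Display aid only — it never feeds statistics."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise ValueError("need >=5 points to smooth")
    return _sm_lowess(y, t, frac=span, it=0, return_sorted=False)


# ---------------------------------------------------------------------------
# Cascade model
# ---------------------------------------------------------------------------

def integrate_cascade(
    kcats: Sequence[float],
    kms: Sequence[float],
    enzyme_conc: float,
    s0: float,
    times: Sequence[float],
    *,
    rtol: float = 1e-9,
) -> np.ndarray:
    """Integrate the shared-enzyme competitive MM cascade.

    ``kcats``/``kms`` have one entry per trimming step (species count
    minus one); the precursor starts at ``s0`` and the terminal species
    is not consumed.  Returns concentrations with shape
    (len(times), n_steps + 1).
    """
    kcats = np.asarray(kcats, dtype=float)
    kms = np.asarray(kms, dtype=float)
    if kcats.shape != kms.shape:
        raise ValueError("kcats and kms must have equal length")
    if np.any(kcats <= 0) or np.any(kms <= 0):
        raise ValueError("rate parameters must be positive")
    n_steps = len(kcats)
    times = np.asarray(times, dtype=float)

    def rhs(_t, y):
        s = np.clip(y[:n_steps], 0.0, None)
        denom = 1.0 + np.sum(s / kms)
        v = kcats * enzyme_conc * (s / kms) / denom
        dy = np.empty_like(y)
        dy[0] = -v[0]
        dy[1:n_steps] = v[:-1] - v[1:]
        dy[n_steps] = v[-1]
        return dy

    y0 = np.zeros(n_steps + 1)
    y0[0] = s0
    t_end = float(times.max())
    sol = solve_ivp(
        rhs,
        (0.0, t_end if t_end > 0 else 1.0),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=rtol * s0,
    )
    if not sol.success:
        raise RuntimeError(f"cascade integration failed: {sol.message}")
    return np.clip(sol.y.T, 0.0, None)


@dataclass(frozen=True)
class CascadeFit:
    """Per-step parameters recovered from a trimming series."""

    efficiencies: np.ndarray  # kcat_i / KM_i, 1/(M s)
    efficiency_se: np.ndarray
    kcats: np.ndarray
    kms: np.ndarray
    converged: bool


def recover_cascade_rates(
    series: TrimmingSeries,
    *,
    kcat_init: Sequence[float] | None = None,
    km_init: Sequence[float] | None = None,
) -> CascadeFit:
    """Jointly fit the competitive-cascade model to all species.

    Parameters are fitted on a log scale for positivity and
    conditioning.  The per-step catalytic efficiency kcat/KM is the
    well-determined combination when the digestion runs below
    saturation, so efficiencies (with delta-method standard errors) are
    the primary output; individual kcat and KM values are returned but
    may be strongly correlated.
    """
    n_steps = len(series.species) - 1
    if n_steps < 1:
        raise ValueError("need at least two species")
    s0 = float(series.conc[0].sum())
    e = series.enzyme_conc

    if kcat_init is None or km_init is None:
        # crude first-order guess from the precursor decay
        c0 = series.conc[0, 0]
        later = series.conc[:, 0] / max(c0, 1e-30)
        positive = np.nonzero((later > 0.01) & (later < 1.0))[0]
        if positive.size:
            i = positive[-1]
            lam = -np.log(later[i]) / series.times[i]
        else:
            lam = 1.0 / series.times[-1]
        km_guess = 4.0 * s0
        kcat_guess = (lam / e) * km_guess
        kcat_init = np.full(n_steps, kcat_guess)
        km_init = np.full(n_steps, km_guess)

    theta0 = np.log(np.concatenate([kcat_init, km_init]))

    def residuals(theta):
        kcats = np.exp(theta[:n_steps])
        kms = np.exp(theta[n_steps:])
        model = integrate_cascade(
            kcats, kms, e, s0, series.times, rtol=1e-8
        )
        return ((model - series.conc) / s0).ravel()

    fit = least_squares(residuals, theta0, method="trf", x_scale="jac")
    converged = bool(fit.success)
    if not converged:
        logger.warning("cascade fit did not converge: %s", fit.message)
    kcats = np.exp(fit.x[:n_steps])
    kms = np.exp(fit.x[n_steps:])
    effs = kcats / kms

    # covariance of the log-parameters from the Gauss-Newton approximation
    m, p = fit.jac.shape
    dof = max(m - p, 1)
    sigma2 = 2.0 * fit.cost / dof
    try:
        cov = sigma2 * np.linalg.pinv(fit.jac.T @ fit.jac)
        # log eff_i = log kcat_i - log KM_i
        grad = np.zeros((n_steps, 2 * n_steps))
        grad[np.arange(n_steps), np.arange(n_steps)] = 1.0
        grad[np.arange(n_steps), n_steps + np.arange(n_steps)] = -1.0
        log_eff_var = np.einsum("ij,jk,ik->i", grad, cov, grad)
        eff_se = effs * np.sqrt(np.clip(log_eff_var, 0.0, None))
    except np.linalg.LinAlgError:
        eff_se = np.full(n_steps, np.nan)
    return CascadeFit(
        efficiencies=effs,
        efficiency_se=eff_se,
        kcats=kcats,
        kms=kms,
        converged=converged,
    )
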