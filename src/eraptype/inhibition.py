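"""Inhibitor/activator titration analysis.

Raw MS readouts of a trimming assay are first converted to percent
turnover (product over product-plus-substrate, after correcting the two
analytes' detection sensitivities), then normalised to percent activity
between uninhibited (high) and fully inhibited (low) control wells, and
finally fitted to a four-parameter logistic (4PL) dose-response:

    r(x) = bottom + (top - bottom) / (1 + (x / XC50)^slope)

The midpoint is reported as pXC50 = -log10(XC50 in molar); for
inhibition curves the field's term pIC50 applies.  Activation curves
(responses above 100%, as seen with regulatory-site binders on small
substrates) use the identical machinery and carry a direction tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .kinetics import StandardCurve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Signal processing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Turnover:
    percent: float
    flagged: bool  # above the QC bound (default 35%)


def percent_turnover(
    sub_signal: float,
    prod_signal: float,
    sub_curve: StandardCurve,
    prod_curve: StandardCurve,
    *,
    flag_above: float = 35.0,
) -> Turnover:
    """Percent substrate turnover from substrate and product signals.

    Calibration curves correct for the detection-sensitivity difference
    between the two analytes; turnover = 100 * [P] / ([P] + [S]).
    Values above ``flag_above`` are flagged (initial-rate conditions are
    doubtful) but not excluded.
    """
    if sub_signal < 0 or prod_signal < 0:
        raise ValueError("signals must be non-negative")
    conc_s = float(sub_curve.invert(sub_signal))
    conc_p = float(prod_curve.invert(prod_signal))
    total = conc_p + conc_s
    if total <= 0:
        raise ValueError("substrate and product concentrations are both zero")
    pct = 100.0 * conc_p / total
    return Turnover(percent=pct, flagged=pct > flag_above)


def normalize_activity(raw, high_ctrl: float, low_ctrl: float):
    """Percent enzymatic activity between high (uninhibited) and low
    (fully inhibited) controls.  May exceed 100 for activators."""
    if high_ctrl == low_ctrl:
        raise ValueError("high and low controls are equal")
    return 100.0 * (np.asarray(raw, dtype=float) - low_ctrl) / (high_ctrl - low_ctrl)


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

@dataclass
class TitrationCurve:
    """One compound-vs-enzyme titration (doses in molar)."""

    compound: str
    allotype: str
    doses: np.ndarray
    responses: np.ndarray  # normalised % activity

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class FourPLFit:
    top: float  # larger asymptote (% activity); > 100 for activators
    bottom: float  # smaller asymptote
    pxc50: float  # -log10 XC50 (M)
    slope: float  # Hill slope (>0 after normalisation)
    top_se: float
    bottom_se: float
    pxc50_se: float
    slope_se: float
    converged: bool
    direction: str  # "inhibition" | "activation"
    in_range: bool  # XC50 inside the tested dose range


def _4pl_log(logx, top, bottom, log_xc50, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logx - log_xc50)))


def fit_4pl(curve: TitrationCurve) -> FourPLFit:
    """Four-parameter logistic fit on log10 dose.

    The fit is parameterised by the zero-dose and saturating-dose
    asymptotes (a negative fitted slope is the mirrored solution and is
    normalised away).  Direction is ``inhibition`` when the response
    falls with dose, ``activation`` when it rises; ``top``/``bottom``
    are then the larger/smaller asymptote.
    """
    if len(curve.doses) < 6:
        raise ValueError("need >=6 doses spanning the transition")
    logx = np.log10(curve.doses)
    r = curve.responses
    order = np.argsort(logx)
    p0 = (float(r[order[0]]), float(r[order[-1]]), float(np.median(logx)), 1.0)
    try:
        popt, pcov = curve_fit(_4pl_log, logx, r, p0=p0, maxfev=20000)
    except RuntimeError:
        nan = float("nan")
        return FourPLFit(
            nan, nan, nan, nan, nan, nan, nan, nan, False, "unknown", False
        )
    ses = np.sqrt(np.diag(pcov))
    r0, r_inf, log_xc50, slope = popt
    r0_se, r_inf_se, log_xc50_se, slope_se = ses
    if slope < 0:  # mirrored solution: swap asymptotes
        r0, r_inf = r_inf, r0
        r0_se, r_inf_se = r_inf_se, r0_se
        slope = -slope
    direction = "inhibition" if r_inf < r0 else "activation"
    if r0 >= r_inf:
        top, bottom, top_se, bottom_se = r0, r_inf, r0_se, r_inf_se
    else:
        top, bottom, top_se, bottom_se = r_inf, r0, r_inf_se, r0_se
    in_range = bool(logx.min() <= log_xc50 <= logx.max())
    if not in_range:
        logger.warning(
            "%s/%s: fitted XC50 outside the tested dose range",
            curve.compound,
            curve.allotype,
        )
    return FourPLFit(
        top=float(top),
        bottom=float(bottom),
        pxc50=float(-log_xc50),
        slope=float(slope),
        top_se=float(top_se),
        bottom_se=float(bottom_se),
        pxc50_se=float(log_xc50_se),
        slope_se=float(slope_se),
        converged=True,
        direction=direction,
        in_range=in_range,
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Correlation:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> Correlation:
    """Pearson (and, because the choice is not always obvious for small
    allotype panels, Spearman) correlation with two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >=3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return Correlation(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n=len(x),
    )
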