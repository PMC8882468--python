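"""Sigmoidal (Hill) dose-response fitting with a flat-fit fallback.

The fitted model on either response scale is

    f(c) = plateau + (top - plateau) / (1 + (c / midpoint)^hill)

with ``top`` fixed at the untreated response (1 on the GR scale, 100 on
percent scales), so the curve starts at the untreated level at dose 0 and
decays to ``plateau`` (GR_inf or RV_inf) at high dose. A sigmoid is only
accepted over a constant fit if an F-test on the residual sums of squares
rejects the flat model; non-responders therefore come out ``flat``, which
is what makes threshold metrics like GR50 legitimately missing for them.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

#: Default parameter bounds; hill and midpoint bounds guard against
#: degenerate fits on 8-point ranges.
HILL_BOUNDS = (0.1, 5.0)
PLATEAU_BOUNDS = {"GR": (-1.0, 1.0), "RV": (-200.0, 100.0), "TC": (0.0, 100.0)}
TOP = {"GR": 1.0, "RV": 100.0, "TC": 100.0}


@dataclasses.dataclass
class CurveFit:
    """Result of fitting one dose-response curve.

    ``scale`` is ``GR`` (growth-rate inhibition), ``RV`` (relative growth,
    percent) or ``TC`` (endpoint viability T/C, percent). For
    ``fit_type == "flat"`` the sigmoid parameters are None and
    ``flat_level`` holds the constant response.
    """

    scale: str
    plateau: float | None
    midpoint: float | None
    hill: float | None
    fit_type: str  # "sigmoid" | "flat"
    flat_level: float | None
    rss: float
    n_points: int
    dose_min: float
    dose_max: float

    @property
    def top(self) -> float:
        return TOP[self.scale]

    def __call__(self, dose):
        """Evaluate the fitted curve at dose(s) in µM."""
        dose = np.asarray(dose, dtype=float)
        if self.fit_type == "flat":
            return np.broadcast_to(np.float64(self.flat_level), dose.shape).copy()
        return hill_curve(dose, self.top, self.plateau, self.midpoint, self.hill)


def hill_curve(dose, top, plateau, midpoint, hill):
    """Decreasing Hill curve anchored at ``top`` for dose -> 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / midpoint, 0.0)
    return plateau + (top - plateau) / (1.0 + ratio ** hill)


def _flat_rss(values: np.ndarray) -> tuple[float, float]:
    level = float(np.mean(values))
    return level, float(np.sum((values - level) ** 2))


def fit_dose_response(
    doses,
    values,
    scale: str = "GR",
    *,
    flat_test_alpha: float = 0.05,
    hill_bounds: tuple[float, float] = HILL_BOUNDS,
    plateau_bounds: tuple[float, float] | None = None,
) -> CurveFit:
    """Fit a Hill curve to pooled replicate points, or fall back to flat.

    Parameters
    ----------
    doses, values:
        Paired arrays; ``doses`` repeats across replicates (all 12 points
        per dose enter one fit). At least 4 distinct positive doses are
        required.
    scale:
        "GR", "RV" or "TC"; fixes the top asymptote and plateau bounds.
    flat_test_alpha:
        Significance level of the sigmoid-vs-flat F-test.

    The optimizer is bounded least squares with three deterministic starts
    (midpoint at the geometric mean of the doses and at the 1st/3rd
    log-quartiles); midpoint bounds are [min_dose/100, max_dose*100].
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if doses.shape != values.shape:
        raise ValueError("doses and values must have the same shape")
    keep = np.isfinite(values)
    doses, values = doses[keep], values[keep]
    distinct = np.unique(doses)
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct doses to fit a dose-response curve")
    if (distinct <= 0).any():
        raise ValueError("doses must be positive")

    top = TOP[scale]
    p_lo, p_hi = plateau_bounds if plateau_bounds is not None else PLATEAU_BOUNDS[scale]
    dose_min, dose_max = float(distinct.min()), float(distinct.max())
    m_lo, m_hi = dose_min / 100.0, dose_max * 100.0
    log_d = np.log10(distinct)

    flat_level, rss_flat = _flat_rss(values)
    n = values.size

    def residuals(theta):
        plateau, log_mid, hill = theta
        return hill_curve(doses, top, plateau, 10.0 ** log_mid, hill) - values

    lo = [p_lo, math.log10(m_lo), hill_bounds[0]]
    hi = [p_hi, math.log10(m_hi), hill_bounds[1]]
    starts = [
        np.quantile(log_d, 0.5),
        np.quantile(log_d, 0.25),
        np.quantile(log_d, 0.75),
    ]
    p0_plateau = float(np.clip(values[doses == dose_max].mean(), p_lo, p_hi))

    best = None
    for s in starts:
        theta0 = [p0_plateau, float(np.clip(s, lo[1], hi[1])), 1.0]
        try:
            res = optimize.least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        except Exception:  # numerical failure on one start: try the others
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        log.warning("sigmoid optimizer failed on %s scale; using flat fit", scale)
        return CurveFit(scale, None, None, None, "flat", flat_level, rss_flat,
                        n, dose_min, dose_max)

    rss_sig = float(2 * best.cost)
    plateau, log_mid, hill = best.x

    # Model comparison: sigmoid (3 params) vs flat (1 param).
    accept = False
    scale_eps = max(1.0, abs(flat_level)) ** 2 * 1e-18 * n
    if rss_flat <= scale_eps:
        accept = False  # data are constant; nothing for the sigmoid to explain
    elif rss_sig <= scale_eps or rss_sig >= rss_flat:
        accept = rss_sig < rss_flat
    else:
        df1, df2 = 2, n - 3
        if df2 <= 0:
            accept = False
        else:
            f = ((rss_flat - rss_sig) / df1) / (rss_sig / df2)
            accept = stats.f.sf(f, df1, df2) < flat_test_alpha

    if not accept:
        return CurveFit(scale, None, None, None, "flat", flat_level, rss_flat,
                        n, dose_min, dose_max)
    return CurveFit(scale, float(plateau), float(10.0 ** log_mid), float(hill),
                    "sigmoid", None, rss_sig, n, dose_min, dose_max)
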