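"""Growth-rate-corrected scoring of organoid viability screens.

The central quantity is the GR value

    GR = 2**(log2(T/T0) / log2(C/T0)) - 1

where T is the endpoint reading of a treated well, T0 the day-0 seeding
control and C the endpoint reading of the DMSO vehicle control. GR = 1
means uninhibited growth, 0 cytostasis and -1 complete kill, and the value
depends on growth only through the ratios T/T0 and C/T0, which is what
removes the doubling-time confound that inflates traditional endpoint
metrics in fast-growing lines.

Alongside GR metrics (GR50, GEC50, GR_inf, GR_aoc, cytostatic dose) the
module computes the traditional metrics on their own scales: relative
growth RV = (T - T0)/(C - T0) * 100 (GI50 = dose where RV = 50), endpoint
viability T/C (IC50 = dose where T/C = 50) and EC50 (midpoint of the RV
fit).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .curves import CurveFit, fit_dose_response

log = logging.getLogger(__name__)

DEFAULT_EXTRAPOLATION_FACTOR = 10.0
AOC_GRID_POINTS = 50


# ---------------------------------------------------------------------------
# pointwise transforms


def gr_value(T, T0, C):
    """Growth-rate inhibition value 2**(log2(T/T0)/log2(C/T0)) - 1.

    Scale-invariant: depends only on the fold-changes T/T0 and C/T0.
    Requires T0 > 0 and C > T0 (the vehicle control must grow).
    """
    T = np.asarray(T, dtype=float)
    T0 = np.asarray(T0, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(T0 <= 0):
        raise ValueError("baseline T0 must be positive")
    if np.any(C <= T0):
        raise ValueError("control did not grow (C <= T0); GR undefined")
    if np.any(T < 0):
        raise ValueError("treated reading T must be nonnegative")
    with np.errstate(divide="ignore"):
        expo = np.log2(T / T0) / np.log2(C / T0)
    out = np.where(np.asarray(T) == 0, -1.0, np.exp2(expo) - 1.0)
    return out if out.ndim else float(out)


def rv_value(T, T0, C):
    """Relative growth (T - T0)/(C - T0) * 100; negative means net cell loss."""
    T = np.asarray(T, dtype=float)
    T0 = np.asarray(T0, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(C == T0):
        raise ValueError("degenerate control: C equals T0")
    out = (T - T0) / (C - T0) * 100.0
    return out if out.ndim else float(out)


def tc_value(T, C):
    """Endpoint viability T/C as percent of vehicle control."""
    T = np.asarray(T, dtype=float)
    C = np.asarray(C, dtype=float)
    out = T / C * 100.0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# profiles


@dataclasses.dataclass
class DoseResponseProfile:
    """Replicate-resolved transformed responses for one (model, drug) pair.

    ``points`` has one row per treated well with columns dose_uM, bio_rep,
    tech_rep, fold_change (T/T0), gr, rv, tc. ``vehicle_fold`` maps
    bio_rep -> C/T0; ``vehicle_fold_pooled`` is the all-replicate value.
    """

    model_id: str
    drug_id: str
    doses: np.ndarray
    points: pd.DataFrame
    vehicle_fold: dict[int, float]
    vehicle_fold_pooled: float


def _day0_aggregate(model_records: pd.DataFrame) -> tuple[dict[int, float], float]:
    """Per-bio-rep day-0 means with pooled fallback."""
    day0 = model_records[model_records["role"] == "day0"]
    if day0.empty:
        raise ValueError(f"model {model_records['model_id'].iloc[0]!r} has no day-0 wells")
    pooled = float(day0["luminescence"].mean())
    if pooled <= 0:
        raise ValueError("day-0 aggregate T0 must be positive")
    per_rep = day0.groupby("bio_rep")["luminescence"].mean().to_dict()
    return {int(k): float(v) for k, v in per_rep.items()}, pooled


def build_profiles(records: pd.DataFrame) -> list[DoseResponseProfile]:
    """Turn validated plate records into per-(model, drug) profiles.

    Day-0 normalization uses the mean of the model's day-0 wells within the
    same biological replicate; a replicate without day-0 wells falls back to
    the pooled mean (logged). The vehicle fold-change C/T0 must exceed 1.
    """
    profiles: list[DoseResponseProfile] = []
    for model_id, mrec in records.groupby("model_id", sort=True):
        t0_by_rep, t0_pooled = _day0_aggregate(mrec)
        vehicle = mrec[mrec["role"] == "vehicle"]
        if vehicle.empty:
            raise ValueError(f"model {model_id!r} has no vehicle wells")

        def t0_for(rep: int) -> float:
            if rep in t0_by_rep:
                return t0_by_rep[rep]
            log.warning("model %s bio_rep %d lacks day-0 wells; using pooled mean",
                        model_id, rep)
            return t0_pooled

        veh_fold = {
            int(rep): float(grp["luminescence"].mean()) / t0_for(int(rep))
            for rep, grp in vehicle.groupby("bio_rep")
        }
        veh_fold_pooled = float(
            np.mean([v for v in veh_fold.values()])
        )
        for fold in veh_fold.values():
            if fold <= 1.0:
                raise ValueError(
                    f"control did not grow for model {model_id!r} (C/T0 = {fold:.3g})"
                )

        treated = mrec[mrec["role"] == "treated"]
        for drug_id, drec in treated.groupby("drug_id", sort=True):
            reps = drec["bio_rep"].to_numpy()
            missing = set(reps) - set(veh_fold)
            if missing:
                raise ValueError(
                    f"model {model_id!r} bio_rep(s) {sorted(missing)} have no vehicle wells"
                )
            t0 = np.array([t0_for(int(r)) for r in reps])
            c_fold = np.array([veh_fold[int(r)] for r in reps])
            fold = drec["luminescence"].to_numpy() / t0
            pts = pd.DataFrame({
                "dose_uM": drec["dose_uM"].to_numpy(),
                "bio_rep": reps,
                "tech_rep": drec["tech_rep"].to_numpy(),
                "fold_change": fold,
                "gr": gr_value(fold, 1.0, c_fold),
                "rv": rv_value(fold, 1.0, c_fold),
                "tc": tc_value(fold, c_fold),
            }).sort_values(["dose_uM", "bio_rep", "tech_rep"], ignore_index=True)
            profiles.append(DoseResponseProfile(
                model_id=str(model_id), drug_id=str(drug_id),
                doses=np.unique(pts["dose_uM"].to_numpy()),
                points=pts, vehicle_fold=veh_fold,
                vehicle_fold_pooled=veh_fold_pooled,
            ))
    return profiles


# ---------------------------------------------------------------------------
# metrics from fits


def _crossing_dose(fit: CurveFit, level: float) -> float:
    """Dose at which a sigmoid fit crosses ``level``; NaN when unreached."""
    if fit.fit_type != "sigmoid":
        return math.nan
    top, p = fit.top, fit.plateau
    if not (p < level < top):
        return math.nan
    x = (top - level) / (level - p)
    return fit.midpoint * x ** (1.0 / fit.hill)


def _within_reporting_range(dose: float, fit: CurveFit, factor: float) -> bool:
    return fit.dose_min / factor <= dose <= fit.dose_max * factor


def gr50(fit: CurveFit, extrapolation_factor: float = DEFAULT_EXTRAPOLATION_FACTOR) -> float:
    """Dose at which the fitted GR curve crosses 0.5 (µM), or NaN.

    NaN when the fit is flat, GR_inf >= 0.5, or the root lies outside the
    tested range extended by ``extrapolation_factor``.
    """
    dose = _crossing_dose(fit, 0.5)
    if math.isnan(dose) or not _within_reporting_range(dose, fit, extrapolation_factor):
        return math.nan
    return dose


def cytostatic_dose(fit: CurveFit) -> float:
    """Dose of zero net growth: GEC50 * (-1/GR_inf)**(1/hill); NaN if GR_inf >= 0."""
    return _crossing_dose(fit, 0.0)


def gi50(fit: CurveFit, extrapolation_factor: float = DEFAULT_EXTRAPOLATION_FACTOR) -> float:
    """Dose at which relative growth crosses 50% on the RV fit, or NaN."""
    dose = _crossing_dose(fit, 50.0)
    if math.isnan(dose) or not _within_reporting_range(dose, fit, extrapolation_factor):
        return math.nan
    return dose


def ic50(fit: CurveFit, extrapolation_factor: float = DEFAULT_EXTRAPOLATION_FACTOR) -> float:
    """Dose at which endpoint viability T/C crosses 50% on its fit, or NaN."""
    dose = _crossing_dose(fit, 50.0)
    if math.isnan(dose) or not _within_reporting_range(dose, fit, extrapolation_factor):
        return math.nan
    return dose


def gr_aoc(fit: CurveFit, doses=None, n_grid: int = AOC_GRID_POINTS) -> float:
    """Normalized area over the GR curve.

    (1/(log10 c_max - log10 c_min)) * integral of (1 - GR(c)) d log10 c,
    trapezoidal on the fitted curve at ``n_grid`` log-spaced points across
    the tested range. Always defined when a fit (sigmoid or flat) exists;
    0 for constant GR = 1, 2 for constant GR = -1.
    """
    if doses is not None:
        doses = np.asarray(doses, dtype=float)
        if doses.size < 2:
            raise ValueError("GR_aoc needs at least 2 doses")
        lo, hi = float(doses.min()), float(doses.max())
    else:
        lo, hi = fit.dose_min, fit.dose_max
    if not lo < hi:
        raise ValueError("GR_aoc needs a nondegenerate dose range")
    grid = np.logspace(math.log10(lo), math.log10(hi), n_grid)
    integrand = 1.0 - fit(grid)
    span = math.log10(hi) - math.log10(lo)
    return float(np.trapezoid(integrand, np.log10(grid)) / span)


def summarize_profile(
    profile: DoseResponseProfile,
    *,
    extrapolation_factor: float = DEFAULT_EXTRAPOLATION_FACTOR,
    flat_test_alpha: float = 0.05,
) -> dict:
    """Fit the GR, RV and T/C curves of one profile and compute all metrics."""
    pts = profile.points
    doses = pts["dose_uM"].to_numpy()
    fit_gr = fit_dose_response(doses, pts["gr"].to_numpy(), "GR",
                               flat_test_alpha=flat_test_alpha)
    fit_rv = fit_dose_response(doses, pts["rv"].to_numpy(), "RV",
                               flat_test_alpha=flat_test_alpha)
    fit_tc = fit_dose_response(doses, pts["tc"].to_numpy(), "TC",
                               flat_test_alpha=flat_test_alpha)
    sig_gr = fit_gr.fit_type == "sigmoid"
    sig_rv = fit_rv.fit_type == "sigmoid"
    return {
        "model_id": profile.model_id,
        "drug_id": profile.drug_id,
        "GR50": gr50(fit_gr, extrapolation_factor),
        "GEC50": fit_gr.midpoint if sig_gr else math.nan,
        "GR_inf": fit_gr.plateau if sig_gr else math.nan,
        "hill": fit_gr.hill if sig_gr else math.nan,
        "GR_aoc": gr_aoc(fit_gr),
        "cytostatic_uM": cytostatic_dose(fit_gr),
        "EC50": fit_rv.midpoint if sig_rv else math.nan,
        "IC50": ic50(fit_tc, extrapolation_factor),
        "GI50": gi50(fit_rv, extrapolation_factor),
        "fit_type_gr": fit_gr.fit_type,
        "fit_type_rv": fit_rv.fit_type,
        "n_points": int(len(pts)),
    }


def score_screen(
    records: pd.DataFrame,
    *,
    extrapolation_factor: float = DEFAULT_EXTRAPOLATION_FACTOR,
    flat_test_alpha: float = 0.05,
    per_bio_rep: bool = False,
) -> pd.DataFrame:
    """Score a whole screen into a metrics table (one row per model x drug).

    With ``per_bio_rep=True``, each biological replicate is scored as its
    own pooled fit (4 points per dose) and the table gains a ``bio_rep``
    column — used for replicate-reproducibility analysis.
    """
    if per_bio_rep:
        out = []
        for rep in sorted(records.loc[records["role"] == "treated", "bio_rep"].unique()):
            sub = records[records["bio_rep"] == int(rep)]
            tab = score_screen(sub, extrapolation_factor=extrapolation_factor,
                               flat_test_alpha=flat_test_alpha)
            tab.insert(0, "bio_rep", int(rep))
            out.append(tab)
        return pd.concat(out, ignore_index=True)

    rows = [
        summarize_profile(p, extrapolation_factor=extrapolation_factor,
                          flat_test_alpha=flat_test_alpha)
        for p in build_profiles(records)
    ]
    from .io import METRIC_COLUMNS, empty_metrics

    if not rows:
        return empty_metrics()
    return pd.DataFrame(rows)[METRIC_COLUMNS]


# ---------------------------------------------------------------------------
# growth


def estimate_doubling_time(timepoints, measures) -> float:
    """Doubling time (days) from a log-linear fit of a viability signal.

    ln2 / slope of the least-squares line of ln(measure) vs time; NaN (with
    a warning) when there is no net growth.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(measures, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 timepoints")
    if np.any(y <= 0):
        raise ValueError("measures must be positive")
    slope = np.polyfit(t, np.log(y), 1)[0]
    if slope <= 0:
        log.warning("no net growth (slope %.3g <= 0); doubling time undefined", slope)
        return math.nan
    return math.log(2.0) / slope
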