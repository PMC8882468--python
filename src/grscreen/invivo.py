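"""In vivo validation statistics for xenograft treatment studies.

Tumor-volume trajectories are summarized as volume relative to treatment
start; arms are compared by the area under the relative growth curve
(trapezoidal, up to a fixed day, two-sided t-test), growth rates come from
log-linear fits, recurrence after treatment cessation is compared by the
log-rank (Mantel-Cox) test, and organoid-to-xenograft concordance is the
Spearman correlation between GR_aoc and the in vivo endpoint.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

VOLUME_COLUMNS = ["mouse_id", "arm", "day", "volume_mm3"]
RECURRENCE_COLUMNS = ["mouse_id", "arm", "day", "event"]


@dataclasses.dataclass
class TumorTrajectory:
    """Volume time series for one mouse, days from treatment start."""

    mouse_id: str
    arm: str
    times: np.ndarray
    volumes: np.ndarray
    relative_volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.size != self.volumes.size or self.times.size < 1:
            raise ValueError("times and volumes must be nonempty and aligned")
        if self.times[0] != 0:
            raise ValueError("trajectory must start at day 0 (treatment start)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")


def trajectories_from_frame(volumes: pd.DataFrame) -> list[TumorTrajectory]:
    """Group a volumes table (mouse_id, arm, day, volume_mm3) into trajectories."""
    missing = [c for c in VOLUME_COLUMNS if c not in volumes.columns]
    if missing:
        raise ValueError(f"volumes table missing columns {missing}")
    out = []
    for (mouse, arm), grp in volumes.groupby(["mouse_id", "arm"], sort=True):
        grp = grp.sort_values("day")
        out.append(relative_volume(TumorTrajectory(
            str(mouse), str(arm), grp["day"].to_numpy(), grp["volume_mm3"].to_numpy())))
    return out


def relative_volume(trajectory: TumorTrajectory) -> TumorTrajectory:
    """Fill volumes relative to the day-0 baseline (baseline must be > 0)."""
    baseline = trajectory.volumes[0]
    if baseline <= 0:
        raise ValueError("baseline volume must be positive")
    trajectory.relative_volumes = trajectory.volumes / baseline
    return trajectory


def trajectory_auc(trajectory: TumorTrajectory, t_max: float) -> float:
    """Trapezoidal AUC of relative volume on [0, t_max].

    Measurement days may differ between mice; the curve is linearly
    interpolated to t_max, but never extrapolated past the last measurement.
    """
    if trajectory.relative_volumes is None:
        relative_volume(trajectory)
    t, rv = trajectory.times, trajectory.relative_volumes
    if t[-1] < t_max:
        raise ValueError(
            f"trajectory for {trajectory.mouse_id} ends at day {t[-1]:g} < t_max {t_max:g}"
        )
    keep = t <= t_max
    tt = np.append(t[keep], t_max) if t[keep][-1] < t_max else t[keep]
    vv = np.interp(tt, t, rv)
    return float(np.trapezoid(vv, tt))


def auc_compare(arm_a: list[TumorTrajectory], arm_b: list[TumorTrajectory],
                t_max: float, *, welch: bool = False) -> dict:
    """Compare two arms by per-mouse growth-curve AUC up to ``t_max`` days.

    Pooled-variance two-sided t-test by default (Welch via flag).
    """
    if len(arm_a) < 2 or len(arm_b) < 2:
        raise ValueError("need >= 2 mice per arm")
    auc_a = np.array([trajectory_auc(t, t_max) for t in arm_a])
    auc_b = np.array([trajectory_auc(t, t_max) for t in arm_b])
    res = sps.ttest_ind(auc_a, auc_b, equal_var=not welch)
    t_stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t_stat) and np.allclose(auc_a.mean(), auc_b.mean()):
        t_stat, p = 0.0, 1.0  # zero variance in both arms, equal means
    return {"auc_a": auc_a, "auc_b": auc_b, "t_statistic": t_stat, "p_value": p}


def growth_rate(trajectory: TumorTrajectory) -> float:
    """Per-day exponential growth rate: log-linear slope of relative volume."""
    if trajectory.times.size < 2:
        raise ValueError("need >= 2 timepoints")
    if trajectory.relative_volumes is None:
        relative_volume(trajectory)
    return float(np.polyfit(trajectory.times, np.log(trajectory.relative_volumes), 1)[0])


def logrank_recurrence(records: pd.DataFrame) -> dict:
    """Log-rank (Mantel-Cox) test of time to recurrence across arms.

    ``records`` columns: mouse_id, arm, day (time to recurrence or
    censoring), event (1 = recurrence observed, 0 = censored).
    """
    missing = [c for c in RECURRENCE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"recurrence table missing columns {missing}")
    if records["arm"].nunique() < 2:
        raise ValueError("need >= 2 arms")
    if (records["day"] <= 0).any():
        raise ValueError("recurrence times must be positive")
    if int(records["event"].sum()) == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(records["day"], records["arm"], records["event"])
    return {"chi_square": float(res.test_statistic), "p_value": float(res.p_value),
            "df": int(res.degrees_of_freedom)}


def pdxo_pdx_concordance(graoc_by_model: pd.Series, invivo_endpoint: pd.Series) -> dict:
    """Spearman concordance of organoid GR_aoc with an in vivo endpoint.

    The endpoint (default AUC of relative volume under treatment) is
    oriented so a smaller value means a better response; the sign
    convention makes perfect concordance rho = +1.
    """
    common = graoc_by_model.index.intersection(invivo_endpoint.index)
    if len(common) < 3:
        raise ValueError("need >= 3 models with both measurements")
    res = sps.spearmanr(graoc_by_model[common], invivo_endpoint[common])
    return {"rho": float(-res.statistic), "p_value": float(res.pvalue), "n": len(common)}
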