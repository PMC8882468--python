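"""Seeded generators for every input the pipeline consumes, with known truth.

The screen generator emulates the study design being analyzed: 384-well
plates, an 8-point half-log dilution dosed in technical quadruplicate
across 3 biological replicates, 16 day-0 seeding-control wells on a
separate plate, DMSO vehicle wells, 96 h exposure, and organoid lines with
doubling times between 3 and 8 days.

Growth over the exposure window is exponential, so the vehicle fold-change
is C/T0 = 2**(exposure_h / (24 * DT)). A line's true response to a drug is
a Hill curve on the GR scale, GR*(c) = GR_inf + (1 - GR_inf)/(1 +
(c/GEC50)^hill), and the treated endpoint inverts the GR transform
exactly: T = T0 * (C/T0)**log2(GR*(c) + 1). Noise is multiplicative
lognormal per well plus a lognormal per-biological-replicate seeding scale
(which cancels under per-replicate day-0 normalization, as in the real
assay). Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .curves import CurveFit, hill_curve
from .synergy import loewe_expected

T0_SIGNAL = 1.0e6  # mean day-0 luminescence (relative light units)


@dataclasses.dataclass(frozen=True)
class DrugTruth:
    """True Hill parameters of one line's response on the GR scale."""

    gr_inf: float
    gec50: float
    hill: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.gr_inf <= 1.0:
            raise ValueError("gr_inf must lie in [-1, 1]")
        if self.gec50 <= 0:
            raise ValueError("gec50 must be positive")
        if not 0.1 <= self.hill <= 5.0:
            raise ValueError("hill must lie in [0.1, 5]")

    def gr(self, dose):
        """True GR value at dose(s) in µM."""
        return hill_curve(np.asarray(dose, dtype=float), 1.0, self.gr_inf,
                          self.gec50, self.hill)


@dataclasses.dataclass
class LineTruth:
    """One simulated organoid line: growth rate, subtype and per-drug truth.

    ``drug_truths`` maps drug_id to a :class:`DrugTruth` or None (inert:
    no effect, GR identically 1).
    """

    model_id: str
    doubling_time: float
    subtype: str
    drug_truths: dict[str, DrugTruth | None]

    def vehicle_fold(self, exposure_h: float) -> float:
        """C/T0 under exponential growth over the exposure window."""
        return 2.0 ** (exposure_h / (24.0 * self.doubling_time))


@dataclasses.dataclass
class NoiseModel:
    """Multiplicative lognormal noise magnitudes (coefficients of variation)."""

    cv_tech: float = 0.05
    cv_bio: float = 0.10
    day0_cv: float = 0.05

    def __post_init__(self) -> None:
        if min(self.cv_tech, self.cv_bio, self.day0_cv) < 0:
            raise ValueError("noise magnitudes must be nonnegative")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


# ---------------------------------------------------------------------------
# truth panels

#: Response archetypes: (gr_inf range). Values chosen to sit decisively on
#: one side of the GR50/GI50/IC50 thresholds for any doubling time in [3, 8] d.
ARCHETYPES = {
    "inert": None,
    "growth_reduction": (0.65, 0.90),
    "cytostatic": (0.05, 0.35),
    "cytotoxic": (-1.0, -0.30),
}
GEC50_RANGE = (0.03, 1.0)   # µM, log-uniform, well inside the default dose ladder
HILL_RANGE = (0.8, 2.5)
SUBTYPES = ("TNBC", "HR+", "HER2+")


def archetype_truth(kind: str, rng: np.random.Generator) -> DrugTruth | None:
    """Draw one drug truth of the given archetype."""
    rng_range = ARCHETYPES[kind]
    if rng_range is None:
        return None
    lo, hi = rng_range
    return DrugTruth(
        gr_inf=float(rng.uniform(lo, hi)),
        gec50=float(np.exp(rng.uniform(*np.log(GEC50_RANGE)))),
        hill=float(rng.uniform(*HILL_RANGE)),
    )


def random_panel(n_lines: int, n_drugs: int, seed: int,
                 archetype_weights: dict[str, float] | None = None,
                 doubling_time_range: tuple[float, float] = (3.0, 8.0),
                 ) -> tuple[list[LineTruth], list[str]]:
    """A random screen truth panel: lines x drugs with archetype responses."""
    rng = np.random.default_rng(seed)
    weights = archetype_weights or {
        "inert": 0.25, "growth_reduction": 0.25, "cytostatic": 0.25, "cytotoxic": 0.25,
    }
    kinds = list(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    drugs = [f"drug{j:03d}" for j in range(n_drugs)]
    lines = []
    for i in range(n_lines):
        truths = {
            d: archetype_truth(str(rng.choice(kinds, p=probs)), rng) for d in drugs
        }
        lines.append(LineTruth(
            model_id=f"line{i:03d}",
            doubling_time=float(rng.uniform(*doubling_time_range)),
            subtype=str(SUBTYPES[i % len(SUBTYPES)]),
            drug_truths=truths,
        ))
    return lines, drugs


def truth_table(lines: list[LineTruth]) -> pd.DataFrame:
    """Flatten line truths into a tidy table for recovery tests."""
    rows = []
    for line in lines:
        for drug, t in line.drug_truths.items():
            rows.append({
                "model_id": line.model_id, "drug_id": drug,
                "doubling_time": line.doubling_time, "subtype": line.subtype,
                "inert": t is None,
                "gr_inf": math.nan if t is None else t.gr_inf,
                "gec50": math.nan if t is None else t.gec50,
                "hill": math.nan if t is None else t.hill,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screen simulation

_ROWS = "ABCDEFGHIJKLMNOP"


def _well_series(n: int) -> list[str]:
    """First n well names of a 384-well plate, row-major."""
    return [f"{_ROWS[i // 24]}{i % 24 + 1:02d}" for i in range(n)]


@dataclasses.dataclass
class SimulatedScreen:
    plate_map: pd.DataFrame
    readings: pd.DataFrame
    truth: pd.DataFrame

    @property
    def records(self) -> pd.DataFrame:
        merged = self.plate_map.merge(self.readings, on=["plate_id", "well"])
        return merged


def simulate_screen(lines: list[LineTruth], config: ScreenConfig | None = None,
                    noise: NoiseModel | None = None, seed: int = 0) -> SimulatedScreen:
    """Generate plate-map + readings CSV tables for a full screen.

    Each (line, biological replicate) occupies its own assay plates
    (treated + vehicle wells) plus a separate day-0 control plate, matching
    the screen layout the readers expect.
    """
    config = config or ScreenConfig()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    doses = np.asarray(config.doses, dtype=float)

    map_rows: list[dict] = []
    lum: list[float] = []
    for line in lines:
        k = line.vehicle_fold(config.exposure_h)
        drugs = sorted(line.drug_truths)
        for b in range(1, config.n_bio_rep + 1):
            bio_scale = float(_lognormal_factor(rng, noise.cv_bio, ()))
            base = T0_SIGNAL * bio_scale

            # day-0 plate
            d0_plate = f"{line.model_id}_b{b}_day0"
            d0_noise = _lognormal_factor(rng, noise.day0_cv, config.n_day0_wells)
            for w, f in zip(_well_series(config.n_day0_wells), d0_noise):
                map_rows.append(dict(plate_id=d0_plate, well=w, model_id=line.model_id,
                                     drug_id="", dose_uM=0.0, role="day0",
                                     bio_rep=b, tech_rep=1))
                lum.append(base * f)

            # assay plates: vehicle wells then treated wells, 384 per plate
            cells: list[tuple[str, float, str, int]] = []  # (drug, dose, role, tech)
            for t in range(1, config.n_vehicle_wells + 1):
                cells.append(("", 0.0, "vehicle", t))
            for drug in drugs:
                for dose in doses:
                    for t in range(1, config.n_tech_rep + 1):
                        cells.append((drug, float(dose), "treated", t))
            for idx, (drug, dose, role, tech) in enumerate(cells):
                plate = f"{line.model_id}_b{b}_p{idx // 384 + 1}"
                well = _well_series(384)[idx % 384]
                if role == "vehicle":
                    signal = base * k
                else:
                    truth = line.drug_truths[drug]
                    gr = 1.0 if truth is None else float(truth.gr(dose))
                    gr = max(gr, -1.0 + 1e-9)
                    signal = base * k ** math.log2(gr + 1.0)
                signal *= float(_lognormal_factor(rng, noise.cv_tech, ()))
                map_rows.append(dict(plate_id=plate, well=well, model_id=line.model_id,
                                     drug_id=drug, dose_uM=dose, role=role,
                                     bio_rep=b, tech_rep=tech))
                lum.append(signal)

    plate_map = pd.DataFrame(map_rows)
    readings = plate_map[["plate_id", "well"]].copy()
    readings["luminescence"] = np.asarray(lum)
    return SimulatedScreen(plate_map, readings, truth_table(lines))


# ---------------------------------------------------------------------------
# truth-side expectations (used by recovery and missingness tests)


def truth_threshold_doses(line: LineTruth, drug_id: str, config: ScreenConfig | None = None,
                          extrapolation_factor: float = 10.0) -> dict:
    """Crossing doses implied by a (line, drug) truth, NaN where unreached.

    Computes, on the *true* curves (not fits), the doses at which GR = 0.5
    (GR50), relative growth = 50% (GI50) and endpoint viability T/C = 50%
    (IC50), restricted to the tested dose range extended by
    ``extrapolation_factor`` — the same reporting convention the scoring
    pipeline uses.
    """
    config = config or ScreenConfig()
    doses = np.asarray(config.doses, dtype=float)
    lo = doses.min() / extrapolation_factor
    hi = doses.max() * extrapolation_factor
    truth = line.drug_truths[drug_id]
    out = {"GR50": math.nan, "GI50": math.nan, "IC50": math.nan}
    if truth is None:
        return out
    k = line.vehicle_fold(config.exposure_h)

    def crossing(func, level) -> float:
        # func is monotone decreasing in dose
        if not func(hi) < level < func(lo):
            return math.nan
        a, b = lo, hi
        for _ in range(200):
            mid = math.sqrt(a * b)
            if func(mid) > level:
                a = mid
            else:
                b = mid
        return math.sqrt(a * b)

    def gr_curve(c):
        return float(truth.gr(c))

    def rv_curve(c):
        r = math.log2(gr_curve(c) + 1.0)
        return (k ** r - 1.0) / (k - 1.0) * 100.0

    def tc_curve(c):
        r = math.log2(gr_curve(c) + 1.0)
        return k ** (r - 1.0) * 100.0

    out["GR50"] = crossing(gr_curve, 0.5)
    out["GI50"] = crossing(rv_curve, 50.0)
    out["IC50"] = crossing(tc_curve, 50.0)
    return out


# ---------------------------------------------------------------------------
# culture growth curves


def simulate_growth_curve(doubling_time: float, seed: int = 0, n_timepoints: int = 6,
                          interval_days: float = 4.0, cv: float = 0.05
                          ) -> tuple[np.ndarray, np.ndarray]:
    """A noisy exponential culture growth curve (times in days, signal)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * interval_days
    signal = T0_SIGNAL * 2.0 ** (t / doubling_time)
    return t, signal * _lognormal_factor(rng, cv, t.size)


# ---------------------------------------------------------------------------
# synergy grids


def _viability_fit(plateau: float, ec50: float, hill: float, doses: np.ndarray) -> CurveFit:
    """Wrap true single-agent viability parameters as a CurveFit."""
    return CurveFit("TC", plateau, ec50, hill, "sigmoid", None, 0.0,
                    doses.size, float(doses.min()), float(doses.max()))


def simulate_synergy_grid(truth_a: tuple[float, float, float],
                          truth_b: tuple[float, float, float],
                          doses_a, doses_b, *, bonus=None,
                          n_bio_rep: int = 3, n_tech_rep: int = 4,
                          cv_tech: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Long-format replicate data for a two-drug checkerboard.

    ``truth_a``/``truth_b`` are (plateau_pct, ec50_uM, hill) of the true
    single-agent viability curves; the observed combination response is the
    Loewe-additive expectation minus ``bonus(dose_a, dose_b)`` (percent
    points of extra kill; None or 0 gives an additive grid), with
    multiplicative lognormal replicate noise.
    """
    rng = np.random.default_rng(seed)
    doses_a = np.asarray(sorted(set([0.0] + list(doses_a))), dtype=float)
    doses_b = np.asarray(sorted(set([0.0] + list(doses_b))), dtype=float)
    fit_a = _viability_fit(*truth_a, doses=doses_a[doses_a > 0])
    fit_b = _viability_fit(*truth_b, doses=doses_b[doses_b > 0])
    rows = []
    for da in doses_a:
        for db in doses_b:
            expected, _ = loewe_expected(fit_a, fit_b, float(da), float(db))
            level = expected
            if bonus is not None and da > 0 and db > 0:
                level = expected - float(bonus(da, db))
            level = max(level, 0.0)
            for b in range(1, n_bio_rep + 1):
                for t in range(1, n_tech_rep + 1):
                    obs = level * float(_lognormal_factor(rng, cv_tech, ()))
                    rows.append(dict(dose_a_uM=float(da), dose_b_uM=float(db),
                                     bio_rep=b, tech_rep=t, response_pct=obs))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in vivo studies


def simulate_invivo(sensitivities: dict[str, float], *, n_mice: int = 5,
                    t_end: float = 21.0, measure_every: float = 3.5,
                    baseline_mm3: float = 150.0, vehicle_doubling_days: float = 7.0,
                    effect: float = 1.6, cv_measure: float = 0.10,
                    recurrence_followup: float = 120.0, recurrence_scale: float = 60.0,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exponential tumor trajectories and recurrence times per model.

    ``sensitivities`` maps model_id to a latent sensitivity s in [0, 1]
    shared with the screen truth. Vehicle tumors grow exponentially at
    ln2/vehicle_doubling_days; treated tumors grow at that rate times
    (1 - effect * s), so sufficiently sensitive lines regress. Recurrence
    times after treatment cessation are exponential with mean proportional
    to 1/burden, where burden is the end-of-treatment relative volume —
    i.e. the hazard increases with residual tumor burden. Mice without
    recurrence by ``recurrence_followup`` days are censored.

    Returns (volumes, recurrence) tables in the reader schemas.
    """
    rng = np.random.default_rng(seed)
    r0 = math.log(2.0) / vehicle_doubling_days
    times = np.arange(0.0, t_end + 1e-9, measure_every)
    if times[-1] < t_end:
        times = np.append(times, t_end)
    vol_rows, rec_rows = [], []
    for model_id in sorted(sensitivities):
        s = sensitivities[model_id]
        for arm, rate in (("vehicle", r0), ("treated", r0 * (1.0 - effect * s))):
            for m in range(1, n_mice + 1):
                mouse = f"{model_id}_{arm}_{m}"
                v0 = baseline_mm3 * float(_lognormal_factor(rng, cv_measure, ()))
                vols = v0 * np.exp(rate * times)
                vols = vols * _lognormal_factor(rng, cv_measure, times.size)
                vols[0] = v0
                for t, v in zip(times, vols):
                    vol_rows.append(dict(mouse_id=mouse, arm=arm, day=float(t),
                                         volume_mm3=float(v), model_id=model_id))
                if arm == "treated":
                    burden = math.exp(rate * t_end)
                    mean_time = recurrence_scale / max(burden, 1e-6)
                    t_rec = max(float(rng.exponential(mean_time)), 1e-6)
                    event = t_rec <= recurrence_followup
                    # recurrence is compared between treatment conditions, so
                    # the condition (model) id is the arm label
                    rec_rows.append(dict(mouse_id=mouse, arm=model_id,
                                         model_id=model_id,
                                         day=min(t_rec, recurrence_followup),
                                         event=int(event)))
    return pd.DataFrame(vol_rows), pd.DataFrame(rec_rows)


def coupled_panel(n_lines: int, drug_id: str = "drugX", seed: int = 0,
                  ) -> tuple[list[LineTruth], dict[str, float]]:
    """Lines whose screen truth and in vivo sensitivity share one latent s.

    The latent sensitivity s ~ U(0, 1) maps to GR_inf = 1 - 2 s, so the
    screen-side GR_aoc and the in vivo response rank the lines identically
    in truth; used for organoid-to-xenograft concordance simulations. The
    drug's potency parameters (GEC50, hill) are one draw shared by all
    lines — it is one compound, and the lines differ in response depth.
    """
    rng = np.random.default_rng(seed)
    gec50 = float(np.exp(rng.uniform(*np.log(GEC50_RANGE))))
    hill = float(rng.uniform(*HILL_RANGE))
    lines, sens = [], {}
    for i in range(n_lines):
        s = float(rng.uniform(0.0, 1.0))
        model = f"line{i:03d}"
        sens[model] = s
        truth = DrugTruth(gr_inf=float(np.clip(1.0 - 2.0 * s, -1.0, 1.0)),
                          gec50=gec50, hill=hill)
        lines.append(LineTruth(model, float(rng.uniform(3.0, 8.0)),
                               SUBTYPES[i % 3], {drug_id: truth}))
    return lines, sens


# ---------------------------------------------------------------------------
# clinical durations


def simulate_clinical(median_pfs_days: list[float], *, median_gap_days: float = 30.0,
                      deterministic: bool = False, seed: int = 0) -> pd.DataFrame:
    """Exponential PFS draws per line of therapy; TTNT = PFS + gap.

    With ``deterministic=True`` the PFS equals the stated median and the
    gap its median exactly (noise off).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, med in enumerate(median_pfs_days, start=1):
        if med <= 0:
            raise ValueError("median PFS must be positive")
        if deterministic:
            pfs, gap = float(med), float(median_gap_days)
        else:
            pfs = float(rng.exponential(med / math.log(2.0)))
            gap = float(rng.exponential(median_gap_days / math.log(2.0)))
        rows.append(dict(therapy=f"line{i}", pfs_days=pfs, ttnt_days=pfs + gap))
    return pd.DataFrame(rows)
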