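"""Two-drug dose-matrix synergy scoring against a Loewe additivity reference.

Observed responses are percent of vehicle control. The single-agent
margins of the matrix (rows/columns at dose 0 of the partner) are fitted
with Hill curves, and the Loewe-expected response at a dose pair (a, b) is
the unique effect level E satisfying

    a / A(E) + b / B(E) = 1

where A(E) and B(E) invert the single-agent curves (the dose of each drug
alone that would produce effect E). A drug that cannot reach E alone
contributes nothing (its term is 0). Synergy is expected minus observed on
the viability scale, so positive values mean more kill than additivity
predicts — the convention of Loewe synergy surface plots.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .curves import CurveFit, fit_dose_response

GRID_COLUMNS = ["dose_a_uM", "dose_b_uM", "bio_rep", "tech_rep", "response_pct"]


@dataclasses.dataclass
class SynergyGrid:
    """A two-drug checkerboard with observed, expected and synergy matrices.

    Matrices are indexed by dose_a (rows, ascending, including 0) and
    dose_b (columns, ascending, including 0); ``mean_synergy`` averages the
    nonzero-dose (combination) cells.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: pd.DataFrame
    observed_sem: pd.DataFrame
    expected_loewe: pd.DataFrame | None = None
    synergy: pd.DataFrame | None = None
    extrapolated: pd.DataFrame | None = None
    mean_synergy: float | None = None
    fit_a: CurveFit | None = None
    fit_b: CurveFit | None = None

    @classmethod
    def from_long(cls, data: pd.DataFrame, drug_a: str = "A", drug_b: str = "B") -> "SynergyGrid":
        """Build a grid from long-format replicate data.

        ``data`` columns: dose_a_uM, dose_b_uM, bio_rep, tech_rep,
        response_pct (percent of vehicle control).
        """
        missing = [c for c in GRID_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"synergy data missing columns {missing}")
        g = data.groupby(["dose_a_uM", "dose_b_uM"])["response_pct"]
        mean = g.mean().unstack()
        sem = (g.std(ddof=1) / np.sqrt(g.count())).unstack()
        doses_a = mean.index.to_numpy(dtype=float)
        doses_b = mean.columns.to_numpy(dtype=float)
        if doses_a[0] != 0 or doses_b[0] != 0:
            raise ValueError("dose matrix must include the 0-dose margins")
        if mean.isna().to_numpy().any():
            raise ValueError("dose matrix has empty cells")
        return cls(drug_a, drug_b, doses_a, doses_b, mean, sem)


def fit_single_agents(grid: SynergyGrid, *, flat_test_alpha: float = 0.05
                      ) -> tuple[CurveFit, CurveFit]:
    """Hill fits (percent-of-control scale, top 100) of the two margins."""
    a_doses = grid.doses_a[grid.doses_a > 0]
    b_doses = grid.doses_b[grid.doses_b > 0]
    if a_doses.size < 4 or b_doses.size < 4:
        raise ValueError("each margin needs >= 4 nonzero doses")
    a_resp = grid.observed.loc[a_doses, 0.0].to_numpy()
    b_resp = grid.observed.loc[0.0, b_doses].to_numpy()
    fit_a = fit_dose_response(a_doses, a_resp, "TC", flat_test_alpha=flat_test_alpha)
    fit_b = fit_dose_response(b_doses, b_resp, "TC", flat_test_alpha=flat_test_alpha)
    grid.fit_a, grid.fit_b = fit_a, fit_b
    return fit_a, fit_b


def _inverse_dose(fit: CurveFit, effect: float) -> float:
    """Dose producing ``effect`` on a decreasing Hill fit; inf if unreachable."""
    top = fit.top
    if fit.fit_type == "flat":
        return np.inf
    p = fit.plateau
    if effect >= top:
        return 0.0
    if effect <= p:
        return np.inf
    x = (top - effect) / (effect - p)
    return fit.midpoint * x ** (1.0 / fit.hill)


def loewe_expected(fit_a: CurveFit, fit_b: CurveFit, dose_a: float, dose_b: float,
                   *, tol: float = 1e-9) -> tuple[float, bool]:
    """Loewe-additive expected response at one dose pair.

    Returns (expected_percent, extrapolated). ``extrapolated`` is True when
    the additive prediction would fall below both single-agent plateaus, in
    which case the response is clamped to the lower attainable plateau.
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be nonnegative")
    if dose_a == 0 and dose_b == 0:
        return 100.0, False
    if dose_b == 0:
        return float(fit_a(dose_a)), False
    if dose_a == 0:
        return float(fit_b(dose_b)), False
    for fit in (fit_a, fit_b):
        if fit.fit_type == "sigmoid" and fit.plateau >= fit.top:
            raise ValueError("single-agent fit is not monotone decreasing")

    def g(effect: float) -> float:
        term_a = dose_a / _inverse_dose(fit_a, effect)
        term_b = dose_b / _inverse_dose(fit_b, effect)
        return term_a + term_b - 1.0

    floors = [f.plateau for f in (fit_a, fit_b) if f.fit_type == "sigmoid"]
    lo = min(floors) if floors else 100.0
    hi = 100.0
    if lo >= hi:  # both margins flat: additive expectation is no effect
        return 100.0, False
    # g is increasing in effect; no root above the attainable floor means
    # the additive prediction saturates below both plateaus.
    if g(lo + tol) > 0:
        return float(lo), True
    lo_e, hi_e = lo + tol, hi - tol
    for _ in range(200):
        mid = 0.5 * (lo_e + hi_e)
        if g(mid) < 0:
            lo_e = mid
        else:
            hi_e = mid
        if hi_e - lo_e < tol:
            break
    return 0.5 * (lo_e + hi_e), False


def synergy_matrix(grid: SynergyGrid, *, flat_test_alpha: float = 0.05) -> SynergyGrid:
    """Fill a grid's Loewe-expected, synergy and mean_synergy fields.

    synergy[i, j] = expected - observed (positive = synergistic kill);
    mean_synergy averages the cells where both doses are nonzero.
    """
    if grid.fit_a is None or grid.fit_b is None:
        fit_single_agents(grid, flat_test_alpha=flat_test_alpha)
    expected = grid.observed.copy() * np.nan
    extrap = grid.observed.copy().astype(bool) & False
    for da in grid.doses_a:
        for db in grid.doses_b:
            e, flag = loewe_expected(grid.fit_a, grid.fit_b, float(da), float(db))
            expected.loc[da, db] = e
            extrap.loc[da, db] = flag
    synergy = expected - grid.observed
    interior = np.ix_(grid.doses_a > 0, grid.doses_b > 0)
    grid.expected_loewe = expected
    grid.synergy = synergy
    grid.extrapolated = extrap
    grid.mean_synergy = float(synergy.to_numpy()[interior].mean())
    return grid


def mean_synergy_se(grid: SynergyGrid, *, n_boot: int = 50, seed: int = 0) -> float:
    """Standard error of mean_synergy derived from the replicate spread.

    Parametric bootstrap: every cell mean (margins included) is perturbed
    by a normal draw with its replicate s.e.m., the single-agent margins
    are refitted and the Loewe surface recomputed. This propagates
    margin-fit uncertainty, which dominates the error of the expected
    surface and which the per-cell s.e.m. alone would miss.
    """
    if grid.mean_synergy is None:
        synergy_matrix(grid)
    rng = np.random.default_rng(seed)
    obs = grid.observed.to_numpy()
    sem = np.nan_to_num(grid.observed_sem.to_numpy())
    idx_a, idx_b = grid.observed.index, grid.observed.columns
    boots = []
    for _ in range(n_boot):
        perturbed = pd.DataFrame(obs + rng.standard_normal(obs.shape) * sem,
                                 index=idx_a, columns=idx_b)
        bgrid = SynergyGrid(grid.drug_a, grid.drug_b, grid.doses_a, grid.doses_b,
                            perturbed, grid.observed_sem)
        try:
            synergy_matrix(bgrid)
        except ValueError:
            continue
        boots.append(bgrid.mean_synergy)
    if len(boots) < 2:
        raise RuntimeError("bootstrap failed to produce replicates")
    return float(np.std(boots, ddof=1))
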