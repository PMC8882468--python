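"""Cross-screen analytics on GR_aoc metric tables.

Covers ranking of models and drugs, unsupervised clustering of the
model x drug GR_aoc matrix, subtype and drug-class group comparisons
(Mann-Whitney with Hodges-Lehmann shifts), GR50-vs-GI50 concordance with
a faster/slower-grower residual analysis, replicate reproducibility, and
clinical benefit ratios against the MOSCATO-01-style 1.3 PFS benchmark.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .stats import GroupTestResult, mann_whitney_hl


@dataclasses.dataclass
class ScreenMatrix:
    """Model x drug GR_aoc matrix plus model/drug annotations."""

    graoc: pd.DataFrame                    # index: model_id, columns: drug_id
    model_labels: pd.Series | None = None  # e.g. subtype per model
    drug_labels: pd.Series | None = None   # e.g. drug class per drug

    @classmethod
    def from_metrics(cls, metrics: pd.DataFrame,
                     model_labels: pd.Series | None = None,
                     drug_labels: pd.Series | None = None) -> "ScreenMatrix":
        mat = metrics.pivot(index="model_id", columns="drug_id", values="GR_aoc")
        return cls(mat, model_labels, drug_labels)


def rank_models_by_drug(matrix: ScreenMatrix, drug_id: str) -> pd.Series:
    """Models ordered by GR_aoc for one drug, most cytotoxic first.

    Ties broken lexicographically by model_id (stable).
    """
    if drug_id not in matrix.graoc.columns:
        raise KeyError(f"unknown drug {drug_id!r}")
    col = matrix.graoc[drug_id].sort_index()
    return col.sort_values(ascending=False, kind="stable")


def rank_drugs_within_model(matrix: ScreenMatrix, model_id: str) -> pd.Series:
    """Rank of each drug within one model; rank 1 = highest GR_aoc.

    Tied drugs share the average rank.
    """
    if model_id not in matrix.graoc.index:
        raise KeyError(f"unknown model {model_id!r}")
    row = matrix.graoc.loc[model_id]
    return row.rank(ascending=False, method="average")


def group_compare_graoc(matrix: ScreenMatrix, group1: list[str], group2: list[str],
                        drug_set: list[str] | None = None) -> GroupTestResult:
    """Mann-Whitney on pooled per-(model, drug) GR_aoc of two model groups.

    Used e.g. for chemotherapy activity in TNBC vs non-TNBC lines; values
    are pooled across the drug set, not averaged per model.
    """
    if not group1 or not group2:
        raise ValueError("both model groups must be nonempty")
    drugs = list(matrix.graoc.columns) if drug_set is None else list(drug_set)
    unknown = set(drugs) - set(matrix.graoc.columns)
    if unknown:
        raise KeyError(f"unknown drugs {sorted(unknown)}")
    x = matrix.graoc.loc[list(group1), drugs].to_numpy().ravel()
    y = matrix.graoc.loc[list(group2), drugs].to_numpy().ravel()
    return mann_whitney_hl(x[np.isfinite(x)], y[np.isfinite(y)])


def class_rank_compare(matrix: ScreenMatrix, drug_class_drugs: list[str],
                       group1: list[str], group2: list[str]) -> GroupTestResult:
    """Compare the within-model rank positions of a drug class between groups.

    For each model the class drugs' rank positions (1 = most sensitive by
    GR_aoc) are collected; the two model groups' rank samples are compared
    by a two-sided Mann-Whitney with the Hodges-Lehmann shift in rank units.
    """
    if not drug_class_drugs:
        raise ValueError("drug class has no drugs")

    def collect(models: list[str]) -> np.ndarray:
        vals = []
        for m in models:
            ranks = rank_drugs_within_model(matrix, m)
            vals.extend(ranks[d] for d in drug_class_drugs)
        return np.asarray(vals, dtype=float)

    return mann_whitney_hl(collect(list(group1)), collect(list(group2)))


@dataclasses.dataclass
class ConcordanceResult:
    """GR50 vs GI50 agreement across a screen."""

    pearson_r: float              # on log10 concentrations, complete cases
    slope: float
    intercept: float
    residuals: pd.DataFrame       # model_id, drug_id, residual (log10 units)
    slow_fast_test: GroupTestResult
    n_pairs: int


def gr_gi_concordance(metrics: pd.DataFrame, doubling_times: pd.Series) -> ConcordanceResult:
    """Concordance of GR50 with GI50 and the growth-rate residual analysis.

    Complete-case pairs (both metrics non-NA) enter a log10-log10 Pearson
    correlation and OLS line of log10 GI50 on log10 GR50; models are split
    into faster/slower growers at the median doubling time and the
    regression residuals compared by Mann-Whitney. A non-significant test
    means the GR-adjusted metric does not inflate potency in slow growers.
    """
    ok = metrics.dropna(subset=["GR50", "GI50"]).copy()
    if len(ok) < 3:
        raise ValueError("need >= 3 complete (GR50, GI50) pairs")
    lx = np.log10(ok["GR50"].to_numpy())
    ly = np.log10(ok["GI50"].to_numpy())
    r = float(sps.pearsonr(lx, ly).statistic)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    residuals = pd.DataFrame({
        "model_id": ok["model_id"].to_numpy(),
        "drug_id": ok["drug_id"].to_numpy(),
        "residual": resid,
    })
    dt = doubling_times.reindex(residuals["model_id"]).to_numpy()
    if np.isnan(dt).any():
        missing = sorted(set(residuals["model_id"]) - set(doubling_times.index))
        raise KeyError(f"missing doubling times for models {missing}")
    slow = resid[dt > np.median(doubling_times)]
    fast = resid[dt <= np.median(doubling_times)]
    test = mann_whitney_hl(slow, fast)
    return ConcordanceResult(r, float(slope), float(intercept), residuals, test, len(ok))


def growth_rate_bias_test(metrics: pd.DataFrame, doubling_times: pd.Series,
                          metric: str = "GR50") -> GroupTestResult:
    """Does a potency metric depend on how fast a line grows?

    For each drug, log10 of the chosen metric is centered on the drug's
    across-model mean (removing drug-to-drug potency differences); models
    are split into slower/faster growers at the median doubling time and
    the centered values compared by a two-sided Mann-Whitney (slow group
    first, so a positive Hodges-Lehmann shift means the metric makes slow
    growers look *less* sensitive). A growth-rate-invariant metric such as
    GR50 should be non-significant; endpoint metrics (GI50, IC50) carry a
    systematic positive shift.
    """
    ok = metrics.dropna(subset=[metric]).copy()
    ok = ok[ok[metric] > 0]
    ok["log_metric"] = np.log10(ok[metric])
    ok["centered"] = ok["log_metric"] - ok.groupby("drug_id")["log_metric"].transform("mean")
    # aggregate to one value per model: models, not wells, are the
    # independent units, and pooling per-(model, drug) points would let
    # shared per-drug noise masquerade as replication
    per_model = ok.groupby("model_id")["centered"].mean()
    dt = doubling_times.reindex(per_model.index)
    if dt.isna().any():
        missing = sorted(set(per_model.index) - set(doubling_times.index))
        raise KeyError(f"missing doubling times for models {missing}")
    cutoff = float(np.median(doubling_times))
    slow = per_model[dt > cutoff].to_numpy()
    fast = per_model[dt <= cutoff].to_numpy()
    return mann_whitney_hl(slow, fast)


@dataclasses.dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_screen(matrix: ScreenMatrix) -> ClusterResult:
    """Agglomerative clustering of models and drugs on the GR_aoc matrix.

    Euclidean distance, average linkage, no scaling; deterministic for a
    given matrix and invariant in topology to input row order.
    """
    mat = matrix.graoc
    if mat.isna().to_numpy().any():
        raise ValueError("GR_aoc matrix contains NA; impute or drop before clustering")

    def one_axis(frame: pd.DataFrame) -> tuple[list[str], np.ndarray]:
        # sort labels first so the linkage is independent of input order
        frame = frame.sort_index()
        labels = list(frame.index)
        if len(labels) == 1:
            return labels, np.empty((0, 4))
        link = hierarchy.linkage(pdist(frame.to_numpy()), method="average")
        order = hierarchy.leaves_list(link)
        return [labels[i] for i in order], link

    row_order, row_link = one_axis(mat)
    col_order, col_link = one_axis(mat.T)
    return ClusterResult(row_order, col_order, row_link, col_link)


@dataclasses.dataclass
class ReproducibilityResult:
    pairwise_correlations: pd.DataFrame  # rep_a, rep_b, pearson_r on GR_aoc
    cv_table: pd.DataFrame               # model_id, drug_id, mean, sd, cv


def replicate_reproducibility(per_rep_metrics: pd.DataFrame) -> ReproducibilityResult:
    """Cross-replicate agreement of GR_aoc from per-bio-rep scoring.

    ``per_rep_metrics`` is the output of ``score_screen(per_bio_rep=True)``.
    """
    reps = sorted(per_rep_metrics["bio_rep"].unique())
    if len(reps) < 2:
        raise ValueError("need >= 2 replicate metric sets")
    wide = per_rep_metrics.pivot_table(index=["model_id", "drug_id"],
                                       columns="bio_rep", values="GR_aoc")
    rows = []
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            pair = wide[[a, b]].dropna()
            r = float(sps.pearsonr(pair[a], pair[b]).statistic)
            rows.append({"rep_a": a, "rep_b": b, "pearson_r": r})
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    cv = (sd / mean.abs()).rename("cv")
    cv_table = pd.concat([mean.rename("mean"), sd.rename("sd"), cv], axis=1).reset_index()
    return ReproducibilityResult(pd.DataFrame(rows), cv_table)


@dataclasses.dataclass
class ClinicalCourse:
    """Durations (days) achieved on one line of therapy."""

    therapy: str
    pfs_days: float
    ttnt_days: float | None = None

    def __post_init__(self) -> None:
        if self.pfs_days <= 0:
            raise ValueError("PFS must be positive")
        if self.ttnt_days is not None:
            if self.ttnt_days <= 0:
                raise ValueError("TTNT must be positive")
            if self.ttnt_days < self.pfs_days:
                raise ValueError("TTNT cannot precede PFS")


def clinical_benefit_ratio(new: ClinicalCourse, prior: ClinicalCourse,
                           benchmark: float = 1.3) -> dict:
    """PFS and TTNT ratios of a new therapy over the prior one.

    Ratios are reported at one decimal; ``meets_benchmark`` is whether the
    PFS ratio reaches the benchmark (1.3 per the MOSCATO-01 criterion).
    """
    out = {"pfs_ratio": round(new.pfs_days / prior.pfs_days, 1)}
    if new.ttnt_days is not None and prior.ttnt_days is not None:
        out["ttnt_ratio"] = round(new.ttnt_days / prior.ttnt_days, 1)
    else:
        out["ttnt_ratio"] = None
    out["meets_benchmark"] = bool(out["pfs_ratio"] >= benchmark)
    return out
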