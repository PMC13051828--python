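"""Cohort-level screens: co-expression, group tests and survival stratification.

The network targets are screened in patient cohorts three ways: a Spearman
correlation of each target with the driver lncRNA (positive co-expression is
the ceRNA-consistent direction), a Wilcoxon rank-sum comparison of tumour
versus normal plasma cells, and a median-split Kaplan-Meier / log-rank
screen of overall and progression-free survival.  All tests are two-sided;
direction is recorded separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortDataset",
    "CorrelationScreenResult",
    "SurvivalScreenResult",
    "spearman",
    "correlation_screen",
    "rank_sum_test",
    "kruskal_dunn",
    "median_split",
    "logrank_test",
    "survival_screen",
    "summarize_target_table",
]

logger = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ["os_time", "os_event", "pfs_time", "pfs_event"]


@dataclass
class CohortDataset:
    """Gene x patient expression with optional group labels and survival.

    ``expr`` is indexed by gene id with one column per patient;
    ``survival`` (if present) is indexed by patient id with columns
    os_time, os_event, pfs_time, pfs_event (times in months, events 0/1).
    """

    expr: pd.DataFrame
    groups: pd.Series | None = None
    survival: pd.DataFrame | None = None
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if self.survival is not None:
            missing = [c for c in SURVIVAL_COLUMNS if c not in self.survival.columns]
            if missing:
                raise ValueError(f"survival table missing columns: {missing}")
            s = self.survival
            if (s[["os_time", "pfs_time"]] < 0).any().any():
                raise ValueError("survival times must be non-negative")
            if not s[["os_event", "pfs_event"]].isin([0, 1]).all().all():
                raise ValueError("event indicators must be 0/1")

    @property
    def patients(self) -> pd.Index:
        return self.expr.columns

    def write_tsv(self, expr_path: str | Path, survival_path: str | Path | None = None) -> None:
        self.expr.to_csv(expr_path, sep="\t", index_label="gene_id")
        if survival_path is not None and self.survival is not None:
            self.survival.to_csv(survival_path, sep="\t", index_label="patient_id")

    @classmethod
    def read_tsv(
        cls,
        expr_path: str | Path,
        survival_path: str | Path | None = None,
        cohort_label: str = "",
    ) -> "CohortDataset":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        survival = None
        if survival_path:
            survival = pd.read_csv(survival_path, sep="\t", index_col=0)
        return cls(expr, survival=survival, cohort_label=cohort_label)


@dataclass
class CorrelationScreenResult:
    """Per-target Spearman statistics against the driver, one cohort."""

    table: pd.DataFrame  # index gene_id; columns rho, p, n, significant_positive
    cohort_label: str = ""

    @property
    def significant_positive(self) -> list[str]:
        flag = self.table["significant_positive"].fillna(False)
        return sorted(self.table.index[flag.astype(bool)])


@dataclass
class SurvivalScreenResult:
    """Per-gene log-rank p-values for OS and PFS with direction flags."""

    table: pd.DataFrame
    # columns: os_p, pfs_p, os_high_worse, pfs_high_worse, note
    cohort_label: str = ""


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Uses midranks for ties and drops incomplete pairs; raises on a constant
    vector (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    p = max(float(p), np.finfo(float).tiny)  # rho = +/-1 -> numerical floor
    return float(rho), p, n


def correlation_screen(
    cohort: CohortDataset,
    driver: str,
    targets,
    alpha: float = 0.05,
) -> CorrelationScreenResult:
    """Spearman screen of each target against the driver across patients.

    Targets absent from the platform get a missing row (rho/p NaN) and a
    warning, mirroring array platforms that lack probes for some genes.
    ``significant_positive`` requires rho > 0 and two-sided p < alpha.
    """
    if driver not in cohort.expr.index:
        raise ValueError(f"driver {driver!r} absent from the expression matrix")
    d = cohort.expr.loc[driver].to_numpy(dtype=float)
    rows = {}
    for g in sorted(set(targets)):
        if g not in cohort.expr.index:
            logger.warning(
                "target %s absent from cohort %s", g, cohort.cohort_label
            )
            rows[g] = (np.nan, np.nan, 0, np.nan)
            continue
        rho, p, n = spearman(d, cohort.expr.loc[g].to_numpy(dtype=float))
        rows[g] = (rho, p, n, bool(rho > 0 and p < alpha))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["rho", "p", "n", "significant_positive"]
    )
    table.index.name = "gene_id"
    return CorrelationScreenResult(table, cohort.cohort_label)


def rank_sum_test(a, b) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test (normal approximation, midranks,
    tie-corrected variance, no continuity correction).

    Returns (rank sum of ``a``, p, direction) where direction names the
    group with the larger rank mean ('a', 'b', or 'tie').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical across both groups")
    ranks = stats.rankdata(pooled)
    w_a = float(ranks[: len(a)].sum())
    mean_a = ranks[: len(a)].mean()
    mean_b = ranks[len(a):].mean()
    _, p = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    if mean_a > mean_b:
        direction = "a"
    elif mean_b > mean_a:
        direction = "b"
    else:
        direction = "tie"
    return w_a, float(p), direction


def kruskal_dunn(
    groups: list, adjust: str = "none"
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z post-hoc.

    Dunn's z for groups i, j uses the pooled midranks:
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided p per pair, optionally
    Benjamini-Hochberg adjusted.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    n = np.array([len(g) for g in arrays])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    if np.ptp(pooled) == 0:
        h, p_global = 0.0, 1.0
    else:
        h, p_global = stats.kruskal(*arrays)
    # Dunn pairwise table on the pooled ranks
    offsets = np.concatenate([[0], np.cumsum(n)])
    rbar = np.array(
        [ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(arrays))]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(base_var * (1.0 / n[i] + 1.0 / n[j]))
            z = 0.0 if se == 0 else (rbar[i] - rbar[j]) / se
            rows.append((i, j, z, 2 * stats.norm.sf(abs(z))))
    pairwise = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"])
    if adjust == "bh" and len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return float(h), float(p_global), pairwise


def median_split(values) -> np.ndarray:
    """Label each value 'low' (<= median) or 'high' (> median)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError(f"need at least 4 values for a median split, got {len(v)}")
    med = float(np.median(v))
    labels = np.where(v <= med, "low", "high")
    if len(np.unique(labels)) < 2:
        raise ValueError("median split leaves one group empty (constant values?)")
    return labels


def logrank_test(times, events, labels) -> tuple[float, float]:
    """Two-group log-rank test (standard hypergeometric formulation).

    Returns (chi-square statistic on 1 df, p-value).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    if not (len(times) == len(events) == len(labels)):
        raise ValueError("times, events and labels must have equal length")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    m = labels == uniq[0]
    res = _lifelines_logrank(
        times[m], times[~m], event_observed_A=events[m], event_observed_B=events[~m]
    )
    return float(res.test_statistic), float(res.p_value)


def _km_final_survival(times, events) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return float(kmf.survival_function_.iloc[-1, 0])


def survival_screen(cohort: CohortDataset, genes) -> SurvivalScreenResult:
    """Median-split log-rank screen of OS and PFS for each gene.

    Per gene, patients are stratified at the median expression; OS and PFS
    are compared between strata by the log-rank test.  ``*_high_worse``
    records whether the high-expression stratum has the lower Kaplan-Meier
    survival at end of follow-up.  Genes whose split or test fails are
    reported with NaN p-values and a note.
    """
    if cohort.survival is None:
        raise ValueError("cohort has no survival records")
    surv = cohort.survival.loc[cohort.patients.intersection(cohort.survival.index)]
    rows = {}
    for g in sorted(set(genes)):
        if g not in cohort.expr.index:
            rows[g] = (np.nan, np.nan, np.nan, np.nan, "absent from platform")
            logger.warning("gene %s absent from cohort %s", g, cohort.cohort_label)
            continue
        try:
            expr = cohort.expr.loc[g, surv.index].to_numpy(dtype=float)
            labels = median_split(expr)
            out = []
            for endpoint in ("os", "pfs"):
                t = surv[f"{endpoint}_time"].to_numpy()
                e = surv[f"{endpoint}_event"].to_numpy()
                _, p = logrank_test(t, e, labels)
                hi = labels == "high"
                high_worse = _km_final_survival(t[hi], e[hi]) < _km_final_survival(
                    t[~hi], e[~hi]
                )
                out.extend([p, bool(high_worse)])
            rows[g] = (out[0], out[2], out[1], out[3], "")
        except ValueError as exc:
            rows[g] = (np.nan, np.nan, np.nan, np.nan, str(exc))
            logger.warning("gene %s skipped in survival screen: %s", g, exc)
    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["os_p", "pfs_p", "os_high_worse", "pfs_high_worse", "note"],
    )
    table.index.name = "gene_id"
    return SurvivalScreenResult(table, cohort.cohort_label)


def summarize_target_table(
    upreg_flags, surv, alpha: float = 0.05
) -> tuple[int, int, int]:
    """Target-table summary counts.

    Returns (number of targets flagged upregulated in tumour vs normal,
    number with both OS and PFS log-rank p < alpha, number with at least
    one of the two).  ``surv`` may be a SurvivalScreenResult or a DataFrame
    with os_p / pfs_p columns (e.g., a transcribed published table).
    """
    table = surv.table if isinstance(surv, SurvivalScreenResult) else surv
    flags = pd.Series(upreg_flags).fillna(False).astype(bool)
    n_up = int(flags.sum())
    os_sig = table["os_p"] < alpha
    pfs_sig = table["pfs_p"] < alpha
    n_both = int((os_sig & pfs_sig).sum())
    n_any = int((os_sig | pfs_sig).sum())
    return n_up, n_both, n_any
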