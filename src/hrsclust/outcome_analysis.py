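"""Between-cluster comparisons and in-hospital mortality odds ratios.

Clusters are compared with the classical battery: one-way ANOVA for
continuous variables, Pearson chi-square (no continuity correction) for
categorical ones, and odds ratios for in-hospital death from 2×2 tables
against the lowest-mortality cluster as the reference.  Confidence
intervals use Woolf's log-OR normal approximation,
exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).  No covariate adjustment is
applied: the cluster assignments were derived from those same covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "TwoByTwo",
    "OddsRatioResult",
    "odds_ratio",
    "mortality_by_cluster",
    "reference_cluster",
    "odds_ratios_vs_reference",
    "chisq_homogeneity",
    "anova_oneway",
    "compare_clusters_table",
    "round_half_away",
]

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class TwoByTwo:
    """Deaths/survivors in an index cluster vs a reference cluster."""

    a: int  # deaths, index cluster
    b: int  # survivors, index cluster
    c: int  # deaths, reference cluster
    d: int  # survivors, reference cluster

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each cluster must contain at least one admission")


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    log_or_se: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.or_point <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")


def odds_ratio(
    t: TwoByTwo, level: float = 0.95, continuity_correction: bool = False
) -> OddsRatioResult:
    """Cross-product odds ratio with a Woolf confidence interval.

    A zero cell makes the OR or its SE degenerate; with
    ``continuity_correction`` the Haldane–Anscombe 0.5 is added to every
    cell (logged), otherwise a zero cell is an error.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0.0:
        if not continuity_correction:
            raise ValueError(
                "zero cell in 2x2 table; enable continuity_correction"
            )
        logger.info("zero cell: adding Haldane-Anscombe 0.5 to all cells")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return OddsRatioResult(
        or_point=point,
        ci_low=point * math.exp(-z * se),
        ci_high=point * math.exp(z * se),
        log_or_se=se,
        level=level,
    )


def mortality_by_cluster(
    cohort: CohortTable, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-cluster death counts/fractions/rounded percents, plus overall."""
    if cohort.outcome is None:
        raise ValueError("cohort has no outcome column")
    labels = np.asarray(labels)
    if labels.shape[0] != cohort.n_admissions:
        raise ValueError("labels must align with cohort rows")
    outcome = cohort.outcome.to_numpy()
    if not np.isin(outcome, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    rows = []
    for c in np.unique(labels):
        mask = labels == c
        deaths = int(outcome[mask].sum())
        n = int(mask.sum())
        rows.append(
            {
                "cluster": int(c),
                "n": n,
                "deaths": deaths,
                "fraction": deaths / n,
                "percent": round_half_away(100.0 * deaths / n),
            }
        )
    total_n = int(len(outcome))
    total_deaths = int(outcome.sum())
    rows.append(
        {
            "cluster": "overall",
            "n": total_n,
            "deaths": total_deaths,
            "fraction": total_deaths / total_n,
            "percent": round_half_away(100.0 * total_deaths / total_n),
        }
    )
    return pd.DataFrame(rows).set_index("cluster")


def reference_cluster(mortality: pd.DataFrame) -> int:
    """Lowest-mortality cluster (ties to the lower label) — the reference."""
    per_cluster = mortality.drop(index="overall", errors="ignore")
    fractions = per_cluster["fraction"]
    best = fractions.min()
    candidates = sorted(int(c) for c in per_cluster.index[fractions == best])
    return candidates[0]


def odds_ratios_vs_reference(
    cohort: CohortTable,
    labels: np.ndarray | pd.Series,
    reference: int | None = None,
    level: float = 0.95,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """In-hospital mortality OR of every cluster against the reference.

    Without an explicit reference, the lowest-mortality cluster is used.
    """
    mort = mortality_by_cluster(cohort, labels)
    if reference is None:
        reference = reference_cluster(mort)
    per = mort.drop(index="overall")
    if reference not in per.index:
        raise ValueError(f"reference cluster {reference} not present")
    c = int(per.loc[reference, "deaths"])
    d = int(per.loc[reference, "n"] - per.loc[reference, "deaths"])
    rows = []
    for cluster in per.index:
        if cluster == reference:
            rows.append(
                {
                    "cluster": int(cluster),
                    "odds_ratio": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "reference": True,
                }
            )
            continue
        a = int(per.loc[cluster, "deaths"])
        b = int(per.loc[cluster, "n"] - per.loc[cluster, "deaths"])
        res = odds_ratio(
            TwoByTwo(a, b, c, d), level=level, continuity_correction=continuity_correction
        )
        rows.append(
            {
                "cluster": int(cluster),
                "odds_ratio": res.or_point,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "reference": False,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def chisq_homogeneity(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test for homogeneity of an r×c count table."""
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (observed < 0).any():
        raise ValueError("counts must be >= 0")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = stats.chi2_contingency(observed, correction=False)
    return float(stat), int(dof), float(p)


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA F test across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in arrays):
        raise ValueError("every group needs at least one value")
    n_total = sum(len(g) for g in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))
    grand = np.concatenate(arrays)
    if np.all(grand == grand[0]):
        return 0.0, df, 1.0
    stat, p = stats.f_oneway(*arrays)
    if math.isnan(stat):  # e.g. zero within-group variance handled upstream
        return float("nan"), df, float("nan")
    return float(stat), df, float(p)


def compare_clusters_table(
    cohort: CohortTable, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Characteristics-by-cluster summary in the familiar "Table 1" layout.

    One row per variable (categorical variables one row per level): overall
    column first, then per-cluster "count (percent)" for indicators or
    "mean ± SD" for continuous variables, then the chi-square or ANOVA
    p-value.  Degenerate (constant) variables get "n/a" instead of a test;
    a single cluster yields summaries without p-values.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != cohort.n_admissions:
        raise ValueError("labels must align with cohort rows")
    clusters = [int(c) for c in np.unique(labels)]
    masks = {c: labels == c for c in clusters}
    single = len(clusters) < 2

    def fmt_count(series: pd.Series) -> str:
        count = int(series.sum())
        pct = round_half_away(100.0 * count / max(len(series), 1))
        return f"{count} ({pct:.0f})"

    def fmt_mean(series: pd.Series) -> str:
        sd = series.std(ddof=1) if len(series) > 1 else 0.0
        return f"{series.mean():.1f} ± {sd:.1f}"

    rows = []

    def add_row(name: str, kind: str, col: pd.Series) -> None:
        fmt = fmt_count if kind == "binary" else fmt_mean
        row = {"variable": name, "overall": fmt(col)}
        for c in clusters:
            row[f"cluster {c}"] = fmt(col[masks[c]])
        if single:
            row["p"] = ""
        elif kind == "binary":
            counts = np.array(
                [
                    [col[masks[c]].sum(), (1 - col[masks[c]]).sum()]
                    for c in clusters
                ],
                dtype=float,
            )
            if (counts.sum(axis=0) == 0).any():
                row["p"] = "n/a"  # variable constant everywhere
            else:
                _, _, p = chisq_homogeneity(counts)
                row["p"] = f"{p:.3g}"
        else:
            groups = [col[masks[c]].to_numpy(dtype=float) for c in clusters]
            stat, _, p = anova_oneway(groups)
            row["p"] = "n/a" if math.isnan(p) else f"{p:.3g}"
        rows.append(row)

    for spec in cohort.variables:
        col = cohort.data[spec.name]
        if spec.kind == "binary":
            add_row(spec.name, "binary", col.astype(float))
        elif spec.kind == "categorical":
            for level in spec.levels:
                add_row(f"{spec.name}: {level}", "binary", (col == level).astype(float))
        else:
            add_row(spec.name, "continuous", col.astype(float))

    if cohort.outcome is not None:
        add_row(cohort.outcome_name, "binary", cohort.outcome.astype(float))

    return pd.DataFrame(rows).set_index("variable")
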