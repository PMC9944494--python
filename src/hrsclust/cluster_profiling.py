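"""Key-feature identification by standardized mean difference (SMD).

Each cluster is contrasted against the pooled remaining admissions, one SMD
per (cluster, variable); |SMD| above a cutoff (0.3 by default) flags the
variable as a key feature of that cluster.  Binary variables use the
two-proportion pooled-variance form, continuous variables Cohen's d with
the same variance pooling; both are scale-free, so a feature's flag does
not depend on its units.  A pairwise-maximum contrast (the largest |SMD|
against any single other cluster) is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = ["SMDRecord", "smd_binary", "smd_continuous", "key_features"]

DEFAULT_CUTOFF = 0.3


@dataclass(frozen=True)
class SMDRecord:
    cluster: int
    variable: str
    smd: float  # NaN when degenerate (both group variances zero)
    flagged: bool
    group_summary: dict

    def __post_init__(self) -> None:
        if not math.isnan(self.smd) and not math.isfinite(self.smd):
            raise ValueError("smd must be finite or NaN")


def smd_binary(p1: float, n1: int, p2: float, n2: int) -> float:
    """SMD between two proportions: (p1 − p2) / sqrt((p1(1−p1)+p2(1−p2))/2).

    Equal proportions give 0 even when both variances vanish; two degenerate
    but different proportions (0 vs 1) have no finite standardization and
    return NaN.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if p1 == p2:
        return 0.0
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0.0:
        return float("nan")
    return (p1 - p2) / math.sqrt(pooled)


def smd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with variance pooling: (m1 − m2) / sqrt((s1² + s2²)/2)."""
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be >= 0")
    if m1 == m2:
        return 0.0
    pooled = (s1 * s1 + s2 * s2) / 2.0
    if pooled == 0.0:
        return float("nan")
    return (m1 - m2) / math.sqrt(pooled)


def _expanded_columns(cohort: CohortTable) -> list[tuple[str, str, pd.Series]]:
    """(display name, kind, column) with categoricals expanded per level."""
    out = []
    for spec in cohort.variables:
        col = cohort.data[spec.name]
        if spec.kind == "binary":
            out.append((spec.name, "binary", col.astype(float)))
        elif spec.kind == "categorical":
            for level in spec.levels:
                out.append(
                    (f"{spec.name}={level}", "binary", (col == level).astype(float))
                )
        else:
            out.append((spec.name, "continuous", col.astype(float)))
    return out


def key_features(
    cohort: CohortTable,
    labels: np.ndarray | pd.Series,
    cutoff: float = DEFAULT_CUTOFF,
    contrast: str = "rest",
) -> list[SMDRecord]:
    """Per-cluster SMD of every variable, sorted by |SMD| within cluster.

    ``contrast="rest"`` (default) compares each cluster against all other
    admissions pooled; ``contrast="pairwise_max"`` reports, per variable,
    the pairwise SMD of largest magnitude against any single other cluster.
    """
    if contrast not in ("rest", "pairwise_max"):
        raise ValueError("contrast must be 'rest' or 'pairwise_max'")
    labels = np.asarray(labels)
    if labels.shape[0] != cohort.n_admissions:
        raise ValueError("labels must align with cohort rows")
    clusters = np.unique(labels)
    for c in clusters:
        if (labels == c).sum() == 0:
            raise ValueError(f"cluster {c} is empty")

    columns = _expanded_columns(cohort)
    records: list[SMDRecord] = []
    for c in clusters:
        in_c = labels == c
        cluster_records = []
        for name, kind, col in columns:
            vals = col.to_numpy(dtype=float)
            if contrast == "rest":
                contrasts = [(vals[in_c], vals[~in_c], "rest")]
            else:
                contrasts = [
                    (vals[in_c], vals[labels == other], f"cluster {other}")
                    for other in clusters
                    if other != c
                ]
            best = None
            for g1, g2, other_name in contrasts:
                if len(g2) == 0:
                    continue
                if kind == "binary":
                    p1, p2 = float(g1.mean()), float(g2.mean())
                    value = smd_binary(p1, len(g1), p2, len(g2))
                    summary = {
                        "contrast": other_name,
                        "p1": p1,
                        "n1": len(g1),
                        "p2": p2,
                        "n2": len(g2),
                    }
                else:
                    m1, m2 = float(g1.mean()), float(g2.mean())
                    s1 = float(g1.std(ddof=1)) if len(g1) > 1 else 0.0
                    s2 = float(g2.std(ddof=1)) if len(g2) > 1 else 0.0
                    value = smd_continuous(m1, s1, m2, s2)
                    summary = {
                        "contrast": other_name,
                        "mean1": m1,
                        "sd1": s1,
                        "n1": len(g1),
                        "mean2": m2,
                        "sd2": s2,
                        "n2": len(g2),
                    }
                if best is None or (
                    not math.isnan(value)
                    and (math.isnan(best[0]) or abs(value) > abs(best[0]))
                ):
                    best = (value, summary)
            if best is None:  # single cluster: nothing to contrast against
                best = (float("nan"), {"contrast": None})
            value, summary = best
            flagged = (not math.isnan(value)) and abs(value) > cutoff
            cluster_records.append(
                SMDRecord(
                    cluster=int(c),
                    variable=name,
                    smd=value,
                    flagged=flagged,
                    group_summary=summary,
                )
            )
        cluster_records.sort(
            key=lambda r: (-abs(r.smd) if not math.isnan(r.smd) else math.inf)
        )
        records.extend(cluster_records)
    return records


def smd_table(records: list[SMDRecord]) -> pd.DataFrame:
    """Flat table of SMD records for CSV export or plotting."""
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster,
                "variable": r.variable,
                "smd": r.smd,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )
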