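"""Cluster-number diagnostics and the k-selection rule.

Four diagnostics are computed from each candidate k's consensus matrix:

* the empirical CDF of the off-diagonal consensus values (a stable k pushes
  mass to 0 and 1, flattening the CDF's middle);
* the area under that CDF, A(k), and its relative increase from k−1,
  Δ(k) — the "delta area" elbow;
* the proportion of ambiguously clustered pairs, PAC: the fraction of pairs
  whose consensus value falls strictly inside predetermined boundaries
  (0.1, 0.9 by default) — lower is more stable;
* per-cluster consensus scores: the mean consensus value over each assigned
  cluster's within-cluster pairs — closer to 1 is more stable.

The published workflow selects k by jointly eyeballing these plots; here
that judgment is operationalized as a deterministic rule (documented in
:func:`select_optimal_k`) so that the choice is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus_core import ConsensusMatrix, assign_final_clusters

__all__ = [
    "ConsensusCDF",
    "SelectionDiagnostics",
    "consensus_cdf",
    "cdf_area",
    "delta_area",
    "pac",
    "cluster_consensus_scores",
    "compute_diagnostics",
    "select_optimal_k",
]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusCDF:
    """Right-continuous empirical CDF of off-diagonal consensus values."""

    sorted_values: np.ndarray  # ascending, in [0, 1]

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        """F(x) = fraction of values <= x."""
        m = len(self.sorted_values)
        if m == 0:
            return np.ones_like(np.asarray(x, dtype=float))
        return np.searchsorted(self.sorted_values, x, side="right") / m


def consensus_cdf(cm: ConsensusMatrix) -> ConsensusCDF:
    """Empirical CDF over the upper-triangle off-diagonal entries.

    The diagonal is excluded: self-pairs always have consensus 1 and would
    inflate apparent stability.
    """
    if cm.n_items < 2:
        raise ValueError("need at least 2 items for a consensus CDF")
    return ConsensusCDF(sorted_values=np.sort(cm.offdiagonal_values()))


def cdf_area(cdf: ConsensusCDF) -> float:
    """Area under the CDF over [0, 1], by the left-closed step integral.

    A = Σ_i (x_i − x_{i−1})·F(x_{i−1}) over the sorted unique values,
    closed with the (1 − x_last)·1 tail.  Equal to 1 − mean(values) for
    values supported on [0, 1]; a matrix of all-zeros consensus gives 1,
    all-ones gives 0.
    """
    v = cdf.sorted_values
    if len(v) == 0:
        return 1.0
    xs = np.concatenate(([0.0], np.unique(v), [1.0]))
    heights = cdf(xs[:-1])
    return float(np.sum(np.diff(xs) * heights))


def delta_area(areas: dict[int, float]) -> dict[int, float | None]:
    """Relative change in CDF area as k grows.

    Δ(k_min) = A(k_min); Δ(k) = (A(k) − A(k−1)) / A(k−1) for larger k.
    Requires a contiguous k range; a zero previous area makes Δ undefined
    (returned as None).
    """
    ks = sorted(areas)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("areas must cover a contiguous k range")
    out: dict[int, float | None] = {ks[0]: float(areas[ks[0]])}
    for k in ks[1:]:
        prev = areas[k - 1]
        if prev == 0:
            logger.warning("A(%d) = 0; delta area at k=%d is undefined", k - 1, k)
            out[k] = None
        else:
            out[k] = float((areas[k] - prev) / prev)
    return out


def pac(cm: ConsensusMatrix, x1: float = 0.1, x2: float = 0.9) -> float:
    """Proportion of ambiguously clustered pairs.

    The fraction of off-diagonal pairs whose consensus value lies strictly
    inside (x1, x2).  0 means every pair is decisively together or apart.
    """
    if not 0 <= x1 < x2 <= 1:
        raise ValueError("need 0 <= x1 < x2 <= 1")
    v = cm.offdiagonal_values()
    if len(v) == 0:
        return 0.0
    return float(np.mean((v > x1) & (v < x2)))


def cluster_consensus_scores(
    cm: ConsensusMatrix, labels: np.ndarray | None = None
) -> tuple[dict[int, float], float]:
    """Mean within-cluster consensus per assigned cluster, plus the mean.

    Singleton clusters have no within pairs and score 1 by convention
    (logged): a lone item is trivially always with itself.
    """
    if labels is None:
        labels = cm.labels
    if labels is None:
        raise ValueError("no labels: run assign_final_clusters first")
    labels = np.asarray(labels)
    if labels.shape[0] != cm.n_items:
        raise ValueError("labels must cover all items")
    scores: dict[int, float] = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            logger.info("cluster %d is a singleton; consensus score set to 1", c)
            scores[int(c)] = 1.0
            continue
        block = cm.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        scores[int(c)] = float(np.mean(block[iu]))
    return scores, float(np.mean(list(scores.values())))


@dataclass
class SelectionDiagnostics:
    """Per-k stability diagnostics and the selected cluster number."""

    k_values: list[int]
    areas: dict[int, float]
    deltas: dict[int, float | None]
    pac_values: dict[int, float]
    cluster_scores: dict[int, dict[int, float]]
    mean_scores: dict[int, float]
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    selected_k: int | None = None
    rationale: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.k_values:
            rows.append(
                {
                    "k": k,
                    "cdf_area": self.areas[k],
                    "delta_area": self.deltas[k],
                    "pac": self.pac_values[k],
                    "mean_cluster_consensus": self.mean_scores[k],
                    "cluster_consensus": ";".join(
                        f"{c}:{s:.4f}" for c, s in sorted(self.cluster_scores[k].items())
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("k")


def compute_diagnostics(
    matrices: dict[int, ConsensusMatrix],
    pac_bounds: tuple[float, float] = (0.1, 0.9),
) -> SelectionDiagnostics:
    """All per-k diagnostics for a family of consensus matrices.

    Final partitions are assigned (if not already) so that within-cluster
    consensus scores can be computed.
    """
    ks = sorted(matrices)
    areas: dict[int, float] = {}
    pacs: dict[int, float] = {}
    cscores: dict[int, dict[int, float]] = {}
    means: dict[int, float] = {}
    for k in ks:
        cm = matrices[k]
        areas[k] = cdf_area(consensus_cdf(cm))
        pacs[k] = pac(cm, *pac_bounds)
        if cm.labels is None:
            assign_final_clusters(cm)
        cscores[k], means[k] = cluster_consensus_scores(cm)
    return SelectionDiagnostics(
        k_values=ks,
        areas=areas,
        deltas=delta_area(areas),
        pac_values=pacs,
        cluster_scores=cscores,
        mean_scores=means,
        pac_bounds=pac_bounds,
    )


def select_optimal_k(
    diag: SelectionDiagnostics,
    pac_tolerance: float = 0.02,
    score_tolerance: float = 0.02,
    min_delta: float = 0.05,
) -> tuple[int, dict]:
    """Deterministic stand-in for the multi-criterion visual judgment.

    1. Candidates: every k whose PAC is within ``pac_tolerance`` of the
       minimum PAC (favorably low ambiguity).
    2. Among candidates, keep those whose mean within-cluster consensus is
       within ``score_tolerance`` of the candidates' best (comparable
       stability).
    3. Of the survivors, choose the LARGEST k whose delta area is at least
       ``min_delta`` (the finest clustering that still added meaningful CDF
       area); if none qualifies, the smallest survivor.

    Preferring the largest qualifying k encodes the published arbitration:
    when a coarse and a fine clustering are both favorably stable, the
    finer, more clinically resolved one is reported.  The selection and the
    values every rule saw are recorded on ``diag``.
    """
    ks = diag.k_values
    min_pac = min(diag.pac_values[k] for k in ks)
    candidates = [k for k in ks if diag.pac_values[k] <= min_pac + pac_tolerance]
    best_score = max(diag.mean_scores[k] for k in candidates)
    survivors = [
        k for k in candidates if diag.mean_scores[k] >= best_score - score_tolerance
    ]
    qualifying = [
        k
        for k in survivors
        if diag.deltas[k] is not None and diag.deltas[k] >= min_delta
    ]
    if qualifying:
        selected = max(qualifying)
        rule = "largest candidate with delta_area >= min_delta"
    else:
        selected = min(survivors)
        rule = "no candidate met min_delta; smallest surviving candidate"
    rationale = {
        "pac": dict(diag.pac_values),
        "mean_cluster_consensus": dict(diag.mean_scores),
        "delta_area": dict(diag.deltas),
        "min_pac": min_pac,
        "pac_candidates": candidates,
        "score_survivors": survivors,
        "delta_qualifying": qualifying,
        "rule": rule,
        "thresholds": {
            "pac_tolerance": pac_tolerance,
            "score_tolerance": score_tolerance,
            "min_delta": min_delta,
        },
    }
    diag.selected_k = selected
    diag.rationale = rationale
    return selected, rationale
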