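"""Resampled K-means consensus clustering.

For each candidate number of clusters k, the algorithm repeatedly draws a
random subsample of admissions (80% by default, without replacement),
partitions the subsample with K-means under Euclidean distance, and records
which pairs landed in the same cluster.  The consensus value M(i, j) is the
proportion of runs, among those that co-sampled admissions i and j, in
which the pair was co-clustered.  A stable clustering drives the consensus
values toward 0 or 1; intermediate values mark ambiguous pairs.

Defaults follow the reference analysis settings: k from 2 to 10, 100
iterations, item subsampling fraction 0.8, K-means with Euclidean distance.
Feature subsampling is supported but off by default (fraction 1.0): the
reference settings name a single subsampling fraction applied to items.

Reproducibility: one master seed spawns an independent substream per
(k, iteration), so results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .preprocessing import FeatureMatrix

__all__ = [
    "ConsensusConfig",
    "RunRecord",
    "ConsensusMatrix",
    "subsample_items",
    "kmeans_partition",
    "accumulate_consensus",
    "run_consensus",
    "assign_final_clusters",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusConfig:
    """Settings for the resampling loop."""

    k_min: int = 2
    k_max: int = 10
    iterations: int = 100
    item_fraction: float = 0.8
    feature_fraction: float = 1.0
    seed: int = 0
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if not (0 < self.item_fraction <= 1 and 0 < self.feature_fraction <= 1):
            raise ValueError("subsampling fractions must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class RunRecord:
    """One resampling run: which items were drawn and how they were labeled."""

    k: int
    iteration: int
    item_indices: np.ndarray  # distinct row indices into the full matrix
    labels: np.ndarray  # in 1..k, aligned with item_indices

    def __post_init__(self) -> None:
        self.item_indices = np.asarray(self.item_indices)
        self.labels = np.asarray(self.labels)
        if len(np.unique(self.item_indices)) != len(self.item_indices):
            raise ValueError("sampled indices must be distinct")
        if self.labels.shape != self.item_indices.shape:
            raise ValueError("labels must align with sampled indices")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError("labels must lie in 1..k")


@dataclass
class ConsensusMatrix:
    """n×n co-clustering proportions for one candidate k."""

    k: int
    matrix: np.ndarray  # float, symmetric, diagonal 1
    cosample_counts: np.ndarray  # runs in which both items were sampled
    labels: np.ndarray | None = None  # final partition (1..k), filled later

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]

    def offdiagonal_values(self) -> np.ndarray:
        """Upper-triangle consensus values, excluding the diagonal."""
        iu = np.triu_indices(self.n_items, k=1)
        return np.asarray(self.matrix[iu], dtype=float)


def subsample_items(
    n: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw floor(fraction·n) distinct item indices uniformly, sorted."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = int(np.floor(fraction * n))
    return np.sort(rng.choice(n, size=m, replace=False))


def kmeans_partition(
    submatrix: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """Lloyd K-means (k-means++ start, single initialization), labels in 1..k.

    A single initialization per run is deliberate: run-to-run variability is
    exactly the signal the consensus matrix aggregates.
    """
    X = np.asarray(submatrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("submatrix must be 2-D")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {X.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        random_state=int(rng.integers(2**31 - 1)),
    )
    return km.fit_predict(X) + 1


def accumulate_consensus(runs: list[RunRecord], n: int) -> ConsensusMatrix:
    """Aggregate runs into a consensus matrix.

    M(i, j) = (#runs co-sampling AND co-clustering i, j) /
              (#runs co-sampling i, j), with never-co-sampled pairs set to 0
    (logged) and the diagonal forced to 1.

    The pair counts are formed by one matrix product per quantity: with S
    the n×runs sampling indicator and Z the n×(runs·k) run-by-cluster
    membership indicator, co-sampling counts are S Sᵀ and co-clustering
    counts are Z Zᵀ.  All increments are small integers, exact in float32.
    """
    if not runs:
        raise ValueError("at least one run is required")
    k = runs[0].k
    if any(r.k != k for r in runs):
        raise ValueError("all runs must share the same k")

    n_runs = len(runs)
    sampled = np.zeros((n, n_runs), dtype=np.float32)
    member = np.zeros((n, n_runs * k), dtype=np.float32)
    for r_idx, run in enumerate(runs):
        idx = run.item_indices
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("sampled index out of range")
        sampled[idx, r_idx] = 1.0
        member[idx, r_idx * k + (run.labels - 1)] = 1.0

    cosample = sampled @ sampled.T
    cocluster = member @ member.T

    never = (cosample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning(
            "%d item pairs were never co-sampled; their consensus is set to 0",
            int(never.sum() // 2),
        )

    # counts are exact small integers in float32; divide in float64 so the
    # stored proportions equal exact pair-count ratios. Never-co-sampled
    # pairs keep 0 (their co-cluster count is necessarily 0 too).
    matrix = cocluster.astype(np.float64)
    del cocluster
    np.divide(matrix, cosample, out=matrix, where=cosample > 0)
    np.fill_diagonal(matrix, 1.0)
    return ConsensusMatrix(
        k=k,
        matrix=matrix,
        cosample_counts=cosample.astype(np.uint16),
    )


def _run_rng(seed: int, k: int, iteration: int) -> np.random.Generator:
    """Independent substream per (k, iteration), order-insensitive."""
    return np.random.default_rng(
        np.random.SeedSequence([seed % 2**32, k, iteration])
    )


def run_consensus(
    matrix: FeatureMatrix | np.ndarray,
    config: ConsensusConfig = ConsensusConfig(),
    return_runs: bool = False,
) -> dict[int, ConsensusMatrix] | tuple[dict[int, ConsensusMatrix], dict[int, list[RunRecord]]]:
    """Full resampling loop: one consensus matrix per k in k_min..k_max."""
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if n < config.k_max:
        raise ValueError(f"need n >= k_max ({config.k_max}), got n = {n}")

    matrices: dict[int, ConsensusMatrix] = {}
    all_runs: dict[int, list[RunRecord]] = {}
    for k in range(config.k_min, config.k_max + 1):
        runs: list[RunRecord] = []
        for it in range(config.iterations):
            rng = _run_rng(config.seed, k, it)
            idx = subsample_items(n, config.item_fraction, rng)
            sub = X[idx]
            if config.feature_fraction < 1.0:
                cols = subsample_items(p, config.feature_fraction, rng)
                sub = sub[:, cols]
            labels = kmeans_partition(
                sub, k, rng, config.kmeans_max_iter, config.kmeans_tol
            )
            runs.append(RunRecord(k=k, iteration=it, item_indices=idx, labels=labels))
        matrices[k] = accumulate_consensus(runs, n)
        logger.info("consensus: k=%d done (%d runs, n=%d)", k, len(runs), n)
        if return_runs:
            all_runs[k] = runs
    if return_runs:
        return matrices, all_runs
    return matrices


def assign_final_clusters(cm: ConsensusMatrix) -> np.ndarray:
    """Cut an average-linkage tree on 1 − M into k groups, labels 1..k.

    The consensus matrix itself is a similarity; the final partition treats
    1 − M as a dissimilarity, builds an average-linkage hierarchy and cuts
    it at k.  Labels are renumbered by descending cluster size (ties by
    first appearance) for stable reporting.  The labels are also stored on
    ``cm``.
    """
    n = cm.n_items
    if n == 1:
        cm.labels = np.array([1])
        return cm.labels
    dist = 1.0 - np.asarray(cm.matrix, dtype=np.float64)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cm.k, criterion="maxclust")

    uniq, counts = np.unique(raw, return_counts=True)
    if len(uniq) < cm.k:
        logger.warning(
            "consensus matrix for k=%d is degenerate: hierarchy yields only "
            "%d distinct groups (unstable clustering)",
            cm.k,
            len(uniq),
        )
    # renumber by descending size; ties broken by original hierarchy label
    order = np.argsort(np.argsort(-counts, kind="stable"), kind="stable")
    remap = {int(u): int(o) + 1 for u, o in zip(uniq, order)}
    labels = np.array([remap[int(r)] for r in raw])
    cm.labels = labels
    return labels
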