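"""End-to-end driver: simulate → encode → consensus → select k → profile → outcomes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plots
from .cluster_profiling import SMDRecord, key_features, smd_table
from .cohort import CohortTable
from .consensus_core import ConsensusConfig, ConsensusMatrix, run_consensus
from .model_selection import SelectionDiagnostics, compute_diagnostics, select_optimal_k
from .outcome_analysis import (
    compare_clusters_table,
    mortality_by_cluster,
    odds_ratios_vs_reference,
)
from .preprocessing import FeatureMatrix, assess_missingness, encode_features, zscore_continuous
from .synthetic_cohort import GeneratorConfig, simulate_cohort, table1_config

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one cohort."""

    cohort: CohortTable
    features: FeatureMatrix
    consensus: dict[int, ConsensusMatrix]
    diagnostics: SelectionDiagnostics
    selected_k: int
    labels: np.ndarray  # final partition at the selected k (1..K)
    smd_records: list[SMDRecord]
    mortality: pd.DataFrame
    odds_ratios: pd.DataFrame
    summary_table: pd.DataFrame

    def write(self, out_dir: str | Path, with_plots: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.write(out / "cohort")
        self.features.write(out / "features")
        self.diagnostics.to_frame().to_csv(out / "selection_diagnostics.csv")
        pd.DataFrame(
            {"admission_id": self.cohort.admission_ids, "cluster": self.labels}
        ).to_csv(out / "cluster_labels.csv", index=False)
        smd_table(self.smd_records).to_csv(out / "smd.csv", index=False)
        self.mortality.to_csv(out / "mortality.csv")
        self.odds_ratios.to_csv(out / "odds_ratios.csv")
        self.summary_table.to_csv(out / "cluster_summary.csv")
        if with_plots:
            plots.plot_all(self, out / "figures")


def run_pipeline(
    cohort: CohortTable | None = None,
    generator: GeneratorConfig | None = None,
    consensus: ConsensusConfig = ConsensusConfig(),
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    smd_cutoff: float = 0.3,
    zscore_all: bool = False,
) -> PipelineResult:
    """Run the full phenotyping analysis on a cohort.

    Provide either an existing ``cohort`` or a ``generator`` config to
    simulate one (defaults to the packaged per-cluster parameters at
    n = 5564 when both are omitted).
    """
    if cohort is None:
        generator = generator or table1_config()
        logger.info("simulating cohort: n=%d", generator.n_admissions)
        cohort = simulate_cohort(generator)

    missing = assess_missingness(cohort)
    if missing["flagged"].any():
        logger.warning(
            "variables with heavy missingness: %s",
            list(missing.index[missing["flagged"]]),
        )

    features = zscore_continuous(encode_features(cohort), zscore_all=zscore_all)
    logger.info(
        "encoded %d admissions x %d feature columns", *features.values.shape
    )

    matrices = run_consensus(features, consensus)
    diagnostics = compute_diagnostics(matrices, pac_bounds=pac_bounds)
    selected_k, _ = select_optimal_k(diagnostics)
    labels = matrices[selected_k].labels
    logger.info("selected k=%d", selected_k)

    smd_records = key_features(cohort, labels, cutoff=smd_cutoff)
    mortality = mortality_by_cluster(cohort, labels)
    odds = odds_ratios_vs_reference(cohort, labels)
    summary = compare_clusters_table(cohort, labels)

    return PipelineResult(
        cohort=cohort,
        features=features,
        consensus=matrices,
        diagnostics=diagnostics,
        selected_k=selected_k,
        labels=labels,
        smd_records=smd_records,
        mortality=mortality,
        odds_ratios=odds,
        summary_table=summary,
    )
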