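"""Encode and normalize the mixed-type feature table for clustering.

Binary indicators stay 0/1, categorical variables are one-hot expanded (a
Euclidean distance must not see an artificial ordering of race levels), and
continuous variables are z-scored.  Standardization uses the population SD
(divide by n); the convention is fixed and recorded in the matrix so it can
be inverted exactly.  By default only continuous columns are standardized —
indicators already live on a bounded scale comparable to a z-scored age —
but ``zscore_all`` standardizes every column for users who prefer it.

The outcome and any latent labels never enter the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, VariableSpec

__all__ = [
    "FeatureMatrix",
    "assess_missingness",
    "encode_features",
    "zscore_continuous",
]


@dataclass
class FeatureMatrix:
    """Numeric n×q matrix fed to clustering, with provenance and scaling."""

    values: np.ndarray
    columns: list[str]
    #: per column: (source variable, categorical level or None)
    provenance: list[tuple[str, str | None]]
    #: columns eligible for z-scoring (continuous, or all if zscore_all)
    scalable: list[str]
    #: per scaled column: (mean, population SD) used for standardization
    norm_constants: dict[str, tuple[float, float]] = field(default_factory=dict)
    index: pd.Index | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape does not match columns")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=self.index)

    def denormalize(self) -> "FeatureMatrix":
        """Invert z-scoring using the stored constants."""
        values = self.values.copy()
        for col, (mean, sd) in self.norm_constants.items():
            j = self.columns.index(col)
            values[:, j] = values[:, j] * sd + mean
        return replace(self, values=values, norm_constants={})

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "features.csv", index_label="admission_id")
        sidecar = {
            "provenance": [
                {"column": c, "source": s, "level": l}
                for c, (s, l) in zip(self.columns, self.provenance)
            ],
            "norm_constants": {
                c: {"mean": float(m), "sd": float(s)}
                for c, (m, s) in self.norm_constants.items()
            },
        }
        (out / "normalization.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def assess_missingness(
    cohort: CohortTable, threshold: float = 0.05
) -> pd.DataFrame:
    """Per-variable missing counts and fractions, flagging heavy missingness.

    Simulated cohorts are complete by construction; on external data this is
    the screen run before clustering.
    """
    counts = cohort.data.isna().sum()
    n = max(cohort.n_admissions, 1)
    out = pd.DataFrame(
        {
            "n_missing": counts.astype(int),
            "fraction_missing": counts / n,
        }
    )
    out["flagged"] = out["fraction_missing"] > threshold
    out.index.name = "variable"
    return out


def encode_features(cohort: CohortTable) -> FeatureMatrix:
    """One-hot/passthrough encoding of the cohort into a numeric matrix."""
    if cohort.data.isna().any().any():
        raise ValueError("cohort contains missing values; resolve before encoding")

    columns: list[str] = []
    provenance: list[tuple[str, str | None]] = []
    scalable: list[str] = []
    blocks: list[np.ndarray] = []

    for spec in cohort.variables:
        col = cohort.data[spec.name]
        if spec.kind == "binary":
            vals = col.to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                raise ValueError(
                    f"binary variable {spec.name!r} has non-0/1 values: "
                    f"{sorted(set(np.asarray(vals)[bad].tolist()))[:5]}"
                )
            blocks.append(vals.astype(float)[:, None])
            columns.append(spec.name)
            provenance.append((spec.name, None))
        elif spec.kind == "categorical":
            seen = set(col.unique())
            unknown = seen - set(spec.levels)
            if unknown:
                raise ValueError(
                    f"categorical variable {spec.name!r} has unseen levels: "
                    f"{sorted(unknown)}"
                )
            for level in spec.levels:
                blocks.append((col == level).to_numpy(dtype=float)[:, None])
                columns.append(f"{spec.name}={level}")
                provenance.append((spec.name, level))
        else:  # continuous
            blocks.append(col.to_numpy(dtype=float)[:, None])
            columns.append(spec.name)
            provenance.append((spec.name, None))
            scalable.append(spec.name)

    values = (
        np.hstack(blocks) if blocks else np.empty((cohort.n_admissions, 0))
    )
    return FeatureMatrix(
        values=values,
        columns=columns,
        provenance=provenance,
        scalable=scalable,
        index=cohort.data.index,
    )


def zscore_continuous(matrix: FeatureMatrix, zscore_all: bool = False) -> FeatureMatrix:
    """Standardize columns to mean 0, population SD 1.

    Only the continuous columns by default; ``zscore_all`` standardizes
    every column instead.  A zero-SD (constant) column is an error — it
    carries no clustering information and cannot be scaled.
    """
    targets = list(matrix.columns) if zscore_all else list(matrix.scalable)
    values = matrix.values.copy()
    constants: dict[str, tuple[float, float]] = dict(matrix.norm_constants)
    for col in targets:
        j = matrix.columns.index(col)
        mean = float(values[:, j].mean())
        sd = float(values[:, j].std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"column {col!r} has zero SD; cannot z-score")
        values[:, j] = (values[:, j] - mean) / sd
        constants[col] = (mean, sd)
    return replace(matrix, values=values, norm_constants=constants)
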