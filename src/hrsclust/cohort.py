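"""Shared data containers for admission-level cohorts.

A cohort is one row per hospital admission: mixed binary / categorical /
continuous phenotyping variables, plus a binary in-hospital-death outcome
kept outside the feature set (the outcome is compared between clusters,
never clustered on), and optionally the latent cluster labels a simulator
planted (kept in a separate file on disk so the analysis stays blind).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["VariableSpec", "CohortTable"]


@dataclass(frozen=True)
class VariableSpec:
    """One phenotyping variable: its name, measurement kind and units."""

    name: str
    kind: str  # "binary" | "categorical" | "continuous"
    units: str = ""
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical variable {self.name!r} needs >= 2 levels")


@dataclass
class CohortTable:
    """Admission-level feature table with per-variable metadata.

    Parameters
    ----------
    data
        One row per admission, one column per variable in ``variables``,
        indexed by admission id.
    variables
        Metadata for every column of ``data`` (order matters).
    outcome
        Binary in-hospital death indicator aligned with ``data``.
    true_labels
        Latent cluster labels (1..K) when the cohort was simulated.
    """

    data: pd.DataFrame
    variables: list[VariableSpec]
    outcome: pd.Series | None = None
    true_labels: pd.Series | None = None
    outcome_name: str = "In-hospital mortality"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValueError(f"variables absent from data: {missing}")
        if not self.data.index.is_unique:
            raise ValueError("admission ids must be unique")
        for obj in (self.outcome, self.true_labels):
            if obj is not None and not obj.index.equals(self.data.index):
                raise ValueError("outcome/true_labels index must match data")

    @property
    def n_admissions(self) -> int:
        return len(self.data)

    @property
    def admission_ids(self) -> pd.Index:
        return self.data.index

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    # ------------------------------------------------------------------ I/O

    def write(self, out_dir: str | Path) -> None:
        """Write cohort CSV + metadata YAML (+ true labels CSV if present)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.data.copy()
        if self.outcome is not None:
            table[self.outcome_name] = self.outcome
        table.to_csv(out / "cohort.csv", index_label="admission_id")
        meta = {
            "outcome": self.outcome_name if self.outcome is not None else None,
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    "units": v.units,
                    "levels": list(v.levels),
                }
                for v in self.variables
            ],
        }
        (out / "variables.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        if self.true_labels is not None:
            self.true_labels.rename("true_cluster").to_csv(
                out / "true_labels.csv", index_label="admission_id"
            )

    @classmethod
    def read(cls, in_dir: str | Path, with_true_labels: bool = False) -> "CohortTable":
        src = Path(in_dir)
        meta = yaml.safe_load((src / "variables.yaml").read_text())
        variables = [
            VariableSpec(
                name=m["name"],
                kind=m["kind"],
                units=m.get("units") or "",
                levels=tuple(m.get("levels") or ()),
            )
            for m in meta["variables"]
        ]
        table = pd.read_csv(src / "cohort.csv", index_col="admission_id")
        outcome_name = meta.get("outcome")
        outcome = None
        if outcome_name is not None and outcome_name in table.columns:
            outcome = table.pop(outcome_name).astype(int)
        true_labels = None
        labels_path = src / "true_labels.csv"
        if with_true_labels and labels_path.exists():
            true_labels = pd.read_csv(labels_path, index_col="admission_id")[
                "true_cluster"
            ].astype(int)
        return cls(
            data=table[[v.name for v in variables]],
            variables=variables,
            outcome=outcome,
            true_labels=true_labels,
            outcome_name=outcome_name or "In-hospital mortality",
        )
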