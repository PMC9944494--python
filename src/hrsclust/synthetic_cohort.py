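"""Synthetic admission cohorts with planted cluster structure.

The study population this package targets (admissions primarily for
hepatorenal syndrome in the National Inpatient Sample) is restricted-access,
but the published per-cluster summary statistics — feature prevalences,
age mean ± SD, race composition and in-hospital mortality for four clusters
of sizes 1617 / 1577 / 642 / 1728 (n = 5564) — fully parameterize a simple
generative stand-in: each admission draws a latent cluster from the cluster
prevalences, then its binary features as independent Bernoulli variables at
the cluster's published frequencies, its age from a truncated Gaussian at
the cluster's published mean ± SD, race from the cluster's four-level
frequencies, and death from the cluster's mortality fraction.

Features are conditionally independent given the cluster: the published
table reports only marginal per-cluster frequencies, and this is the
simplest generative model consistent with them.  Cells suppressed in the
source table under HCUP small-cell reporting rules (printed "*") are given
a small fixed probability, below the reportable count in the smallest
cluster.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, VariableSpec

__all__ = [
    "ClusterProfile",
    "GeneratorConfig",
    "CohortTable",
    "load_table1_profiles",
    "table1_config",
    "high_separation_config",
    "simulate_cohort",
    "empirical_frequencies",
]

#: probability substituted for HCUP-suppressed ("*") cells; below the
#: ~10-count reporting cutoff in the smallest cluster (10/642 ≈ 0.0156)
DEFAULT_SUPPRESSED_CELL_PROB = 0.005

AGE_BOUNDS = (18.0, 100.0)  # adult inpatient cohort; resample outside


@dataclass(frozen=True)
class ClusterProfile:
    """Generative parameters (or recovered estimates) for one latent cluster."""

    label: int
    prevalence: float
    binary_probs: dict[str, float]
    age_mean: float
    age_sd: float
    mortality_prob: float
    race_probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = {"prevalence": self.prevalence, "mortality_prob": self.mortality_prob}
        probs.update({f"binary_probs[{k}]": v for k, v in self.binary_probs.items()})
        probs.update({f"race_probs[{k}]": v for k, v in self.race_probs.items()})
        for name, p in probs.items():
            if not np.isfinite(p) or not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"cluster {self.label}: {name} = {p!r} is not a probability"
                )
        if not np.isfinite(self.age_sd) or self.age_sd <= 0:
            raise ValueError(f"cluster {self.label}: age_sd must be > 0")
        if not np.isfinite(self.age_mean):
            raise ValueError(f"cluster {self.label}: age_mean must be finite")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one simulated cohort."""

    n_admissions: int
    profiles: tuple[ClusterProfile, ...]
    suppressed_cell_prob: float = DEFAULT_SUPPRESSED_CELL_PROB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_admissions < 0:
            raise ValueError("n_admissions must be >= 0")
        if not self.profiles:
            raise ValueError("at least one cluster profile is required")
        total = sum(p.prevalence for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile prevalences sum to {total}, expected 1")
        names = [tuple(sorted(p.binary_probs)) for p in self.profiles]
        if len(set(names)) != 1:
            raise ValueError("all profiles must share the same binary variables")


# --------------------------------------------------------------------------
# parameter loading


def _packaged_params_path() -> Path:
    return Path(importlib.resources.files("hrsclust") / "data" / "table1.yaml")


def load_table1_profiles(
    source: str | Path | dict | None = None,
    suppressed_cell_prob: float = DEFAULT_SUPPRESSED_CELL_PROB,
) -> list[ClusterProfile]:
    """Load per-cluster generative profiles from a structured parameter file.

    ``source`` is a YAML file (or an already-parsed dict) holding cluster
    sizes and per-cluster counts keyed by the published row names; ``None``
    loads the packaged hepatorenal-syndrome parameters.  Counts printed
    ``"*"`` in the source table (suppressed small cells) take
    ``suppressed_cell_prob``; a missing cell is a validation error naming
    the offending row.
    """
    if source is None:
        source = _packaged_params_path()
    if isinstance(source, dict):
        params = source
    else:
        params = yaml.safe_load(Path(source).read_text())

    for key in ("total_n", "cluster_n", "age", "binary", "mortality"):
        if key not in params:
            raise ValueError(f"parameter file is missing section {key!r}")

    cluster_n = {int(k): int(v) for k, v in params["cluster_n"].items()}
    labels = sorted(cluster_n)
    total_n = int(params["total_n"])
    if sum(cluster_n.values()) != total_n:
        raise ValueError(
            f"cluster sizes sum to {sum(cluster_n.values())}, "
            f"but total_n = {total_n}"
        )

    def cell_prob(row: str, cells: dict, label: int, n_c: int) -> float:
        if label not in cells and str(label) not in cells:
            raise ValueError(f"row {row!r}: missing cell for cluster {label}")
        raw = cells.get(label, cells.get(str(label)))
        if raw == "*":
            return suppressed_cell_prob
        count = int(raw)
        if not 0 <= count <= n_c:
            raise ValueError(
                f"row {row!r}: count {count} outside [0, {n_c}] for cluster {label}"
            )
        return count / n_c

    mort_rows = params["mortality"]
    if len(mort_rows) != 1:
        raise ValueError("mortality section must contain exactly one row")
    mort_row, mort_cells = next(iter(mort_rows.items()))

    race_rows = params.get("race", {})

    profiles = []
    for label in labels:
        n_c = cluster_n[label]
        binary_probs = {
            row: cell_prob(row, cells, label, n_c)
            for row, cells in params["binary"].items()
        }
        race_probs = {
            level: cell_prob(f"Race {level}", cells, label, n_c)
            for level, cells in race_rows.items()
        }
        if race_probs:
            # printed race percentages need not total 100 (rounding, "other")
            total = sum(race_probs.values())
            if total <= 0:
                raise ValueError(f"race probabilities for cluster {label} sum to 0")
            race_probs = {k: v / total for k, v in race_probs.items()}
        age = params["age"]
        for part in ("mean", "sd"):
            if label not in age[part] and str(label) not in age[part]:
                raise ValueError(f"row 'Age': missing {part} for cluster {label}")
        profiles.append(
            ClusterProfile(
                label=label,
                prevalence=n_c / total_n,
                binary_probs=binary_probs,
                age_mean=float(age["mean"].get(label, age["mean"].get(str(label)))),
                age_sd=float(age["sd"].get(label, age["sd"].get(str(label)))),
                mortality_prob=cell_prob(mort_row, mort_cells, label, n_c),
                race_probs=race_probs,
            )
        )
    return profiles


def table1_config(
    n_admissions: int = 5564,
    seed: int = 0,
    suppressed_cell_prob: float = DEFAULT_SUPPRESSED_CELL_PROB,
    source: str | Path | dict | None = None,
) -> GeneratorConfig:
    """GeneratorConfig parameterized by the published per-cluster table."""
    profiles = load_table1_profiles(source, suppressed_cell_prob)
    return GeneratorConfig(
        n_admissions=n_admissions,
        profiles=tuple(profiles),
        suppressed_cell_prob=suppressed_cell_prob,
        seed=seed,
    )


def high_separation_config(n_admissions: int = 400, seed: int = 0) -> GeneratorConfig:
    """A well-separated four-cluster configuration over the same variables.

    The published clusters overlap substantially, so exact label-recovery
    tests need a separable planted partition: binary probabilities are
    pushed to 0.95 for the block of variables "owned" by each cluster and
    0.05 elsewhere, and age means are spread far apart.  Equal prevalences.
    """
    base = load_table1_profiles()
    names = sorted(base[0].binary_probs)
    age_means = (40.0, 55.0, 70.0, 85.0)
    profiles = []
    for i in range(4):
        probs = {
            name: (0.95 if j % 4 == i else 0.05) for j, name in enumerate(names)
        }
        profiles.append(
            ClusterProfile(
                label=i + 1,
                prevalence=0.25,
                binary_probs=probs,
                age_mean=age_means[i],
                age_sd=3.0,
                mortality_prob=0.1 * (i + 1),
                race_probs={"White": 0.25, "Black": 0.25, "Hispanic": 0.25, "Other": 0.25},
            )
        )
    return GeneratorConfig(n_admissions=n_admissions, profiles=tuple(profiles), seed=seed)


# --------------------------------------------------------------------------
# simulation


def _variable_specs(profile: ClusterProfile) -> list[VariableSpec]:
    specs = [VariableSpec(name, "binary") for name in profile.binary_probs]
    if profile.race_probs:
        specs.append(
            VariableSpec("Race", "categorical", levels=tuple(profile.race_probs))
        )
    specs.append(VariableSpec("Age", "continuous", units="years"))
    return specs


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gaussian draws resampled into the adult age range."""
    lo, hi = AGE_BOUNDS
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw an admission-level cohort from per-cluster profiles.

    Each row samples a latent cluster from the prevalences, then its
    features conditionally independently: Bernoulli binaries, categorical
    race, truncated-Gaussian age and a Bernoulli death outcome.  Identical
    configs (including seed) produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_admissions
    profiles = config.profiles
    prevalences = np.array([p.prevalence for p in profiles])
    prevalences = prevalences / prevalences.sum()  # guard 1e-9 slack

    specs = _variable_specs(profiles[0])
    binary_names = [s.name for s in specs if s.kind == "binary"]
    race_levels = profiles[0].race_probs

    labels = rng.choice([p.label for p in profiles], size=n, p=prevalences)

    columns: dict[str, np.ndarray] = {
        name: np.zeros(n, dtype=int) for name in binary_names
    }
    if race_levels:
        race = np.empty(n, dtype=object)
    age = np.zeros(n, dtype=float)
    outcome = np.zeros(n, dtype=int)

    for profile in profiles:
        mask = labels == profile.label
        m = int(mask.sum())
        if m == 0:
            continue
        for name in binary_names:
            columns[name][mask] = rng.binomial(1, profile.binary_probs[name], m)
        if race_levels:
            levels = list(profile.race_probs)
            race[mask] = rng.choice(
                levels, size=m, p=np.array([profile.race_probs[l] for l in levels])
            )
        age[mask] = _truncated_normal(rng, profile.age_mean, profile.age_sd, m)
        outcome[mask] = rng.binomial(1, profile.mortality_prob, m)

    data = pd.DataFrame(columns, index=pd.RangeIndex(n, name="admission_id"))
    if race_levels:
        data["Race"] = race
    data["Age"] = age
    data = data[[s.name for s in specs]]

    return CohortTable(
        data=data,
        variables=specs,
        outcome=pd.Series(outcome, index=data.index, name="In-hospital mortality"),
        true_labels=pd.Series(labels, index=data.index, name="true_cluster"),
    )


def empirical_frequencies(
    cohort: CohortTable,
    labels: np.ndarray | pd.Series,
    expected_labels: list[int] | None = None,
) -> list[ClusterProfile]:
    """Observed per-cluster prevalences, frequencies, age moments, mortality.

    The inverse of :func:`simulate_cohort`'s parameterization: used to check
    that a generated cohort reproduces its generator, or to summarize the
    clusters an analysis assigned.  Every cluster must be non-empty: when
    ``expected_labels`` is given, a cluster with no rows is an error naming
    the cluster.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != cohort.n_admissions:
        raise ValueError("labels must align with cohort rows")
    if expected_labels is not None:
        present = set(np.unique(labels).tolist())
        for lbl in expected_labels:
            if lbl not in present:
                raise ValueError(f"cluster {lbl} is empty")
    if cohort.outcome is None:
        raise ValueError("cohort has no outcome column")

    binary_names = [v.name for v in cohort.variables if v.kind == "binary"]
    race_spec = next((v for v in cohort.variables if v.name == "Race"), None)

    profiles = []
    n = cohort.n_admissions
    for label in np.unique(labels):
        mask = labels == label
        m = int(mask.sum())
        if m == 0:
            raise ValueError(f"cluster {label} is empty")
        sub = cohort.data.loc[mask]
        race_probs = {}
        if race_spec is not None:
            counts = sub["Race"].value_counts()
            race_probs = {
                level: counts.get(level, 0) / m for level in race_spec.levels
            }
        ages = sub["Age"].to_numpy(dtype=float)
        sd = float(ages.std(ddof=1)) if m > 1 else 0.0
        profiles.append(
            ClusterProfile(
                label=int(label),
                prevalence=m / n,
                binary_probs={
                    name: float(sub[name].mean()) for name in binary_names
                },
                age_mean=float(ages.mean()),
                age_sd=sd if sd > 0 else 1e-12,
                mortality_prob=float(cohort.outcome.to_numpy()[mask].mean()),
                race_probs=race_probs,
            )
        )
    return profiles
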