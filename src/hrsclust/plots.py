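"""Diagnostic figures: CDF overlay, delta-area elbow, consensus heatmaps,
within-cluster consensus and PAC bars, and the SMD key-feature panel."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cluster_profiling import smd_table
from .consensus_core import ConsensusMatrix
from .model_selection import SelectionDiagnostics, consensus_cdf

__all__ = [
    "plot_cdf_overlay",
    "plot_delta_area",
    "plot_consensus_heatmap",
    "plot_stability_bars",
    "plot_smd_panel",
    "plot_all",
]


def plot_cdf_overlay(matrices: dict[int, ConsensusMatrix], path: str | Path) -> None:
    """Consensus-value CDFs for every k, overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    grid = np.linspace(0, 1, 201)
    for k in sorted(matrices):
        cdf = consensus_cdf(matrices[k])
        ax.plot(grid, cdf(grid), label=f"k={k}", lw=1.2)
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_delta_area(diag: SelectionDiagnostics, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ks = diag.k_values
    deltas = [diag.deltas[k] if diag.deltas[k] is not None else np.nan for k in ks]
    ax.plot(ks, deltas, "o-")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("relative change in CDF area")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_consensus_heatmap(cm: ConsensusMatrix, path: str | Path) -> None:
    """Heatmap with items ordered by the final partition (white → blue)."""
    order = (
        np.argsort(cm.labels, kind="stable")
        if cm.labels is not None
        else np.arange(cm.n_items)
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(
        cm.matrix[np.ix_(order, order)],
        cmap="Blues",
        vmin=0,
        vmax=1,
        interpolation="nearest",
    )
    ax.set_title(f"consensus matrix, k={cm.k}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stability_bars(diag: SelectionDiagnostics, path: str | Path) -> None:
    """Mean within-cluster consensus and PAC, per k."""
    ks = diag.k_values
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].bar(ks, [diag.mean_scores[k] for k in ks], color="steelblue")
    axes[0].set_xlabel("k")
    axes[0].set_ylabel("mean within-cluster consensus")
    axes[1].bar(ks, [diag.pac_values[k] for k in ks], color="indianred")
    axes[1].set_xlabel("k")
    axes[1].set_ylabel("PAC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_smd_panel(records, cutoff: float, path: str | Path) -> None:
    """Dot plot of standardized mean differences, variables × clusters."""
    table = smd_table(records)
    variables = sorted(table["variable"].unique())
    clusters = sorted(table["cluster"].unique())
    fig, ax = plt.subplots(figsize=(7, max(4, 0.18 * len(variables))))
    y = {v: i for i, v in enumerate(variables)}
    for c in clusters:
        sub = table[table["cluster"] == c]
        ax.plot(
            sub["smd"],
            [y[v] for v in sub["variable"]],
            "o",
            ms=3.5,
            label=f"cluster {c}",
        )
    for x in (-cutoff, cutoff):
        ax.axvline(x, color="gray", ls="--", lw=0.8)
    ax.set_yticks(range(len(variables)))
    ax.set_yticklabels(variables, fontsize=6)
    ax.set_xlabel("standardized mean difference (cluster vs rest)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_all(result, out_dir: str | Path) -> None:
    """Write the full diagnostic figure set for a pipeline result."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plot_cdf_overlay(result.consensus, out / "cdf_overlay.png")
    plot_delta_area(result.diagnostics, out / "delta_area.png")
    plot_stability_bars(result.diagnostics, out / "stability.png")
    plot_consensus_heatmap(
        result.consensus[result.selected_k], out / "consensus_heatmap.png"
    )
    plot_smd_panel(result.smd_records, 0.3, out / "smd_panel.png")
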