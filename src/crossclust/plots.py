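"""The two figure archetypes: block-ordered correlation heatmap and
per-bicluster group panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .tables import SampleDesign, ValidationError

__all__ = ["plot_cocluster_heatmap", "plot_bicluster_panels"]


def plot_cocluster_heatmap(reordered: pd.DataFrame, block_boundaries, path=None, ax=None):
    """Diverging heatmap of the block-ordered correlation matrix.

    Cell color encodes sign and magnitude of the correlation; white lines
    mark bicluster boundaries so the diagonal blocks are visible.
    """
    if reordered.size == 0:
        raise ValidationError("empty matrix")
    values = reordered.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-finite cell at row {reordered.index[i]!r}, column {reordered.columns[j]!r}"
        )
    row_bounds, col_bounds = block_boundaries
    if ax is None:
        fig, ax = plt.subplots(figsize=(max(6, values.shape[1] * 0.12),
                                        max(4, values.shape[0] * 0.16)))
    else:
        fig = ax.figure
    vmax = max(np.abs(values).max(), 1e-12)
    im = ax.imshow(values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    for r in row_bounds:
        ax.axhline(r - 0.5, color="white", lw=1.5)
    for c in col_bounds:
        ax.axvline(c - 0.5, color="white", lw=1.5)
    ax.set_xticks(range(values.shape[1]))
    ax.set_xticklabels(reordered.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(values.shape[0]))
    ax.set_yticklabels(reordered.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bicluster_panels(
    summary: pd.DataFrame,
    design: SampleDesign,
    biomarker: pd.Series | None = None,
    path=None,
):
    """One panel per bicluster: groups on x, mean-centered summary on y.

    Boxes show quartiles with 1.5 IQR whiskers; scatter markers are sized
    by the chosen biomarker when one is given, uniform otherwise.
    """
    if list(summary.index) != list(design.sample_ids):
        raise ValidationError("summary and design are not sample-aligned")
    centered = summary - summary.mean(axis=0)
    groups = sorted(set(design.group))
    k = summary.shape[1]
    fig, axes = plt.subplots(1, k, figsize=(3 * k, 3.2), sharey=False, squeeze=False)
    if biomarker is not None:
        b = biomarker.loc[summary.index].to_numpy(dtype=float)
        span = np.nanmax(b) - np.nanmin(b)
        sizes = 20 + 80 * (b - np.nanmin(b)) / (span if span > 0 else 1.0)
        sizes = np.nan_to_num(sizes, nan=20.0)
    else:
        sizes = np.full(len(summary.index), 30.0)
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for j, col in enumerate(centered.columns):
        ax = axes[0, j]
        data = [centered.loc[design.samples_in_group(g), col].to_numpy() for g in groups]
        ax.boxplot(data, tick_labels=groups, whis=1.5, showfliers=False)
        for gi, g in enumerate(groups):
            ids = design.samples_in_group(g)
            x = gi + 1 + rng.uniform(-0.12, 0.12, size=len(ids))
            idx = [summary.index.get_loc(s) for s in ids]
            ax.scatter(x, centered.loc[ids, col], s=sizes[idx], alpha=0.6, zorder=3)
        ax.axhline(0.0, color="grey", lw=0.5, ls="--")
        ax.set_title(col, fontsize=9)
        ax.tick_params(axis="x", labelrotation=45, labelsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
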