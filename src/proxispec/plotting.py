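"""Static PNG plots for spectra, indices, PCA scores and fieldmaps.

Every function writes a PNG and returns its path.  Plots are deliberately
non-interactive: per-sample traces or points, per-group mean traces
coloured by attribute, index boxplots with optional sample overlay, and
PC1/PC2 score plots coloured by attribute.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import SpectralCollection
from .errors import UsageError
from .fieldmap import render_fieldmap
from .qc import PcaResult

__all__ = [
    "plot_spectra",
    "plot_boxplot",
    "plot_scatter",
    "plot_pca",
    "plot_fieldmap",
]


def _save(fig, path) -> str:
    fig.tight_layout()
    fig.savefig(path, format="png", dpi=120)
    plt.close(fig)
    return str(path)


def plot_spectra(
    collection: SpectralCollection,
    path,
    by: str | None = None,
    show_samples: bool = True,
    stat: str | None = None,
) -> str:
    """Reflectance vs wavelength; optionally per-group mean traces.

    With ``by`` set to a discrete attribute, one mean trace per level is
    drawn (individual samples become faint background lines).  ``stat`` may
    add a mean/median/variance summary trace of the whole collection.
    """
    fig, ax = plt.subplots(figsize=(8, 4.5))
    if by is not None:
        groups = collection.group_by_attribute(by)
        if show_samples:
            for row in collection.values:
                ax.plot(collection.grid, row, color="0.85", lw=0.5, zorder=1)
        for level, sub in groups.items():
            ax.plot(
                sub.grid, sub.summarize("mean").reflectance,
                lw=1.8, label=f"{by}={level} (mean, n={sub.n_samples})", zorder=2,
            )
        ax.legend(fontsize=8)
    else:
        if show_samples:
            for sid, row in zip(collection.sample_ids, collection.values):
                ax.plot(collection.grid, row, lw=0.7,
                        label=sid if collection.n_samples <= 12 else None)
        if stat is not None:
            tr = collection.summarize(stat)
            ax.plot(tr.wavelengths, tr.reflectance, "k-", lw=2, label=stat)
        if collection.n_samples <= 12 or stat is not None:
            ax.legend(fontsize=8)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    return _save(fig, path)


def plot_boxplot(
    values: pd.Series,
    groups: pd.Series,
    path,
    overlay_points: bool = True,
    title: str | None = None,
) -> str:
    """Boxplot of an index by a discrete grouping, optional sample overlay."""
    groups = groups.reindex(values.index)
    ok = values.notna() & groups.notna()
    if not ok.any():
        raise UsageError("no complete (value, group) pairs to plot")
    levels = sorted(groups[ok].astype(str).unique())
    data = [values[ok][groups[ok].astype(str) == lvl].to_numpy() for lvl in levels]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(levels), 4))
    ax.boxplot(data, tick_labels=levels, showfliers=not overlay_points)
    if overlay_points:
        rng = np.random.default_rng(0)  # jitter only; cosmetic
        for k, arr in enumerate(data, start=1):
            ax.plot(k + rng.uniform(-0.08, 0.08, len(arr)), arr, "o",
                    ms=3, alpha=0.6, color="tab:blue")
    ax.set_ylabel(values.name or "index value")
    ax.set_xlabel(groups.name or "group")
    if title:
        ax.set_title(title)
    return _save(fig, path)


def plot_scatter(x: pd.Series, y: pd.Series, path, title: str | None = None) -> str:
    """Scatter of an index against a continuous trait."""
    x = pd.to_numeric(x, errors="coerce")
    y = pd.to_numeric(y.reindex(x.index), errors="coerce")
    ok = x.notna() & y.notna()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x[ok], y[ok], "o", ms=4, alpha=0.8)
    ax.set_xlabel(x.name or "x")
    ax.set_ylabel(y.name or "y")
    if title:
        ax.set_title(title)
    return _save(fig, path)


def plot_pca(
    result: PcaResult,
    path,
    color_by: pd.Series | None = None,
    flagged: Sequence[str] = (),
    title: str | None = None,
) -> str:
    """PC1 vs PC2 score plot, optionally coloured by an attribute.

    Samples named in ``flagged`` (e.g. detected outliers) are circled and
    labelled.
    """
    scores = result.scores_frame()
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    if color_by is not None:
        color_by = color_by.reindex(scores.index)
        levels = sorted(color_by.dropna().astype(str).unique())
        for lvl in levels:
            sel = color_by.astype(str) == lvl
            ax.plot(scores.loc[sel.to_numpy(), "PC1"], scores.loc[sel.to_numpy(), "PC2"],
                    "o", ms=5, alpha=0.8, label=str(lvl))
        missing = color_by.isna()
        if missing.any():
            ax.plot(scores.loc[missing.to_numpy(), "PC1"],
                    scores.loc[missing.to_numpy(), "PC2"],
                    "s", ms=5, color="0.4", label="unassigned")
        ax.legend(fontsize=8, title=color_by.name)
    else:
        ax.plot(scores["PC1"], scores["PC2"], "o", ms=5, alpha=0.8)
    for sid in flagged:
        if sid in scores.index:
            ax.plot(scores.at[sid, "PC1"], scores.at[sid, "PC2"], "o", ms=12,
                    mfc="none", mec="red")
            ax.annotate(sid, (scores.at[sid, "PC1"], scores.at[sid, "PC2"]),
                        fontsize=7, xytext=(4, 4), textcoords="offset points")
    evf = result.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({evf[0] * 100:.1f}% var)")
    ax.set_ylabel(f"PC2 ({evf[1] * 100:.1f}% var)" if len(evf) > 1 else "PC2")
    if title:
        ax.set_title(title)
    return _save(fig, path)


def plot_fieldmap(matrix, path, color_scale: str = "viridis", **kwargs) -> str:
    """Delegates to :func:`proxispec.fieldmap.render_fieldmap`."""
    return render_fieldmap(matrix, path, color_scale=color_scale, **kwargs)
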