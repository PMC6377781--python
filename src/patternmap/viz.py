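"""Static figure export: pattern heatmaps and expression line charts.

Purely presentational — every number shown here is computed upstream.  The
heatmap draws one row per pattern key, one column per time point, cells
colored by symbol (up / neutral / down); the line chart draws per-gene log2
fold-change trajectories.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .discretize import PatternGroup
from .io import ExpressionProfile

__all__ = ["pattern_matrix", "render_heatmap", "render_linechart"]

_SYMBOL_VALUE = {"-": -1, "0": 0, "+": 1}
_CMAP = ListedColormap(["#2166ac", "#f0f0f0", "#b2182b"])  # down, neutral, up


def pattern_matrix(groups: Sequence[PatternGroup]) -> tuple[np.ndarray, list[str]]:
    """Rows = pattern keys, columns = time points, cells = -1/0/+1."""
    keys = [g.key for g in groups]
    mat = np.array([[_SYMBOL_VALUE[s] for s in key] for key in keys]) if keys else np.empty((0, 0))
    return mat, keys


def render_heatmap(
    groups: Sequence[PatternGroup],
    timepoints: Sequence[str],
    path: str | Path,
    title: str = "pattern heatmap",
) -> bool:
    """Render the symbol matrix of pattern groups; returns False for empty input."""
    mat, keys = pattern_matrix(groups)
    if mat.size == 0:
        warnings.warn("no pattern groups to render", stacklevel=2)
        return False
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * mat.shape[1], 0.8 + 0.35 * mat.shape[0]))
    ax.imshow(mat, cmap=_CMAP, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(timepoints)), labels=list(timepoints))
    ax.set_yticks(range(len(keys)), labels=[f"{k} (n={g.count})" for k, g in zip(keys, groups)])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return True


def render_linechart(
    series: Mapping[str, ExpressionProfile],
    timepoints: Sequence[str],
    path: str | Path,
    title: str = "log2 fold change",
) -> bool:
    """Render per-gene log2 fold-change trajectories; returns False for empty input."""
    if not series:
        warnings.warn("no profiles to render", stacklevel=2)
        return False
    fig, ax = plt.subplots(figsize=(6, 4))
    x = range(len(timepoints))
    for label in sorted(series):
        ax.plot(x, series[label].fc, marker="o", label=label)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(list(x), labels=list(timepoints))
    ax.set_ylabel("log2 fold change")
    ax.set_title(title)
    if len(series) <= 12:
        ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return True
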