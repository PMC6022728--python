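"""Map per-sample values onto the field-trial grid and render heatmaps.

The field layout is a rectangular matrix of sample filenames mirroring the
physical plot arrangement; ``build_fieldmap`` fills each cell with its
sample's value (e.g. an NDVI), leaving empty cells and unmatched filenames
missing, and ``render_fieldmap`` draws the matrix as a PNG heatmap with the
top layout row at the top of the image.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping

import numpy as np

from .errors import UsageError
from .io import FieldLayout, _strip_extension

logger = logging.getLogger(__name__)

__all__ = ["build_fieldmap", "render_fieldmap"]


def build_fieldmap(layout: FieldLayout, values: Mapping[str, float]) -> np.ndarray:
    """n_rows x n_cols value matrix; NaN marks empty or unmatched cells.

    Filenames are matched exactly first, then by basename without
    extension; unmatched filenames are logged, never invented.
    """
    stem_values = {}
    for key, val in values.items():
        stem_values.setdefault(_strip_extension(str(key)), val)
    out = np.full((layout.n_rows, layout.n_cols), np.nan)
    for i in range(layout.n_rows):
        for j in range(layout.n_cols):
            cell = layout.grid[i, j]
            if cell is None:
                continue
            if cell in values:
                out[i, j] = values[cell]
            elif _strip_extension(cell) in stem_values:
                out[i, j] = stem_values[_strip_extension(cell)]
            else:
                logger.warning(
                    "fieldmap cell (%d, %d) filename %r has no value; left missing",
                    i, j, cell,
                )
    return out


def render_fieldmap(
    matrix: np.ndarray,
    output_path,
    color_scale: str = "viridis",
    title: str | None = None,
    value_label: str | None = None,
) -> str:
    """Render a fieldmap matrix as a PNG heatmap.

    One rectangle per cell, missing cells drawn in a distinct neutral
    colour, colour bar included; row 0 renders at the top.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise UsageError("fieldmap matrix is empty")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap(color_scale).copy()
    cmap.set_bad("lightgrey")
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.6 * matrix.shape[1]), max(2.5, 0.6 * matrix.shape[0]))
    )
    masked = np.ma.masked_invalid(matrix)
    im = ax.imshow(masked, cmap=cmap, aspect="auto", origin="upper")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=value_label or "value")
    fig.tight_layout()
    try:
        fig.savefig(output_path, format="png", dpi=120)
    except OSError as exc:
        raise OSError(f"cannot write fieldmap PNG to {output_path}: {exc}") from exc
    finally:
        plt.close(fig)
    if not os.path.exists(output_path):
        raise OSError(f"fieldmap PNG {output_path} was not written")
    return str(output_path)
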