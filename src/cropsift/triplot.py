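"""Grain : rachis : weed ternary plots.

Percentages of the three item categories are mapped onto a unit-side
triangle with grain at the apex, rachis at the lower-left and weed
seeds at the lower-right, and drawn as two side-by-side panels:
ethnographic groups on the left, archaeological samples on the right.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from cropsift.io import DataError, TriplotTable

logger = logging.getLogger(__name__)

_APEX = (0.5, math.sqrt(3) / 2)  # grain
_LEFT = (0.0, 0.0)  # rachis
_RIGHT = (1.0, 0.0)  # weeds

#: Default marker per ethnographic group (monochrome, shape-coded).
GROUP_MARKERS = {1: "o", 2: "s", 3: "^", 4: "D"}


def triplot_proportions(table: TriplotTable) -> pd.DataFrame:
    """Per-sample percentages of grain, rachis and weed items.

    Raises :class:`~cropsift.io.DataError` for a zero-total sample —
    apply the minimum-items filter first.
    """
    totals = table.total_items()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise DataError(f"samples with zero items: {zero}")
    return 100.0 * table.totals.div(totals, axis=0)


def ternary_coordinates(proportions) -> np.ndarray:
    """Map (grain, rachis, weeds) percentages to planar (x, y).

    Standard barycentric mapping onto a unit-side equilateral
    triangle; accepts a single triple, an array or the DataFrame from
    :func:`triplot_proportions`.
    """
    arr = np.atleast_2d(np.asarray(proportions, dtype=float))
    if arr.shape[1] != 3:
        raise ValueError("proportions must have three components")
    frac = arr / arr.sum(axis=1, keepdims=True)
    g, r, w = frac[:, 0], frac[:, 1], frac[:, 2]
    x = g * _APEX[0] + r * _LEFT[0] + w * _RIGHT[0]
    y = g * _APEX[1] + r * _LEFT[1] + w * _RIGHT[1]
    out = np.column_stack([x, y])
    return out[0] if np.asarray(proportions).ndim == 1 else out


def planar_to_proportions(xy) -> np.ndarray:
    """Inverse of :func:`ternary_coordinates` (percent scale)."""
    arr = np.atleast_2d(np.asarray(xy, dtype=float))
    g = arr[:, 1] / _APEX[1]
    w = arr[:, 0] - 0.5 * g
    r = 1.0 - g - w
    out = 100.0 * np.column_stack([g, r, w])
    return out[0] if np.asarray(xy).ndim == 1 else out


def _draw_triangle(ax) -> None:
    xs = [_LEFT[0], _RIGHT[0], _APEX[0], _LEFT[0]]
    ys = [_LEFT[1], _RIGHT[1], _APEX[1], _LEFT[1]]
    ax.plot(xs, ys, color="black", linewidth=1)
    ax.text(*_APEX, "grain", ha="center", va="bottom")
    ax.text(*_LEFT, "rachis", ha="right", va="top")
    ax.text(*_RIGHT, "weeds", ha="left", va="top")
    ax.set_aspect("equal")
    ax.axis("off")


def make_triplot(
    arch: TriplotTable,
    reference: TriplotTable,
    reference_groups: pd.Series | None = None,
    highlight: Iterable = (),
    arch_marker: str = "o",
    arch_color: str = "black",
    group_markers: Mapping[int, str] | None = None,
    title: str | None = None,
):
    """Side-by-side ternary plot: ethnographic left, archaeological right.

    ``highlight`` lists archaeological sample ids to label (and fill);
    absent ids produce a warning, not an error.  Samples with fewer
    than 30 items draw a warning as well — eligibility filtering is
    the caller's job.  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    low = arch.total_items()
    low = low.index[low < 30].tolist()
    if low:
        logger.warning("archaeological samples with < 30 items: %s", low)

    markers = dict(GROUP_MARKERS)
    if group_markers:
        markers.update(group_markers)

    fig, (ax_ref, ax_arch) = plt.subplots(1, 2, figsize=(10, 5))
    for ax in (ax_ref, ax_arch):
        _draw_triangle(ax)

    ref_xy = ternary_coordinates(triplot_proportions(reference).to_numpy())
    if reference_groups is not None:
        groups = pd.Series(reference_groups, index=reference.sample_ids).astype(int)
        for g in sorted(groups.unique()):
            pts = ref_xy[(groups == g).to_numpy()]
            ax_ref.scatter(
                pts[:, 0], pts[:, 1], marker=markers.get(g, "o"),
                facecolors="none", edgecolors="black", label=str(g),
            )
        ax_ref.legend(title="group", loc="upper left", fontsize="small")
    else:
        ax_ref.scatter(
            ref_xy[:, 0], ref_xy[:, 1], facecolors="none", edgecolors="black"
        )
    ax_ref.set_title("ethnographic")

    arch_xy = ternary_coordinates(triplot_proportions(arch).to_numpy())
    ax_arch.scatter(
        arch_xy[:, 0], arch_xy[:, 1], marker=arch_marker,
        facecolors="none", edgecolors=arch_color,
    )
    ids = arch.sample_ids
    missing = [h for h in highlight if h not in set(ids)]
    if missing:
        logger.warning("highlight ids not in table: %s", missing)
    for h in highlight:
        if h in set(ids):
            i = ids.index(h)
            ax_arch.scatter(
                [arch_xy[i, 0]], [arch_xy[i, 1]], marker=arch_marker,
                color=arch_color, zorder=3,
            )
            ax_arch.annotate(
                str(h), (arch_xy[i, 0], arch_xy[i, 1]),
                textcoords="offset points", xytext=(5, 5),
            )
    ax_arch.set_title(title or "archaeological")
    fig.tight_layout()
    return fig
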