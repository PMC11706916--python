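"""Discriminant-score plots in 2D and 3D.

Plots read coordinates straight off a
:class:`~cropsift.classify.ClassificationResult`; nothing is refitted
here, so plots from the five-group method automatically use that
model's reference coordinates (which differ from the four-group
model's).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cropsift.classify import GROUP_NAMES, ClassificationResult

logger = logging.getLogger(__name__)

GROUP_MARKERS = {1: "o", 2: "s", 3: "^", 4: "D", 5: "v"}


def _check_axes(result: ClassificationResult, axes: Sequence[int]) -> list[str]:
    m = result.model.n_functions
    valid = list(range(1, m + 1))
    if len(set(axes)) != len(axes):
        raise ValueError("axes must be distinct")
    for a in axes:
        if a not in valid:
            raise ValueError(f"axis {a} out of range; valid axes: {valid}")
    return [f"LD{a}" for a in axes]


def _series(result, cols, site, group_colors, arch_color):
    """Yield (label, frame, marker, color, is_site) per plotted series."""
    for g in sorted(result.ref_groups.unique()):
        mask = (result.ref_groups == g).to_numpy()
        yield (
            f"{g}: {GROUP_NAMES.get(int(g), str(g))}",
            result.ref_scores.loc[mask, cols],
            GROUP_MARKERS.get(int(g), "o"),
            (group_colors or {}).get(int(g), "black"),
            False,
        )
    yield site, result.scores[cols], "x", arch_color, True


def plot_scores_2d(
    result: ClassificationResult,
    axes: Sequence[int] = (1, 2),
    labels: Iterable = (),
    site: str = "archaeological",
    group_colors: Mapping[int, str] | None = None,
    arch_color: str = "black",
):
    """Scatter the chosen pair of discriminant functions.

    Ethnographic groups are shape-coded (monochrome by default);
    archaeological samples draw as crosses.  ``labels`` names samples
    to annotate.  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    if result.model.n_functions < 2:
        raise ValueError("need at least two discriminant functions for a 2D plot")
    if len(axes) != 2:
        raise ValueError("axes must be a pair")
    cols = _check_axes(result, axes)

    fig, ax = plt.subplots(figsize=(7, 6))
    for name, frame, marker, color, is_site in _series(
        result, cols, site, group_colors, arch_color
    ):
        style = (
            {"color": color} if is_site
            else {"facecolors": "none", "edgecolors": color}
        )
        ax.scatter(frame[cols[0]], frame[cols[1]], marker=marker, label=name, **style)
    _annotate(ax, result, cols, labels)
    ax.set_xlabel(cols[0])
    ax.set_ylabel(cols[1])
    ax.legend(fontsize="small")
    fig.tight_layout()
    return fig


def plot_scores_3d(
    result: ClassificationResult,
    axes: Sequence[int] = (1, 2, 3),
    labels: Iterable = (),
    site: str = "archaeological",
    group_colors: Mapping[int, str] | None = None,
    arch_color: str = "black",
    elev: float | None = None,
    azim: float | None = None,
):
    """Three-axis scatter of discriminant scores.

    Interactive when shown in a GUI backend; for static export pass
    an explicit camera angle (``elev``/``azim``) — no automatic "best
    rotation" is attempted.  Requires a model with at least three
    discriminant functions (use :func:`plot_scores_2d` otherwise).
    """
    import matplotlib.pyplot as plt

    if result.model.n_functions < 3:
        raise ValueError(
            "model has fewer than three discriminant functions; use plot_scores_2d"
        )
    if len(axes) != 3:
        raise ValueError("axes must be a triple")
    cols = _check_axes(result, axes)

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for name, frame, marker, color, _is_site in _series(
        result, cols, site, group_colors, arch_color
    ):
        ax.scatter(
            frame[cols[0]], frame[cols[1]], frame[cols[2]],
            marker=marker, color=color, label=name,
        )
    for sample in labels:
        if sample in result.scores.index:
            row = result.scores.loc[sample, cols]
            ax.text(row[cols[0]], row[cols[1]], row[cols[2]], str(sample))
        else:
            logger.warning("label id %r not among archaeological samples", sample)
    ax.set_xlabel(cols[0])
    ax.set_ylabel(cols[1])
    ax.set_zlabel(cols[2])
    if elev is not None or azim is not None:
        ax.view_init(elev=elev, azim=azim)
    ax.legend(fontsize="small")
    return fig


def _annotate(ax, result, cols, labels) -> None:
    for sample in labels:
        if sample in result.scores.index:
            x, y = result.scores.loc[sample, cols[0]], result.scores.loc[sample, cols[1]]
            ax.annotate(
                str(sample), (x, y), textcoords="offset points", xytext=(5, 5)
            )
        else:
            logger.warning("label id %r not among archaeological samples", sample)
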