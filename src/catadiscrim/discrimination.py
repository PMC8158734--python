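"""Assessor-level discrimination diagnostics from the consensus matrix.

An assessor who produces *low* consensus similarity between samples is the
one perceiving differences between them.  The grand mean of the pair x
assessor consensus matrix is the *consensus limit*: assessors whose column
average falls strictly below it are flagged good discriminators, the rest
poor (ties count as poor).  Expressed as a percentage the grand mean is the
dataset-level *discrimination index* — lower means the panel as a whole
discriminated better.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO

import numpy as np
import pandas as pd

from .metrics import PairSimilarityMatrix
from .panel import write_matrix

__all__ = ["DiscriminationSummary", "summarize", "discrimination_index", "heatmap_export"]


@dataclass(frozen=True)
class DiscriminationSummary:
    """Column averages, consensus limit, good/poor flags and global index."""

    assessors: tuple[str, ...]
    assessor_averages: np.ndarray = field(repr=False)
    consensus_limit: float
    flags: tuple[str, ...]  # "good" | "poor" per assessor
    row_min: float
    row_max: float
    discrimination_index: float  # = 100 * consensus_limit

    @property
    def n_good(self) -> int:
        return sum(f == "good" for f in self.flags)

    @property
    def n_poor(self) -> int:
        return sum(f == "poor" for f in self.flags)

    def good_assessors(self) -> tuple[str, ...]:
        return tuple(a for a, f in zip(self.assessors, self.flags) if f == "good")

    def poor_assessors(self) -> tuple[str, ...]:
        return tuple(a for a, f in zip(self.assessors, self.flags) if f == "poor")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assessor_average": self.assessor_averages,
                "flag": list(self.flags),
            },
            index=pd.Index(self.assessors, name="assessor"),
        )


def summarize(matrix: PairSimilarityMatrix) -> DiscriminationSummary:
    """Compute the consensus-limit classification of all assessors.

    Flags use strict inequality: an assessor is "good" iff their column
    average is strictly below the grand mean; an average exactly at the
    limit is "poor".
    """
    v = matrix.values
    if v.size == 0:
        raise ValueError("cannot summarize an empty similarity matrix")
    averages = v.mean(axis=0)
    limit = float(v.mean())
    flags = tuple("good" if av < limit else "poor" for av in averages)
    return DiscriminationSummary(
        assessors=matrix.assessors,
        assessor_averages=averages,
        consensus_limit=limit,
        flags=flags,
        row_min=float(v.min()),
        row_max=float(v.max()),
        discrimination_index=100.0 * limit,
    )


def discrimination_index(matrix: PairSimilarityMatrix) -> float:
    """Grand average of the consensus matrix as a percentage (lower = better)."""
    if matrix.values.size == 0:
        raise ValueError("cannot compute discrimination index of an empty matrix")
    return 100.0 * float(matrix.values.mean())


def heatmap_export(
    matrix: PairSimilarityMatrix,
    summary: DiscriminationSummary,
    sink: IO[str] | str,
    image: IO[bytes] | str | None = None,
) -> None:
    """Write the heatmap data: matrix CSV plus assessor-average and flag rows.

    The CSV is the canonical artifact.  If ``image`` is given, a raster
    heatmap is also rendered with a linear green-to-red colormap anchored at
    [row_min, row_max] of the data (green = lowest similarity = best
    discrimination), mirroring the usual panel-diagnostic display.
    """
    frame = matrix.to_frame()
    aug = pd.concat(
        [
            frame,
            pd.DataFrame(
                [summary.assessor_averages, list(summary.flags)],
                index=pd.Index(["assessor_average", "flag"], name="pair"),
                columns=frame.columns,
            ),
        ]
    )
    write_matrix(aug, sink)
    if image is not None:
        _render_heatmap(matrix, summary, image)


def _render_heatmap(
    matrix: PairSimilarityMatrix, summary: DiscriminationSummary, image: IO[bytes] | str
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, Normalize

    cmap = LinearSegmentedColormap.from_list("discrim", ["green", "yellow", "red"])
    span = summary.row_max - summary.row_min
    norm = Normalize(
        vmin=summary.row_min,
        vmax=summary.row_max if span > 0 else summary.row_min + 1e-12,
    )
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.22 * len(matrix.assessors)), max(2.5, 0.45 * matrix.n_pairs))
    )
    im = ax.imshow(matrix.values, cmap=cmap, norm=norm, aspect="auto")
    ax.set_yticks(range(matrix.n_pairs), matrix.pair_labels)
    ax.set_xlabel("assessor")
    fig.colorbar(im, ax=ax, label="consensus similarity")
    fig.tight_layout()
    fig.savefig(image, format="png", dpi=100)
    plt.close(fig)
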