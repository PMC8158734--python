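"""Grouping assessors into good/poor discriminators by hierarchical clustering.

Each assessor is a point in pair-space: their column of the consensus
similarity matrix (one coordinate per sample pair, already on a common
[0, 1] scale, so no further standardization is applied).  Agglomerative
hierarchical clustering with Ward's minimum-variance criterion on Euclidean
distances — the textbook Lance-Williams recurrence, as provided by
scipy — builds the tree; cutting it at k clusters and comparing cluster
mean similarities assigns the roles: the cluster with the *lower* mean
consensus similarity is the good-discriminator group.

The number of clusters defaults to 2 (one good, one poor group); an
average-silhouette sweep over candidate k is reported alongside so the
choice is inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

from .metrics import PairSimilarityMatrix
from .panel import write_matrix

__all__ = ["ClusterResult", "ahc_cluster", "silhouette_sweep", "profile_export"]


@dataclass(frozen=True)
class ClusterResult:
    """Assessor partition with merge history, silhouettes and role labels."""

    assessors: tuple[str, ...]
    labels: np.ndarray = field(repr=False)  # cluster ids 1..k per assessor
    k: int
    linkage_tree: np.ndarray = field(repr=False)  # scipy linkage matrix
    silhouette_by_k: dict[int, float]
    cluster_means: dict[int, float]
    roles: dict[int, str]  # cluster id -> "good" | "poor"

    @property
    def good_cluster(self) -> int:
        return next(cid for cid, r in self.roles.items() if r == "good")

    def members(self, cluster_id: int) -> tuple[str, ...]:
        return tuple(
            a for a, l in zip(self.assessors, self.labels) if l == cluster_id
        )

    def role_of(self, assessor: str) -> str:
        return self.roles[int(self.labels[self.assessors.index(assessor)])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.labels,
                "role": [self.roles[int(l)] for l in self.labels],
            },
            index=pd.Index(self.assessors, name="assessor"),
        )


def _points(matrix: PairSimilarityMatrix) -> np.ndarray:
    """Assessors as rows, sample-pair consensus values as coordinates."""
    return np.ascontiguousarray(matrix.values.T)


def ahc_cluster(
    matrix: PairSimilarityMatrix,
    k: int = 2,
    k_range: Sequence[int] | None = None,
) -> ClusterResult:
    """Ward/Euclidean AHC of assessors cut at ``k`` clusters, with roles.

    ``k_range`` controls the silhouette sweep reported alongside (default
    2..min(6, m-1)).  Roles: among the k clusters, the one with the lowest
    mean consensus similarity is labeled "good"; all others "poor".  Ties in
    merge order are broken deterministically (scipy's nearest-neighbor
    chain on the canonical condensed distance ordering).
    """
    pts = _points(matrix)
    m = pts.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2 (a single cluster carries no contrast)")
    if k > m:
        raise ValueError(f"k={k} exceeds the number of assessors ({m})")
    tree = linkage(pts, method="ward", metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust")
    if k_range is None:
        k_range = range(2, min(6, m - 1) + 1)
    sweep = silhouette_sweep(matrix, k_range) if m > 2 else {}
    means = {
        int(cid): float(matrix.values[:, labels == cid].mean())
        for cid in np.unique(labels)
    }
    best = min(means, key=lambda cid: (means[cid], cid))
    roles = {cid: ("good" if cid == best else "poor") for cid in means}
    return ClusterResult(
        assessors=matrix.assessors,
        labels=labels,
        k=int(k),
        linkage_tree=tree,
        silhouette_by_k=sweep,
        cluster_means=means,
        roles=roles,
    )


def _mean_silhouette(pts: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width; singleton clusters and 0/0 widths count 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        widths = silhouette_samples(pts, labels, metric="euclidean")
    return float(np.nan_to_num(widths, nan=0.0).mean())


def silhouette_sweep(
    matrix: PairSimilarityMatrix, k_range: Sequence[int]
) -> dict[int, float]:
    """Average silhouette width of the Ward partition for each candidate k."""
    pts = _points(matrix)
    m = pts.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > m - 1:
        raise ValueError(
            f"k_range must lie within [2, {m - 1}] for {m} assessors; got {ks}"
        )
    tree = linkage(pts, method="ward", metric="euclidean")
    out: dict[int, float] = {}
    for k in ks:
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            # degenerate geometry (e.g. all points identical): convention 0
            out[k] = 0.0
        else:
            out[k] = _mean_silhouette(pts, labels)
    return out


def profile_export(
    matrix: PairSimilarityMatrix, result: ClusterResult, sink: IO[str] | str
) -> pd.DataFrame:
    """Per-cluster mean consensus per sample pair (the profile-plot data)."""
    if result.k < 2:
        raise ValueError("profile export needs at least 2 clusters")
    cols = {}
    for cid in sorted(result.cluster_means):
        cols[f"cluster_{cid} ({result.roles[cid]})"] = matrix.values[
            :, result.labels == cid
        ].mean(axis=1)
    frame = pd.DataFrame(cols, index=pd.Index(matrix.pair_labels, name="pair"))
    write_matrix(frame, sink)
    return frame
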