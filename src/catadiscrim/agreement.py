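"""Panel agreement via the CATATIS homogeneity index.

Each assessor's responses form a product x attribute 0/1 matrix.  The
agreement between two assessors is the cosine of their matrices in the
Frobenius inner product; the assessor x assessor cosine matrix is a Gram
matrix (positive semidefinite, unit diagonal for non-zero assessors).  The
CATATIS homogeneity index is its leading eigenvalue divided by the number
of assessors, as a percentage: 100% when all assessors respond
identically, 100/m% when their matrices are pairwise orthogonal.

Agreement measures *consensus with the panel*, discrimination measures
*contrast between products* — the joint per-assessor view pairs each
assessor's CATATIS weight with their mean consensus similarity, plus the
Pearson correlation of the two across the panel (typically near zero: one
does not imply the other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import PairSimilarityMatrix
from .panel import CATAPanel

__all__ = ["AgreementResult", "catatis_homogeneity", "agreement_vs_discrimination"]


@dataclass(frozen=True)
class AgreementResult:
    """Cosine Gram matrix, first-eigenvector weights and homogeneity index."""

    assessors: tuple[str, ...]
    cosine_matrix: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)  # leading eigenvector, unit sum
    homogeneity: float  # percentage in [100/m, 100]
    dropped: tuple[str, ...] = ()  # zero-norm assessors excluded

    def cosine_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.assessors, name="assessor")
        return pd.DataFrame(self.cosine_matrix, index=idx, columns=list(self.assessors))


def catatis_homogeneity(panel: CATAPanel) -> AgreementResult:
    """CATATIS agreement of a panel: leading eigenvalue of the cosine Gram.

    Assessors whose response matrix is entirely zero have no direction in
    response space; they are dropped from the index and reported in
    ``dropped``.  An entirely zero panel is an error.
    """
    flat = panel.checks.reshape(panel.n_assessors, -1).astype(float)
    norms = np.linalg.norm(flat, axis=1)
    keep = norms > 0
    if not keep.any():
        raise ValueError("all assessors gave all-zero responses; agreement undefined")
    dropped = tuple(a for a, k in zip(panel.assessors, keep) if not k)
    flat = flat[keep]
    norms = norms[keep]
    assessors = tuple(a for a, k in zip(panel.assessors, keep) if k)
    unit = flat / norms[:, None]
    cosine = unit @ unit.T
    np.fill_diagonal(cosine, 1.0)
    m = len(assessors)
    eigvals, eigvecs = np.linalg.eigh(cosine)
    lam1 = float(eigvals[-1])
    v1 = eigvecs[:, -1]
    # Perron direction of a non-negative matrix: make it non-negative
    if v1.sum() < 0:
        v1 = -v1
    weights = v1 / v1.sum()
    return AgreementResult(
        assessors=assessors,
        cosine_matrix=cosine,
        weights=weights,
        homogeneity=100.0 * lam1 / m,
        dropped=dropped,
    )


def agreement_vs_discrimination(
    panel: CATAPanel, matrix: PairSimilarityMatrix
) -> tuple[pd.DataFrame, float]:
    """Per-assessor agreement weight vs. mean consensus similarity.

    Returns the paired table (one row per assessor with columns
    ``agreement_weight`` and ``mean_similarity``) and the Pearson
    correlation between the two columns across assessors.
    """
    if set(panel.assessors) != set(matrix.assessors):
        raise ValueError("panel and similarity matrix cover different assessor sets")
    agree = catatis_homogeneity(panel)
    if agree.dropped:
        raise ValueError(
            f"assessors with all-zero responses have no agreement weight: {agree.dropped}"
        )
    weights = dict(zip(agree.assessors, agree.weights))
    table = pd.DataFrame(
        {
            "agreement_weight": [weights[a] for a in matrix.assessors],
            "mean_similarity": matrix.values.mean(axis=0),
        },
        index=pd.Index(matrix.assessors, name="assessor"),
    )
    w = table["agreement_weight"].to_numpy()
    s = table["mean_similarity"].to_numpy()
    if len(table) < 2 or np.std(w) == 0 or np.std(s) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(w, s)[0, 1])
    return table, corr
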