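"""Attribute- and product-level statistics per assessor group.

Three classical tools applied to a CATA panel (whole panel or one cluster
of assessors):

* **Cochran's Q** per attribute — does the proportion of assessors checking
  the attribute differ across samples?  Q is chi-square distributed with
  S - 1 degrees of freedom under the null of equal proportions.
* **Correspondence analysis** of the product x attribute count table
  (how many assessors in the group checked each attribute for each
  product): SVD of the standardized residuals of the correspondence
  matrix; total inertia equals the table's Pearson chi-square divided by
  its grand total.
* **One-way ANOVA with Tukey HSD** on overall liking across products,
  summarized as a compact letter display (samples sharing a letter are not
  significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.sandbox.stats.multicomp import MultiComparison
from statsmodels.stats.multitest import multipletests

from .panel import CATAPanel, LikingTable

__all__ = [
    "CochranQResult",
    "CAResult",
    "TukeyLetters",
    "cochran_q",
    "significant_attributes",
    "build_counts",
    "correspondence",
    "liking_anova_tukey",
]


# --------------------------------------------------------------------------
# Cochran's Q
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CochranQResult:
    attribute: str
    Q: float
    df: int
    p_value: float
    significant: bool
    degenerate: bool = False


def _attribute_block(panel: CATAPanel, attribute: str, subset: Sequence[str]) -> np.ndarray:
    """Assessor x sample 0/1 block for one attribute, restricted to ``subset``."""
    k = panel.attributes.index(attribute)
    idx = [panel.assessors.index(a) for a in subset]
    return panel.checks[idx, :, k].astype(np.int64)


def cochran_q(
    panel: CATAPanel,
    attribute: str,
    subset: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> CochranQResult:
    """Cochran's Q test of equal check proportions across samples.

    Q = (S-1) * [S * sum(C_j^2) - (sum C_j)^2] / [S * sum(R_i) - sum(R_i^2)]
    with C_j the per-sample totals and R_i the per-assessor totals over the
    subset.  Assessors with constant responses cancel out of the statistic.
    A zero denominator (every assessor constant) yields the degenerate
    result Q = 0, p = 1, significant = False.
    """
    if subset is None:
        subset = panel.assessors
    subset = list(subset)
    if not subset:
        raise ValueError("assessor subset must not be empty")
    S = panel.n_samples
    if S < 2:
        raise ValueError("Cochran's Q needs at least 2 samples")
    block = _attribute_block(panel, attribute, subset)
    C = block.sum(axis=0)
    R = block.sum(axis=1)
    num = S * (C**2).sum() - C.sum() ** 2
    den = S * R.sum() - (R**2).sum()
    df = S - 1
    if den == 0:
        return CochranQResult(attribute, 0.0, df, 1.0, False, degenerate=True)
    Q = df * num / den
    p = float(sps.chi2.sf(Q, df))
    return CochranQResult(attribute, float(Q), df, p, p < alpha)


def significant_attributes(
    panel: CATAPanel,
    subset: Sequence[str] | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[str]:
    """Attributes whose Cochran's Q p-value falls below alpha, lexicon order.

    ``correction`` in {None, "bonferroni", "fdr_bh"} applies a multiplicity
    adjustment across attributes; none is applied by default.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1]; got {alpha}")
    results = [cochran_q(panel, t, subset, alpha) for t in panel.attributes]
    pvals = np.array([r.p_value for r in results])
    if correction is None:
        keep = pvals < alpha
    else:
        keep = multipletests(pvals, alpha=alpha, method=correction)[0]
        keep &= ~np.array([r.degenerate for r in results])
    return [t for t, k in zip(panel.attributes, keep) if k]


def cochran_q_table(
    panel: CATAPanel,
    subset: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-attribute Q-test table (attribute, Q, df, p, significant)."""
    rows = [cochran_q(panel, t, subset, alpha) for t in panel.attributes]
    return pd.DataFrame(
        {
            "Q": [r.Q for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "degenerate": [r.degenerate for r in rows],
        },
        index=pd.Index(panel.attributes, name="attribute"),
    )


# --------------------------------------------------------------------------
# counts and correspondence analysis
# --------------------------------------------------------------------------


def build_counts(
    panel: CATAPanel,
    subset: Sequence[str] | None = None,
    attributes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Product x attribute citation counts over an assessor subset."""
    if subset is None:
        subset = panel.assessors
    if attributes is None:
        attributes = panel.attributes
    if not len(attributes):
        raise ValueError("attribute list must not be empty")
    a_idx = [panel.assessors.index(a) for a in subset]
    t_idx = [panel.attributes.index(t) for t in attributes]
    counts = panel.checks[a_idx][:, :, t_idx].sum(axis=0)
    return pd.DataFrame(
        counts,
        index=pd.Index(panel.samples, name="product"),
        columns=list(attributes),
    )


@dataclass(frozen=True)
class CAResult:
    """Correspondence analysis of a two-way count table.

    ``row_coords``/``col_coords`` hold principal coordinates (rows/columns
    of the table x retained dimensions).  ``explained`` are percentages of
    total inertia per dimension; ``plane_explained`` is the first-plane sum.
    """

    row_names: tuple[str, ...]
    col_names: tuple[str, ...]
    row_coords: np.ndarray = field(repr=False)
    col_coords: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    total_inertia: float
    explained: np.ndarray = field(repr=False)
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()

    @property
    def n_dims(self) -> int:
        return len(self.eigenvalues)

    @property
    def plane_explained(self) -> float:
        return float(self.explained[:2].sum()) if self.n_dims else 0.0

    def coords_frame(self) -> pd.DataFrame:
        dims = [f"dim{i + 1}" for i in range(self.n_dims)]
        rows = pd.DataFrame(self.row_coords, index=self.row_names, columns=dims)
        rows.insert(0, "type", "product")
        cols = pd.DataFrame(self.col_coords, index=self.col_names, columns=dims)
        cols.insert(0, "type", "attribute")
        out = pd.concat([rows, cols])
        out.index.name = "entity"
        return out

    def eigen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "explained_pct": self.explained},
            index=pd.Index(
                [f"dim{i + 1}" for i in range(self.n_dims)], name="dimension"
            ),
        )


_SV_TOL = 1e-12


def correspondence(table: pd.DataFrame) -> CAResult:
    """Standard correspondence analysis of a non-negative count table.

    The correspondence matrix P = N / n is decomposed through the SVD of
    the standardized residuals (P - r c') / sqrt(r c'); principal
    coordinates are the mass-rescaled singular vectors scaled by their
    singular values.  All-zero rows/columns are dropped (and reported);
    singular values below 1e-12 are treated as null dimensions.  An exactly
    independent table yields zero inertia and no retained dimensions.
    """
    N = np.asarray(table, dtype=float)
    if (N < 0).any():
        raise ValueError("count table must be non-negative")
    if N.sum() == 0:
        raise ValueError("count table is entirely zero")
    row_names = [str(r) for r in table.index]
    col_names = [str(c) for c in table.columns]
    keep_r = N.sum(axis=1) > 0
    keep_c = N.sum(axis=0) > 0
    dropped_rows = tuple(n for n, k in zip(row_names, keep_r) if not k)
    dropped_cols = tuple(n for n, k in zip(col_names, keep_c) if not k)
    N = N[np.ix_(keep_r, keep_c)]
    row_names = [n for n, k in zip(row_names, keep_r) if k]
    col_names = [n for n, k in zip(col_names, keep_c) if k]

    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    resid = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(resid, full_matrices=False)
    keep = sv > _SV_TOL
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    eigen = sv**2
    total = float(eigen.sum())
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None]
    explained = 100.0 * eigen / total if total > 0 else eigen.copy()
    return CAResult(
        row_names=tuple(row_names),
        col_names=tuple(col_names),
        row_coords=row_coords,
        col_coords=col_coords,
        eigenvalues=eigen,
        total_inertia=total,
        explained=explained,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


# --------------------------------------------------------------------------
# liking ANOVA + Tukey compact letter display
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TukeyLetters:
    sample: str
    mean: float
    letters: str


def _letter_display(
    ordered: Sequence[str], significant: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``ordered`` lists the samples by ascending mean; the returned letters
    start at 'a' for the lowest-mean group.  Two samples share a letter iff
    their pair is not in ``significant``.
    """
    columns: list[set[str]] = [set(ordered)]
    for pair in sorted(significant, key=lambda fs: sorted(fs)):
        i, j = sorted(pair)
        new_cols: list[set[str]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {j})
                new_cols.append(col - {i})
            else:
                new_cols.append(col)
        # absorb: drop duplicates and strict subsets
        columns = []
        for col in new_cols:
            if any(col < other or col == other for other in columns) or any(
                col < other for other in new_cols if other is not col
            ):
                continue
            if col not in columns:
                columns.append(col)
    rank = {s: i for i, s in enumerate(ordered)}
    columns.sort(key=lambda col: min(rank[s] for s in col))
    letters: dict[str, list[str]] = {s: [] for s in ordered}
    for letter_idx, col in enumerate(columns):
        letter = chr(ord("a") + letter_idx)
        for s in col:
            letters[s].append(letter)
    return {s: "".join(sorted(v)) for s, v in letters.items()}


def liking_anova_tukey(
    liking: LikingTable,
    subset: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[TukeyLetters]:
    """One-way ANOVA + Tukey HSD on overall liking across products.

    Requires at least two products with at least two ratings each in the
    subset, and non-zero pooled within-product variance.  Returns one entry
    per product, ordered by ascending mean, with letters assigned from 'a'
    at the lowest mean upward.
    """
    df = liking.ratings
    if subset is not None:
        df = df[df["assessor"].isin(set(subset))]
    groups = {s: g["liking"].to_numpy(float) for s, g in df.groupby("sample", sort=False)}
    groups = {s: v for s, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 products with >= 2 ratings each")
    if all(np.var(v) == 0 for v in groups.values()):
        raise ValueError("zero within-product variance everywhere; F undefined")
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[s] * len(v) for s, v in groups.items()])
    tukey = MultiComparison(values, labels).tukeyhsd(alpha=alpha)
    names = [str(n) for n in tukey.groupsunique]
    significant = {
        frozenset((names[i], names[j])): bool(rej)
        for (i, j), rej in zip(
            [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))],
            tukey.reject,
        )
    }
    sig_pairs = {pair for pair, rej in significant.items() if rej}
    means = {s: float(v.mean()) for s, v in groups.items()}
    ordered = sorted(means, key=lambda s: (means[s], s))
    letters = _letter_display(ordered, sig_pairs)
    return [TukeyLetters(s, means[s], letters[s]) for s in ordered]


def tukey_frame(letters: Sequence[TukeyLetters]) -> pd.DataFrame:
    return pd.DataFrame(
        {"mean_liking": [t.mean for t in letters], "letters": [t.letters for t in letters]},
        index=pd.Index([t.sample for t in letters], name="sample"),
    )
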