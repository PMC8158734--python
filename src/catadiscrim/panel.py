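"""Containers and CSV I/O for check-all-that-apply (CATA) panels.

A CATA evaluation yields one binary vector per (assessor, sample): a 1 marks
every attribute the assessor ticked for that sample.  Two CSV dialects are
supported:

* ``long`` — columns ``assessor, sample, attribute, checked``; rows for
  unchecked attributes may be omitted (many capture tools record only the
  ticked terms).
* ``wide`` — key columns ``assessor, sample`` followed by one 0/1 column per
  attribute.

Labels are matched case-sensitively after stripping surrounding whitespace.
Ordering of assessors, samples and attributes is first-appearance order and
is stable across a write/read round trip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATAPanel",
    "LikingTable",
    "PanelValidationError",
    "read_panel",
    "read_liking",
    "write_panel",
    "write_liking",
    "write_matrix",
    "read_matrix",
]


class PanelValidationError(ValueError):
    """Raised when an input table violates a CATA panel invariant."""


def _strip(label: object) -> str:
    return str(label).strip()


@dataclass(frozen=True)
class CATAPanel:
    """A complete CATA design: binary checks per (assessor, sample, attribute).

    Parameters
    ----------
    assessors, samples, attributes
        Ordered unique identifiers (first-appearance order of the source).
    checks
        Binary array of shape ``(n_assessors, n_samples, n_attributes)``.
    """

    assessors: tuple[str, ...]
    samples: tuple[str, ...]
    attributes: tuple[str, ...]
    checks: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.checks)
        expected = (len(self.assessors), len(self.samples), len(self.attributes))
        if arr.shape != expected:
            raise PanelValidationError(
                f"checks shape {arr.shape} does not match design {expected}"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise PanelValidationError("checks must contain only 0 or 1")
        for name, labels in (
            ("assessor", self.assessors),
            ("sample", self.samples),
            ("attribute", self.attributes),
        ):
            if len(set(labels)) != len(labels):
                raise PanelValidationError(f"duplicate {name} labels: {labels}")
        object.__setattr__(self, "checks", arr.astype(np.int8))

    @property
    def n_assessors(self) -> int:
        return len(self.assessors)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    def vector(self, assessor: str, sample: str) -> np.ndarray:
        """Binary attribute vector for one (assessor, sample) cell."""
        i = self.assessors.index(assessor)
        j = self.samples.index(sample)
        return self.checks[i, j]

    def subset_assessors(self, keep: Iterable[str]) -> "CATAPanel":
        keep = [_strip(k) for k in keep]
        missing = [k for k in keep if k not in self.assessors]
        if missing:
            raise PanelValidationError(f"unknown assessors: {missing}")
        idx = [self.assessors.index(k) for k in keep]
        return CATAPanel(tuple(keep), self.samples, self.attributes, self.checks[idx])

    def to_frame(self, dialect: str = "wide") -> pd.DataFrame:
        """Render the panel as a DataFrame in the given CSV dialect."""
        if dialect == "wide":
            rows = []
            for i, a in enumerate(self.assessors):
                for j, s in enumerate(self.samples):
                    rows.append([a, s, *self.checks[i, j].tolist()])
            return pd.DataFrame(rows, columns=["assessor", "sample", *self.attributes])
        if dialect == "long":
            recs = []
            for i, a in enumerate(self.assessors):
                for j, s in enumerate(self.samples):
                    for k, t in enumerate(self.attributes):
                        recs.append((a, s, t, int(self.checks[i, j, k])))
            return pd.DataFrame(recs, columns=["assessor", "sample", "attribute", "checked"])
        raise ValueError(f"unknown dialect {dialect!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CATAPanel):
            return NotImplemented
        return (
            self.assessors == other.assessors
            and self.samples == other.samples
            and self.attributes == other.attributes
            and np.array_equal(self.checks, other.checks)
        )


@dataclass(frozen=True)
class LikingTable:
    """Hedonic (overall liking) ratings per (assessor, sample).

    ``scale_min``/``scale_max`` declare the rating scale; every rating must
    lie inside those bounds.  Assessor/sample identifiers are expected to be
    a subset of a companion :class:`CATAPanel`'s.
    """

    ratings: pd.DataFrame = field(repr=False)  # columns: assessor, sample, liking
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        df = self.ratings
        required = ["assessor", "sample", "liking"]
        if list(df.columns[:3]) != required:
            raise PanelValidationError(f"liking table needs columns {required}")
        if len(df):
            vals = df["liking"].to_numpy(dtype=float)
            bad = (vals < self.scale_min) | (vals > self.scale_max)
            if bad.any():
                row = df.index[bad][0]
                raise PanelValidationError(
                    f"liking {df.loc[row, 'liking']} outside scale "
                    f"[{self.scale_min}, {self.scale_max}] at row {row}"
                )

    def __len__(self) -> int:
        return len(self.ratings)

    def for_assessors(self, keep: Iterable[str]) -> "LikingTable":
        keep = set(keep)
        sub = self.ratings[self.ratings["assessor"].isin(keep)].reset_index(drop=True)
        return LikingTable(sub, self.scale_min, self.scale_max)


def _ordered_unique(values: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def _as_binary(value: object, where: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise PanelValidationError(f"non-numeric check value {value!r} at {where}") from None
    if f not in (0.0, 1.0):
        raise PanelValidationError(f"non-binary check value {value!r} at {where}")
    return int(f)


def read_panel(source: IO[str] | str, dialect: str = "wide", sep: str = ",") -> CATAPanel:
    """Read a CATA panel from a CSV stream or path.

    The design must be complete: every assessor must have a row (wide) or
    rows (long) for every sample.  In the long dialect an absent
    (assessor, sample, attribute) record means unchecked (0); absent
    *cells* — an (assessor, sample) pair with no record at all — make the
    design incomplete and are rejected.
    """
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [_strip(c) for c in df.columns]
    if dialect == "wide":
        return _panel_from_wide(df)
    if dialect == "long":
        return _panel_from_long(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def _panel_from_wide(df: pd.DataFrame) -> CATAPanel:
    if list(df.columns[:2]) != ["assessor", "sample"]:
        raise PanelValidationError(
            f"wide dialect needs leading columns 'assessor','sample'; got {list(df.columns[:2])}"
        )
    attributes = list(df.columns[2:])
    if not attributes:
        raise PanelValidationError("wide panel has no attribute columns")
    if len(set(attributes)) != len(attributes):
        raise PanelValidationError(f"duplicate attribute columns: {attributes}")
    df = df.copy()
    df["assessor"] = df["assessor"].map(_strip)
    df["sample"] = df["sample"].map(_strip)
    assessors = _ordered_unique(df["assessor"])
    samples = _ordered_unique(df["sample"])
    dup = df.duplicated(subset=["assessor", "sample"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["assessor", "sample"]].tolist()
        raise PanelValidationError(f"duplicate (assessor, sample) row: {pair}")
    checks = np.zeros((len(assessors), len(samples), len(attributes)), dtype=np.int8)
    seen = np.zeros((len(assessors), len(samples)), dtype=bool)
    a_idx = {a: i for i, a in enumerate(assessors)}
    s_idx = {s: j for j, s in enumerate(samples)}
    for rownum, rec in enumerate(df.itertuples(index=False), start=2):
        i, j = a_idx[rec[0]], s_idx[rec[1]]
        seen[i, j] = True
        for k, t in enumerate(attributes):
            checks[i, j, k] = _as_binary(rec[2 + k], f"row {rownum}, column {t!r}")
    _require_complete(seen, assessors, samples)
    return CATAPanel(tuple(assessors), tuple(samples), tuple(attributes), checks)


def _panel_from_long(df: pd.DataFrame) -> CATAPanel:
    required = ["assessor", "sample", "attribute", "checked"]
    if list(df.columns[:4]) != required:
        raise PanelValidationError(f"long dialect needs columns {required}; got {list(df.columns[:4])}")
    df = df.copy()
    for col in ("assessor", "sample", "attribute"):
        df[col] = df[col].map(_strip)
    assessors = _ordered_unique(df["assessor"])
    samples = _ordered_unique(df["sample"])
    attributes = _ordered_unique(df["attribute"])
    dup = df.duplicated(subset=["assessor", "sample", "attribute"])
    if dup.any():
        trip = df.loc[dup.idxmax(), ["assessor", "sample", "attribute"]].tolist()
        raise PanelValidationError(f"duplicate (assessor, sample, attribute) record: {trip}")
    checks = np.zeros((len(assessors), len(samples), len(attributes)), dtype=np.int8)
    seen = np.zeros((len(assessors), len(samples)), dtype=bool)
    a_idx = {a: i for i, a in enumerate(assessors)}
    s_idx = {s: j for j, s in enumerate(samples)}
    t_idx = {t: k for k, t in enumerate(attributes)}
    for rownum, rec in enumerate(df.itertuples(index=False), start=2):
        i, j, k = a_idx[rec[0]], s_idx[rec[1]], t_idx[rec[2]]
        seen[i, j] = True
        checks[i, j, k] = _as_binary(rec[3], f"row {rownum}")
    _require_complete(seen, assessors, samples)
    return CATAPanel(tuple(assessors), tuple(samples), tuple(attributes), checks)


def _require_complete(seen: np.ndarray, assessors: Sequence[str], samples: Sequence[str]) -> None:
    if not seen.all():
        missing = [
            (assessors[i], samples[j])
            for i, j in zip(*np.nonzero(~seen))
        ]
        raise PanelValidationError(f"incomplete design; missing cells: {missing}")


def read_liking(
    source: IO[str] | str, scale_min: float, scale_max: float, sep: str = ","
) -> LikingTable:
    """Read (assessor, sample, liking) ratings; bounds are a required input."""
    df = pd.read_csv(source, sep=sep, dtype={0: str, 1: str})
    df.columns = [_strip(c) for c in df.columns]
    if len(df.columns) < 3:
        raise PanelValidationError("liking table needs columns assessor, sample, liking")
    df = df.iloc[:, :3].copy()
    df.columns = ["assessor", "sample", "liking"]
    if len(df):
        df["assessor"] = df["assessor"].map(_strip)
        df["sample"] = df["sample"].map(_strip)
        df["liking"] = df["liking"].astype(float)
    return LikingTable(df.reset_index(drop=True), float(scale_min), float(scale_max))


def write_panel(panel: CATAPanel, sink: IO[str] | str, dialect: str = "wide", sep: str = ",") -> None:
    """Write a panel in either CSV dialect (inverse of :func:`read_panel`)."""
    panel.to_frame(dialect).to_csv(sink, sep=sep, index=False)


def write_liking(table: LikingTable, sink: IO[str] | str, sep: str = ",") -> None:
    table.ratings.to_csv(sink, sep=sep, index=False)


def write_matrix(matrix: pd.DataFrame, sink: IO[str] | str, sep: str = ",") -> None:
    """Write any labeled 2-D result: header = column labels, first column = row labels.

    Values keep at least 9 significant digits so a write/read round trip is
    faithful well below 1e-9.
    """
    matrix.to_csv(sink, sep=sep, float_format="%.12g", index_label=matrix.index.name or "")


def read_matrix(source: IO[str] | str, sep: str = ",") -> pd.DataFrame:
    """Read back a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(source, sep=sep, index_col=0)
    df.index.name = df.index.name or None
    return df
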