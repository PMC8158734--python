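"""Binary similarity coefficients and their consensus for CATA sample pairs.

Two binary attribute vectors (one assessor's responses to two samples) are
summarized by the 2x2 contingency quad

    a = attributes checked in both samples
    b = checked in the first sample only
    c = checked in the second only
    d = checked in neither
    p = a + b + c + d  (lexicon size)

on which a registry of 44 binary similarity coefficients is evaluated.  The
registry draws on the comprehensive collection of Todeschini et al. (J.
Chem. Inf. Model. 2012, 52, 2884), the standard reference for binary
similarity in chemometrics.  Coefficients whose
natural range is not [0, 1] are mapped onto it by the affine scaling

    scaled = (similarity + alpha) / beta

with per-coefficient constants (possibly depending on p); distance-type
entries are first converted through similarity = 1 / (1 + distance).  The
*consensus similarity* of a sample pair is the unweighted arithmetic mean of
all 44 scaled coefficients: no single coefficient can be privileged a
priori, and averaging partially cancels their individual biases.

Every registry entry is symmetric under swapping the two compared vectors
(equivalently under the b/c swap).  Degenerate 0/0 denominators never raise;
each entry records its convention (e.g. co-occurrence coefficients such as
Jaccard-Tanimoto evaluate to 0 on two all-zero vectors, agreement
coefficients such as Cohen evaluate to 1 on identical vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import CATAPanel

__all__ = [
    "ContingencyQuad",
    "MetricSpec",
    "PairSimilarityMatrix",
    "REGISTRY",
    "registry",
    "registry_frame",
    "contingency_quad",
    "eval_metric",
    "distance_to_similarity",
    "scale_similarity",
    "scaled_similarity",
    "consensus_similarity",
    "pairwise_matrix",
]

_EPS = 1e-9


@dataclass(frozen=True)
class ContingencyQuad:
    """2x2 match/mismatch counts for one pair of binary attribute vectors."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"quad count {name}={v} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.p < 1:
            raise ValueError("quad total p must be >= 1")

    @property
    def p(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyQuad":
        """The quad of the same pair with the two vectors exchanged."""
        return ContingencyQuad(self.a, self.c, self.b, self.d)


def contingency_quad(x: Sequence[int], y: Sequence[int]) -> ContingencyQuad:
    """Tally the (a, b, c, d) quad for two equal-length binary vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D with equal length; got {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("vectors must have length >= 1")
    for name, v in (("x", x), ("y", y)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"vector {name} contains non-binary entries")
    x = x.astype(bool)
    y = y.astype(bool)
    return ContingencyQuad(
        int((x & y).sum()),
        int((x & ~y).sum()),
        int((~x & y).sum()),
        int((~x & ~y).sum()),
    )


# --------------------------------------------------------------------------
# raw coefficient formulas, vectorized over broadcastable (a, b, c, d, p)
# --------------------------------------------------------------------------


def _div(num, den, fill=0.0):
    """Elementwise num/den with a declared value where den == 0."""
    num, den, fill = np.broadcast_arrays(
        np.asarray(num, float), np.asarray(den, float), np.asarray(fill, float)
    )
    out = np.array(fill, dtype=float, copy=True)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _jt(a, b, c, d, p):
    return _div(a, a + b + c)


def _sm(a, b, c, d, p):
    return (a + d) / p


def _gle(a, b, c, d, p):
    return _div(2 * a, 2 * a + b + c)


def _rr(a, b, c, d, p):
    return a / p


def _rt(a, b, c, d, p):
    return (a + d) / (p + b + c)


def _dk(a, b, c, d, p):
    return _div(a, np.sqrt((a + b) * (a + c)))


def _kul(a, b, c, d, p):
    return 0.5 * (_div(a, a + b) + _div(a, a + c))


def _bb(a, b, c, d, p):
    return _div(a, np.maximum(a + b, a + c))


def _simpson(a, b, c, d, p):
    return _div(a, np.minimum(a + b, a + c))


def _ss1(a, b, c, d, p):
    return _div(a, a + 2 * (b + c))


def _ss2(a, b, c, d, p):
    return 2 * (a + d) / (p + a + d)


def _ss4(a, b, c, d, p):
    return 0.25 * (
        _div(a, a + b) + _div(a, a + c) + _div(d, b + d) + _div(d, c + d)
    )


def _rg(a, b, c, d, p):
    return _div(a, 2 * a + b + c, 0.5) + _div(d, 2 * d + b + c, 0.5)


def _hd(a, b, c, d, p):
    return 0.5 * (_div(a, a + b + c, 1.0) + _div(d, b + c + d, 1.0))


def _fai(a, b, c, d, p):
    return (a + 0.5 * d) / p


def _ac(a, b, c, d, p):
    return (2.0 / np.pi) * np.arcsin(np.sqrt((a + d) / p))


def _ct1(a, b, c, d, p):
    return np.log1p(a + d) / np.log1p(p)


def _ct2(a, b, c, d, p):
    return (np.log1p(p) - np.log1p(b + c)) / np.log1p(p)


def _ct3(a, b, c, d, p):
    return np.log1p(a) / np.log1p(p)


def _ct4(a, b, c, d, p):
    return _div(np.log1p(a), np.log1p(a + b + c))


def _ja3w(a, b, c, d, p):
    return _div(3 * a, 3 * a + b + c)


def _sor(a, b, c, d, p):
    return _div(a * a, (a + b) * (a + c))


def _gl(a, b, c, d, p):
    return (a + d) / (a + d + 0.5 * (b + c))


def _bub(a, b, c, d, p):
    s = np.sqrt(a * d)
    return _div(s + a, s + a + b + c)


def _ham(a, b, c, d, p):
    return (a + d - b - c) / p


def _phi(a, b, c, d, p):
    return _div(a * d - b * c, np.sqrt((a + b) * (a + c) * (b + d) * (c + d)))


def _yu1(a, b, c, d, p):
    return _div(a * d - b * c, a * d + b * c)


def _yu2(a, b, c, d, p):
    sad, sbc = np.sqrt(a * d), np.sqrt(b * c)
    return _div(sad - sbc, sad + sbc)


def _mcc(a, b, c, d, p):
    return _div(a * a - b * c, (a + b) * (a + c))


def _tar(a, b, c, d, p):
    m = (a + b) * (a + c)
    return _div(p * a - m, p * a + m)


def _gk(a, b, c, d, p):
    m = np.minimum(a, d)
    return _div(2 * m - b - c, 2 * m + b + c, 1.0)


def _coh(a, b, c, d, p):
    return _div(2 * (a * d - b * c), (a + b) * (b + d) + (a + c) * (c + d), 1.0)


def _mp(a, b, c, d, p):
    # denominator vanishes only for identical (b=c=0) or complementary
    # (a=d=0) vectors; the respective limits are +1 and -1
    fill = np.where(np.asarray(b + c) == 0, 1.0, -1.0)
    return _div(2 * (a * d - b * c), (a + b) * (c + d) + (a + c) * (b + d), fill)


def _mic(a, b, c, d, p):
    return 4 * (a * d - b * c) / ((a + d) ** 2 + (b + c) ** 2)


def _ct5(a, b, c, d, p):
    return (np.log1p(a * d) - np.log1p(b * c)) / np.log1p(p * p / 4.0)


def _sco(a, b, c, d, p):
    return _div(4 * a * d - (b + c) ** 2, (2 * a + b + c) * (2 * d + b + c), 1.0)


def _dis(a, b, c, d, p):
    return (a * d - b * c) / p**2


def _den(a, b, c, d, p):
    return _div(a * d - b * c, np.sqrt(p * (a + b) * (a + c)))


def _fos(a, b, c, d, p):
    return _div(p * (a - 0.5) ** 2, (a + b) * (a + c))


def _forbes(a, b, c, d, p):
    return _div(p * a, (a + b) * (a + c))


def _mou(a, b, c, d, p):
    fill = np.where((np.asarray(b + c) == 0) & (np.asarray(a) > 0), 2.0, 0.0)
    return _div(2 * a, a * (b + c) + 2 * b * c, fill)


def _har(a, b, c, d, p):
    return _div(a * (2 * d + b + c), 2 * (a + b + c)) + _div(
        d * (2 * a + b + c), 2 * (b + c + d)
    )


def _and(a, b, c, d, p):
    t1 = (
        np.maximum(a, b)
        + np.maximum(c, d)
        + np.maximum(a, c)
        + np.maximum(b, d)
    )
    t2 = np.maximum(a + c, b + d) + np.maximum(a + b, c + d)
    return (t1 - t2) / (2.0 * p)


def _mmd(a, b, c, d, p):
    # mean Manhattan *distance*; converted via 1/(1+D) before scaling
    return (b + c) / p


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------


@dataclass(frozen=True, kw_only=True)
class MetricSpec:
    """One registry entry: formula, scaling and documented conventions.

    ``alpha``/``beta``/``raw_range`` are functions of the vector length p,
    because a few coefficients (Dennis, Forbes, Fossum, Harris-Lahey) have
    p-dependent natural ranges.  ``raw_range`` is the attainable range of
    the value entering the affine scaling — for distance-type entries that
    is the similarity *after* the 1/(1+D) conversion.
    """

    name: str
    long_name: str
    raw: Callable = field(repr=False)
    source: str
    formula: str
    is_distance: bool = False
    alpha: Callable[[float], float] = field(repr=False)
    beta: Callable[[float], float] = field(repr=False)
    raw_range: Callable[[float], tuple[float, float]] = field(repr=False)
    identity_dominant: bool = True
    degenerate: str = "0/0 -> 0"


def _const(x: float) -> Callable[[float], float]:
    return lambda p: x


def _unit_range(p):
    return (0.0, 1.0)


def _sym_range(p):
    return (-1.0, 1.0)


def _spec01(name, long_name, raw, source, formula, **kw) -> MetricSpec:
    return MetricSpec(
        name=name, long_name=long_name, raw=raw, source=source, formula=formula,
        alpha=_const(0.0), beta=_const(1.0), raw_range=_unit_range, **kw,
    )


def _spec11(name, long_name, raw, source, formula, **kw) -> MetricSpec:
    return MetricSpec(
        name=name, long_name=long_name, raw=raw, source=source, formula=formula,
        alpha=_const(1.0), beta=_const(2.0), raw_range=_sym_range, **kw,
    )


_TOD = "Todeschini et al., J. Chem. Inf. Model. 52 (2012) 2884"

_SPECS: tuple[MetricSpec, ...] = (
    # --- natively in [0, 1] -------------------------------------------------
    _spec01("JT", "Jaccard-Tanimoto", _jt, f"Jaccard 1901; {_TOD}", "a/(a+b+c)"),
    _spec01("SM", "Simple Matching (Sokal-Michener)", _sm, f"Sokal & Michener 1958; {_TOD}",
            "(a+d)/p", degenerate="always defined"),
    _spec01("Gle", "Gleason (Dice-Sorensen)", _gle, f"Gleason 1920; Dice 1945; {_TOD}",
            "2a/(2a+b+c)"),
    _spec01("RR", "Russel-Rao", _rr, f"Russel & Rao 1940; {_TOD}", "a/p",
            degenerate="always defined"),
    _spec01("RT", "Rogers-Tanimoto", _rt, f"Rogers & Tanimoto 1960; {_TOD}",
            "(a+d)/(p+b+c)", degenerate="always defined"),
    _spec01("DK", "Driver-Kroeber (Ochiai cosine)", _dk, f"Driver & Kroeber 1932; Ochiai 1957; {_TOD}",
            "a/sqrt((a+b)(a+c))"),
    _spec01("Kul", "Kulczynski 2", _kul, f"Kulczynski 1927; {_TOD}",
            "(a/(a+b)+a/(a+c))/2", degenerate="each 0/0 term -> 0"),
    _spec01("BB", "Braun-Blanquet", _bb, f"Braun-Blanquet 1932; {_TOD}",
            "a/max(a+b,a+c)"),
    _spec01("Sim", "Simpson", _simpson, f"Simpson 1943; {_TOD}", "a/min(a+b,a+c)"),
    _spec01("SS1", "Sokal-Sneath 1", _ss1, f"Sokal & Sneath 1963; {_TOD}",
            "a/(a+2b+2c)"),
    _spec01("SS2", "Sokal-Sneath 2", _ss2, f"Sokal & Sneath 1963; {_TOD}",
            "2(a+d)/(p+a+d)", degenerate="always defined"),
    _spec01("SS4", "Sokal-Sneath 4", _ss4, f"Sokal & Sneath 1963; {_TOD}",
            "(a/(a+b)+a/(a+c)+d/(b+d)+d/(c+d))/4", degenerate="each 0/0 term -> 0"),
    _spec01("RG", "Rogot-Goldberg", _rg, f"Rogot & Goldberg 1966; {_TOD}",
            "a/(2a+b+c)+d/(2d+b+c)", degenerate="each 0/0 term -> 1/2 (identical vectors score 1)"),
    _spec01("HD", "Hawkins-Dotson", _hd, f"Hawkins & Dotson 1968; {_TOD}",
            "(a/(a+b+c)+d/(b+c+d))/2", degenerate="each 0/0 term -> 1 (identical vectors score 1)"),
    _spec01("Fai", "Faith", _fai, f"Faith 1983; {_TOD}", "(a+d/2)/p",
            degenerate="always defined"),
    _spec01("AC", "Austin-Colwell", _ac, f"Austin & Colwell 1977; {_TOD}",
            "(2/pi) arcsin(sqrt((a+d)/p))", degenerate="always defined"),
    _spec01("CT1", "Consonni-Todeschini 1", _ct1, f"Consonni & Todeschini 2012; {_TOD}",
            "ln(1+a+d)/ln(1+p)", degenerate="always defined"),
    _spec01("CT2", "Consonni-Todeschini 2", _ct2, f"Consonni & Todeschini 2012; {_TOD}",
            "(ln(1+p)-ln(1+b+c))/ln(1+p)", degenerate="always defined"),
    _spec01("CT3", "Consonni-Todeschini 3", _ct3, f"Consonni & Todeschini 2012; {_TOD}",
            "ln(1+a)/ln(1+p)", degenerate="always defined"),
    _spec01("CT4", "Consonni-Todeschini 4", _ct4, f"Consonni & Todeschini 2012; {_TOD}",
            "ln(1+a)/ln(1+a+b+c)"),
    _spec01("Ja", "3W-Jaccard", _ja3w, f"{_TOD}", "3a/(3a+b+c)"),
    _spec01("Sor", "Sorgenfrei", _sor, f"Sorgenfrei 1958; {_TOD}",
            "a^2/((a+b)(a+c))"),
    _spec01("GL", "Gower-Legendre", _gl, f"Gower & Legendre 1986; {_TOD}",
            "(a+d)/(a+d+(b+c)/2)", degenerate="always defined"),
    _spec01("BUB", "Baroni-Urbani-Buser", _bub, f"Baroni-Urbani & Buser 1976; {_TOD}",
            "(sqrt(ad)+a)/(sqrt(ad)+a+b+c)"),
    # --- natively in [-1, 1]; scaled (x+1)/2 --------------------------------
    _spec11("Ham", "Hamann", _ham, f"Hamann 1961; {_TOD}", "(a+d-b-c)/p",
            degenerate="always defined"),
    _spec11("Phi", "Pearson phi", _phi, f"Pearson 1900 (Yule phi); {_TOD}",
            "(ad-bc)/sqrt((a+b)(a+c)(b+d)(c+d))"),
    _spec11("Yu1", "Yule Q", _yu1, f"Yule 1900; {_TOD}", "(ad-bc)/(ad+bc)"),
    _spec11("Yu2", "Yule omega", _yu2, f"Yule 1912; {_TOD}",
            "(sqrt(ad)-sqrt(bc))/(sqrt(ad)+sqrt(bc))"),
    _spec11("McC", "McConnaughey", _mcc, f"McConnaughey 1964; {_TOD}",
            "(a^2-bc)/((a+b)(a+c))"),
    _spec11("Tar", "Tarwid", _tar, f"Tarwid 1960; {_TOD}",
            "(pa-(a+b)(a+c))/(pa+(a+b)(a+c))"),
    _spec11("GK", "Goodman-Kruskal", _gk, f"Goodman & Kruskal 1954; {_TOD}",
            "(2 min(a,d)-b-c)/(2 min(a,d)+b+c)",
            degenerate="0/0 (identical all-ones/all-zeros) -> 1"),
    _spec11("Coh", "Cohen", _coh, f"Cohen 1960; {_TOD}",
            "2(ad-bc)/((a+b)(b+d)+(a+c)(c+d))",
            degenerate="0/0 (only for identical vectors) -> 1"),
    _spec11("MP", "Maxwell-Pilliner", _mp, f"Maxwell & Pilliner 1968; {_TOD}",
            "2(ad-bc)/((a+b)(c+d)+(a+c)(b+d))",
            degenerate="0/0 -> 1 for identical, -1 for complementary vectors"),
    _spec11("Mic", "Michael", _mic, f"Michael 1920; {_TOD}",
            "4(ad-bc)/((a+d)^2+(b+c)^2)",
            degenerate="always defined", identity_dominant=False),
    _spec11("CT5", "Consonni-Todeschini 5", _ct5, f"Consonni & Todeschini 2012; {_TOD}",
            "(ln(1+ad)-ln(1+bc))/ln(1+p^2/4)", degenerate="always defined"),
    _spec11("Sco", "Scott", _sco, f"Scott 1955; {_TOD}",
            "(4ad-(b+c)^2)/((2a+b+c)(2d+b+c))",
            degenerate="0/0 (only for identical vectors) -> 1"),
    # --- other natural ranges -----------------------------------------------
    MetricSpec(
        name="Dis", long_name="Dispersion", raw=_dis,
        source=f"{_TOD}", formula="(ad-bc)/p^2",
        alpha=_const(0.25), beta=_const(0.5),
        raw_range=lambda p: (-0.25, 0.25), degenerate="always defined",
    ),
    MetricSpec(
        name="Den", long_name="Dennis", raw=_den,
        source=f"Dennis 1965; {_TOD}", formula="(ad-bc)/sqrt(p(a+b)(a+c))",
        alpha=lambda p: np.sqrt(p) / 2.0,
        beta=lambda p: np.sqrt(p) / 2.0 + (p - 1.0) / np.sqrt(p),
        raw_range=lambda p: (-np.sqrt(p) / 2.0, (p - 1.0) / np.sqrt(p)),
        degenerate="0/0 -> 0 (scaled midpoint-high for p=1)",
    ),
    MetricSpec(
        name="Fos", long_name="Fossum", raw=_fos,
        source=f"Fossum 1966; {_TOD}", formula="p(a-1/2)^2/((a+b)(a+c))",
        alpha=_const(0.0), beta=lambda p: (p - 0.5) ** 2 / p,
        raw_range=lambda p: (0.0, (p - 0.5) ** 2 / p),
        identity_dominant=True,
    ),
    MetricSpec(
        name="For", long_name="Forbes", raw=_forbes,
        source=f"Forbes 1907; {_TOD}", formula="pa/((a+b)(a+c))",
        alpha=_const(0.0), beta=lambda p: np.asarray(p, float),
        raw_range=lambda p: (0.0, np.asarray(p, float)),
    ),
    MetricSpec(
        name="Mou", long_name="Mountford", raw=_mou,
        source=f"Mountford 1962; {_TOD}", formula="2a/(ab+ac+2bc)",
        alpha=_const(0.0), beta=_const(2.0),
        raw_range=lambda p: (0.0, 2.0),
        degenerate="b=c=0 -> 2 if a>0 else 0",
    ),
    MetricSpec(
        name="Har", long_name="Harris-Lahey", raw=_har,
        source=f"Harris & Lahey 1983; {_TOD}",
        formula="a(2d+b+c)/(2(a+b+c)) + d(2a+b+c)/(2(b+c+d))",
        alpha=_const(0.0), beta=lambda p: np.asarray(p, float),
        raw_range=lambda p: (0.0, np.asarray(p, float)),
        degenerate="each 0/0 term -> 0", identity_dominant=False,
    ),
    MetricSpec(
        name="And", long_name="Anderberg", raw=_and,
        source=f"Anderberg 1973; {_TOD}",
        formula="[max(a,b)+max(c,d)+max(a,c)+max(b,d)-max(a+c,b+d)-max(a+b,c+d)]/(2p)",
        alpha=_const(0.0), beta=_const(0.5),
        raw_range=lambda p: (0.0, 0.5),
        degenerate="always defined", identity_dominant=False,
    ),
    # --- distance-type, converted via 1/(1+D) -------------------------------
    MetricSpec(
        name="MMD", long_name="Mean Manhattan (distance)", raw=_mmd,
        source=f"{_TOD} (distance coefficient)", formula="D=(b+c)/p; S=1/(1+D)",
        is_distance=True,
        alpha=_const(-0.5), beta=_const(0.5),
        raw_range=lambda p: (0.5, 1.0),
        degenerate="always defined",
    ),
)

#: The canonical registry: exactly 44 uniquely named coefficients.
REGISTRY: dict[str, MetricSpec] = {s.name: s for s in _SPECS}
assert len(REGISTRY) == 44, f"registry must hold 44 metrics, has {len(REGISTRY)}"


def registry(names: Iterable[str] | None = None) -> tuple[MetricSpec, ...]:
    """The full 44-entry registry, or an explicit named subset (in registry order)."""
    if names is None:
        return _SPECS
    names = list(names)
    unknown = [n for n in names if n not in REGISTRY]
    if unknown:
        raise KeyError(f"unknown metrics: {unknown}")
    return tuple(s for s in _SPECS if s.name in set(names))


def registry_frame() -> pd.DataFrame:
    """Registry listing (name, formula, scaling, source) for CSV export."""
    rows = []
    for s in _SPECS:
        rows.append(
            {
                "name": s.name,
                "long_name": s.long_name,
                "formula": s.formula,
                "type": "distance" if s.is_distance else "similarity",
                "alpha_p38": s.alpha(38),
                "beta_p38": s.beta(38),
                "identity_dominant": s.identity_dominant,
                "degenerate_convention": s.degenerate,
                "source": s.source,
            }
        )
    return pd.DataFrame(rows).set_index("name")


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


def eval_metric(spec: MetricSpec, quad: ContingencyQuad) -> float:
    """Raw coefficient value (a raw *distance* for distance-type entries)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(spec.raw(quad.a, quad.b, quad.c, quad.d, quad.p))


def distance_to_similarity(distance: float) -> float:
    """Convert a non-negative distance to a similarity: S = 1/(1+D)."""
    arr = np.asarray(distance, float)
    if (arr < 0).any():
        raise ValueError(f"distance must be non-negative, got {distance}")
    return 1.0 / (1.0 + arr) if arr.ndim else float(1.0 / (1.0 + arr))


def scale_similarity(value: float, spec: MetricSpec, p: int) -> float:
    """Affine-map a raw similarity onto [0, 1]: (value + alpha) / beta.

    ``value`` must lie inside the entry's documented natural range for
    vector length ``p`` (for distance-type entries, the range of the
    similarity after the 1/(1+D) conversion).
    """
    lo, hi = spec.raw_range(p)
    arr = np.asarray(value, float)
    if ((arr < lo - _EPS) | (arr > hi + _EPS)).any():
        raise ValueError(
            f"value {value} outside natural range [{lo}, {hi}] of metric {spec.name}"
        )
    out = (arr + spec.alpha(p)) / spec.beta(p)
    return out if out.ndim else float(out)


def _scaled_arrays(spec: MetricSpec, a, b, c, d, p) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = spec.raw(a, b, c, d, p)
    sim = 1.0 / (1.0 + raw) if spec.is_distance else raw
    return (sim + spec.alpha(p)) / spec.beta(p)


def scaled_similarity(spec: MetricSpec, quad: ContingencyQuad) -> float:
    """Fully processed coefficient: raw -> (distance conversion) -> scaling."""
    return float(_scaled_arrays(spec, quad.a, quad.b, quad.c, quad.d, quad.p))


def consensus_similarity(
    quad: ContingencyQuad, specs: Sequence[MetricSpec] | None = None
) -> float:
    """Unweighted mean of the scaled registry coefficients for one quad."""
    specs = _SPECS if specs is None else tuple(specs)
    if not specs:
        raise ValueError("registry subset must not be empty")
    return float(
        np.mean([scaled_similarity(s, quad) for s in specs])
    )


def _consensus_arrays(a, b, c, d, p, specs: Sequence[MetricSpec]) -> np.ndarray:
    acc = np.zeros(np.broadcast(np.asarray(a, float), np.asarray(d, float)).shape)
    for s in specs:
        acc += _scaled_arrays(s, a, b, c, d, p)
    return acc / len(specs)


# --------------------------------------------------------------------------
# the pair x assessor consensus matrix
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PairSimilarityMatrix:
    """Consensus similarity per (sample pair, assessor).

    Rows are the S(S-1)/2 unordered sample pairs in lexicographic order of
    sample indices (i < j, first-appearance order), labeled ``"Si vs Sj"``;
    columns are assessors.  All values lie in [0, 1].
    """

    pairs: tuple[tuple[str, str], ...]
    assessors: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.pairs), len(self.assessors)):
            raise ValueError(
                f"values shape {v.shape} != ({len(self.pairs)}, {len(self.assessors)})"
            )
        if v.size and ((v < -_EPS) | (v > 1 + _EPS)).any():
            raise ValueError("consensus similarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def pair_labels(self) -> tuple[str, ...]:
        return tuple(f"{i} vs {j}" for i, j in self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.pair_labels, name="pair"),
            columns=list(self.assessors),
        )

    def column(self, assessor: str) -> np.ndarray:
        return self.values[:, self.assessors.index(assessor)]

    def subset(self, assessors: Sequence[str]) -> "PairSimilarityMatrix":
        idx = [self.assessors.index(a) for a in assessors]
        return PairSimilarityMatrix(self.pairs, tuple(assessors), self.values[:, idx])


def pairwise_matrix(
    panel: CATAPanel, specs: Sequence[MetricSpec] | None = None
) -> PairSimilarityMatrix:
    """Consensus similarity of every unordered sample pair, per assessor.

    For each assessor and each sample pair (i < j) the contingency quad of
    the assessor's two attribute vectors is evaluated through the full
    registry (or an explicit subset) and averaged.
    """
    specs = _SPECS if specs is None else tuple(specs)
    if not specs:
        raise ValueError("registry subset must not be empty")
    S = panel.n_samples
    if S < 2:
        raise ValueError("pairwise similarity needs at least 2 samples")
    X = panel.checks.astype(np.int64)  # (m, S, A)
    pairs = [(i, j) for i in range(S) for j in range(S) if i < j]
    a = np.stack([(X[:, i] & X[:, j]).sum(axis=1) for i, j in pairs])
    b = np.stack([(X[:, i] & (1 - X[:, j])).sum(axis=1) for i, j in pairs])
    c = np.stack([((1 - X[:, i]) & X[:, j]).sum(axis=1) for i, j in pairs])
    p = panel.n_attributes
    d = p - a - b - c
    values = _consensus_arrays(a, b, c, d, float(p), specs)
    return PairSimilarityMatrix(
        tuple((panel.samples[i], panel.samples[j]) for i, j in pairs),
        panel.assessors,
        values,
    )
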