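"""Synthetic CATA panels with planted statistical structure.

Every stage of the pipeline — consensus similarity, consensus-limit
classification, clustering, attribute screening, liking comparison,
agreement — is testable without the (request-only) consumer datasets by
simulating panels whose ground truth is known:

* assessors belong to a *good* or *poor* discriminator class;
* attributes are *discriminating* (check probability depends on the
  product) or *noise* (constant probability ``p_base``);
* good assessors check a discriminating attribute for product s with the
  planted probability ``p_signal[s, j]``; poor assessors use the attenuated
  mixture ``attenuation * p_signal + (1 - attenuation) * product-mean``,
  so ``attenuation = 1`` makes them indistinguishable from good assessors
  and ``attenuation = 0`` removes all product dependence from their
  responses;
* overall liking is truncated-normal around a per-(class, product) mean,
  rounded to integers when the hedonic scale is declared integer (the
  default: fractional published means arise from averaging integer votes).

All draws are independent Bernoulli across assessors, products and
attributes, and fully reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import lexicons
from .panel import CATAPanel, LikingTable

__all__ = [
    "PanelScenario",
    "PlantedTruth",
    "SimulatedPanel",
    "simulate",
    "planted_truth",
    "two_class_scenario",
    "recovery_scenario",
    "cricket_like",
    "apple_pomace_like",
    "strawberry_like",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

DISCRIMINATING = "discriminating"
NOISE = "noise"


@dataclass(frozen=True)
class PanelScenario:
    """Full specification of one synthetic panel draw."""

    samples: tuple[str, ...]
    attributes: tuple[str, ...]
    attribute_types: tuple[str, ...]
    n_assessors: int
    p_base: float
    p_signal: np.ndarray = field(repr=False)  # (n_samples, n_discriminating)
    good_fraction: float
    attenuation: float
    liking_means: np.ndarray = field(repr=False)  # (2, n_samples): good, poor
    liking_sd: float
    scale: tuple[float, float] = (1.0, 9.0)
    integer_scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.attribute_types) != len(self.attributes):
            raise ValueError("attribute_types must match attributes in length")
        bad = [t for t in self.attribute_types if t not in (DISCRIMINATING, NOISE)]
        if bad:
            raise ValueError(f"unknown attribute types: {bad}")
        ps = np.asarray(self.p_signal, float)
        n_disc = self.attribute_types.count(DISCRIMINATING)
        if ps.shape != (len(self.samples), n_disc):
            raise ValueError(
                f"p_signal shape {ps.shape} != ({len(self.samples)}, {n_disc})"
            )
        for name, val in (("p_base", np.asarray(self.p_base)), ("p_signal", ps)):
            if ((val < 0) | (val > 1)).any():
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
        if not 0 <= self.good_fraction <= 1:
            raise ValueError("good_fraction must lie in [0, 1]")
        if not 0 <= self.attenuation <= 1:
            raise ValueError("attenuation must lie in [0, 1]")
        lm = np.asarray(self.liking_means, float)
        if lm.shape != (2, len(self.samples)):
            raise ValueError(f"liking_means shape {lm.shape} != (2, {len(self.samples)})")
        lo, hi = self.scale
        if ((lm < lo) | (lm > hi)).any():
            raise ValueError("liking_means must lie within the hedonic scale")
        if self.liking_sd < 0:
            raise ValueError("liking_sd must be non-negative")
        object.__setattr__(self, "p_signal", ps)
        object.__setattr__(self, "liking_means", lm)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def n_good(self) -> int:
        return int(round(self.good_fraction * self.n_assessors))

    def check_probabilities(self, assessor_class: str) -> np.ndarray:
        """Planted check-probability matrix (n_samples x n_attributes)."""
        probs = np.full((self.n_samples, self.n_attributes), float(self.p_base))
        disc_cols = [
            k for k, t in enumerate(self.attribute_types) if t == DISCRIMINATING
        ]
        signal = self.p_signal
        if assessor_class == "poor":
            flat = signal.mean(axis=0, keepdims=True)
            signal = self.attenuation * signal + (1 - self.attenuation) * flat
        elif assessor_class != "good":
            raise ValueError(f"unknown assessor class {assessor_class!r}")
        probs[:, disc_cols] = signal
        return probs


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels aligned index-wise with the simulated panel."""

    assessor_classes: tuple[str, ...]  # "good" | "poor" per assessor
    attribute_types: tuple[str, ...]  # "discriminating" | "noise" per attribute

    def good_assessors(self, panel: CATAPanel) -> tuple[str, ...]:
        return tuple(
            a for a, c in zip(panel.assessors, self.assessor_classes) if c == "good"
        )


class SimulatedPanel(NamedTuple):
    panel: CATAPanel
    liking: LikingTable
    truth: PlantedTruth


def planted_truth(scenario: PanelScenario) -> PlantedTruth:
    """Class/type labels the generator will plant for this scenario.

    The first ``round(good_fraction * n_assessors)`` assessors are good;
    assessor order carries no information for any downstream analysis, so
    the assignment needs no shuffling.
    """
    n_good = scenario.n_good
    classes = tuple(
        "good" if i < n_good else "poor" for i in range(scenario.n_assessors)
    )
    return PlantedTruth(classes, scenario.attribute_types)


def simulate(scenario: PanelScenario) -> SimulatedPanel:
    """Draw one complete panel + liking table from a scenario."""
    rng = np.random.default_rng(scenario.seed)
    truth = planted_truth(scenario)
    probs = {
        cls: scenario.check_probabilities(cls) for cls in ("good", "poor")
    }
    m, S, A = scenario.n_assessors, scenario.n_samples, scenario.n_attributes
    checks = np.zeros((m, S, A), dtype=np.int8)
    u = rng.random((m, S, A))
    for i, cls in enumerate(truth.assessor_classes):
        checks[i] = (u[i] < probs[cls]).astype(np.int8)
    assessors = tuple(f"A{i + 1}" for i in range(m))
    panel = CATAPanel(assessors, scenario.samples, scenario.attributes, checks)

    lo, hi = scenario.scale
    records = []
    for i, cls in enumerate(truth.assessor_classes):
        mu = scenario.liking_means[0 if cls == "good" else 1]
        for j, s in enumerate(scenario.samples):
            if scenario.liking_sd == 0:
                val = float(mu[j])
            else:
                a_std = (lo - mu[j]) / scenario.liking_sd
                b_std = (hi - mu[j]) / scenario.liking_sd
                val = float(
                    truncnorm.rvs(
                        a_std, b_std, loc=mu[j], scale=scenario.liking_sd,
                        random_state=rng,
                    )
                )
            if scenario.integer_scale:
                val = float(np.clip(round(val), lo, hi))
            records.append((assessors[i], s, val))
    liking = LikingTable(
        pd.DataFrame(records, columns=["assessor", "sample", "liking"]),
        float(lo),
        float(hi),
    )
    return SimulatedPanel(panel, liking, truth)


# --------------------------------------------------------------------------
# ready-made scenarios
# --------------------------------------------------------------------------


def _ramp_signal(n_samples: int, n_disc: int, lo: float, hi: float) -> np.ndarray:
    """Product-dependent check probabilities: half the discriminating
    attributes ramp up with product index (dose-following terms), half ramp
    down (terms displaced by the enrichment)."""
    ramp = np.linspace(lo, hi, n_samples)
    cols = [ramp if j % 2 == 0 else ramp[::-1] for j in range(n_disc)]
    return np.column_stack(cols)


def _contrast_signal(n_samples: int, n_disc: int, lo: float, hi: float) -> np.ndarray:
    """Two-level check probabilities: each discriminating attribute is
    checked with probability ``hi`` for half the products (chosen
    cyclically so attributes cover different product subsets) and ``lo``
    for the rest."""
    half = max(1, n_samples // 2)
    out = np.full((n_samples, n_disc), lo)
    for j in range(n_disc):
        rows = [(j + t) % n_samples for t in range(half)]
        out[rows, j] = hi
    return out


def two_class_scenario(
    n_assessors: int = 30,
    n_samples: int = 4,
    n_discriminating: int = 10,
    n_noise: int = 10,
    contrast: tuple[float, float] = (0.1, 0.6),
    p_base: float = 0.15,
    good_fraction: float = 0.5,
    attenuation: float = 0.0,
    seed: int = 0,
) -> PanelScenario:
    """Compact planted two-class scenario: good vs attenuated poor
    assessors, discriminating attributes at a two-level probability
    contrast (``hi`` for half the products, ``lo`` for the rest) plus
    pure-noise attributes."""
    samples = tuple(f"S{j + 1}" for j in range(n_samples))
    attributes = tuple(
        [f"signal_{k + 1}" for k in range(n_discriminating)]
        + [f"noise_{k + 1}" for k in range(n_noise)]
    )
    types = (DISCRIMINATING,) * n_discriminating + (NOISE,) * n_noise
    liking_means = np.vstack(
        [np.linspace(7.0, 4.0, n_samples), np.full(n_samples, 6.0)]
    )
    return PanelScenario(
        samples=samples,
        attributes=attributes,
        attribute_types=types,
        n_assessors=n_assessors,
        p_base=p_base,
        p_signal=_contrast_signal(n_samples, n_discriminating, *contrast),
        good_fraction=good_fraction,
        attenuation=attenuation,
        liking_means=liking_means,
        liking_sd=1.2,
        seed=seed,
    )


def recovery_scenario(
    n_assessors: int = 30,
    n_signal: int = 32,
    n_anchor: int = 4,
    seed: int = 0,
) -> PanelScenario:
    """Maximum-separation scenario for planted-class recovery tests.

    Two products with complementary near-deterministic profiles: half the
    signal attributes belong to the first product (checked with p=0.98
    there, 0.02 elsewhere), half to the second, plus ``n_anchor``
    always-checked anchor terms (p_base=0.9) that every assessor ticks for
    every product.  Good assessors therefore produce near-complementary
    response pairs (low consensus similarity), while fully attenuated poor
    assessors check each signal attribute with the product-averaged
    probability 0.5 regardless of product.  The expected consensus
    similarity gap between the classes is about 0.33 — under independent
    Bernoulli responses, designs with three or more products cannot reach
    a gap much above ~0.15, because the poor class's own response noise
    already depresses its similarity between products.
    """
    half = n_signal // 2
    p_signal = np.full((2, n_signal), 0.02)
    p_signal[0, :half] = 0.98
    p_signal[1, half:] = 0.98
    attributes = tuple(
        [f"signal_{k + 1}" for k in range(n_signal)]
        + [f"anchor_{k + 1}" for k in range(n_anchor)]
    )
    return PanelScenario(
        samples=("S1", "S2"),
        attributes=attributes,
        attribute_types=(DISCRIMINATING,) * n_signal + (NOISE,) * n_anchor,
        n_assessors=n_assessors,
        p_base=0.9,
        p_signal=p_signal,
        good_fraction=0.5,
        attenuation=0.0,
        liking_means=np.array([[7.0, 4.0], [6.0, 6.0]]),
        liking_sd=1.2,
        seed=seed,
    )


def _study_scenario(
    lexicon: str,
    samples: tuple[str, ...],
    n_assessors: int,
    n_discriminating: int,
    good_fraction: float,
    liking_means: np.ndarray,
    seed: int,
) -> PanelScenario:
    attributes = lexicons.parse_lexicon(lexicons.LEXICONS[lexicon])
    types = tuple(
        DISCRIMINATING if k < n_discriminating else NOISE
        for k in range(len(attributes))
    )
    return PanelScenario(
        samples=samples,
        attributes=attributes,
        attribute_types=types,
        n_assessors=n_assessors,
        p_base=0.15,
        p_signal=_ramp_signal(len(samples), n_discriminating, 0.1, 0.6),
        good_fraction=good_fraction,
        attenuation=0.25,
        liking_means=liking_means,
        liking_sd=1.5,
        seed=seed,
    )


def cricket_like(seed: int = 0) -> PanelScenario:
    """67 assessors x 4 products x 38 attributes (cricket-biscuit shape).

    Liking means follow the published cluster-wise product means of the
    cricket study; 19 of the 38 ballot terms are planted discriminating
    (the study's good-discriminator significant-term count)."""
    return _study_scenario(
        "cricket_biscuit",
        ("Ctrl", "CP5", "CP10", "CP15"),
        n_assessors=67,
        n_discriminating=19,
        good_fraction=56 / 67,
        liking_means=np.array(
            [[6.536, 6.339, 5.357, 4.518], [6.727, 6.818, 6.182, 6.091]]
        ),
        seed=seed,
    )


def apple_pomace_like(seed: int = 0) -> PanelScenario:
    """60 assessors x 4 products x 34 attributes (apple-pomace shape)."""
    return _study_scenario(
        "apple_pomace_biscuit",
        ("AP0", "AP2.5", "AP5", "AP10"),
        n_assessors=60,
        n_discriminating=20,
        good_fraction=37 / 60,
        liking_means=np.array(
            [[6.216, 5.541, 5.081, 3.568], [6.304, 5.435, 4.870, 3.652]]
        ),
        seed=seed,
    )


def strawberry_like(seed: int = 0) -> PanelScenario:
    """117 assessors x 6 varieties x 16 attributes (strawberry shape)."""
    return _study_scenario(
        "strawberry",
        ("L20.1", "Festival", "Guenoa", "Yvahe", "K31.5", "Yuri"),
        n_assessors=117,
        n_discriminating=12,
        good_fraction=81 / 116,
        liking_means=np.array(
            [
                [5.753, 5.247, 5.136, 4.938, 4.469, 4.358],
                [6.571, 6.029, 6.171, 5.486, 5.229, 4.971],
            ]
        ),
        seed=seed,
    )


# --------------------------------------------------------------------------
# YAML round trip for scenario configs
# --------------------------------------------------------------------------


def scenario_to_yaml(scenario: PanelScenario, path: str) -> None:
    data = {
        "samples": list(scenario.samples),
        "attributes": list(scenario.attributes),
        "attribute_types": list(scenario.attribute_types),
        "n_assessors": scenario.n_assessors,
        "p_base": float(scenario.p_base),
        "p_signal": np.asarray(scenario.p_signal).tolist(),
        "good_fraction": float(scenario.good_fraction),
        "attenuation": float(scenario.attenuation),
        "liking_means": np.asarray(scenario.liking_means).tolist(),
        "liking_sd": float(scenario.liking_sd),
        "scale": list(scenario.scale),
        "integer_scale": bool(scenario.integer_scale),
        "seed": int(scenario.seed),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scenario_from_yaml(path: str) -> PanelScenario:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return PanelScenario(
        samples=tuple(data["samples"]),
        attributes=tuple(data["attributes"]),
        attribute_types=tuple(data["attribute_types"]),
        n_assessors=int(data["n_assessors"]),
        p_base=float(data["p_base"]),
        p_signal=np.asarray(data["p_signal"], float),
        good_fraction=float(data["good_fraction"]),
        attenuation=float(data["attenuation"]),
        liking_means=np.asarray(data["liking_means"], float),
        liking_sd=float(data["liking_sd"]),
        scale=tuple(float(x) for x in data.get("scale", (1.0, 9.0))),
        integer_scale=bool(data.get("integer_scale", True)),
        seed=int(data.get("seed", 0)),
    )


def with_seed(scenario: PanelScenario, seed: int) -> PanelScenario:
    """The same scenario with a different RNG seed."""
    return replace(scenario, seed=seed)
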