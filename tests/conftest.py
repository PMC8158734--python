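import io

import numpy as np
import pytest

from catadiscrim import CATAPanel, PairSimilarityMatrix
from catadiscrim import synth


@pytest.fixture
def toy_panel() -> CATAPanel:
    """3 assessors x 3 samples x 5 attributes, fixed by seed."""
    rng = np.random.default_rng(42)
    checks = rng.integers(0, 2, size=(3, 3, 5), dtype=np.int8)
    return CATAPanel(
        ("A1", "A2", "A3"),
        ("S1", "S2", "S3"),
        ("sweet", "sour", "bitter", "salty", "umami"),
        checks,
    )


@pytest.fixture
def tiny_wide_csv() -> io.StringIO:
    """Smallest complete design: 2 assessors x 2 samples x 3 attributes."""
    return io.StringIO(
        "assessor,sample,sweet,sour,bitter\n"
        "A1,S1,1,0,1\n"
        "A1,S2,0,0,1\n"
        "A2,S1,1,1,0\n"
        "A2,S2,1,0,0\n"
    )


@pytest.fixture
def random_matrix() -> PairSimilarityMatrix:
    """6 pairs x 30 assessors of uniform consensus values."""
    rng = np.random.default_rng(7)
    pairs = tuple(
        (f"S{i + 1}", f"S{j + 1}") for i in range(4) for j in range(i + 1, 4)
    )
    return PairSimilarityMatrix(
        pairs,
        tuple(f"A{i + 1}" for i in range(30)),
        rng.random((6, 30)),
    )


@pytest.fixture
def recovery_sim():
    """One draw of the maximum-separation two-class scenario."""
    return synth.simulate(synth.recovery_scenario(seed=11))
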