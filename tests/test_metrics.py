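"""Similarity registry: quad counting, formulas, scaling, consensus."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catadiscrim import (
    REGISTRY,
    ContingencyQuad,
    consensus_similarity,
    contingency_quad,
    distance_to_similarity,
    eval_metric,
    pairwise_matrix,
    registry,
    scale_similarity,
    scaled_similarity,
)
from catadiscrim.metrics import _scaled_arrays
from catadiscrim import synth


def binary_vectors(length):
    return st.lists(st.integers(0, 1), min_size=length, max_size=length)


class TestContingencyQuad:
    def test_direct_count(self):
        q = contingency_quad((1, 1, 0, 0, 1), (1, 0, 1, 0, 1))
        assert (q.a, q.b, q.c, q.d, q.p) == (2, 1, 1, 1, 5)

    def test_identical_vectors(self):
        q = contingency_quad((1, 0, 1), (1, 0, 1))
        assert q.b == q.c == 0 and q.a + q.d == q.p

    def test_swap_exchanges_b_and_c(self):
        q = contingency_quad((1, 1, 0), (0, 1, 1))
        r = contingency_quad((0, 1, 1), (1, 1, 0))
        assert (q.a, q.b, q.c, q.d) == (r.a, r.c, r.b, r.d)

    @settings(max_examples=50, derandomize=True)
    @given(x=binary_vectors(38), y=binary_vectors(38))
    def test_matches_positionwise_oracle(self, x, y):
        tally = {"a": 0, "b": 0, "c": 0, "d": 0}
        for xi, yi in zip(x, y):
            tally["a" if xi and yi else "b" if xi else "c" if yi else "d"] += 1
        q = contingency_quad(x, y)
        assert (q.a, q.b, q.c, q.d) == tuple(tally.values())

    def test_length_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            contingency_quad((1, 0), (1, 0, 1))
        with pytest.raises(ValueError, match="non-binary"):
            contingency_quad((1, 2), (1, 0))


class TestCoreFormulas:
    QUAD = ContingencyQuad(2, 1, 1, 1)

    def test_jaccard_tanimoto(self):
        assert eval_metric(REGISTRY["JT"], self.QUAD) == pytest.approx(0.5)

    def test_simple_matching(self):
        assert eval_metric(REGISTRY["SM"], self.QUAD) == pytest.approx(0.6)

    def test_driver_kroeber(self):
        assert eval_metric(REGISTRY["DK"], self.QUAD) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("d,s", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.25)])
    def test_distance_conversion(self, d, s):
        assert distance_to_similarity(d) == pytest.approx(s)

    def test_distance_conversion_rejects_negative(self):
        with pytest.raises(ValueError):
            distance_to_similarity(-0.1)

    def test_distance_conversion_strictly_decreasing(self):
        grid = np.linspace(0, 50, 200)
        vals = [distance_to_similarity(d) for d in grid]
        assert np.all(np.diff(vals) < 0)
        assert np.allclose(vals, 1 / (1 + grid))


class TestScaling:
    def test_correlation_type_endpoints(self):
        ham = REGISTRY["Ham"]  # alpha=1, beta=2 on [-1, 1]
        assert scale_similarity(-1.0, ham, p=5) == pytest.approx(0.0)
        assert scale_similarity(1.0, ham, p=5) == pytest.approx(1.0)

    def test_identity_transform_for_unit_range_metric(self):
        jt = REGISTRY["JT"]
        assert scale_similarity(0.37, jt, p=10) == pytest.approx(0.37)

    def test_out_of_range_value_names_metric(self):
        with pytest.raises(ValueError, match="JT"):
            scale_similarity(1.5, REGISTRY["JT"], p=10)

    def test_all_metrics_scaled_into_unit_interval_exhaustive(self):
        quads = np.array(
            [q for q in itertools.product(range(7), repeat=4) if sum(q) >= 1],
            dtype=float,
        )
        a, b, c, d = quads.T
        p = a + b + c + d
        for spec in registry():
            v = _scaled_arrays(spec, a, b, c, d, p)
            assert np.isfinite(v).all(), spec.name
            assert v.min() >= -1e-12 and v.max() <= 1 + 1e-12, spec.name


class TestRegistry:
    def test_exactly_44_uniquely_named_metrics(self):
        specs = registry()
        assert len(specs) == 44
        assert len({s.name for s in specs}) == 44

    def test_every_entry_cites_a_source(self):
        assert all(s.source for s in registry())

    def test_subset_selection(self):
        sub = registry(["JT", "SM", "DK"])
        assert [s.name for s in sub] == ["JT", "SM", "DK"]
        with pytest.raises(KeyError):
            registry(["JT", "nope"])

    @settings(max_examples=300, derandomize=True)
    @given(
        quad=st.tuples(
            st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
        ).filter(lambda q: sum(q) >= 1)
    )
    def test_symmetry_under_vector_swap(self, quad):
        a, b, c, d = quad
        q = ContingencyQuad(a, b, c, d)
        for spec in registry():
            assert scaled_similarity(spec, q) == pytest.approx(
                scaled_similarity(spec, q.swapped()), abs=1e-12
            ), spec.name

    def test_identity_dominance_where_declared(self):
        rng = np.random.default_rng(19)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            qxx, qxy = contingency_quad(x, x), contingency_quad(x, y)
            for spec in registry():
                if spec.identity_dominant:
                    assert (
                        scaled_similarity(spec, qxx)
                        >= scaled_similarity(spec, qxy) - 1e-9
                    ), spec.name


class TestConsensus:
    def test_three_metric_subset_average(self):
        q = ContingencyQuad(2, 1, 1, 1)
        sub = registry(["JT", "SM", "DK"])
        assert consensus_similarity(q, sub) == pytest.approx((0.5 + 0.6 + 2 / 3) / 3)

    def test_equals_mean_of_independently_scaled_parts(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 20, 4)
            if a + b + c + d == 0:
                continue
            q = ContingencyQuad(int(a), int(b), int(c), int(d))
            parts = [scaled_similarity(s, q) for s in registry()]
            assert consensus_similarity(q) == pytest.approx(np.mean(parts), abs=1e-12)

    def test_permutation_invariant_in_registry_order(self):
        q = ContingencyQuad(3, 2, 1, 4)
        specs = list(registry())
        rng = np.random.default_rng(0)
        rng.shuffle(specs)
        assert consensus_similarity(q, specs) == pytest.approx(
            consensus_similarity(q), abs=1e-12
        )

    def test_identity_pair_near_registry_maximum(self):
        # identical responses (b=c=0, a>0, d>0): every identity-dominant
        # metric sits at its own maximum over quads sharing that x-vector,
        # and the consensus beats every non-identical quad with the same x
        rng = np.random.default_rng(8)
        x = np.array([1] * 5 + [0] * 15)
        q_id = contingency_quad(x, x)
        c_id = consensus_similarity(q_id)
        for _ in range(200):
            y = rng.integers(0, 2, 20)
            q = contingency_quad(x, y)
            assert c_id >= consensus_similarity(q) - 1e-9
            for spec in registry():
                if spec.identity_dominant:
                    assert scaled_similarity(spec, q_id) >= scaled_similarity(spec, q) - 1e-9

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            consensus_similarity(ContingencyQuad(1, 0, 0, 1), [])


class TestPairwiseMatrix:
    @pytest.mark.parametrize("n_samples,n_pairs", [(4, 6), (6, 15)])
    def test_pair_enumeration(self, n_samples, n_pairs):
        sim = synth.simulate(
            synth.two_class_scenario(n_assessors=5, n_samples=n_samples, seed=1)
        )
        matrix = pairwise_matrix(sim.panel)
        assert matrix.n_pairs == n_pairs
        assert len(matrix.assessors) == 5

    def test_pairs_in_lexicographic_index_order(self, toy_panel):
        matrix = pairwise_matrix(toy_panel)
        assert matrix.pair_labels == ("S1 vs S2", "S1 vs S3", "S2 vs S3")

    def test_constant_assessor_column_at_identity_value(self, toy_panel):
        checks = toy_panel.checks.copy()
        checks[0] = checks[0, 0]  # assessor 1 answers identically for all samples
        panel = type(toy_panel)(
            toy_panel.assessors, toy_panel.samples, toy_panel.attributes, checks
        )
        matrix = pairwise_matrix(panel)
        col = matrix.column("A1")
        expected = consensus_similarity(
            contingency_quad(checks[0, 0], checks[0, 0])
        )
        assert np.allclose(col, expected)

    def test_cell_equals_direct_consensus(self, toy_panel):
        matrix = pairwise_matrix(toy_panel)
        for ai, a in enumerate(toy_panel.assessors):
            for pi, (s1, s2) in enumerate(matrix.pairs):
                q = contingency_quad(
                    toy_panel.vector(a, s1), toy_panel.vector(a, s2)
                )
                assert matrix.values[pi, ai] == pytest.approx(
                    consensus_similarity(q), abs=1e-12
                )

    def test_single_sample_panel_rejected(self, toy_panel):
        panel = type(toy_panel)(
            toy_panel.assessors,
            ("S1",),
            toy_panel.attributes,
            toy_panel.checks[:, :1],
        )
        with pytest.raises(ValueError, match="2 samples"):
            pairwise_matrix(panel)
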