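"""Cochran's Q, correspondence analysis, Tukey letters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from catadiscrim import (
    CATAPanel,
    LikingTable,
    build_counts,
    cochran_q,
    correspondence,
    liking_anova_tukey,
    significant_attributes,
)
from catadiscrim.stats import _letter_display


def _panel_from_block(block):
    """One-attribute panel from an assessor x sample 0/1 array."""
    block = np.asarray(block, dtype=np.int8)
    m, S = block.shape
    return CATAPanel(
        tuple(f"A{i + 1}" for i in range(m)),
        tuple(f"S{j + 1}" for j in range(S)),
        ("attr",),
        block[:, :, None],
    )


class TestCochranQ:
    def test_everyone_checks_everywhere_is_degenerate(self):
        res = cochran_q(_panel_from_block(np.ones((5, 3))), "attr")
        assert res.degenerate and res.p_value == 1.0 and not res.significant

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(0)
        from statsmodels.stats.contingency_tables import cochrans_q

        for _ in range(20):
            block = rng.integers(0, 2, size=(12, 4))
            if np.ptp(block.sum(axis=1)) == 0:
                continue
            res = cochran_q(_panel_from_block(block), "attr")
            ref = cochrans_q(block, return_object=True)
            assert res.Q == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_permutation_null_within_mc_error(self):
        # moderately sized block so the chi-square approximation applies
        rng = np.random.default_rng(21)
        block = (rng.random((15, 3)) < [0.2, 0.45, 0.6]).astype(int)
        res = cochran_q(_panel_from_block(block), "attr")
        stats = []
        for _ in range(10_000):
            perm = np.array([rng.permutation(row) for row in block])
            stats.append(cochran_q(_panel_from_block(perm), "attr").Q)
        p_perm = float(np.mean(np.asarray(stats) >= res.Q - 1e-12))
        assert res.p_value == pytest.approx(p_perm, abs=0.03)

    def test_reduces_to_mcnemar_with_two_samples(self):
        rng = np.random.default_rng(5)
        from statsmodels.stats.contingency_tables import mcnemar

        for _ in range(20):
            block = rng.integers(0, 2, size=(15, 2))
            b = int(((block[:, 0] == 1) & (block[:, 1] == 0)).sum())
            c = int(((block[:, 0] == 0) & (block[:, 1] == 1)).sum())
            if b + c == 0:
                continue
            res = cochran_q(_panel_from_block(block), "attr")
            expected = (b - c) ** 2 / (b + c)  # McNemar without correction
            assert res.Q == pytest.approx(expected, abs=1e-10)
            table = [[0, b], [c, 0]]
            ref = mcnemar(table, exact=False, correction=False)
            assert res.Q == pytest.approx(ref.statistic, abs=1e-10)

    def test_single_discriminating_sample_attains_margin_maximum(self):
        # attribute checked by everyone for exactly one sample: Q equals the
        # maximum over all tables with the same row margins (enumerated)
        m, S = 4, 3
        block = np.zeros((m, S), dtype=int)
        block[:, 0] = 1
        res = cochran_q(_panel_from_block(block), "attr")
        import itertools

        q_max = 0.0
        rows = [r for r in itertools.product(range(2), repeat=S) if sum(r) == 1]
        for combo in itertools.product(rows, repeat=m):
            q = cochran_q(_panel_from_block(np.array(combo)), "attr").Q
            q_max = max(q_max, q)
        assert res.Q == pytest.approx(q_max)
        assert res.Q == pytest.approx((S - 1) * m)  # closed form at this margin


class TestSignificantAttributes:
    def _panel(self, seed=0):
        from catadiscrim import synth

        sim = synth.simulate(
            synth.two_class_scenario(
                n_assessors=40,
                n_discriminating=5,
                n_noise=5,
                contrast=(0.1, 0.6),
                attenuation=1.0,
                seed=seed,
            )
        )
        return sim.panel

    def test_alpha_one_keeps_all_nondegenerate(self):
        panel = self._panel()
        sig = significant_attributes(panel, alpha=1 - 1e-12)
        degenerate = [
            t for t in panel.attributes if cochran_q(panel, t).degenerate
        ]
        assert set(sig) == set(panel.attributes) - set(degenerate)

    def test_tiny_alpha_keeps_none(self):
        assert significant_attributes(self._panel(), alpha=1e-300) == []

    def test_planted_attributes_recovered(self):
        hits = []
        for seed in range(20):
            panel = self._panel(seed)
            sig = set(significant_attributes(panel, alpha=0.05))
            planted = {t for t in panel.attributes if t.startswith("signal")}
            hits.append(len(sig & planted) >= 4)
        assert np.mean(hits) >= 0.9

    def test_results_in_lexicon_order(self):
        panel = self._panel()
        sig = significant_attributes(panel, alpha=0.5)
        order = {t: i for i, t in enumerate(panel.attributes)}
        assert sig == sorted(sig, key=order.get)


class TestBuildCounts:
    def test_direct_tally(self, toy_panel):
        counts = build_counts(toy_panel)
        for s in toy_panel.samples:
            for t in toy_panel.attributes:
                manual = sum(
                    toy_panel.vector(a, s)[toy_panel.attributes.index(t)]
                    for a in toy_panel.assessors
                )
                assert counts.loc[s, t] == manual

    def test_row_sums_are_total_checks_per_product(self, toy_panel):
        counts = build_counts(toy_panel)
        j = {s: i for i, s in enumerate(toy_panel.samples)}
        for s in toy_panel.samples:
            assert counts.loc[s].sum() == toy_panel.checks[:, j[s], :].sum()

    def test_subset_restriction(self, toy_panel):
        full = build_counts(toy_panel)
        part = build_counts(toy_panel, subset=["A1"])
        assert (part.to_numpy() <= full.to_numpy()).all()


class TestCorrespondence:
    def test_independent_table_has_zero_inertia(self):
        table = pd.DataFrame(np.outer([2, 3, 5], [1, 4, 2, 3]))
        ca = correspondence(table)
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert ca.n_dims == 0

    def test_dependent_2x2_has_one_dimension_fully_explained(self):
        ca = correspondence(pd.DataFrame([[10, 2], [3, 9]]))
        assert ca.n_dims == 1
        assert ca.explained[0] == pytest.approx(100.0)
        assert ca.plane_explained == pytest.approx(100.0)

    def test_total_inertia_equals_chisquare_over_n(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            table = pd.DataFrame(rng.integers(1, 30, size=(4, 10)))
            ca = correspondence(table)
            chi2 = sps.chi2_contingency(table.to_numpy(), correction=False)[0]
            assert ca.total_inertia == pytest.approx(
                chi2 / table.to_numpy().sum(), abs=1e-10
            )

    def test_transition_formulas(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.integers(1, 25, size=(5, 8)))
        ca = correspondence(table)
        N = table.to_numpy(float)
        P = N / N.sum()
        r = P.sum(axis=1)
        sv = np.sqrt(ca.eigenvalues)
        # rows are barycenters of column coords, rescaled by singular values
        F_pred = (P / r[:, None]) @ ca.col_coords / sv
        assert np.abs(F_pred - ca.row_coords).max() < 1e-9

    def test_explained_sums_to_hundred(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.integers(1, 20, size=(4, 6)))
        ca = correspondence(table)
        assert ca.explained.sum() == pytest.approx(100.0, abs=1e-9)
        assert ca.plane_explained <= 100.0 + 1e-9

    def test_eigenvalues_nonincreasing_nonnegative(self):
        table = pd.DataFrame(np.random.default_rng(6).integers(0, 20, (5, 7)) )
        ca = correspondence(table)
        assert (ca.eigenvalues >= 0).all()
        assert np.all(np.diff(ca.eigenvalues) <= 1e-12)

    def test_zero_rows_dropped_and_reported(self):
        table = pd.DataFrame(
            [[5, 2, 1], [0, 0, 0], [1, 4, 2]], index=["x", "y", "z"]
        )
        ca = correspondence(table)
        assert ca.dropped_rows == ("y",)
        assert ca.row_names == ("x", "z")

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            correspondence(pd.DataFrame(np.zeros((2, 2))))


def _liking(samples_ratings, lo=1, hi=9):
    records = []
    for s, vals in samples_ratings.items():
        for i, v in enumerate(vals):
            records.append((f"A{i + 1}", s, float(v)))
    return LikingTable(
        pd.DataFrame(records, columns=["assessor", "sample", "liking"]), lo, hi
    )


class TestTukeyLetters:
    def test_identical_groups_share_a_letter(self):
        table = _liking({"S1": [4, 5, 6, 5], "S2": [4, 5, 6, 5]})
        letters = {t.sample: t.letters for t in liking_anova_tukey(table)}
        assert set(letters["S1"]) & set(letters["S2"])

    def test_widely_separated_groups_get_distinct_letters(self):
        table = _liking({"S1": [1.0, 1.1, 1.2, 1.0], "S2": [8.0, 8.1, 7.9, 8.0]})
        out = liking_anova_tukey(table)
        assert out[0].letters == "a" and out[1].letters == "b"
        assert out[0].mean < out[1].mean  # 'a' at the lowest mean

    def test_letters_encode_pairwise_nonsignificance(self):
        rng = np.random.default_rng(9)
        from statsmodels.sandbox.stats.multicomp import MultiComparison

        for trial in range(5):
            data = {
                f"S{j + 1}": rng.normal(5 + 0.8 * j, 1.0, size=20) for j in range(4)
            }
            data = {s: np.clip(v, 1, 9) for s, v in data.items()}
            table = _liking(data)
            letters = {t.sample: set(t.letters) for t in liking_anova_tukey(table)}
            values = np.concatenate(list(data.values()))
            labels = np.concatenate([[s] * 20 for s in data])
            tuk = MultiComparison(values, labels).tukeyhsd(alpha=0.05)
            names = [str(n) for n in tuk.groupsunique]
            pairs = [
                (names[i], names[j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
            ]
            for (s1, s2), rej in zip(pairs, tuk.reject):
                share = bool(letters[s1] & letters[s2])
                assert share == (not rej), (trial, s1, s2)

    def test_zero_variance_everywhere_rejected(self):
        table = _liking({"S1": [5, 5, 5], "S2": [6, 6, 6]})
        with pytest.raises(ValueError, match="variance"):
            liking_anova_tukey(table)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            liking_anova_tukey(_liking({"S1": [4, 5, 6]}))


class TestLetterDisplay:
    @pytest.mark.parametrize(
        "sig,expected",
        [
            (set(), {"w": "a", "x": "a", "y": "a", "z": "a"}),
            ({frozenset(("w", "z"))}, {"w": "a", "x": "ab", "y": "ab", "z": "b"}),
            (
                {frozenset(("w", "y")), frozenset(("w", "z")), frozenset(("x", "z"))},
                {"w": "a", "x": "ab", "y": "bc", "z": "c"},
            ),
        ],
    )
    def test_insert_and_absorb_examples(self, sig, expected):
        assert _letter_display(["w", "x", "y", "z"], sig) == expected
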