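import numpy as np
import pandas as pd
import pytest

import coexkit as ck
from coexkit.stratify import categorize_alterations

from conftest import make_matrix
from oracles import fisher_exact_enumeration


def split_from_values(values, gene="G"):
    m = make_matrix(np.asarray(values, dtype=float)[None, :], genes=[gene],
                    samples=[f"S{i:03d}" for i in range(len(values))])
    return m, ck.quartile_split(m, gene)


class TestQuartileSplit:
    def test_cohort_of_208_retains_104(self, rng):
        m, split = split_from_values(rng.normal(size=208))
        assert len(split.high) == len(split.low) == 52
        assert split.n_retained == 104
        assert split.n_cohort == 208

    def test_top_and_bottom_by_value(self):
        values = [10, 80, 30, 40, 50, 60, 70, 20]
        m, split = split_from_values(values)
        expr = m.data.loc["G"]
        assert sorted(expr[list(split.high)]) == [70, 80]
        assert sorted(expr[list(split.low)]) == [10, 20]

    def test_floor_rule_against_sorting_oracle(self, rng):
        values = rng.normal(size=10)
        m, split = split_from_values(values)
        order = np.argsort(values, kind="stable")
        samples = list(m.samples)
        assert set(split.low) == {samples[i] for i in order[:2]}
        assert set(split.high) == {samples[i] for i in order[-2:]}

    def test_groups_disjoint_and_sized(self, rng):
        for n in (4, 7, 13, 100):
            _, split = split_from_values(rng.normal(size=n))
            assert len(split.high) == len(split.low) == n // 4
            assert not set(split.high) & set(split.low)

    def test_monotone_transform_preserves_membership(self, rng):
        values = rng.normal(size=30)
        _, s1 = split_from_values(values)
        _, s2 = split_from_values(np.exp(values))
        assert s1.high == s2.high and s1.low == s2.low

    def test_errors(self, rng):
        m, _ = split_from_values(rng.normal(size=8))
        with pytest.raises(KeyError):
            ck.quartile_split(m, "ABSENT")
        m_small = make_matrix(np.ones((1, 3)), genes=["G"])
        with pytest.raises(ValueError, match="4 samples"):
            ck.quartile_split(m_small, "G")


class TestCompareGroupsNumeric:
    def test_identical_multisets_give_p_one(self, rng):
        _, split = split_from_values(rng.normal(size=12))
        vals = pd.Series(0.0, index=list(split.high) + list(split.low))
        vals[list(split.high)] = [1.0, 2.0, 3.0]
        vals[list(split.low)] = [1.0, 2.0, 3.0]
        _, p = ck.compare_groups_numeric(vals, split)
        assert p == pytest.approx(1.0)

    def test_fully_separated_three_vs_three_exact(self, rng):
        # all C(6,3)=20 labelings; the two extreme ones give two-sided p=0.1
        _, split = split_from_values(rng.normal(size=12))
        vals = pd.Series(index=list(split.high) + list(split.low), dtype=float)
        vals[list(split.high)] = [10.0, 11.0, 12.0]
        vals[list(split.low)] = [1.0, 2.0, 3.0]
        u, p = ck.compare_groups_numeric(vals, split)
        assert u == 9.0
        assert p == pytest.approx(0.1)

    def test_label_swap_symmetric(self, rng):
        _, split = split_from_values(rng.normal(size=20))
        vals = pd.Series(rng.normal(size=10),
                         index=list(split.high) + list(split.low))
        swapped = ck.QuartileSplit(gene=split.gene, high=split.low, low=split.high,
                                   cutoff_low=split.cutoff_low,
                                   cutoff_high=split.cutoff_high,
                                   n_cohort=split.n_cohort)
        _, p1 = ck.compare_groups_numeric(vals, split)
        _, p2 = ck.compare_groups_numeric(vals, swapped)
        assert p1 == pytest.approx(p2)

    def test_empty_group_after_missing_removal_errors(self, rng):
        _, split = split_from_values(rng.normal(size=8))
        vals = pd.Series(1.0, index=list(split.low))  # no high-group values
        with pytest.raises(ValueError, match="empty"):
            ck.compare_groups_numeric(vals, split)


class TestCategorizeAlterations:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "event_code"])

    @pytest.mark.parametrize("codes,expected", [
        (["MUT", "1"], "MULTIPLE"),
        (["-2"], "HOMODEL"),
        (["-1"], "HETERODEL"),
        (["0"], "NEUTRAL"),
        (["1"], "GAIN"),
        (["2"], "AMP"),
        (["MUT"], "MUT_ONLY"),
        (["MUT", "0"], "MUT_ONLY"),
    ])
    def test_collapse_rules(self, codes, expected):
        rows = [("S1", "TP53", c) for c in codes]
        calls = categorize_alterations(self.table(rows), "TP53")
        assert calls["S1"] == expected

    def test_absent_sample_is_na_excluded(self):
        calls = categorize_alterations(self.table([("S1", "PTEN", "-2")]), "PTEN")
        assert list(calls.index) == ["S1"]

    def test_profiled_samples_fill_neutral(self):
        calls = categorize_alterations(self.table([("S1", "PTEN", "-2")]), "PTEN",
                                       profiled_samples=["S1", "S2", "S3"])
        assert calls["S2"] == calls["S3"] == "NEUTRAL"
        assert calls["S1"] == "HOMODEL"

    def test_unknown_code_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            categorize_alterations(self.table([("S1", "PTEN", "5")]), "PTEN")


class TestFisherAlterationTest:
    def make_split(self, high, low):
        return ck.QuartileSplit(gene="G", high=tuple(high), low=tuple(low),
                                cutoff_low=0.0, cutoff_high=1.0,
                                n_cohort=len(high) + len(low))

    def calls_for(self, high_altered, high_total, low_altered, low_total):
        high = [f"H{i}" for i in range(high_total)]
        low = [f"L{i}" for i in range(low_total)]
        cats = {}
        for i, s in enumerate(high):
            cats[s] = "HOMODEL" if i < high_altered else "NEUTRAL"
        for i, s in enumerate(low):
            cats[s] = "HOMODEL" if i < low_altered else "NEUTRAL"
        return pd.Series(cats, name="PTEN"), self.make_split(high, low)

    def test_fully_separated_three_vs_three(self):
        calls, split = self.calls_for(3, 3, 0, 3)
        res = ck.fisher_alteration_test(calls, split)
        np.testing.assert_array_equal(res.table, [[3, 0], [0, 3]])
        assert res.p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_equal_proportions_give_p_one(self):
        calls, split = self.calls_for(2, 4, 2, 4)
        assert ck.fisher_alteration_test(calls, split).p == pytest.approx(1.0)

    def test_group_transposition_invariant(self):
        calls, split = self.calls_for(3, 6, 1, 6)
        swapped = self.make_split(split.low, split.high)
        p1 = ck.fisher_alteration_test(calls, split).p
        p2 = ck.fisher_alteration_test(calls, swapped).p
        assert p1 == pytest.approx(p2)

    def test_zero_margin_degenerate(self):
        calls, split = self.calls_for(0, 4, 0, 4)
        res = ck.fisher_alteration_test(calls, split)
        assert res.degenerate and res.p == 1.0

    def test_na_samples_counted_and_removed(self):
        calls, split = self.calls_for(2, 3, 1, 3)
        calls = calls.drop("H2")
        res = ck.fisher_alteration_test(calls, split)
        assert res.n_na == 1
        assert res.table.sum() == 5

    def test_matches_hypergeometric_enumeration_small_margins(self):
        # exhaustive over all tables with group sizes <= 8 (acceptance runs <= 12)
        for r1 in range(1, 9):
            for r2 in range(1, 9):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        calls, split = self.calls_for(a, r1, c, r2)
                        res = ck.fisher_alteration_test(calls, split)
                        expected = (1.0 if res.degenerate
                                    else fisher_exact_enumeration([[a, r1 - a],
                                                                   [c, r2 - c]]))
                        assert res.p == pytest.approx(expected, abs=1e-9)


class TestBHAndStars:
    def test_equal_ps_stay_equal(self):
        np.testing.assert_allclose(ck.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_stepup_by_hand(self):
        np.testing.assert_allclose(ck.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ck.bh_adjust([0.04]), [0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ck.bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("q,label", [
        (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.03, "*"), (0.011, "*"),
        (0.01, "**"), (0.002, "**"), (0.001, "***"), (0.0002, "***"),
        (0.0001, "****"), (0.0, "****"),
    ])
    def test_star_tiers(self, q, label):
        assert ck.significance_stars(q) == label

    def test_star_range_check(self):
        with pytest.raises(ValueError):
            ck.significance_stars(1.2)
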