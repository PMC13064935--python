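import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexkit as ck

from conftest import make_matrix
from oracles import spearman_bruteforce


@pytest.fixture
def small_behavior(rng):
    return ck.build_behavior_matrix(make_matrix(rng.normal(size=(6, 12))))


class TestBuildBehaviorMatrix:
    def test_identical_profiles_correlate_perfectly(self, rng):
        profile = rng.normal(size=8)
        m = make_matrix(np.vstack([profile, profile, rng.normal(size=8)]),
                        genes=["A", "B", "C"])
        behavior = ck.build_behavior_matrix(m)
        assert behavior.data.loc["A", "B"] == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self, rng):
        profile = rng.normal(size=8)
        m = make_matrix(np.vstack([profile, -profile]), genes=["A", "B"])
        behavior = ck.build_behavior_matrix(m)
        assert behavior.data.loc["A", "B"] == pytest.approx(-1.0)

    def test_every_entry_matches_bruteforce_oracle(self, rng):
        m = make_matrix(rng.normal(size=(5, 8)))
        behavior = ck.build_behavior_matrix(m)
        for a in m.genes:
            for b in m.genes:
                expected = spearman_bruteforce(m.data.loc[a], m.data.loc[b])
                assert behavior.data.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, small_behavior):
        arr = small_behavior.data.to_numpy()
        np.testing.assert_array_equal(arr, arr.T)
        np.testing.assert_array_equal(np.diag(arr), 1.0)
        assert np.abs(arr).max() <= 1.0

    def test_blockwise_equals_single_block(self, rng):
        m = make_matrix(rng.normal(size=(20, 15)))
        full = ck.build_behavior_matrix(m, block_size=1000)
        blocked = ck.build_behavior_matrix(m, block_size=3)
        pd.testing.assert_frame_equal(full.data, blocked.data)

    def test_constant_gene_listed_in_error(self, rng):
        m = make_matrix(np.vstack([rng.normal(size=6), np.full(6, 2.0)]),
                        genes=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            ck.build_behavior_matrix(m)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            ck.build_behavior_matrix(make_matrix(rng.normal(size=(4, 2))))

    def test_monotone_transform_invariance(self, rng):
        m = make_matrix(np.abs(rng.normal(size=(8, 10))))
        b1 = ck.build_behavior_matrix(m)
        b2 = ck.build_behavior_matrix(
            ck.ExpressionMatrix(np.exp(m.data), ck.Unit.LOG_TPM))
        pd.testing.assert_frame_equal(b1.data, b2.data)


class TestAlanScore:
    def test_self_comparison_is_one(self, small_behavior):
        assert ck.alan_score(small_behavior, "G0", "G0") == 1.0

    def test_identical_expression_profiles_score_one(self, rng):
        profile = rng.normal(size=10)
        m = make_matrix(np.vstack([profile, profile, rng.normal(size=10),
                                   rng.normal(size=10)]),
                        genes=["A", "B", "C", "D"])
        behavior = ck.build_behavior_matrix(m)
        assert ck.alan_score(behavior, "A", "B") == pytest.approx(1.0)

    def test_matches_explicit_vector_oracle(self, rng):
        m = make_matrix(rng.normal(size=(6, 9)))
        behavior = ck.build_behavior_matrix(m)
        a, b = "G1", "G4"
        keep = [g for g in m.genes if g not in (a, b)]
        va = behavior.data.loc[a, keep].to_numpy()
        vb = behavior.data.loc[b, keep].to_numpy()
        expected = float(np.corrcoef(va, vb)[0, 1])
        assert ck.alan_score(behavior, a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_exact(self, small_behavior):
        assert ck.alan_score(small_behavior, "G1", "G3") == \
            ck.alan_score(small_behavior, "G3", "G1")

    def test_unknown_gene_errors(self, small_behavior):
        with pytest.raises(KeyError, match="NOPE"):
            ck.alan_score(small_behavior, "G0", "NOPE")

    def test_bounded_on_random_cohorts(self, rng):
        for _ in range(5):
            m = make_matrix(rng.normal(size=(10, 7)))
            behavior = ck.build_behavior_matrix(m)
            for a in m.genes:
                for b in m.genes:
                    assert abs(ck.alan_score(behavior, a, b)) <= 1.0


class TestGenesetHeatmap:
    def test_focal_inside_panel_scores_one_with_itself(self, small_behavior):
        panel = ck.GeneSet("panel", ["G0", "G1", "G2"])
        hm = ck.geneset_alan_heatmap(small_behavior, ["G1"], panel)
        assert hm.loc["G1", "G1"] == 1.0

    def test_rank_reversed_panel_scores_minus_one(self, rng):
        focal = rng.normal(size=12)
        rows = [focal, -focal, -2.0 * focal]
        rows += [rng.normal(size=12) for _ in range(5)]
        genes = ["F", "R1", "R2"] + [f"N{i}" for i in range(5)]
        behavior = ck.build_behavior_matrix(make_matrix(np.vstack(rows), genes=genes))
        hm = ck.geneset_alan_heatmap(behavior, ["F"], ck.GeneSet("rev", ["R1", "R2"]))
        assert hm.loc["F", "R1"] == pytest.approx(-1.0)
        assert hm.loc["F", "R2"] == pytest.approx(-1.0)

    def test_absent_members_dropped_empty_panel_errors(self, small_behavior):
        with pytest.raises(ValueError, match="panel"):
            ck.geneset_alan_heatmap(small_behavior, ["G0"],
                                    ck.GeneSet("ghost", ["X", "Y"]))

    def test_module_gene_prefers_its_own_panel(self, demo_cohort):
        truth = demo_cohort["truth"]
        behavior = ck.build_behavior_matrix(demo_cohort["log"])
        focal = truth.modules["basal"][0]
        own = ck.GeneSet("basal", truth.modules["basal"][1:])
        other = ck.GeneSet("luminal", truth.modules["luminal"])
        hm_own = ck.geneset_alan_heatmap(behavior, [focal], own)
        hm_other = ck.geneset_alan_heatmap(behavior, [focal], other)
        assert hm_own.loc[focal].mean() > hm_other.loc[focal].mean()


class TestCompareProfiles:
    def test_identical_profiles(self, small_behavior):
        p = small_behavior.profile("G0")
        r2, slope, intercept = ck.compare_profiles_r2(p, p)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_keeps_r2(self, small_behavior):
        p = small_behavior.profile("G0")
        neg = ck.ALANProfile(focal="G0", values=-p.values)
        r2, slope, _ = ck.compare_profiles_r2(p, neg)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(-1.0)

    def test_r2_equals_squared_pearson_oracle(self, rng):
        genes = [f"G{i}" for i in range(10)]
        v1 = pd.Series(rng.uniform(-1, 1, 10), index=genes)
        v2 = pd.Series(rng.uniform(-1, 1, 10), index=genes)
        p1 = ck.ALANProfile("A", v1)
        p2 = ck.ALANProfile("B", v2)
        common = [g for g in genes if g not in ("A", "B")]
        expected = float(np.corrcoef(v1[common], v2[common])[0, 1]) ** 2
        r2, _, _ = ck.compare_profiles_r2(p1, p2)
        assert r2 == pytest.approx(expected, abs=1e-12)

    def test_tiny_intersection_errors(self):
        p1 = ck.ALANProfile("A", pd.Series({"A": 1.0, "B": 0.2}))
        p2 = ck.ALANProfile("B", pd.Series({"A": 0.3, "B": 1.0}))
        with pytest.raises(ValueError, match="intersection"):
            ck.compare_profiles_r2(p1, p2)

    def test_cross_cohort_concordance_of_planted_genes(self):
        # a planted-module gene's behavior vector reproduces across
        # independent cohorts from the same spec; a background gene's does not
        wins = 0
        for seed in range(20):
            spec_a = ck.default_demo_spec(seed=1000 + seed, n_samples=300,
                                          n_genes=150)
            spec_b = ck.default_demo_spec(seed=2000 + seed, n_samples=300,
                                          n_genes=150)
            profiles = []
            for spec in (spec_a, spec_b):
                matrix, _, _, truth = ck.generate_cohort(spec)
                behavior = ck.build_behavior_matrix(ck.log_transform(matrix))
                profiles.append((behavior.profile(truth.modules["basal"][0]),
                                 behavior.profile("BG0050")))
            r2_mod, _, _ = ck.compare_profiles_r2(profiles[0][0], profiles[1][0])
            r2_bg, _, _ = ck.compare_profiles_r2(profiles[0][1], profiles[1][1])
            assert r2_mod >= 0.5
            wins += r2_mod > r2_bg
        assert wins == 20


class TestCountPotentialInteractions:
    @pytest.mark.parametrize("n,expected", [(20000, 400_000_000), (1, 1), (10, 100)])
    def test_square_law(self, n, expected):
        assert ck.count_potential_interactions(n) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ck.count_potential_interactions(0)
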