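import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from arspattern.data_io import reference_design
from arspattern.normalization import normalize
from arspattern.univariate_stats import (
    anova_table,
    bh_adjust,
    group_summaries,
    oneway_anova,
    pairwise_ttest,
    tukey_hsd,
    tukey_table,
)


class TestAnova:
    def test_textbook_two_group_f(self):
        f, p = oneway_anova([np.array([1, 2, 3]), np.array([2, 3, 4])])
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(stats.f.sf(1.5, 1, 4))

    def test_identical_groups_give_f0_p1(self):
        f, p = oneway_anova([np.array([1, 2, 3]), np.array([1, 2, 3])])
        assert (f, p) == (0.0, 1.0)

    def test_zero_within_variance_with_separation(self):
        f, p = oneway_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0]), np.array([3.0, 3.0])])
        assert np.isinf(f) and p == 0.0

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [rng.normal(size=rng.integers(2, 6)) for _ in range(rng.integers(2, 5))]
            f, p = oneway_anova(groups)
            ref = stats.f_oneway(*groups)
            assert f == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 8))
            f, _ = oneway_anova([a, b])
            t, _ = stats.ttest_ind(a, b, equal_var=True)
            assert abs(f - t**2) < 1e-9


class TestBH:
    def test_stepup_collapse(self):
        assert list(bh_adjust([0.01, 0.02, 0.03, 0.04])) == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_direct_formula(self):
        assert list(bh_adjust([0.001, 0.02, 0.9])) == pytest.approx([0.003, 0.03, 0.9])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_permutation_invariance_and_monotonicity(self, ps):
        q = bh_adjust(ps)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_adjust(np.asarray(ps)[perm])
        assert np.allclose(np.sort(q), np.sort(q_perm))
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)


class TestTukey:
    def test_toy_triple_q_statistic(self):
        res = tukey_hsd([np.array([0, 1, 2]), np.array([1, 2, 3]), np.array([2, 3, 4])], list("ABC"))
        ac = next(r for r in res if (r.group1, r.group2) == ("A", "C"))
        assert ac.q_statistic == pytest.approx(3.4641, abs=1e-4)
        assert ac.direction == "down"

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = [rng.normal(size=4) for _ in range(3)]
            ours = tukey_hsd(groups, list("abc"))
            ref = stats.tukey_hsd(*groups)
            for r in ours:
                i, j = "abc".index(r.group1), "abc".index(r.group2)
                assert r.p == pytest.approx(ref.pvalue[i, j], rel=1e-8, abs=1e-12)

    def test_all_identical_groups_tie(self):
        res = tukey_hsd([np.array([1.0, 2.0])] * 3)
        assert all(r.p == 1.0 and r.direction == "tie" for r in res)

    def test_degenerate_zero_within_variance(self):
        res = tukey_hsd([np.array([0.0, 0.0]), np.array([5.0, 5.0]), np.array([5.0, 5.0])], list("abc"))
        ab = next(r for r in res if (r.group1, r.group2) == ("a", "b"))
        bc = next(r for r in res if (r.group1, r.group2) == ("b", "c"))
        assert ab.p == 0.0 and bc.p == 1.0

    def test_multiplicity_penalty_vs_unadjusted_pairwise(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            groups = [rng.normal(size=5) for _ in range(4)]
            res = tukey_hsd(groups, list("abcd"))
            for r in res:
                i, j = "abcd".index(r.group1), "abcd".index(r.group2)
                _, p_t = stats.ttest_ind(groups[i], groups[j], equal_var=True)
                assert r.p >= p_t - 1e-9


class TestTTests:
    def test_paired_example(self):
        t, p = pairwise_ttest([1, 2, 3], [2, 4, 3], mode="paired")
        assert t == pytest.approx(-np.sqrt(3))
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(3), 2))

    def test_paired_identical_vectors_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_ttest([1, 2, 3], [1, 2, 3], mode="paired")

    def test_welch_p_shrinks_with_jitter(self):
        rng = np.random.default_rng(2)
        last = 1.0
        for eps in (1e-1, 1e-3, 1e-5):
            a = 0 + eps * rng.normal(size=4)
            b = 1 + eps * rng.normal(size=4)
            _, p = pairwise_ttest(a, b, mode="welch")
            assert p < last
            last = p
        assert last < 1e-10

    def test_unequal_lengths_rejected_in_paired_mode(self):
        with pytest.raises(ValueError, match="equal-length"):
            pairwise_ttest([1, 2, 3], [1, 2], mode="paired")


class TestAnovaTable:
    def test_planted_effects_are_detected(self, planted_normalized, planted_experiment):
        norm, design = planted_normalized
        _, _, _, truth = planted_experiment
        table = anova_table(norm, design)
        assert (table["q"] >= table["p"] - 1e-12).all()
        planted = [a for a in truth.accessions_of("arsr_dependent") if a in table.index]
        assert table.loc[planted, "significant_005"].mean() > 0.8

    def test_flags_consistent_with_thresholds(self, planted_normalized):
        norm, design = planted_normalized
        table = anova_table(norm, design)
        tested = ~table["skipped"]
        assert (table.loc[tested, "significant_005"] == (table.loc[tested, "q"] < 0.05)).all()
        assert (table.loc[tested, "significant_0001"] == (table.loc[tested, "q"] < 0.001)).all()
        # strict set nests inside the broad set
        assert not (table["significant_0001"] & ~table["significant_005"]).any()


class TestGroupSummaries:
    def test_median_and_mean(self, design):
        df = pd.DataFrame(
            [np.arange(21, dtype=float)], index=["P0"], columns=design.sample_ids
        )
        out = group_summaries(df, design)
        first = out.iloc[0]
        assert first["median"] == 1.0 and first["mean"] == 1.0  # group values 0,1,2

    def test_linear_interpolation_quartiles_and_singleton(self):
        from arspattern.data_io import StudyDesign

        d = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b", "c", "d", "solo"],
                    "strain": ["K12"] * 4 + ["AW3110"],
                    "arsenite_dose_uM": [0, 0, 0, 0, 0],
                    "replicate": [1, 2, 3, 4, 1],
                }
            )
        )
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["P"], columns=d.sample_ids)
        out = group_summaries(df, d).set_index("group")
        k12 = out.loc["K12:control"]
        assert (k12["q1"], k12["q3"]) == (1.75, 3.25)
        solo = out.loc["AW3110:control"]
        assert all(solo[c] == 5.0 for c in ["min", "q1", "median", "q3", "max", "mean"])

    def test_shape_is_proteins_times_groups(self, planted_normalized):
        norm, design = planted_normalized
        accs = norm.accessions[:5]
        out = group_summaries(norm, design, accs)
        assert len(out) == 5 * 7
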