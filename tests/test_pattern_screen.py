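import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arspattern.data_io import (
    GROUP_ARSR_C,
    GROUP_ARSR_H,
    GROUP_AW_C,
    GROUP_AW_H,
    GROUP_K12_C,
    GROUP_K12_H,
    GROUP_K12_L,
    REFERENCE_GROUPS,
)
from arspattern.normalization import normalize
from arspattern.pattern_screen import (
    classify_arsr_dependent,
    classify_one,
    compute_group_means,
    null_inclusion_probability,
    screen,
)
from arspattern.synthetic_data import SyntheticSpec, generate_experiment
from arspattern.univariate_stats import anova_table

GROUPS = list(REFERENCE_GROUPS)


def means_frame(**overrides):
    base = {g: 0.0 for g in GROUPS}
    base.update(overrides)
    return pd.DataFrame([base], index=["P"])


class TestInclusionRule:
    def test_control_branch_fires(self):
        call = classify_one(
            {**{g: 0.0 for g in GROUPS}, GROUP_ARSR_C: 2.0, GROUP_AW_C: 1.0, GROUP_K12_C: 1.5},
            "P",
        )
        assert call.included and call.branch == "control"

    def test_all_equal_means_excluded(self):
        call = classify_one({g: 1.0 for g in GROUPS}, "P")
        assert not call.included and call.branch == "none"

    def test_gsha_like_inverse_profile_excluded(self):
        # most abundant in the deletion mutant under arsenite; AW control ≥ complement control
        call = classify_one(
            {
                GROUP_AW_C: 1.0,
                GROUP_ARSR_C: 0.5,
                GROUP_K12_C: 0.6,
                GROUP_AW_H: 3.0,
                GROUP_ARSR_H: 1.0,
                GROUP_K12_L: 1.2,
                GROUP_K12_H: 1.1,
            },
            "gshA",
        )
        assert not call.included

    def test_lldd_like_profile_fires_both_branches(self):
        # higher wherever ArsR is expressed, in both conditions
        call = classify_one(
            {
                GROUP_AW_C: 0.0,
                GROUP_ARSR_C: 2.0,
                GROUP_K12_C: 1.0,
                GROUP_AW_H: 0.2,
                GROUP_ARSR_H: 2.5,
                GROUP_K12_L: 2.2,
                GROUP_K12_H: 1.8,
            },
            "lldD",
        )
        assert call.included and call.branch == "both"

    def test_arsenite_branch_is_a_disjunction_over_k12_doses(self):
        # only the high-dose K-12 group exceeds the mutant: still fires
        call = classify_one(
            {
                GROUP_AW_H: 0.0,
                GROUP_ARSR_H: 1.0,
                GROUP_K12_L: -0.5,
                GROUP_K12_H: 0.5,
                GROUP_AW_C: 1.0,
                GROUP_ARSR_C: 0.0,
                GROUP_K12_C: 0.0,
            },
            "P",
        )
        assert call.included and call.branch == "arsenite"

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-50, 50))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(20, 7)), columns=GROUPS)
        a = classify_arsr_dependent(frame)
        b = classify_arsr_dependent(frame + shift)
        assert a["branch"].equals(b["branch"])

    def test_monotone_in_complement_control_mean(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.normal(size=(200, 7)), columns=GROUPS)
        before = classify_arsr_dependent(frame)["included"]
        frame2 = frame.copy()
        frame2[GROUP_ARSR_C] += 5.0
        after = classify_arsr_dependent(frame2)["included"]
        assert not (before & ~after).any()

    def test_margin_option_requires_buffer(self):
        frame = means_frame(**{GROUP_ARSR_C: 0.05, GROUP_K12_C: 0.05, GROUP_AW_C: 0.0})
        assert classify_arsr_dependent(frame)["included"].iloc[0]
        assert not classify_arsr_dependent(frame, margin=0.1)["included"].iloc[0]


class TestNullCalibration:
    def test_exact_probability_is_11_18(self):
        # brute-force enumeration over orderings of iid means:
        # control branch ⇔ AW_C is the minimum of 3 iid values;
        # arsenite branch counted over permutations of 4 iid values
        import itertools

        control = sum(
            1
            for perm in itertools.permutations([1, 2, 3])
            if perm[1] > perm[0] and perm[2] > perm[0]  # (AW, arsR, K12)
        ) / 6
        arsenite = sum(
            1
            for perm in itertools.permutations([1, 2, 3, 4])
            if perm[1] > perm[0] and (perm[2] > perm[0] or perm[3] > perm[0])
        ) / 24
        assert control == pytest.approx(1 / 3)
        assert arsenite == pytest.approx(5 / 12)
        combined = 1 - (1 - control) * (1 - arsenite)
        assert combined == pytest.approx(11 / 18)
        assert null_inclusion_probability() == pytest.approx(combined)

    def test_monte_carlo_matches_enumeration(self):
        rng = np.random.default_rng(77)
        frame = pd.DataFrame(rng.normal(size=(10000, 7)), columns=GROUPS)
        rate = classify_arsr_dependent(frame)["included"].mean()
        se = np.sqrt(11 / 18 * 7 / 18 / 10000)
        assert abs(rate - 11 / 18) < 3 * se


class TestScreen:
    def test_misaligned_accessions_rejected(self):
        anova = pd.DataFrame({"q": [0.0]}, index=["A"])
        calls = classify_arsr_dependent(means_frame())
        with pytest.raises(ValueError, match="misaligned"):
            screen(anova, calls)

    def test_empty_when_nothing_significant(self, planted_normalized):
        norm, design = planted_normalized
        table = anova_table(norm, design)
        table = table.assign(q=1.0)
        calls = classify_arsr_dependent(compute_group_means(norm, design))
        assert screen(table, calls) == []

    def test_recovers_planted_and_rejects_inverse(self, planted_normalized, planted_experiment):
        norm, design = planted_normalized
        _, _, _, truth = planted_experiment
        table = anova_table(norm, design)
        calls = classify_arsr_dependent(compute_group_means(norm, design))
        hits = set(screen(table, calls))
        planted = set(truth.accessions_of("arsr_dependent"))
        inverse = set(truth.accessions_of("inverse"))
        assert len(hits & planted) / len(planted) >= 0.8
        assert not hits & inverse

    def test_sorted_deterministically(self, planted_normalized):
        norm, design = planted_normalized
        table = anova_table(norm, design)
        calls = classify_arsr_dependent(compute_group_means(norm, design))
        a = screen(table, calls)
        b = screen(table.sample(frac=1, random_state=1), calls)
        assert a == b


class TestGroupMeans:
    def test_mean_of_centered_group(self, design):
        df = pd.DataFrame(
            [np.zeros(21)], index=["P0"], columns=design.sample_ids
        )
        df.loc["P0", design.samples_in_group(GROUP_AW_C)] = [-1.0, 0.0, 1.0]
        means = compute_group_means(df, design)
        assert means.loc["P0", GROUP_AW_C] == 0.0

    def test_missing_reference_group_rejected(self, design):
        sub = design.table[design.table["group_label"] != GROUP_K12_L]
        from arspattern.data_io import StudyDesign

        d = StudyDesign(sub[["sample_id", "strain", "arsenite_dose_uM", "replicate"]])
        df = pd.DataFrame(np.zeros((1, len(d.sample_ids))), index=["P"], columns=d.sample_ids)
        with pytest.raises(ValueError, match="missing reference groups"):
            compute_group_means(df, d)

    def test_planted_fold_orders_group_means(self):
        spec = SyntheticSpec(
            n_proteins=300,
            n_arsr_dependent=50,
            arsr_fold=4.0,
            n_arsenite_responsive=0,
            n_inverse=0,
            noise_cv=0.05,
            dropout_rate=0.0,
            seed=6,
        )
        matrix, design, truth = generate_experiment(spec)
        means = compute_group_means(normalize(matrix).data, design)
        planted = truth.accessions_of("arsr_dependent")
        ordered = (means.loc[planted, GROUP_ARSR_C] > means.loc[planted, GROUP_AW_C]).mean()
        assert ordered > 0.99
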