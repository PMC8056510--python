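"""Group percentages, mutation differences/extrema, and the linear threshold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genopheno import (
    MutationMatrix,
    SelectionConfig,
    SimulationConfig,
    apply_linear_threshold,
    group_percentages,
    mutation_differences,
    mutation_extrema,
    select_snps,
    simulate_matrix,
)
from genopheno.snp_preselection import GroupMutationProfile

from conftest import random_matrix


def labelled_matrix(columns, labels):
    frame = pd.DataFrame(columns, index=[f"s{i}" for i in range(len(labels))])
    return MutationMatrix(frame, pd.Series(labels, index=frame.index))


class TestGroupPercentages:
    def test_seven_sample_percentages_to_six_decimals(self):
        codes = [2, 2, 2, 2, 1, 1, 0]
        m = labelled_matrix({"rs82": codes + [0] * 3}, ["A"] * 7 + ["B"] * 3)
        prof_a = group_percentages(m)["rs82"][0]
        assert prof_a.pfm == pytest.approx(57.142857, abs=5e-7)
        assert prof_a.pnm == pytest.approx(14.285714, abs=5e-7)
        assert prof_a.ppm == pytest.approx(28.571429, abs=5e-7)

    def test_all_missing_group_yields_zeros(self):
        m = labelled_matrix(
            {"rs373523829": [np.nan] * 4 + [0, 0]}, ["A"] * 4 + ["B"] * 2
        )
        prof_a, prof_b = group_percentages(m)["rs373523829"]
        assert (prof_a.pnm, prof_a.ppm, prof_a.pfm) == (0, 0, 0)
        assert prof_a.n_observed == 0
        assert prof_b.pnm == 100

    def test_all_zero_codes(self):
        m = labelled_matrix({"rs1": [0, 0, 0, 0]}, ["A", "A", "B", "B"])
        prof_a, _ = group_percentages(m)["rs1"]
        assert (prof_a.pnm, prof_a.ppm, prof_a.pfm) == (100, 0, 0)

    def test_requires_exactly_two_labels(self):
        m = labelled_matrix({"rs1": [0, 1, 2]}, ["A", "B", "C"])
        with pytest.raises(ValueError):
            group_percentages(m)

    def test_matches_naive_counting_loop_on_random_matrices(self):
        """Independent per-sample counting oracle over 50 random matrices."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = random_matrix(rng, int(rng.integers(4, 12)), int(rng.integers(1, 6)))
            result = group_percentages(m)
            for snp in m.snp_ids:
                for prof in result[snp]:
                    members = [s for s in m.sample_ids if m.labels[s] == prof.group]
                    observed = [
                        m.codes.loc[s, snp]
                        for s in members
                        if not np.isnan(m.codes.loc[s, snp])
                    ]
                    if not observed:
                        assert (prof.pnm, prof.ppm, prof.pfm) == (0, 0, 0)
                        continue
                    n = len(observed)
                    assert prof.n_observed == n
                    assert prof.pnm == pytest.approx(100 * observed.count(0) / n)
                    assert prof.ppm == pytest.approx(100 * observed.count(1) / n)
                    assert prof.pfm == pytest.approx(100 * observed.count(2) / n)

    def test_percentages_normalise_to_100(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 30, 20, missing_rate=0.3)
        for pair in group_percentages(m).values():
            for prof in pair:
                if prof.n_observed:
                    assert prof.pnm + prof.ppm + prof.pfm == pytest.approx(100, abs=1e-6)


def profiles_pair(a, b, snp="rs82"):
    pa = GroupMutationProfile(snp, "A", *a, n_observed=100)
    pb = GroupMutationProfile(snp, "B", *b, n_observed=100)
    return pa, pb


class TestDifferencesAndExtrema:
    def test_absolute_differences_from_group_percentage_rows(self):
        pa, pb = profiles_pair(
            (5.219783, 36.538462, 58.241758), (2.754821, 33.057851, 64.187328)
        )
        d = mutation_differences(pa, pb)
        assert d.abs_no_diff == pytest.approx(2.464962, abs=1e-6)
        assert d.abs_partial_diff == pytest.approx(3.480611, abs=1e-6)
        assert d.abs_full_diff == pytest.approx(5.945570, abs=1e-6)

    def test_identical_profiles_zero_difference(self):
        pa, pb = profiles_pair((10, 20, 70), (10, 20, 70))
        d = mutation_differences(pa, pb)
        assert (d.abs_no_diff, d.abs_partial_diff, d.abs_full_diff) == (0, 0, 0)

    def test_extreme_difference(self):
        pa, pb = profiles_pair((100, 0, 0), (0, 0, 100))
        d = mutation_differences(pa, pb)
        assert (d.abs_no_diff, d.abs_partial_diff, d.abs_full_diff) == (100, 0, 100)

    def test_extrema_are_componentwise(self):
        pa, pb = profiles_pair(
            (5.219783, 36.538462, 58.241758), (2.754821, 33.057851, 64.187328)
        )
        e = mutation_extrema(pa, pb)
        assert e.max_full == pytest.approx(64.187328)
        assert e.min_full == pytest.approx(58.241758)
        assert e.max_no == pytest.approx(5.219783)

    def test_snp_mismatch_is_fatal(self):
        pa = GroupMutationProfile("rs1", "A", 10, 20, 70, 5)
        pb = GroupMutationProfile("rs2", "B", 10, 20, 70, 5)
        with pytest.raises(ValueError):
            mutation_differences(pa, pb)
        with pytest.raises(ValueError):
            mutation_extrema(pa, pb)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(deadline=None, max_examples=50)
    def test_extrema_equal_sorted_pair(self, x, y):
        pa, pb = profiles_pair((x, 0, 0), (y, 0, 0))
        e = mutation_extrema(pa, pb)
        assert (e.max_no, e.min_no) == (max(x, y), min(x, y))


class TestApplyLinearThreshold:
    def test_hand_evaluated_example(self):
        thr, low, sel = apply_linear_threshold(60, 30, SelectionConfig(slope=-1, intercept=100))
        assert thr == pytest.approx(40)
        assert low == pytest.approx(36)
        assert sel  # 30 <= 36

    def test_zero_slope_selects_only_zero_minimum(self):
        cfg = SelectionConfig(slope=0, intercept=100)
        thr, low, sel = apply_linear_threshold(80, 10, cfg)
        assert (thr, low, sel) == (100, 0, False)
        assert apply_linear_threshold(80, 0, cfg)[2]

    @given(
        st.floats(0, 100),
        st.floats(0, 100),
        st.integers(0, 4),
    )
    @settings(deadline=None, max_examples=200)
    def test_selection_monotone_in_slope(self, a, b, i):
        """A SNP selected at slope s stays selected at any s' < s."""
        slopes = [-0.5, -1, -1.5, -2, -3]
        mx, mn = max(a, b), min(a, b)
        if i + 1 >= len(slopes):
            return
        sel_hi = apply_linear_threshold(mx, mn, SelectionConfig(slope=slopes[i]))[2]
        sel_lo = apply_linear_threshold(mx, mn, SelectionConfig(slope=slopes[i + 1]))[2]
        if sel_hi:
            assert sel_lo

    def test_invert_flag_flips_predicate(self):
        cfg = SelectionConfig(slope=-1, intercept=100, invert_threshold=True)
        assert not apply_linear_threshold(60, 30, cfg)[2]


class TestSelectSnps:
    def test_planted_snp_recovered_among_flat_background(self):
        config = SimulationConfig(
            n_per_class=(100, 100), n_snps=201, n_informative=1,
            informative_profiles=((0.1, 0.1, 0.8), (0.8, 0.1, 0.1)),
            missing_rate=0.0, nocall_rate=0.0, seed=21,
        )
        matrix, truth = simulate_matrix(config)
        panel = select_snps(matrix, SelectionConfig(slope=-1.5, intercept=100))
        (planted,) = truth.informative_snp_ids
        assert planted in panel.snp_ids

    def test_impossible_prefilter_empties_panel(self, small_cohort):
        matrix, _ = small_cohort
        panel = select_snps(matrix, SelectionConfig(slope=-1.5, abs_diff_threshold=100))
        assert len(panel) == 0

    def test_steeper_negative_slope_selects_superset(self, small_cohort):
        matrix, _ = small_cohort
        p1 = select_snps(matrix, SelectionConfig(slope=-1))
        p2 = select_snps(matrix, SelectionConfig(slope=-2))
        assert set(p1.snp_ids) <= set(p2.snp_ids)

    def test_group_label_swap_leaves_panel_unchanged(self, small_cohort):
        matrix, _ = small_cohort
        swapped = MutationMatrix(
            matrix.codes, matrix.labels.map({"case": "control", "control": "case"})
        )
        cfg = SelectionConfig(slope=-1.5)
        assert select_snps(matrix, cfg).snp_ids == select_snps(swapped, cfg).snp_ids

    def test_snp_unobserved_in_one_group_is_excluded(self):
        m = labelled_matrix(
            {"rs1": [2, 2, np.nan, np.nan], "rs2": [2, 2, 0, 0]},
            ["A", "A", "B", "B"],
        )
        panel = select_snps(m, SelectionConfig(slope=-3))
        assert "rs1" not in panel.snp_ids
        assert "rs2" in panel.snp_ids

    def test_panel_order_descending_max_difference(self, small_cohort):
        matrix, _ = small_cohort
        panel = select_snps(matrix, SelectionConfig(slope=-1.5))
        diffs = [panel.audits[s].difference.max_diff for s in panel.snp_ids]
        assert all(a >= b - 1e-12 for a, b in zip(diffs, diffs[1:]))
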