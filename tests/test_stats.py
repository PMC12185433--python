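"""Statistics: test selection gates, effect sizes, mixed ANOVA, dose arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from catrans import (DoseSchedule, EventCountTable, choose_two_group_test,
                     cumulative_dose, kruskal_wallis, mixed_anova,
                     percent_change, ptz_sst_schedule, two_group_compare)
from catrans.errors import (InsufficientSampleError, InvalidDesignError,
                            InvalidParameterError)


def make_table(counts_by_group, window_labels=None):
    """Assemble an EventCountTable from {group: (n_cells x n_windows) array}."""
    blocks = {g: np.asarray(c) for g, c in counts_by_group.items()}
    n_windows = next(iter(blocks.values())).shape[1]
    counts = np.vstack(list(blocks.values()))
    ids = [f"{g}_{i}" for g, c in blocks.items() for i in range(c.shape[0])]
    groups = [g for g, c in blocks.items() for _ in range(c.shape[0])]
    labels = window_labels or [f"w{k}" for k in range(n_windows)]
    return EventCountTable(counts, ids, groups, labels)


def split_plot_oracle(table):
    """Independent sums-of-squares decomposition of the mixed design.

    Group is between-subjects, window within-subjects, one observation per
    cell x window.  Returns F and partial eta squared per effect.
    """
    y = table.counts.astype(float)
    groups = np.asarray(table.groups)
    glabels = list(dict.fromkeys(groups))
    n, w = y.shape
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    # between-subjects stratum
    ss_group = sum(w * (groups == g).sum() * (subj_mean[groups == g].mean() - grand) ** 2
                   for g in glabels)
    ss_subj = w * ((subj_mean - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_group
    # within-subjects stratum
    win_mean = y.mean(axis=0)
    ss_window = n * ((win_mean - grand) ** 2).sum()
    ss_inter = 0.0
    for g in glabels:
        sel = groups == g
        cellmean_gw = y[sel].mean(axis=0)
        ss_inter += sel.sum() * ((cellmean_gw - y[sel].mean() - win_mean + grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_subj - ss_window - ss_inter
    g_ = len(glabels)
    F_group = (ss_group / (g_ - 1)) / (ss_err_between / (n - g_))
    F_window = (ss_window / (w - 1)) / (ss_err_within / ((n - g_) * (w - 1)))
    F_inter = (ss_inter / ((g_ - 1) * (w - 1))) / (ss_err_within / ((n - g_) * (w - 1)))
    return {
        "F_group": F_group, "F_time": F_window, "F_interaction": F_inter,
        "np2_group": ss_group / (ss_group + ss_err_between),
        "np2_time": ss_window / (ss_window + ss_err_within),
        "np2_interaction": ss_inter / (ss_inter + ss_err_within),
    }


class TestChooseTest:
    def test_normal_equal_sd_gives_t(self, rng):
        x, y = rng.normal(0, 1, 100), rng.normal(0.2, 1, 100)
        assert choose_two_group_test(x, y) == "t"

    def test_skewed_sample_gives_mannwhitney(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.exponential(1.0, 50)
            y = r.normal(0, 1, 50)
            hits += choose_two_group_test(x, y) == "mannwhitney"
        assert hits >= 8  # Shapiro-Wilk rejects exponential at n=50 w.h.p.

    def test_unequal_sd_gives_welch(self):
        r = np.random.default_rng(2)
        x, y = r.normal(0, 1, 30), r.normal(0, 4, 30)
        assert choose_two_group_test(x, y) == "welch"

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientSampleError):
            choose_two_group_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTwoGroupCompare:
    def test_identical_samples(self, rng):
        x = rng.normal(0, 1, 40)
        res = two_group_compare(x, x.copy())
        assert res.effect_size == 0.0 if res.effect_size_kind == "cohen_d" else True
        assert res.p_value > 0.99
        assert res.delta_mean == 0.0

    def test_fully_separated_samples_rank_biserial_one(self):
        x = np.array([10.0, 11.0, 12.0, 13.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_group_compare(x, y, test_name="mannwhitney")
        assert res.effect_size == 1.0
        assert res.effect_size_kind == "rank_biserial"

    def test_cohens_d_matches_pooled_sd_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 4.0, 5.0])
        res = two_group_compare(x, y, test_name="t")
        # pooled SD of two n=4 samples each with variance 5/3
        pooled = np.sqrt(5.0 / 3.0)
        assert res.effect_size == pytest.approx((2.5 - 3.5) / pooled)
        assert res.delta_mean == pytest.approx(-1.0)

    def test_all_tied_data_warns_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = two_group_compare(np.ones(5), np.ones(5))
        assert res.p_value == 1.0

    @given(seed=st.integers(0, 2**16), scale=st.floats(0.1, 10.0),
           shift=st.floats(-5.0, 5.0))
    def test_mannwhitney_p_invariant_under_monotone_transform(self, seed, scale, shift):
        r = np.random.default_rng(seed)
        x, y = r.normal(0, 1, 12), r.normal(0.5, 1, 15)
        p0 = two_group_compare(x, y, test_name="mannwhitney").p_value
        # strictly monotone transforms of the pooled data
        p_aff = two_group_compare(scale * x + shift, scale * y + shift,
                                  test_name="mannwhitney").p_value
        p_exp = two_group_compare(np.exp(x), np.exp(y), test_name="mannwhitney").p_value
        assert p_aff == pytest.approx(p0, rel=1e-9)
        assert p_exp == pytest.approx(p0, rel=1e-9)


class TestKruskal:
    def test_design_df_echo(self):
        r = np.random.default_rng(0)
        samples = [r.normal(0, 1, n) for n in (10, 10, 10, 9)]
        res = kruskal_wallis(samples)
        assert res.df_between == 3
        assert res.df_within == 35

    def test_null_rejection_rate_near_alpha(self):
        rej = 0
        n_sim = 200
        for seed in range(n_sim):
            r = np.random.default_rng(seed)
            res = kruskal_wallis([r.normal(0, 1, 10) for _ in range(3)])
            rej += res.p_value < 0.05
        assert 0.01 <= rej / n_sim <= 0.10

    def test_shifted_group_detected(self):
        r = np.random.default_rng(1)
        samples = [r.normal(0, 1, 10), r.normal(0, 1, 10), r.normal(3, 1, 10)]
        assert kruskal_wallis(samples).p_value < 0.01

    def test_separated_constant_groups_reach_max_h(self):
        # distinct constants per group: complete separation with within-group ties
        samples = [np.full(3, v) for v in (1.0, 2.0, 3.0)]
        res = kruskal_wallis(samples)
        # rank-arithmetic oracle with tie correction
        ranks = np.array([2.0] * 3 + [5.0] * 3 + [8.0] * 3)
        N = 9
        h_raw = 12.0 / (N * (N + 1)) * sum(3 * (ranks[i:i + 3].mean() - 5.0) ** 2
                                           for i in (0, 3, 6))
        ties = 3 * (3 ** 3 - 3)
        h = h_raw / (1 - ties / (N ** 3 - N))
        assert res.H == pytest.approx(h)

    def test_two_groups_rejected(self):
        with pytest.raises(InvalidDesignError):
            kruskal_wallis([np.ones(5), np.zeros(5)])


class TestMixedAnova:
    def test_identical_groups_have_near_zero_group_effect(self, rng):
        block = rng.poisson(3, size=(40, 4))
        table = make_table({"a": block, "b": block.copy()})
        res = mixed_anova(table)
        assert res.partial_eta_sq_group < 1e-10

    @pytest.mark.parametrize("n1,n2,df2", [(161, 145, 304), (15, 24, 37)])
    def test_between_subjects_df(self, rng, n1, n2, df2):
        table = make_table({"a": rng.poisson(3, (n1, 4)), "b": rng.poisson(3, (n2, 4))})
        res = mixed_anova(table)
        assert res.df == (1, df2)

    def test_matches_sums_of_squares_oracle(self, rng):
        table = make_table({"a": rng.poisson(3, (12, 4)) + np.arange(4),
                            "b": rng.poisson(5, (12, 4))})
        res = mixed_anova(table)
        want = split_plot_oracle(table)
        assert res.F_group == pytest.approx(want["F_group"])
        assert res.F_time == pytest.approx(want["F_time"])
        assert res.F_interaction == pytest.approx(want["F_interaction"])
        assert res.partial_eta_sq_group == pytest.approx(want["np2_group"])
        assert res.partial_eta_sq_time == pytest.approx(want["np2_time"])
        assert res.partial_eta_sq_interaction == pytest.approx(want["np2_interaction"])
        for v in (res.partial_eta_sq_group, res.partial_eta_sq_time,
                  res.partial_eta_sq_interaction):
            assert 0.0 <= v <= 1.0

    def test_single_group_rejected(self, rng):
        table = make_table({"a": rng.poisson(3, (10, 4))})
        with pytest.raises(InvalidDesignError):
            mixed_anova(table)


class TestPercentChange:
    def test_equal_means_zero_percent(self):
        table = make_table({"ref": np.full((5, 2), 3), "test": np.full((5, 2), 3)})
        pc = percent_change(table, "ref")
        assert np.allclose(pc.to_numpy(), 0.0)

    def test_fifty_percent_increase(self):
        table = make_table({"ref": np.full((4, 1), 2), "test": np.full((4, 1), 3)})
        assert percent_change(table, "ref").iloc[0] == pytest.approx(50.0)

    def test_zero_reference_mean_rejected(self):
        table = make_table({"ref": np.zeros((4, 1), dtype=int),
                            "test": np.full((4, 1), 3)})
        with pytest.raises(InvalidParameterError, match="undefined"):
            percent_change(table, "ref")

    def test_doubled_rate_near_plus_100_percent(self, rng):
        table = make_table({"ref": rng.poisson(3.0, (150, 1)),
                            "test": rng.poisson(6.0, (150, 1))})
        pc = percent_change(table, "ref").iloc[0]
        assert 75.0 < pc < 125.0


class TestDose:
    def test_schedule_arithmetic(self):
        sched = ptz_sst_schedule(initial_dose=40.0)
        assert cumulative_dose(sched, 1) == 40.0
        assert cumulative_dose(sched, 3) == 50.0  # 40 + 5 + 5
        assert cumulative_dose(sched, 4) == 60.0  # then 10 mg/kg boosters

    def test_reduced_start_arm(self):
        sched = ptz_sst_schedule(initial_dose=30.0)
        assert cumulative_dose(sched, 2) == 35.0

    @given(k=st.integers(1, 12), seed=st.integers(0, 1000))
    def test_matches_brute_force_summation(self, k, seed):
        r = np.random.default_rng(seed)
        doses = r.uniform(1, 20, 12)
        sched = DoseSchedule(initial_dose=doses[0],
                             booster_doses=tuple((d, 5.0 * (i + 1))
                                                 for i, d in enumerate(doses[1:])))
        assert cumulative_dose(sched, k) == pytest.approx(doses[:k].sum())

    def test_index_out_of_schedule_rejected(self):
        sched = ptz_sst_schedule(n_boosters=2)
        with pytest.raises(InvalidParameterError):
            cumulative_dose(sched, 5)
        with pytest.raises(InvalidParameterError):
            cumulative_dose(sched, 0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(InvalidParameterError):
            DoseSchedule(initial_dose=-1.0, booster_doses=((5.0, 10.0),))
        with pytest.raises(InvalidParameterError):
            DoseSchedule(initial_dose=40.0, booster_doses=((5.0, 10.0), (5.0, 10.0)))
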