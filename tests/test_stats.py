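import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from glucotrig.stats import (
    StatsError,
    between_visit_cv,
    exclude_outliers,
    rm_anova,
    summarize,
)


def brute_force_rm_anova(matrix):
    """Independent oracle: within-subjects sums of squares by explicit
    loops, no shortcuts shared with the implementation."""
    y = [list(map(float, row)) for row in matrix]
    n, k = len(y), len(y[0])
    grand = sum(sum(row) for row in y) / (n * k)
    ss_subj = 0.0
    for i in range(n):
        m = sum(y[i]) / k
        ss_subj += k * (m - grand) ** 2
    ss_cond = 0.0
    for j in range(k):
        m = sum(y[i][j] for i in range(n)) / n
        ss_cond += n * (m - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (y[i][j] - grand) ** 2
    ss_err = ss_tot - ss_subj - ss_cond
    df_e, df_err = k - 1, (k - 1) * (n - 1)
    return (ss_cond / df_e) / (ss_err / df_err), df_e, df_err


class TestSummarize:
    def test_constant_sample(self):
        s = summarize([19, 19, 19])
        assert (s.mean, s.sd, s.sem, s.cv_percent) == (19, 0, 0, 0)

    def test_hand_computed_sd_and_sem(self):
        s = summarize([16, 19, 22])
        assert s.mean == pytest.approx(19)
        assert s.sd == pytest.approx(3)                    # sample sd, n-1
        assert s.sem == pytest.approx(3 / math.sqrt(3))    # 1.732

    def test_visit_level_cv(self):
        s = summarize([18.8, 19.0, 19.2])
        assert s.cv_percent == pytest.approx(100 * 0.2 / 19, rel=1e-6)  # 1.05%

    def test_cv_undefined_at_zero_mean(self):
        assert summarize([-1, 0, 1]).cv_percent is None

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(StatsError):
            summarize([])
        with pytest.raises(StatsError):
            summarize([19])

    @settings(derandomize=True, max_examples=100)
    @given(
        vals=st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=2, max_size=30),
        shift=st.floats(min_value=-100, max_value=100),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_shift_and_scale_equivariance(self, vals, shift, scale):
        base = summarize(vals)
        shifted = summarize([v + shift for v in vals])
        assert shifted.mean == pytest.approx(base.mean + shift, rel=1e-6, abs=1e-6)
        assert shifted.sd == pytest.approx(base.sd, rel=1e-6, abs=1e-6)
        scaled = summarize([v * scale for v in vals])
        assert scaled.sd == pytest.approx(base.sd * scale, rel=1e-6, abs=1e-6)
        assert scaled.sem == pytest.approx(base.sem * scale, rel=1e-6, abs=1e-6)
        if base.cv_percent is not None and abs(base.mean) > 1e-6:
            assert scaled.cv_percent == pytest.approx(base.cv_percent, rel=1e-4)


class TestOutlierRule:
    def test_identical_values_keep_everything(self):
        rep = exclude_outliers([(f"S{i}", 19.0) for i in range(12)])
        assert rep.excluded == []
        assert len(rep.retained) == 12

    def test_two_of_twelve_excluded(self):
        """Ten values of 19 plus {200, -150}: mean 20, sd 74.66, bounds
        about [-129.3, 169.3] -> exactly the two extremes fall outside."""
        pairs = [(f"S{i}", 19.0) for i in range(10)] + [("S10", 200.0), ("S11", -150.0)]
        rep = exclude_outliers(pairs)
        assert rep.lower_bound == pytest.approx(-129.31, abs=0.01)
        assert rep.upper_bound == pytest.approx(169.31, abs=0.01)
        assert sorted(v for _, v in rep.excluded) == [-150.0, 200.0]
        assert len(rep.retained) == 10

    def test_small_samples_rejected(self):
        with pytest.raises(StatsError):
            exclude_outliers([("a", 1.0), ("b", 2.0)])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=3, max_size=40),
           st.randoms(use_true_random=False))
    def test_partition_and_order_invariance(self, vals, rnd):
        pairs = list(enumerate(vals))
        rep = exclude_outliers(pairs)
        assert len(rep.retained) + len(rep.excluded) == len(pairs)
        assert {i for i, _ in rep.retained} | {i for i, _ in rep.excluded} == set(range(len(vals)))
        for _, v in rep.excluded:
            assert v < rep.lower_bound or v > rep.upper_bound
        for _, v in rep.retained:
            assert rep.lower_bound <= v <= rep.upper_bound
        shuffled = pairs[:]
        rnd.shuffle(shuffled)
        rep2 = exclude_outliers(shuffled)
        assert sorted(rep2.excluded) == sorted(rep.excluded)
        # summation order may move the bounds by a last ulp
        assert rep2.lower_bound == pytest.approx(rep.lower_bound, rel=1e-12, abs=1e-12)
        assert rep2.upper_bound == pytest.approx(rep.upper_bound, rel=1e-12, abs=1e-12)


class TestRmAnova:
    def test_identical_columns_no_effect(self):
        col = [1.0, 2.0, 5.0, 7.0]
        res = rm_anova(np.column_stack([col, col, col]))
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_two_conditions_equal_squared_paired_t(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(8, 2))
        res = rm_anova(y)
        t = sps.ttest_rel(y[:, 0], y[:, 1])
        assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            y = rng.normal(loc=10, scale=3, size=(5, 3))
            res = rm_anova(y)
            f_oracle, df_e, df_err = brute_force_rm_anova(y)
            assert res.f_stat == pytest.approx(f_oracle, rel=1e-10)
            assert (res.df_effect, res.df_error) == (df_e, df_err)
            assert res.p_value == pytest.approx(float(sps.f.sf(f_oracle, df_e, df_err)), rel=1e-10)

    def test_matches_statsmodels_anovarm(self):
        """Independent cross-check against the reference implementation."""
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        y = rng.normal(loc=19, scale=5, size=(10, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "visit": np.tile(np.arange(3), 10),
                "value": y.ravel(),
            }
        )
        sm_res = AnovaRM(long, depvar="value", subject="subject", within=["visit"]).fit()
        res = rm_anova(y)
        assert res.f_stat == pytest.approx(sm_res.anova_table["F Value"].iloc[0], rel=1e-8)
        assert res.p_value == pytest.approx(sm_res.anova_table["Pr > F"].iloc[0], rel=1e-8)

    def test_subject_constant_absorbed_and_relabel_invariant(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(6, 4))
        base = rm_anova(y)
        shifted = rm_anova(y + rng.normal(size=(6, 1)) * 50)  # per-subject offsets
        assert shifted.f_stat == pytest.approx(base.f_stat, rel=1e-8)
        perm = rng.permutation(4)
        relabeled = rm_anova(y[:, perm])
        assert relabeled.f_stat == pytest.approx(base.f_stat, rel=1e-10)

    def test_bonferroni_bounds(self):
        rng = np.random.default_rng(5)
        res = rm_anova(rng.normal(size=(7, 4)))
        assert len(res.posthoc) == 6  # 4*3/2 pairs
        for _, raw, adj in res.posthoc:
            assert adj >= raw
            assert adj <= 1.0
            assert adj == pytest.approx(min(1.0, raw * 6))

    def test_degenerate_zero_error_flagged(self):
        # perfect additive structure: residual MS is exactly 0
        subj = np.array([[0.0], [10.0], [20.0]])
        cond = np.array([[1.0, 2.0, 3.0]])
        res = rm_anova(subj + cond)
        assert res.degenerate
        assert math.isinf(res.f_stat)
        assert res.p_value == 0.0

    def test_all_equal_matrix_degenerate_zero_f(self):
        res = rm_anova(np.zeros((4, 3)))
        assert res.degenerate
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_missing_cells_rejected(self):
        y = np.ones((3, 3))
        y[1, 2] = np.nan
        with pytest.raises(StatsError, match="missing"):
            rm_anova(y)

    def test_too_small_rejected(self):
        with pytest.raises(StatsError):
            rm_anova(np.ones((1, 3)))


class TestBetweenVisitCv:
    def test_hand_value(self):
        assert between_visit_cv([18.8, 19.0, 19.2]) == pytest.approx(100 * 0.2 / 19, rel=1e-6)

    def test_zero_mean_rejected(self):
        with pytest.raises(StatsError):
            between_visit_cv([-1.0, 1.0])
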