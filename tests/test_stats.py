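"""Effect sizes, t-tests, chi-squared, ICC and the table-shaped reports."""

import numpy as np
import pandas as pd
import pytest

from tonemg import (
    CohortSpec,
    GroupSummary,
    build_comparison_report,
    build_reliability_report,
    chi_squared,
    cohens_d,
    icc,
    simulate_cohort,
    students_t,
)
from tonemg.stats import significance_stars


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d(10.0, 2.0, 20, 10.0, 2.0, 20).d == 0.0

    def test_published_max_drop_effect_size(self):
        # tone-4 maximal 5 ms drop: 16.1 +- 5.7 (n=17) vs 27.8 +- 14.8 (n=71)
        assert round(cohens_d(16.1, 5.7, 17, 27.8, 14.8, 71).d, 2) == 0.86

    def test_published_tone1_turns_effect_size(self):
        assert round(cohens_d(442.4, 285.0, 17, 730.6, 231.6, 71).d, 2) == 1.19

    def test_symmetric_in_group_order(self):
        a = cohens_d(10.0, 3.0, 15, 14.0, 4.0, 30)
        b = cohens_d(14.0, 4.0, 30, 10.0, 3.0, 15)
        assert a.d == pytest.approx(b.d)
        assert a.direction == -b.direction

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        m1, s1, m2, s2 = 10.0, 3.0, 14.0, 4.0
        base = cohens_d(m1, s1, 15, m2, s2, 30).d
        for _ in range(10):
            a, b = rng.uniform(0.5, 3.0), rng.uniform(-5, 5)
            scaled = cohens_d(a * m1 + b, a * s1, 15, a * m2 + b, a * s2, 30).d
            assert scaled == pytest.approx(base)

    def test_zero_pooled_sd_flags_infinite(self):
        res = cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert res.infinite
        assert np.isinf(res.d)

    def test_small_group_guard(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestStudentsT:
    def test_identical_samples_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p, df = students_t(x, x)
        assert t == 0.0
        assert p == 1.0
        assert df == 6.0

    def test_summary_path_equals_raw_path(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 40)))
            b = rng.normal(0.3, 1.4, int(rng.integers(5, 40)))
            t1, p1, df1 = students_t(a, b)
            s1 = GroupSummary.from_samples("a", a)
            s2 = GroupSummary.from_samples("b", b)
            t2, p2, df2 = students_t(s1, s2)
            assert t1 == pytest.approx(t2, abs=1e-10)
            assert p1 == pytest.approx(p2, abs=1e-10)
            assert df1 == df2

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.5, 10)
        b = rng.normal(0, 3.0, 50)
        _, _, df_pooled = students_t(a, b)
        _, _, df_welch = students_t(a, b, welch=True)
        assert df_welch < df_pooled

    def test_type_i_error_near_alpha(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (2000, 12))
        y = rng.normal(0, 1, (2000, 20))
        rej = np.mean([students_t(x[i], y[i])[1] < 0.05 for i in range(2000)])
        assert 0.03 < rej < 0.07


class TestChiSquared:
    def test_proportional_table_zero_statistic(self):
        stat, p, _ = chi_squared([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_paralysis_side_regression(self):
        # published p = 0.099 for the 7/10 vs 47/24 side split matches the
        # continuity-corrected test; the uncorrected Pearson value is frozen
        # as a regression anchor
        table = [[7, 10], [47, 24]]
        _, p_corr, _ = chi_squared(table, correction=True)
        assert p_corr == pytest.approx(0.099, abs=0.01)
        _, p_raw, _ = chi_squared(table)
        assert p_raw == pytest.approx(0.0570, abs=0.0005)

    def test_empty_cell_warns_small_expected(self):
        with pytest.warns(UserWarning, match="expected count"):
            stat, p, expected = chi_squared([[0, 6], [5, 5]])
        assert np.isfinite(stat)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [5, 5]])


class TestICC:
    def test_duplicated_trials_icc_exactly_one(self):
        m = np.tile(np.array([[200.0], [220.0], [250.0], [180.0]]), (1, 3))
        res = icc(m)
        assert res.icc == 1.0
        assert res.cross_trial_sd == 0.0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        m = rng.normal(200, 40, 15)[:, None] + rng.normal(0, 8, (15, 3))
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(15), 3),
            "trial": np.tile(np.arange(3), 15),
            "y": m.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subj", raters="trial", ratings="y")
        ref = ref.set_index("Type")["ICC"]
        ref_a1 = float(ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"])
        ref_31 = float(ref.loc["ICC(C,1)"] if "ICC(C,1)" in ref.index else ref.loc["ICC3"])
        assert icc(m, "ICC(A,1)").icc == pytest.approx(ref_a1, abs=1e-9)
        assert icc(m, "ICC(3,1)").icc == pytest.approx(ref_31, abs=1e-9)

    def test_within_noise_dominates_icc_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [icc(rng.normal(0, 0.5, 40)[:, None] + rng.normal(0, 50, (40, 3))).icc
                for _ in range(200)]
        assert abs(np.mean(vals)) < 0.03

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(8)
        vals = [icc(rng.normal(0, 40, 100)[:, None] + rng.normal(0, 10, (100, 3))).icc
                for _ in range(300)]
        assert np.mean(vals) == pytest.approx(1600 / 1700, abs=0.01)

    def test_missing_cells_dropped_with_warning(self):
        m = np.array([[1.0, 2.0, 3.0], [2.0, np.nan, 3.0], [5.0, 6.0, 7.0],
                      [0.0, 1.0, 2.0]])
        with pytest.warns(UserWarning, match="dropped 1"):
            res = icc(m)
        assert res.n_subjects == 3

    def test_zero_between_variance_flagged(self):
        m = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        res = icc(m)
        assert "zero_between_subject_variance" in res.flags
        assert np.isnan(res.icc)


class TestStars:
    @pytest.mark.parametrize("p,stars", [(0.2, ""), (0.04, "*"), (0.004, "**"),
                                         (0.0004, "***"), (0.05, "")])
    def test_footnote_convention(self, p, stars):
        assert significance_stars(p) == stars


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(seed=42))


class TestReports:
    def test_comparison_has_21_acoustic_rows(self, cohort):
        rep = build_comparison_report(cohort.subject_means)
        assert rep.shape[0] == 21  # 4 + 4 + 8 + 5 tone-feature rows
        assert set(rep.columns) >= {"tone", "feature", "t", "p", "cohens_d", "stars"}

    def test_effect_sizes_recover_generator_targets(self, cohort):
        rep = build_comparison_report(cohort.subject_means)
        row = rep[(rep.tone == 4) & (rep.feature == "max_drop_5ms")].iloc[0]
        assert row.cohens_d == pytest.approx(0.86, abs=0.45)  # one cohort draw

    def test_empty_group_raises(self, cohort):
        only_neg = cohort.subject_means[cohort.subject_means.group == "CT-"]
        with pytest.raises(ValueError, match="n < 2"):
            build_comparison_report(only_neg)

    def test_reliability_report_perfect_when_trials_identical(self):
        spec = CohortSpec(
            n_ct_pos=5, n_ct_neg=5,
            acoustic_stats={1: {"f0_onset": (212.3, 40.0, 233.4, 40.0, 0.0)}},
            turns_stats={},
            within_sd={(1, "f0_onset"): 0.0},
            seed=9,
        )
        rel = build_reliability_report(simulate_cohort(spec).trials)
        assert rel.shape[0] == 1
        assert rel.icc.iloc[0] == 1.0
        assert rel.cross_trial_sd.iloc[0] == 0.0

    def test_reliability_report_shape(self, cohort):
        rel = build_reliability_report(cohort.trials)
        assert rel.shape[0] == 21
        assert ((rel.icc <= 1.0) | rel.icc.isna()).all()
        assert (rel.cross_trial_sd >= 0).all()
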