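"""Longitudinal statistics: rBF, dRBF, summaries, t-tests, durations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dcsflow import (
    MeasurementRecord,
    compute_delta_rbf,
    compute_rbf,
    elevation_duration,
    group_summary,
    records_to_frame,
    student_t_test,
    weekly_comparisons,
)
from dcsflow.errors import DataError


def _rec(mouse, week, position, bfi, group="autograft", sep=5.0):
    return MeasurementRecord(mouse=mouse, group=group, week=week, position=position,
                             separation_mm=sep, bfi=bfi)


def _frame(series_by_site):
    """series_by_site: {(mouse, position): [bfi at week 0, 1, ...]}"""
    recs = []
    for (mouse, pos), series in series_by_site.items():
        for week, bfi in enumerate(series):
            recs.append(_rec(mouse, week, pos, bfi))
    return records_to_frame(recs)


class TestComputeRbf:
    def test_elementwise_ratio(self):
        df = compute_rbf(_frame({("m1", "P4"): [2e-8, 4e-8, 3e-8]}))
        assert list(df.sort_values("week")["rbf"]) == pytest.approx([1.0, 2.0, 1.5])

    def test_constant_series_is_unity(self):
        df = compute_rbf(_frame({("m1", "P4"): [2e-8] * 5}))
        assert np.allclose(df["rbf"], 1.0)

    def test_missing_baseline_drops_site(self, caplog):
        recs = [_rec("m1", 1, "P4", 2e-8), _rec("m2", 0, "P4", 1e-8), _rec("m2", 1, "P4", 2e-8)]
        df = compute_rbf(records_to_frame(recs))
        assert set(df["mouse"]) == {"m2"}

    def test_bad_baseline_raises_naming_record(self):
        frame = records_to_frame([_rec("m1", 0, "P4", 1e-8), _rec("m1", 1, "P4", 2e-8)])
        frame.loc[frame["week"] == 0, "bfi"] = -1.0
        with pytest.raises(DataError, match="m1"):
            compute_rbf(frame)

    def test_duplicate_records_rejected(self):
        with pytest.raises(DataError):
            records_to_frame([_rec("m1", 0, "P4", 1e-8), _rec("m1", 0, "P4", 2e-8)])


class TestComputeDeltaRbf:
    def _rbf(self, graft, contra):
        recs = []
        for week, (g, c) in enumerate(zip([1.0] + graft, [1.0] + contra)):
            recs.append(_rec("m1", week, "P4", g * 1e-8))
            recs.append(_rec("m1", week, "P7", c * 1e-8))
        return compute_rbf(records_to_frame(recs))

    def test_equal_legs_give_zero(self):
        delta = compute_delta_rbf(self._rbf([1.5], [1.5]))
        assert delta[delta.week == 1]["delta_rbf"].iloc[0] == pytest.approx(0.0)

    def test_printed_operands(self):
        # graft 1.99 vs contralateral 1.47 -> 0.52
        delta = compute_delta_rbf(self._rbf([1.99], [1.47]))
        assert delta[delta.week == 1]["delta_rbf"].iloc[0] == pytest.approx(0.52)

    def test_sign_convention(self):
        delta = compute_delta_rbf(self._rbf([1.0], [1.2]))
        assert delta[delta.week == 1]["delta_rbf"].iloc[0] == pytest.approx(-0.2)

    def test_antisymmetry_under_leg_swap(self):
        d1 = compute_delta_rbf(self._rbf([1.8, 1.3], [1.2, 1.1]))
        d2 = compute_delta_rbf(self._rbf([1.2, 1.1], [1.8, 1.3]))
        assert np.allclose(d1.sort_values("week")["delta_rbf"].to_numpy(),
                           -d2.sort_values("week")["delta_rbf"].to_numpy())

    def test_missing_contralateral_propagates(self):
        recs = [_rec("m1", 0, "P4", 1e-8), _rec("m1", 1, "P4", 2e-8)]
        delta = compute_delta_rbf(compute_rbf(records_to_frame(recs)))
        assert delta.empty


class TestGroupSummary:
    def _table(self, values, group="autograft"):
        return pd.DataFrame(
            dict(group=group, week=1, position="P4", separation_mm=5.0,
                 mouse=[f"m{i}" for i in range(len(values))], rbf=values)
        )

    def test_mean_and_sem(self):
        out = group_summary(self._table([1.0, 2.0, 3.0]))
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["sem"].iloc[0] == pytest.approx(1.0 / np.sqrt(3))
        assert out["n"].iloc[0] == 3

    def test_single_mouse_sem_missing(self):
        out = group_summary(self._table([1.4]))
        assert out["mean"].iloc[0] == pytest.approx(1.4)
        assert np.isnan(out["sem"].iloc[0])

    def test_equal_values_zero_sem(self):
        assert group_summary(self._table([1.2, 1.2, 1.2]))["sem"].iloc[0] == 0.0


class TestStudentTTest:
    def test_identical_samples(self):
        res = student_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0 and not res.significant

    def test_separated_samples_highly_significant(self):
        res = student_t_test([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        assert res.p < 0.001 and res.significant
        assert res.df == 4

    def test_matches_closed_form_pooled_t(self):
        """Cross-check against the textbook pooled-variance formula."""
        rng = np.random.default_rng(1)
        a, b = rng.normal(1.0, 0.2, 7), rng.normal(1.2, 0.2, 10)
        res = student_t_test(a, b)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p = 2 * sps.t.sf(abs(t), a.size + b.size - 2)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning):
            res = student_t_test([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.significant

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1.0, 2.0])


class TestElevationDuration:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([1.8, 1.9, 1.2, 1.1], 2),
            ([1.0, 1.1, 1.2], 0),
            ([1.25, 1.4], 0),            # strict inequality at the threshold
            ([1.3, 1.2, 1.4], 1),        # later excursion does not extend the run
            ([1.5] * 9, 9),
        ],
    )
    def test_definition(self, series, expected):
        assert elevation_duration(series) == expected

    def test_requires_weeks_from_one(self):
        with pytest.raises(DataError):
            elevation_duration(pd.Series([1.5, 1.4], index=[2, 3]))
        with pytest.raises(DataError):
            elevation_duration(pd.Series([1.5, 1.4], index=[1, 3]))


class TestWeeklyComparisons:
    def _cohort_frames(self, shift=0.0, n_a=4, n_b=4):
        rng = np.random.default_rng(0)
        recs = []
        for group, n, off in [("autograft", n_a, 0.0), ("allograft", n_b, shift)]:
            for i in range(n):
                m = f"{group[:4]}{i}"
                for pos in ("P4", "P7"):
                    base = 1e-8 * rng.lognormal(0, 0.1)
                    recs.append(_rec(m, 0, pos, base, group=group))
                    bump = off if pos == "P4" else 0.0
                    recs.append(_rec(m, 1, pos, base * (1.0 + bump + 0.02 * rng.standard_normal()),
                                     group=group))
        rbf = compute_rbf(records_to_frame(recs))
        return rbf, compute_delta_rbf(rbf)

    def test_null_groups_not_significant(self):
        rbf, delta = self._cohort_frames(shift=0.0)
        tests = weekly_comparisons(rbf, delta)
        group_tests = tests[tests.comparison != "graft_vs_contralateral"]
        assert not group_tests["significant"].any()

    def test_large_group_difference_flagged(self):
        rbf, delta = self._cohort_frames(shift=1.0)
        tests = weekly_comparisons(rbf, delta)
        row = tests[(tests.comparison == "group_delta_rbf") & (tests.position == "P4")]
        assert row["significant"].all()

    def test_small_cells_skipped(self):
        rbf, delta = self._cohort_frames(n_a=1)
        tests = weekly_comparisons(rbf, delta)
        assert tests[tests.comparison == "group_rbf"].empty

    def test_paired_option_runs(self):
        rbf, delta = self._cohort_frames(shift=0.5)
        tests = weekly_comparisons(rbf, delta, paired_contralateral=True)
        paired = tests[tests.comparison == "graft_vs_contralateral"]
        assert (paired["df"] == 3).all()  # n-1 for 4 mice
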