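"""Outlier screening, CVs, ICC(A,k) and Bland-Altman agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vibropsych as vp
from vibropsych._exceptions import InsufficientDataError
from conftest import make_tidy


def anova_icc_oracle(a: np.ndarray) -> float:
    """Brute-force two-way ANOVA ICC(A,k) via explicit cell sums."""
    n, k = a.shape
    grand = sum(a[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = sum(k * (sum(a[i, :]) / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (sum(a[:, j]) / n - grand) ** 2 for j in range(k))
    ss_tot = sum((a[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)


class TestMadOutliers:
    def test_flags_single_gross_outlier(self):
        mask = vp.mad_outliers([2, 4, 6, 8, 100])
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_vector_flags_nothing(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            assert not vp.mad_outliers([5.0] * 6).any()

    def test_needs_three_observations(self):
        with pytest.raises(InsufficientDataError):
            vp.mad_outliers([1.0, 2.0])

    @settings(deadline=None, max_examples=40)
    @given(
        xs=st.lists(st.integers(-10_000, 10_000), min_size=4, max_size=20),
        a=st.floats(0.1, 50), b=st.floats(-100, 100),
    )
    def test_affine_invariance(self, xs, a, b):
        # well-scaled values so the transform is exact in float64
        x = np.asarray(xs, dtype=float) / 8.0
        if np.median(np.abs(x - np.median(x))) == 0:
            return
        assert (vp.mad_outliers(a * x + b) == vp.mad_outliers(x)).all()


class TestCVs:
    def test_between_zero_for_constant(self):
        assert vp.cv_between([10, 10, 10]) == 0.0

    def test_between_example(self):
        # SD of {8, 12} is sqrt(8), mean 10
        assert vp.cv_between([8, 12]) == pytest.approx(100 * np.sqrt(8) / 10)

    def test_between_scale_invariance(self):
        x = [3.0, 5.0, 9.0]
        assert vp.cv_between([7 * v for v in x]) == pytest.approx(vp.cv_between(x))

    def test_within_mixed_rows(self):
        m = np.array([[10, 10, 10], [10, 20, 30.0]])
        # per-row CVs: 0% and 100*10/20 = 50%
        assert vp.cv_within(m) == pytest.approx(25.0)

    def test_within_column_permutation_invariance(self):
        m = np.array([[1, 2, 3], [4, 5, 6.0]])
        assert vp.cv_within(m[:, [2, 0, 1]]) == pytest.approx(vp.cv_within(m))

    def test_within_equals_mean_of_row_cvs(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(1, 10, size=(6, 4))
        rows = [vp.cv_between(r) for r in m]
        assert vp.cv_within(m) == pytest.approx(np.mean(rows))

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            vp.cv_between([-1.0, 1.0])


class TestICC:
    def test_perfect_agreement(self):
        m = np.array([[1, 1, 1], [2, 2, 2], [5, 5, 5.0]])
        assert vp.icc_avg_absolute(m) == pytest.approx(1.0)

    def test_matches_bruteforce_anova(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 11)
            k = rng.integers(2, 5)
            m = rng.normal(10, 3, (n, k)) + rng.normal(0, 2, (n, 1))
            assert vp.icc_avg_absolute(m) == pytest.approx(anova_icc_oracle(m), abs=1e-10)

    def test_matches_pingouin_icc2k(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        m = rng.normal(10, 3, (8, 3)) + rng.normal(0, 1, (8, 3))
        df = pd.DataFrame(m).reset_index().melt("index", var_name="sess", value_name="v")
        icc = pg.intraclass_corr(df, targets="index", raters="sess", ratings="v")
        ref = float(icc.loc[icc["Type"] == "ICC(A,k)", "ICC"].iloc[0])
        assert vp.icc_avg_absolute(m) == pytest.approx(ref, abs=1e-10)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(7)
        m = rng.normal(5, 2, (10, 3)) + rng.normal(0, 1, (10, 1))
        base = vp.icc_avg_absolute(m)
        assert vp.icc_avg_absolute(m + 100) == pytest.approx(base)
        assert vp.icc_avg_absolute(3.5 * m) == pytest.approx(base)

    def test_session_bias_lowers_absolute_agreement(self):
        rng = np.random.default_rng(8)
        m = rng.normal(10, 3, (12, 3)) + rng.normal(0, 0.5, (12, 3))
        shifted = m + np.array([0.0, 4.0, -4.0])
        assert vp.icc_avg_absolute(shifted) < vp.icc_avg_absolute(m)

    def test_incomplete_subjects_dropped(self):
        m = np.array([[1, 1, 1], [2, 2, 2], [3, np.nan, 3], [5, 5, 5.0]])
        complete = m[[0, 1, 3]]
        assert vp.icc_avg_absolute(m) == pytest.approx(vp.icc_avg_absolute(complete))

    def test_zero_variance_is_nan(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            assert np.isnan(vp.icc_avg_absolute(np.full((4, 3), 7.0)))

    def test_too_small_rejected(self):
        with pytest.raises(InsufficientDataError):
            vp.icc_avg_absolute(np.array([[1.0, 2.0]]))


class TestBlandAltman:
    def test_identical_pair(self):
        out = vp.bland_altman([10.0], [10.0])
        assert out["mean"].iloc[0] == 10 and out["pct_diff"].iloc[0] == 0

    def test_example_pair(self):
        out = vp.bland_altman([10.0], [20.0])
        assert out["mean"].iloc[0] == pytest.approx(15.0)
        assert out["pct_diff"].iloc[0] == pytest.approx(-66.6667, abs=1e-3)

    def test_antisymmetry(self):
        a = np.array([3.0, 8.0, 12.0])
        b = np.array([4.0, 7.5, 15.0])
        ab = vp.bland_altman(a, b)
        ba = vp.bland_altman(b, a)
        assert np.allclose(ab["pct_diff"], -ba["pct_diff"])
        assert np.allclose(ab["mean"], ba["mean"])

    def test_zero_mean_pair_warns(self):
        with pytest.warns(UserWarning, match="zero mean"):
            out = vp.bland_altman([1.0, -1.0], [2.0, 1.0])
        assert np.isnan(out["pct_diff"].iloc[1])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            vp.bland_altman([1.0], [1.0, 2.0])


class TestReliabilityTable:
    def test_zero_residual_dataset_gives_icc_one(self):
        mat = np.array([[4.0, 4.0, 4.0], [6.0, 6.0, 6.0], [9.0, 9.0, 9.0]])
        table = vp.reliability_table(make_tidy(mat))
        row = table.iloc[0]
        assert row["cv_ws"] == pytest.approx(0.0)
        assert row["icc"] == pytest.approx(1.0)

    def test_row_count_matches_task_measure_pairs(self, tiny_study):
        _, ds = tiny_study
        table = vp.reliability_table(ds.measures)
        pairs = ds.measures[ds.measures["measure"] != "convergence"]
        assert len(table) == pairs.groupby(["task", "measure"]).ngroups == 13

    def test_session_subset_changes_k(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 3, (12, 1)) + rng.normal(0, 0.5, (12, 3))
        shifted = base.copy()
        shifted[:, 2] += 6.0  # bias confined to the Long column
        tidy = make_tidy(shifted)
        # screening disabled so the hand-computed oracle sees the same data
        full = vp.reliability_table(tidy, mad_threshold=float("inf"))
        subset = vp.reliability_table(tidy, icc_sessions=("Short1", "Short2"),
                                      mad_threshold=float("inf"))
        assert subset.iloc[0]["icc"] > full.iloc[0]["icc"]
        expected = vp.icc_avg_absolute(shifted[:, :2])
        assert subset.iloc[0]["icc_raw"] == pytest.approx(expected)

    def test_outlier_removal_drops_subject_from_icc(self):
        mat = np.array([[4.0, 4.0, 4.0], [6.0, 6.0, 6.0], [9.0, 9.0, 9.0],
                        [5.0, 400.0, 5.0]])
        table = vp.reliability_table(make_tidy(mat))
        row = table.iloc[0]
        assert row["n_removed"] == 1
        assert row["n_subjects_icc"] == 3
        assert row["icc"] == pytest.approx(1.0)

    def test_model_results_surface(self):
        mat = np.abs(np.random.default_rng(0).normal(10, 3, (8, 3)))
        res = vp.ReliabilityAnalysis(make_tidy(mat)).fit()
        assert "ICC" in res.summary()
        ba = res.bland_altman("sDT", "threshold", pair=("Short1", "Long"))
        assert set(ba.columns) == {"subject_id", "mean", "pct_diff"}
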