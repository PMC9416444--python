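import numpy as np
import pandas as pd
import pytest

from emats import evaluation
from emats.evaluation import (
    MCD_CONST,
    aggregate,
    mann_whitney,
    mcd,
    pearson,
    vc_matrix_report,
)

# published per-speaker MCD values (dB) of the seven experiment designs
PUBLISHED_MCD = pd.DataFrame(
    {
        "SD": [4.98, 5.47, 6.02, 5.99, 8.96, 7.54, 6.59, 7.14],
        "SI": [7.80, 8.41, 9.04, 8.37, 10.41, 10.66, 8.18, 8.83],
        "SI-P": [7.48, 8.21, 8.66, 8.35, 10.44, 10.05, 8.37, 8.69],
        "SI-VC": [6.63, 6.82, 8.03, 7.87, 9.45, 9.25, 7.95, 8.71],
        "SI-VC-P": [5.79, 6.45, 6.99, 7.19, 9.33, 8.85, 7.55, 8.38],
        "SA-P": [5.26, 5.51, 6.11, 6.14, 8.22, 7.29, 6.87, 7.11],
        "SA-VC-P": [5.08, 5.23, 6.20, 6.33, 8.23, 7.21, 6.85, 7.03],
    },
    index=["F01", "F02", "F03", "F04", "M01", "M02", "M03", "M04"],
)


class TestMcd:
    def test_identical_is_zero(self):
        x = np.random.default_rng(0).normal(size=(9, 13))
        assert mcd(x, x) == 0.0

    def test_single_coefficient_unit_difference(self):
        ref = np.zeros((1, 13))
        gen = np.zeros((1, 13))
        gen[0, 4] = 1.0
        assert mcd(ref, gen) == pytest.approx(MCD_CONST * np.sqrt(2.0), abs=1e-12)

    def test_all_coefficients_unit_difference(self):
        ref = np.zeros((1, 13))
        gen = np.ones((1, 13))
        assert mcd(ref, gen) == pytest.approx(MCD_CONST * np.sqrt(26.0), abs=1e-12)

    def test_symmetry_and_linearity_in_difference_scale(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 13))
        d = rng.normal(size=(6, 13))
        assert mcd(a, a + d) == pytest.approx(mcd(a + d, a))
        assert mcd(a, a + 3 * d) == pytest.approx(3 * mcd(a, a + d))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            mcd(np.zeros((3, 13)), np.zeros((4, 13)))
        with pytest.raises(ValueError):
            mcd(np.zeros((3, 12)), np.zeros((3, 12)))


class TestAggregate:
    def test_reproduces_published_mean_and_std_rows(self):
        out = aggregate(PUBLISHED_MCD)
        means = {"SD": 6.59, "SI": 8.96, "SI-P": 8.78, "SI-VC": 8.09,
                 "SI-VC-P": 7.57, "SA-P": 6.56, "SA-VC-P": 6.52}
        stds = {"SD": 1.27, "SI": 1.04, "SI-P": 0.98, "SI-VC": 1.03,
                "SI-VC-P": 1.21, "SA-P": 0.99, "SA-VC-P": 1.05}
        for col, m in means.items():
            assert round(out.loc["Mean", col], 2) == m
        for col, s in stds.items():
            assert round(out.loc["STD", col], 2) == s

    def test_constant_column_std_zero(self):
        df = pd.DataFrame({"A": [2.0, 2.0, 2.0]})
        out = aggregate(df)
        assert out.loc["STD", "A"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame())


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_of_eight(self):
        a = list(range(8))
        b = list(range(100, 108))
        u, p = mann_whitney(a, b)
        assert u == 64
        assert p == pytest.approx(2 / 12870)

    def test_published_adaptive_vs_independent_columns(self):
        u, p = mann_whitney(PUBLISHED_MCD["SA-P"], PUBLISHED_MCD["SI"])
        assert u == 62
        assert p == pytest.approx(8 / 12870, rel=1e-9)
        assert p < 0.001

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=7)
            b = rng.normal(0.5, 1, size=6)
            _, p = mann_whitney(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        assert abs(pearson(rng.normal(size=1000), rng.normal(size=1000))) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# published pairwise voice-conversion MCD matrix (source rows, target columns)
PUBLISHED_VC = pd.DataFrame(
    [
        [np.nan, 6.32, 7.23, 6.71, 7.08, 6.86, 7.91, 8.69],
        [9.26, np.nan, 6.75, 7.60, 7.66, 7.55, 8.46, 9.15],
        [7.43, 7.01, np.nan, 7.02, 6.85, 7.04, 7.83, 8.77],
        [7.15, 6.24, 7.45, np.nan, 7.24, 7.66, 8.02, 9.25],
        [6.64, 6.40, 6.32, 7.38, np.nan, 7.03, 7.68, 8.52],
        [6.47, 6.64, 6.50, 7.56, 6.78, np.nan, 7.77, 8.70],
        [6.97, 6.63, 6.65, 7.51, 6.70, 7.05, np.nan, 8.50],
        [7.01, 6.32, 7.05, 7.42, 7.96, 7.17, 7.71, np.nan],
    ],
    index=["F01", "F02", "F03", "F04", "M01", "M02", "M03", "M04"],
    columns=["F01", "F02", "F03", "F04", "M01", "M02", "M03", "M04"],
)


class TestVcMatrix:
    def test_published_f02_column_average(self):
        out = vc_matrix_report(PUBLISHED_VC)
        assert round(out.loc["Average", "F02"], 2) == 6.51

    def test_all_equal_matrix(self):
        m = pd.DataFrame(np.full((3, 3), 5.0), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(m.values, np.nan)
        out = vc_matrix_report(m)
        assert (out.loc["Average"] == 5.0).all()

    def test_filled_diagonal_rejected(self):
        m = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="diagonal"):
            vc_matrix_report(m)
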