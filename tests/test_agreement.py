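"""ICC forms, Cronbach's alpha, agreement regression, bands, SEM/MDC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planargait.agreement import (MeasurementMatrix, agreement_regression,
                                  agreement_report, anova_mean_squares,
                                  bias_flags, classify, cronbach_alpha,
                                  diff_of_means, format_p, icc, sem_mdc)
from planargait.errors import StatisticsError, ValidationError


def brute_force_icc(x):
    """Independent oracle: explicit-loop ANOVA decomposition.

    Computes the mean squares by summing squared deviations directly and
    forms the three average-measure ICCs from their textbook definitions.
    """
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (np.mean(x[i]) - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (np.mean(x[:, j]) - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    wms = (ss_tot - ss_rows) / (n * (k - 1))
    return {
        "icc1k": (bms - wms) / bms,
        "icc2k": (bms - ems) / (bms + (jms - ems) / n),
        "icc3k": (bms - ems) / bms,
    }


def random_matrix(rng, n=None, k=None):
    n = n or int(rng.integers(5, 11))
    k = k or int(rng.integers(2, 4))
    return (rng.normal(100, 15, (n, 1))
            + rng.normal(0, 4, (1, k))
            + rng.normal(0, 5, (n, k)))


class TestICC:
    def test_identical_columns_perfect(self):
        m = MeasurementMatrix(np.column_stack([np.arange(1.0, 6.0)] * 2))
        for form in ("icc1k", "icc2k", "icc3k"):
            assert icc(m, form).estimate == 1.0

    def test_constant_offset_penalizes_absolute_agreement(self):
        rows = np.arange(1.0, 6.0)
        m = MeasurementMatrix(np.column_stack([rows, rows + 1.0]))
        res3 = icc(m, "icc3k")
        res2 = icc(m, "icc2k")
        assert res3.estimate == pytest.approx(1.0)
        assert res2.estimate < 1.0
        # oracle values from the explicit ANOVA decomposition
        oracle = brute_force_icc(m.values)
        assert res2.estimate == pytest.approx(oracle["icc2k"], abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            m = MeasurementMatrix(random_matrix(rng))
            oracle = brute_force_icc(m.values)
            for form, want in oracle.items():
                assert icc(m, form).estimate == pytest.approx(want,
                                                              abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        """Independent library cross-check of estimates, CIs and p."""
        pg = pytest.importorskip("pingouin")
        label = {"icc1": "ICC(1,1)", "icc2": "ICC(A,1)", "icc3": "ICC(C,1)",
                 "icc1k": "ICC(1,k)", "icc2k": "ICC(A,k)",
                 "icc3k": "ICC(C,k)"}
        for _ in range(5):
            x = random_matrix(rng)
            n, k = x.shape
            m = MeasurementMatrix(x)
            df = pd.DataFrame({"targets": np.repeat(np.arange(n), k),
                               "raters": np.tile(np.arange(k), n),
                               "ratings": x.ravel()})
            ref = pg.intraclass_corr(df, "targets", "raters",
                                     "ratings").set_index("Type")
            for form, typ in label.items():
                mine = icc(m, form)
                want = ref.loc[typ]
                assert mine.estimate == pytest.approx(want["ICC"], abs=1e-10)
                assert mine.p == pytest.approx(want["pval"], rel=1e-6)
                # pingouin rounds its CI to 2 decimals
                assert mine.ci_low == pytest.approx(want["CI95"][0],
                                                    abs=6e-3)
                assert mine.ci_high == pytest.approx(want["CI95"][1],
                                                    abs=6e-3)

    def test_ci_contains_estimate(self, rng):
        for _ in range(20):
            m = MeasurementMatrix(random_matrix(rng))
            for form in ("icc1", "icc1k", "icc2", "icc2k", "icc3", "icc3k"):
                r = icc(m, form)
                assert r.ci_low <= r.estimate <= r.ci_high
                assert r.estimate <= 1.0

    def test_zero_between_row_variance_rejected(self):
        m = MeasurementMatrix(np.array([[5.0, 7.0], [5.0, 7.0],
                                        [5.0, 7.0]]))
        with pytest.raises(StatisticsError, match="between-row"):
            icc(m, "icc2k")

    def test_adding_column_constant(self, rng):
        """A column offset leaves consistency forms alone but lowers the
        absolute-agreement and one-way forms."""
        x = random_matrix(rng, n=30, k=2)
        a = MeasurementMatrix(x)
        shifted = x.copy()
        shifted[:, 1] += 25.0
        b = MeasurementMatrix(shifted)
        assert icc(b, "icc3k").estimate == pytest.approx(
            icc(a, "icc3k").estimate, abs=1e-12)
        assert cronbach_alpha(b) == pytest.approx(cronbach_alpha(a),
                                                  abs=1e-12)
        assert icc(b, "icc2k").estimate < icc(a, "icc2k").estimate
        assert icc(b, "icc1k").estimate < icc(a, "icc1k").estimate

    def test_convergence_to_analytic_value(self):
        """Variance components sigma_b^2=100, sigma_e^2=25 give
        ICC(2,1) = 100/125 = 0.8; the estimate at n=500 lands nearby."""
        rng = np.random.default_rng(77)
        tau = rng.normal(0, 10, 500)
        x = tau[:, None] + rng.normal(0, 5, (500, 2))
        est = icc(MeasurementMatrix(x), "icc2").estimate
        assert est == pytest.approx(0.8, abs=0.05)


class TestCronbachAlpha:
    def test_identical_columns(self):
        m = MeasurementMatrix(np.column_stack([np.arange(5.0)] * 3))
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        m = MeasurementMatrix(rng.normal(0, 1, (10000, 2)))
        assert abs(cronbach_alpha(m)) < 0.05

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_identical_to_icc3k(self, seed):
        """alpha == ICC(3,k) to 1e-12 on arbitrary matrices."""
        rng = np.random.default_rng(seed)
        m = MeasurementMatrix(random_matrix(rng))
        assert abs(cronbach_alpha(m) - icc(m, "icc3k").estimate) < 1e-12

    def test_zero_variance_rejected(self):
        m = MeasurementMatrix(np.array([[1.0, -1.0], [2.0, -2.0],
                                        [3.0, -3.0]]))
        with pytest.raises(StatisticsError, match="alpha"):
            cronbach_alpha(m)


class TestRegression:
    def test_identity_line(self):
        x = np.arange(10.0)
        r = agreement_regression(x, x)
        assert r.B == pytest.approx(1.0)
        assert r.constant == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == pytest.approx(1.0)

    def test_exact_affine_line_zero_ci_width(self):
        x = np.arange(10.0)
        r = agreement_regression(x, 2.0 * x + 3.0)
        assert r.B == pytest.approx(2.0)
        assert r.constant == pytest.approx(3.0)
        assert r.b_ci_high - r.b_ci_low == pytest.approx(0.0, abs=1e-9)

    def test_normal_equations_oracle(self, rng):
        """Closed-form least squares computed independently."""
        for _ in range(10):
            x = rng.uniform(0, 100, 15)
            y = 1.3 * x - 7.0 + rng.normal(0, 4, 15)
            r = agreement_regression(x, y)
            sx, sy = x.sum(), y.sum()
            n = len(x)
            b = (n * (x * y).sum() - sx * sy) / (n * (x * x).sum() - sx**2)
            c = (sy - b * sx) / n
            assert r.B == pytest.approx(b, abs=1e-10)
            assert r.constant == pytest.approx(c, abs=1e-10)
            assert r.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2,
                                         abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(StatisticsError, match="constant x"):
            agreement_regression(np.full(5, 3.0), np.arange(5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(StatisticsError, match="n >= 3"):
            agreement_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestBiasFlags:
    def test_slope_ci_straddling_one_is_unbiased(self):
        """A slope CI like 0.918..1.002 contains 1: no proportional bias."""
        x = np.arange(12.0)
        r = agreement_regression(x, x)
        r = r.__class__(**{**r.__dict__, "b_ci_low": 0.918,
                           "b_ci_high": 1.002})
        assert bias_flags(r)["proportional"] is False

    def test_positive_constant_ci_is_fixed_bias(self):
        x = np.arange(12.0)
        r = agreement_regression(x, x + 5.0)
        flags = bias_flags(r)
        assert flags["fixed"] is True
        assert flags["proportional"] is False

    def test_symmetric_noise_flags_mostly_clear(self):
        rng = np.random.default_rng(11)
        clear = 0
        trials = 200
        for _ in range(trials):
            x = rng.uniform(0, 100, 50)
            y = x + rng.normal(0, 5, 50)
            f = bias_flags(agreement_regression(x, y))
            clear += (not f["fixed"]) and (not f["proportional"])
        # each flag fires ~5% of the time under H0
        assert clear / trials > 0.85


class TestClassifyAndFriends:
    @pytest.mark.parametrize("value,scale,label", [
        (0.3, "icc", "poor"),
        (0.6, "icc", "moderate"),
        (0.8, "icc", "good"),
        (0.92, "icc", "excellent"),
        (0.9, "icc", "excellent"),   # boundary goes to the upper band
        (0.5, "icc", "moderate"),
        (0.10, "r2", "small"),
        (0.3, "r2", "medium"),
        (0.7, "r2", "large"),
        (0.3, "r", "small"),
        (0.5, "r", "medium"),
        (0.75, "r", "large"),
        (0.2, "r_alt", "small"),
        (0.35, "r_alt", "medium"),
        (0.72, "alpha", "acceptable"),
        (0.69, "alpha", "unacceptable"),
    ])
    def test_bands(self, value, scale, label):
        assert classify(value, scale) == label

    def test_unknown_scale_rejected(self):
        with pytest.raises(StatisticsError, match="scale"):
            classify(0.5, "zscore")

    @pytest.mark.parametrize("a,b,want", [
        (714.4, 694.8, 19.6),
        (1699.9, 1662.5, 37.4),
        (5.0, 5.0, 0.0),
    ])
    def test_diff_of_means(self, a, b, want):
        assert diff_of_means(a, b) == pytest.approx(want)

    @pytest.mark.parametrize("sd,icc_v,sem,mdc", [
        (0.05, 1.0, 0.0, 0.0),
        (0.05, 0.96, 0.01, 0.0277),
        (0.05, 0.0, 0.05, 0.1386),
    ])
    def test_sem_mdc_formula(self, sd, icc_v, sem, mdc):
        out = sem_mdc(sd, icc_v)
        assert out["SEM"] == pytest.approx(sem, abs=1e-4)
        assert out["MDC95"] == pytest.approx(mdc, abs=1e-4)

    def test_sem_mdc_domain(self):
        with pytest.raises(StatisticsError):
            sem_mdc(0.05, 1.2)

    def test_format_p(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.0314) == "0.031"


class TestReport:
    def test_full_battery_populated(self, rng):
        x = rng.normal(700, 70, 20)
        m = MeasurementMatrix(np.column_stack([x + rng.normal(0, 10, 20),
                                               x + rng.normal(0, 10, 20)]),
                              measurement_name="step_length", units="mm")
        rep = agreement_report(m)
        assert set(rep.icc) == {"icc1k", "icc2k", "icc3k"}
        assert rep.icc["icc3k"].estimate == pytest.approx(rep.alpha,
                                                          abs=1e-12)
        assert rep.regression is not None
        assert rep.bands["icc"] in ("poor", "moderate", "good", "excellent")
        row = rep.to_row()
        assert "B" in row and "icc2k" in row and "MDC95" in row

    def test_listwise_deletion(self):
        df = pd.DataFrame({"cam": [1.0, 2.0, np.nan, 4.0],
                           "ref": [1.1, 2.1, 3.0, 3.9]})
        m = MeasurementMatrix.from_dataframe(df)
        assert m.n == 3

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            MeasurementMatrix(np.array([[1.0, 2.0]]))  # n < 2
        with pytest.raises(ValidationError):
            MeasurementMatrix(np.array([[1.0], [2.0]]))  # k < 2
        with pytest.raises(ValidationError, match="non-finite"):
            MeasurementMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
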