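"""Agreement statistics: error extraction, quartiles, ICC, Bland-Altman, CDFs."""

import numpy as np
import pytest

from kneemorph.agreement import (
    ErrorSample,
    bland_altman,
    icc,
    landmark_errors,
    measurement_errors,
    outliers_per_subject,
    quartile_summary,
    success_rates,
)
from kneemorph.landmarks import LandmarkSet
from kneemorph.morphometry import MeasurementResult


def icc_a1_oracle(table: np.ndarray) -> float:
    """Independent absolute-agreement single-rater ICC via explicit ANOVA loops."""
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = sum(k * (table[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((table[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def _lset(subject, observer, points: dict):
    return LandmarkSet(subject, observer, {k: np.asarray(v, float) for k, v in points.items()})


class TestLandmarkErrors:
    def test_identical_observations_zero_error(self):
        sets = [_lset("s", f"obs{i}", {"A": [1, 2, 3]}) for i in range(3)]
        for s in landmark_errors(sets, "INTER"):
            assert s.error == 0.0

    def test_two_observer_symmetric_errors(self):
        sets = [_lset("s", "obs1", {"A": [0, 0, 0]}),
                _lset("s", "obs2", {"A": [2, 0, 0]})]
        errs = [s.error for s in landmark_errors(sets, "INTER")]
        assert errs == [1.0, 1.0]

    def test_random_sets_match_direct_norms(self):
        rng = np.random.default_rng(7)
        pts = {f"obs{i}": rng.normal(0, 5, 3) for i in range(3)}
        sets = [_lset("s", o, {"A": p}) for o, p in pts.items()]
        gt = np.mean(list(pts.values()), axis=0)
        got = {s.observer: s.error for s in landmark_errors(sets, "INTER")}
        for o, p in pts.items():
            assert got[o] == pytest.approx(np.linalg.norm(p - gt), abs=1e-12)

    def test_intra_requires_repeats(self):
        sets = [_lset("s", "obs1", {"A": [0, 0, 0]}),
                _lset("s", "obs2", {"A": [1, 0, 0]})]
        with pytest.raises(ValueError):
            landmark_errors(sets, "INTRA")

    def test_method_mode_uses_expert_mean_with_preaveraging(self):
        sets = [
            _lset("s", "obs1", {"A": [0, 0, 0]}),
            _lset("s", "obs1", {"A": [2, 0, 0]}),  # obs1 repeats average to (1,0,0)
            _lset("s", "obs2", {"A": [3, 0, 0]}),
            _lset("s", "AUTO", {"A": [4, 0, 0]}),
        ]
        (sample,) = landmark_errors(sets, "METHOD")
        assert sample.error == pytest.approx(2.0)  # expert mean at (2,0,0)


class TestMeasurementErrors:
    def _meas(self, subject, observer, value):
        return MeasurementResult("AP MFC", subject, observer, value)

    def test_identical_values_zero(self):
        ms = [self._meas("s", f"obs{i}", 10.0) for i in range(3)]
        assert all(s.error == 0 for s in measurement_errors(ms, "INTER"))

    def test_three_observers_example(self):
        ms = [self._meas("s", "obs1", 10.0), self._meas("s", "obs2", 12.0),
              self._meas("s", "obs3", 14.0)]
        errs = sorted(s.error for s in measurement_errors(ms, "INTER"))
        assert errs == [0.0, 2.0, 2.0]

    def test_method_difference(self):
        ms = [self._meas("s", "obs1", 11.0), self._meas("s", "obs2", 12.0),
              self._meas("s", "AUTO", 10.0)]
        (sample,) = measurement_errors(ms, "METHOD")
        assert sample.error == pytest.approx(1.5)


class TestQuartileSummary:
    def _samples(self, values):
        return [ErrorSample("s", "A", "INTER", float(v)) for v in values]

    def test_linear_interpolation_convention(self):
        s = quartile_summary(self._samples([1, 2, 3, 4, 5]))
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
        assert s.iqr == 2.0
        assert s.outlier_low == 2.0 - 3.0 and s.outlier_high == 4.0 + 3.0
        assert not s.outlier_ids

    def test_constant_samples(self):
        s = quartile_summary(self._samples([2, 2, 2, 2]))
        assert s.iqr == 0.0 and s.sd == 0.0 and not s.outlier_ids

    def test_gross_error_flagged(self):
        s = quartile_summary(self._samples([1, 1, 1, 1, 100]))
        assert [o.error for o in s.outlier_ids] == [100.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quartile_summary([])


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.array([1.0, 5.0, 9.0, 2.0])
        r = icc(np.c_[col, col, col])
        assert r.value == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_penalised(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 0.1, 20)
        r = icc(np.c_[col, col + 100.0])
        assert r.value < 0.01

    def test_fixed_table_matches_oracle_exactly(self):
        rng = np.random.default_rng(42)
        table = rng.normal(50, 5, size=(6, 3)) + rng.normal(0, 1, size=(6, 1))
        r = icc(table)
        assert r.value == pytest.approx(icc_a1_oracle(table), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        table = rng.normal(30, 4, size=(8, 3))
        long = pd.DataFrame([
            {"subject": i, "rater": j, "score": table[i, j]}
            for i in range(8) for j in range(3)])
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score")
        icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(table).value == pytest.approx(icc2, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        table = rng.normal(0, 1, size=(10, 4))
        base = icc(table).value
        assert icc(table + 17.3).value == pytest.approx(base, abs=1e-10)
        assert icc(table * 4.2).value == pytest.approx(base, abs=1e-10)

    def test_mixed_and_random_point_estimates_coincide(self):
        rng = np.random.default_rng(11)
        table = rng.normal(0, 1, size=(7, 3))
        assert icc(table, "TWO_WAY_MIXED").value == icc(table, "TWO_WAY_RANDOM").value

    def test_degenerate_table_flagged(self):
        r = icc(np.full((4, 3), 2.5))
        assert r.value == 1.0 and r.degenerate

    def test_variance_component_recovery(self):
        """ICC converges to sigma_s^2/(sigma_s^2+sigma_r^2+sigma_e^2)."""
        rng = np.random.default_rng(123)
        n, k = 200, 3
        sig_s, sig_r, sig_e = 2.0, 0.8, 1.0
        subj = rng.normal(0, sig_s, (n, 1))
        rater = rng.normal(0, sig_r, (1, k))
        table = subj + rater + rng.normal(0, sig_e, (n, k))
        expected = sig_s ** 2 / (sig_s ** 2 + sig_r ** 2 + sig_e ** 2)
        assert icc(table).value == pytest.approx(expected, abs=0.05)

    def test_shape_contracts(self):
        with pytest.raises(ValueError):
            icc(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            icc(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestBlandAltman:
    def test_identical_methods(self):
        v = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(v, v)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self):
        v = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(v, v + 1.0)
        assert ba.bias == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(1.0) and ba.loa_high == pytest.approx(1.0)

    def test_random_pairs_match_direct_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(50, 5, 20), rng.normal(50, 5, 20)
        ba = bland_altman(a, b)
        diff = b - a
        assert ba.bias == pytest.approx(diff.mean())
        assert ba.loa_high == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1))
        assert ba.loa_low <= ba.bias <= ba.loa_high

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestSuccessRates:
    def _samples(self, values):
        return [ErrorSample("s", "A", "METHOD", float(v)) for v in values]

    def test_worked_example(self):
        curve = success_rates(self._samples([1, 2, 3, 5]), [4.0])
        assert curve.rates[0] == pytest.approx(0.75)

    def test_bounds(self):
        s = self._samples([1, 2, 3])
        assert success_rates(s, [0.5]).rates[0] == 0.0
        assert success_rates(s, [10.0]).rates[0] == 1.0

    def test_equals_empirical_cdf_and_monotone(self):
        rng = np.random.default_rng(8)
        errors = rng.exponential(1.5, 100)
        grid = np.linspace(0.1, 8, 64)
        curve = success_rates(self._samples(errors), grid)
        cdf = [(errors <= t).mean() for t in grid]
        np.testing.assert_allclose(curve.rates, cdf)
        assert np.all(np.diff(curve.rates) >= 0)


class TestPropertyInvariants:
    """Distribution-free invariants of the descriptive statistics."""

    from hypothesis import given, settings, strategies as st

    errors = st.lists(st.floats(min_value=0.0, max_value=50.0,
                                allow_nan=False), min_size=1, max_size=60)

    @given(values=errors)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_quartile_identities_hold(self, values):
        s = quartile_summary([ErrorSample("s", "A", "INTER", v) for v in values])
        assert s.q1 <= s.median <= s.q3
        assert s.iqr == pytest.approx(s.q3 - s.q1)
        assert s.outlier_low == pytest.approx(s.q1 - 1.5 * s.iqr)
        assert s.outlier_high == pytest.approx(s.q3 + 1.5 * s.iqr)
        for o in s.outlier_ids:
            assert o.error < s.outlier_low or o.error > s.outlier_high

    @given(values=errors)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_success_curve_is_monotone_cdf(self, values):
        samples = [ErrorSample("s", "A", "INTER", v) for v in values]
        grid = np.linspace(0.1, 60.0, 37)
        curve = success_rates(samples, grid)
        assert np.all(np.diff(curve.rates) >= 0)
        assert curve.rates[-1] == 1.0  # grid end beyond the largest error


class TestOutliersPerSubject:
    def test_no_outliers(self):
        samples = [ErrorSample(f"s{i}", "A", "INTER", 1.0 + 0.01 * i) for i in range(8)]
        counts = outliers_per_subject(samples)
        assert all(v == 0 for v in counts.values())

    def test_planted_gross_errors_located(self):
        samples = [ErrorSample(f"s{i}", "A", "INTER", 1.0) for i in range(10)]
        samples += [ErrorSample(f"s{i}", "B", "INTER", 0.5) for i in range(10)]
        samples[3] = ErrorSample("s3", "A", "INTER", 50.0)  # plant
        samples[15] = ErrorSample("s5", "B", "INTER", 40.0)  # plant
        counts = outliers_per_subject(samples)
        assert counts[("s3", "INTER")] == 1
        assert counts[("s5", "INTER")] == 1
        assert counts[("s0", "INTER")] == 0
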