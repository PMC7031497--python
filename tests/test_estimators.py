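import math

import numpy as np
import pytest

from traitcv.estimators import (
    CorrectionDomainError,
    InsufficientSampleError,
    NonPositiveMeanError,
    TraitSample,
    batch_estimates,
    compute_moments,
    cv1,
    cv2,
    cv3,
    cv4,
    cv_composites,
    estimate_all,
    _cv4_parts,
)


def direct_moments(values):
    """Independent direct-summation oracle (Fisher-adjusted conventions)."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    sd = math.sqrt(m2 * n / (n - 1))
    skew = (m3 / m2**1.5) * math.sqrt(n * (n - 1)) / (n - 2)
    kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * (m4 / m2**2 - 3) + 6)
    return mean, sd, skew, kurt


class TestTraitSample:
    def test_n_too_small(self):
        with pytest.raises(InsufficientSampleError):
            TraitSample([1.0])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            TraitSample([1.0, np.nan, 2.0])

    def test_n_property(self):
        assert TraitSample([1, 2, 3]).n == 3


class TestMoments:
    def test_symmetric_sample(self):
        m = compute_moments([1, 2, 3])
        assert m.mean == pytest.approx(2.0)
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_degenerate(self):
        m = compute_moments([4.2, 4.2, 4.2, 4.2])
        assert m.sd == 0.0
        assert m.degenerate
        assert m.skewness == 0.0 and m.kurtosis == 0.0

    def test_against_direct_summation(self):
        values = [2, 4, 4, 4, 5, 5, 7, 9]
        m = compute_moments(values)
        mean, sd, g1, g2 = direct_moments(values)
        assert m.mean == pytest.approx(5.0)
        assert m.sd == pytest.approx(sd)  # n-1 denominator
        assert m.sd == pytest.approx(math.sqrt(32 / 7))
        assert m.skewness == pytest.approx(g1)
        assert m.kurtosis == pytest.approx(g2)

    def test_against_pandas_conventions(self, gamma_sample):
        # independent library oracle for the adjusted sample statistics
        import pandas as pd

        s = pd.Series(gamma_sample)
        m = compute_moments(gamma_sample)
        assert m.skewness == pytest.approx(float(s.skew()), rel=1e-12)
        assert m.kurtosis == pytest.approx(float(s.kurt()), rel=1e-12)

    def test_raw_kurtosis_offset(self, gamma_sample):
        m = compute_moments(gamma_sample)
        assert m.raw_kurtosis == pytest.approx(m.kurtosis + 3.0)

    def test_kurtosis_nan_below_four(self):
        assert math.isnan(compute_moments([1.0, 2.0, 4.0]).kurtosis)

    def test_shape_moments_scale_invariant(self, gamma_sample):
        a = compute_moments(gamma_sample)
        b = compute_moments(3.7 * gamma_sample)
        assert b.skewness == pytest.approx(a.skewness, rel=1e-12)
        assert b.kurtosis == pytest.approx(a.kurtosis, rel=1e-12)

    def test_insufficient(self):
        with pytest.raises(InsufficientSampleError):
            compute_moments([1.0])


class TestCV1:
    def test_constant_sample(self):
        assert cv1([5, 5, 5, 5]) == 0.0

    def test_direct_arithmetic(self):
        # sample sd of 1..5 is sqrt(2.5), mean is 3
        assert cv1([1, 2, 3, 4, 5]) == pytest.approx(math.sqrt(2.5) / 3)

    def test_scale_invariance(self, gamma_sample):
        assert cv1(10 * gamma_sample) == pytest.approx(cv1(gamma_sample),
                                                       rel=1e-12)

    def test_non_positive_mean(self):
        with pytest.raises(NonPositiveMeanError):
            cv1([-1.0, -2.0, -3.0])


class TestCV2:
    def test_zero_propagates(self):
        assert cv2([7, 7, 7]) == 0.0

    def test_direct_substitution(self, gamma_sample):
        # cv2 = cv1 (1 + 1/(4n)) exactly
        n = gamma_sample.size
        assert cv2(gamma_sample) == pytest.approx(
            cv1(gamma_sample) * (1 + 1 / (4 * n)), rel=1e-15)

    def test_known_value(self):
        # a sample engineered to cv1 = 0.5 at n = 25 must give 0.505
        rng = np.random.default_rng(3)
        x = rng.gamma(4, 1, 25)
        x = 1 + (x - x.mean()) / x.std(ddof=1) * 0.5  # mean 1, sd 0.5
        assert cv1(x) == pytest.approx(0.5)
        assert cv2(x) == pytest.approx(0.505)

    def test_correction_vanishes_at_large_n(self, rng):
        x = rng.gamma(4, 1, 200000)
        assert cv2(x) == pytest.approx(cv1(x), rel=1e-4)


class TestCV3:
    def test_zero_propagates(self):
        assert cv3([7, 7, 7, 7]) == 0.0

    def test_symmetric_direct_substitution(self):
        # symmetric sample: g1 = 0, cv3 = cv1 / (1 - 3 cv1^2 / n)
        x = [1, 2, 3, 4, 5, 6, 7]
        c1 = cv1(x)
        assert compute_moments(x).skewness == pytest.approx(0.0, abs=1e-12)
        assert cv3(x) == pytest.approx(c1 / (1 - 3 * c1**2 / 7))

    def test_correction_out_of_domain(self):
        with pytest.raises(CorrectionDomainError, match="bracket"):
            cv3([1.0, 0.001, 0.001, 0.001])

    def test_requires_three(self):
        with pytest.raises(InsufficientSampleError):
            cv3([1.0, 2.0])


class TestCV4:
    def test_zero_propagates(self):
        assert cv4([3, 3, 3, 3]) == 0.0

    def test_direct_substitution_oracle(self):
        # fixed parts cv1=0.4, n=20, g1=1.2, g2=2.0, by hand:
        # 0.4 - 0.0032 + 0.005 + 0.0048 + 0.004 = 0.4106... computed below
        expected = (0.4 - 0.4**3 / 20 + 0.4 / 80
                    + 0.4**2 * 1.2 / 40 + 0.4 * 2.0 / 160)
        got = _cv4_parts(20, np.array(0.4), np.array(1.2), np.array(2.0))
        assert got == pytest.approx(expected, rel=1e-15)

    def test_sample_matches_parts(self, gamma_sample):
        m = compute_moments(gamma_sample)
        c1 = m.sd / m.mean
        expected = _cv4_parts(m.n, np.array(c1), np.array(m.skewness),
                              np.array(m.kurtosis))
        assert cv4(gamma_sample) == pytest.approx(float(expected), rel=1e-14)

    def test_negative_clamped_in_kernel(self):
        # n=5, cv1=2, g1=-4, g2=0: 2 - 1.6 + 0.1 - 1.6 + 0 = -1.1 -> 0
        got = _cv4_parts(5, np.array(2.0), np.array(-4.0), np.array(0.0))
        assert got == 0.0

    def test_requires_four(self):
        with pytest.raises(InsufficientSampleError):
            cv4([1.0, 2.0, 3.0])


class TestComposites:
    def test_arithmetic_means(self, gamma_sample):
        c2, c3, c4 = (cv2(gamma_sample), cv3(gamma_sample), cv4(gamma_sample))
        c5, c6, c7, c8 = cv_composites(gamma_sample)
        assert c5 == pytest.approx(0.5 * (c3 + c4), rel=1e-15)
        assert c6 == pytest.approx(0.5 * (c2 + c4), rel=1e-15)
        assert c7**2 == pytest.approx(c3 * c4, rel=1e-12)
        assert c8**2 == pytest.approx(c2 * c4, rel=1e-12)

    def test_equal_parents(self):
        # symmetric-ish fabricated check on the kernel level
        out = batch_estimates(np.array([[10.0, 12.0, 14.0, 16.0, 18.0]]))
        assert out["cv5"][0] == pytest.approx(
            0.5 * (out["cv3"][0] + out["cv4"][0]))

    def test_bracketing(self, rng):
        for _ in range(50):
            x = rng.gamma(rng.uniform(1, 10), 5.0, size=rng.integers(5, 40))
            e = estimate_all(x)
            assert min(e.cv3, e.cv4) - 1e-12 <= e.cv5 <= max(e.cv3, e.cv4) + 1e-12
            assert min(e.cv2, e.cv4) - 1e-12 <= e.cv6 <= max(e.cv2, e.cv4) + 1e-12


class TestEstimateAll:
    def test_cv2_dominates_cv1(self, gamma_sample):
        e = estimate_all(gamma_sample)
        assert e.cv2 >= e.cv1

    def test_scale_invariance_full_set(self, gamma_sample):
        a = estimate_all(gamma_sample)
        b = estimate_all(3.7 * gamma_sample)
        for name in ("cv1", "cv2", "cv3", "cv4", "cv5", "cv6", "cv7", "cv8"):
            assert getattr(b, name) == pytest.approx(getattr(a, name),
                                                     rel=1e-12)
        assert b.moments.mean == pytest.approx(3.7 * a.moments.mean)
        assert b.moments.sd == pytest.approx(3.7 * a.moments.sd)

    def test_n3_names_cv4(self):
        with pytest.raises(InsufficientSampleError, match="cv4"):
            estimate_all([1.0, 2.0, 3.0])

    def test_as_dict_keys(self, gamma_sample):
        d = estimate_all(gamma_sample).as_dict()
        assert {"cv1", "cv8", "mean", "sd", "skewness", "kurtosis",
                "n", "degenerate"} <= set(d)


class TestBatchKernel:
    def test_matches_scalar_api(self, rng):
        x = rng.gamma(3.0, 8.0, size=(20, 12))
        out = batch_estimates(x)
        for i in range(20):
            e = estimate_all(x[i])
            for name in out:
                assert out[name][i] == pytest.approx(getattr(e, name),
                                                     rel=1e-12)

    def test_degenerate_rows_zero(self):
        x = np.array([[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]])
        out = batch_estimates(x)
        assert all(out[name][0] == 0.0 for name in out)
        assert out["cv1"][1] > 0

    def test_domain_error_is_nan(self):
        x = np.array([[1.0, 0.001, 0.001, 0.001]])
        out = batch_estimates(x, ("cv3",))
        assert np.isnan(out["cv3"][0])


class TestMonteCarloBias:
    """Reduced-scale bias-reduction oracle (full scale in acceptance)."""

    def test_cv3_cv4_beat_cv1_on_skewed_gamma(self, rng):
        n, reps, shape = 10, 30_000, 4.0
        x = rng.gamma(shape, 2.0, size=(reps, n))
        out = batch_estimates(x, ("cv1", "cv3", "cv4"))
        true = 1 / math.sqrt(shape)
        b1 = abs(np.nanmean(out["cv1"]) - true)
        assert abs(np.nanmean(out["cv3"]) - true) < b1
        assert abs(np.nanmean(out["cv4"]) - true) < b1

    def test_normal_theory_bias(self, rng):
        # bias of cv1 under normality ~ -CV/(4N); cv2 nearly unbiased
        reps, n, cv = 50_000, 10, 0.1
        x = rng.normal(100.0, 10.0, size=(reps, n))
        out = batch_estimates(x, ("cv1", "cv2"))
        b1 = out["cv1"].mean() - cv
        se = out["cv1"].std(ddof=1) / math.sqrt(reps)
        assert b1 == pytest.approx(-cv / (4 * n), abs=4 * se)
        assert abs(out["cv2"].mean() - cv) < abs(b1)
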