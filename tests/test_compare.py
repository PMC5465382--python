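"""Density estimation, KS testing, symmetric KL and summaries."""

import numpy as np
import pytest

from moodlatent import (
    divergence_report,
    kde,
    ks_two_sample,
    project,
    summarize,
    symmetric_kl,
)
from moodlatent.exceptions import DegenerateSampleError, ValidationError


class TestProject:
    def test_basis_vector_selects_column(self, rng):
        X = rng.standard_normal((30, 4))
        w = np.array([0.0, 1.0, 0.0, 0.0])
        assert np.allclose(project(X, w), X[:, 1])

    def test_equal_weights_proportional_to_sum(self, rng):
        X = rng.standard_normal((30, 3))
        w = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        assert np.allclose(project(X, w), (X[:, 0] + X[:, 1]) / np.sqrt(2))

    def test_matches_row_dot_product_oracle(self, rng):
        X = rng.standard_normal((20, 5))
        w = rng.standard_normal(5)
        expected = [sum(X[n, j] * w[j] for j in range(5)) for n in range(20)]
        assert np.allclose(project(X, w), expected)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValidationError):
            project(rng.standard_normal((10, 3)), np.ones(4))


class TestKde:
    def test_standard_normal_peak(self, rng):
        x = rng.standard_normal(20_000)
        d = kde(x)
        at_zero = np.interp(0.0, d.grid, d.density)
        assert at_zero == pytest.approx(1 / np.sqrt(2 * np.pi), abs=0.03)

    def test_integral_is_one(self, rng):
        d = kde(rng.exponential(size=500))
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-6)

    def test_two_point_sample_symmetric(self):
        d = kde(np.array([-1.0, 1.0]))
        assert np.allclose(d.density, d.density[::-1], atol=1e-10)

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            kde(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(DegenerateSampleError):
            kde(np.array([1.0]))

    def test_degenerate_fallback_flags_point_mass(self):
        d = kde(np.array([2.0, 2.0]), allow_degenerate=True)
        assert d.point_mass

    def test_consistency_mise_decreases_with_n(self):
        """Mean integrated squared error against the true normal density
        shrinks as the sample grows."""
        true = lambda g: np.exp(-g**2 / 2) / np.sqrt(2 * np.pi)
        mise = []
        for n in (200, 2000, 20000):
            errs = []
            for seed in range(3):
                x = np.random.default_rng(seed).standard_normal(n)
                d = kde(x)
                errs.append(np.trapezoid((d.density - true(d.grid)) ** 2,
                                         d.grid))
            mise.append(np.mean(errs))
        assert mise[0] > mise[1] > mise[2]


class TestKsTwoSample:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(100)
        d, p = ks_two_sample(x, x)
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert d == 1.0
        assert p < 0.2

    def test_monotone_transform_invariance(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200) + 0.5
        d1, _ = ks_two_sample(a, b)
        d2, _ = ks_two_sample(np.exp(a), np.exp(b))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_small_samples_use_exact_mode(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        from scipy import stats

        d, p = ks_two_sample(a, b)
        exact = stats.ks_2samp(a, b, method="exact")
        assert p == pytest.approx(float(exact.pvalue))


class TestSymmetricKl:
    def test_identical_samples_near_zero(self, rng):
        x = rng.standard_normal(2000)
        d = kde(x)
        assert symmetric_kl(d, d) < 1e-6

    def test_symmetry_exact(self, rng):
        da = kde(rng.standard_normal(1000))
        db = kde(rng.standard_normal(1000) + 1.0)
        assert abs(symmetric_kl(da, db) - symmetric_kl(db, da)) < 1e-12

    def test_gaussian_closed_form(self, rng):
        """Unit mean shift at unit variance: each directed KL is 1/2, the
        symmetric sum is 1."""
        da = kde(rng.standard_normal(20_000))
        db = kde(rng.standard_normal(20_000) + 1.0)
        assert symmetric_kl(da, db) == pytest.approx(1.0, abs=0.15)

    def test_monotone_in_mean_separation(self):
        rng = np.random.default_rng(99)
        base = rng.standard_normal(5000)
        densities = [kde(rng.standard_normal(5000) + mu)
                     for mu in (0.0, 0.5, 1.0, 2.0)]
        d0 = kde(base)
        values = [symmetric_kl(d0, d) for d in densities]
        assert values == sorted(values)

    def test_mean_variant_halves_sum(self, rng):
        da = kde(rng.standard_normal(500))
        db = kde(rng.standard_normal(500) + 1.0)
        assert symmetric_kl(da, db, "mean") == pytest.approx(
            symmetric_kl(da, db, "sum") / 2
        )

    def test_nonnegative(self, rng):
        for _ in range(5):
            da = kde(rng.standard_normal(300))
            db = kde(rng.standard_normal(300) * rng.uniform(0.5, 2.0))
            assert symmetric_kl(da, db) >= 0.0


class TestSummarize:
    def test_median_of_small_sample(self):
        med, _ = summarize([1, 2, 3, 4, 5])
        assert med == 3.0

    def test_constant_sample_iqr_zero(self):
        med, iqr = summarize([4.0] * 10)
        assert (med, iqr) == (4.0, 0.0)

    def test_matches_sort_based_quantile_oracle(self, rng):
        x = rng.standard_normal(1001)
        med, iqr = summarize(x)
        s = np.sort(x)
        # n = 1001: exact order statistics at ranks 250, 500, 750.
        assert med == pytest.approx(s[500])
        assert iqr == pytest.approx(s[750] - s[250])


class TestDivergenceReport:
    def test_report_structure(self, rng):
        scores = {
            "a+b": {
                "BD": rng.standard_normal(300),
                "HC": rng.standard_normal(300) + 1.0,
            }
        }
        rep = divergence_report(scores)
        assert len(rep.summaries) == 2
        assert len(rep.pairwise) == 1
        row = rep.pairwise.iloc[0]
        assert 0 <= row.ks_statistic <= 1
        assert row.symmetric_kl >= 0

    def test_degenerate_cohort_gets_nan_divergence(self, rng):
        scores = {
            "a+b": {
                "BD": rng.standard_normal(50),
                "HC": np.zeros(50),
            }
        }
        rep = divergence_report(scores)
        assert np.isnan(rep.pairwise.iloc[0].symmetric_kl)
        assert rep.pairwise.iloc[0].ks_statistic > 0
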