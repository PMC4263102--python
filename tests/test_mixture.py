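import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import f as f_dist

from ipsckit import (
    GaussianMixtureModel,
    MixtureSpec,
    empirical_cdf,
    f_test_extra_component,
    fit_mixture_cdf,
    ks_two_sample,
    sample_decay_mixture,
    select_mixture_order,
)
from ipsckit import params as P


class TestEmpiricalCdf:
    def test_single_value(self):
        x, p = empirical_cdf([5.0])
        np.testing.assert_array_equal(x, [5.0])
        np.testing.assert_array_equal(p, [1.0])

    def test_quartiles(self):
        x, p = empirical_cdf([3, 1, 4, 2])
        np.testing.assert_array_equal(x, [1, 2, 3, 4])
        np.testing.assert_allclose(p, [0.25, 0.5, 0.75, 1.0])

    def test_ties_take_highest_rank(self):
        x, p = empirical_cdf([1.0, 2.0, 2.0, 3.0])
        np.testing.assert_array_equal(x, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(p, [0.25, 0.75, 1.0])

    def test_monotone(self, rng):
        _, p = empirical_cdf(rng.normal(size=500))
        assert (np.diff(p) > 0).all()


class TestMixtureSpec:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureSpec((0.5, 0.4), (1.0, 2.0), (1.0, 1.0))

    def test_sds_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            MixtureSpec((1.0,), (1.0,), (0.0,))


class TestFitMixtureCdf:
    def test_single_gaussian_recovery(self, rng):
        taus = rng.normal(100.0, 20.0, 5000)
        m = fit_mixture_cdf(taus, 1, seed=0)
        assert m.means[0] == pytest.approx(100.0, rel=0.02)
        assert m.sds[0] == pytest.approx(20.0, rel=0.05)

    def test_three_component_recovery(self):
        taus = sample_decay_mixture(P.MIXTURE_EGFP_NEG, 5000, seed=11)
        m = fit_mixture_cdf(taus, 3, seed=0)
        for got, want in zip(m.means, P.MIXTURE_EGFP_NEG.means):
            assert got == pytest.approx(want, rel=0.10)

    def test_weights_on_simplex(self):
        taus = sample_decay_mixture(P.MIXTURE_EGFP_POS, 2000, seed=1)
        m = fit_mixture_cdf(taus, 3, seed=0)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (m.weights >= 0).all()

    def test_fitted_cdf_monotone_and_bounded(self):
        taus = sample_decay_mixture(P.MIXTURE_EGFP_NEG, 1000, seed=2)
        m = fit_mixture_cdf(taus, 3, seed=0)
        grid = np.linspace(-100.0, 1000.0, 4000)
        cdf = m.cdf(grid)
        assert (np.diff(cdf) >= -1e-12).all()
        assert cdf.min() >= -1e-12 and cdf.max() <= 1 + 1e-12

    def test_overparameterized_fit_flagged(self, rng):
        taus = rng.normal(100.0, 20.0, 2000)
        m = fit_mixture_cdf(taus, 3, seed=0)
        assert m.flags

    def test_deterministic_under_seed(self):
        taus = sample_decay_mixture(P.MIXTURE_EGFP_NEG, 800, seed=3)
        a = fit_mixture_cdf(taus, 3, seed=4)
        b = fit_mixture_cdf(taus, 3, seed=4)
        np.testing.assert_array_equal(a.means, b.means)

    def test_mean_recovery_across_seeds(self):
        # median absolute error of the recovered means stays below 10%
        errs = {0: [], 1: [], 2: []}
        for s in range(10):
            taus = sample_decay_mixture(P.MIXTURE_EGFP_NEG, 2000, seed=100 + s)
            m = fit_mixture_cdf(taus, 3, seed=s)
            for i, want in enumerate(P.MIXTURE_EGFP_NEG.means):
                errs[i].append(abs(m.means[i] - want) / want)
        for i in errs:
            assert np.median(errs[i]) < 0.10


def _model(chi2, nu, n):
    w = np.full(n, 1.0 / n)
    return GaussianMixtureModel(w, np.arange(1.0, n + 1), np.ones(n),
                                chi2=chi2, nu=nu)


class TestFTest:
    def test_identical_chi2_gives_zero(self):
        res = f_test_extra_component(_model(5.0, 100, 1), _model(5.0, 97, 2))
        assert res.F == 0.0
        assert not res.accept_extra

    def test_unit_improvement_is_definitional(self):
        # delta(reduced chi2) equal to the complex reduced chi2 -> F = 1
        simple = _model(2.0 * 97, 97, 1)
        complex_ = _model(1.0 * 94, 94, 2)
        res = f_test_extra_component(simple, complex_)
        assert res.F == pytest.approx(1.0)

    def test_requires_one_extra_component(self):
        with pytest.raises(ValueError):
            f_test_extra_component(_model(1.0, 10, 1), _model(1.0, 10, 3))

    @pytest.mark.parametrize("F,df2", [(0.5, 50), (2.0, 100), (7.0, 400),
                                       (12.0, 997), (25.0, 1992)])
    def test_p_value_against_quadrature_oracle(self, F, df2):
        # integrate the F(3, df2) density numerically, independent of the
        # survival-function implementation used by the test statistic
        pdf = f_dist(3, df2).pdf
        p_quad, _ = quad(pdf, F, np.inf, limit=200)
        res = f_test_extra_component(_model((F + 1) * (df2 + 3), df2 + 3, 1),
                                     _model(df2 * 1.0, df2, 2))
        # construct models whose reduced-chi2 ratio gives exactly F
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p_quad, abs=1e-6)


class TestOrderSelection:
    def test_single_gaussian_yields_one_component(self, rng):
        hits = 0
        for r in range(20):
            taus = np.random.default_rng(r).normal(100.0, 20.0, 1000)
            if select_mixture_order(taus, max_n=3, seed=r).n > 1:
                hits += 1
        assert hits <= 1  # >= 95% of seeds select a single component

    def test_three_component_data_selects_three(self):
        hits = 0
        for s in range(5):
            taus = sample_decay_mixture(P.MIXTURE_EGFP_NEG, 2000, seed=700 + s)
            if select_mixture_order(taus, max_n=4, seed=s).n == 3:
                hits += 1
        assert hits >= 4

    def test_small_sample_never_goes_beyond_two(self, rng):
        for r in range(5):
            taus = sample_decay_mixture(P.MIXTURE_EGFP_NEG, 20, seed=r)
            assert select_mixture_order(taus, max_n=4, seed=r).n <= 2


class TestKsTwoSample:
    def test_identical_samples(self):
        x = np.linspace(1, 10, 50)
        d, _ = ks_two_sample(x, x)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        d, p = ks_two_sample(np.arange(10.0), np.arange(100.0, 110.0))
        assert d == pytest.approx(1.0)
        assert p < 1e-4

    def test_asymptotic_p_agreement(self, rng):
        from scipy.stats import kstwobign
        a = rng.normal(0.0, 1.0, 500)
        b = rng.normal(0.3, 1.0, 500)
        d, p = ks_two_sample(a, b)
        en = np.sqrt(500 * 500 / 1000)
        p_asym = kstwobign.sf(en * d)
        assert p == pytest.approx(p_asym, abs=1e-3)
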