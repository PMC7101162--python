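"""Sampler correctness: conjugate oracle, diagnostics, invariants."""

import numpy as np
import pytest

from coccomix import MixtureConfig
from coccomix.mixture import (
    MixtureResults,
    NormalMixtureModel,
    gelman_rubin,
    run_gibbs,
    sd_from_precision,
    summarize_posterior,
)

# a light schedule for structural tests; statistical assertions use more
FAST = dict(iterations=4_000, burn_in=1_000, thinning=5)


class TestSdFromPrecision:
    @pytest.mark.parametrize("precision,expected", [
        (1.0, 1.0), (400.0, 0.05), (100.0, 0.1), (25.0, 0.2),
    ])
    def test_reciprocal_square_root(self, precision, expected):
        assert sd_from_precision(precision) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_vectorized(self):
        out = sd_from_precision(np.array([1.0, 4.0]))
        assert np.allclose(out, [1.0, 0.5])

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            sd_from_precision(bad)


class TestGelmanRubin:
    def test_permuted_chains_near_one(self, rng):
        draws = rng.normal(0, 1, 3000)
        chains = np.stack([draws, rng.permutation(draws),
                           rng.permutation(draws)])
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_far_above_one(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert gelman_rubin(chains) > 3.0

    def test_hand_computed_split_formula(self):
        # two length-4 chains -> four split halves of length 2;
        # W = mean of the four within variances, B = 2 * var of the
        # four half means, rhat = sqrt(((n-1)/n W + B/n) / W)
        chains = np.array([[1.0, 2.0, 3.0, 4.0],
                           [2.0, 4.0, 6.0, 8.0]])
        halves = np.array([[1, 2], [3, 4], [2, 4], [6, 8]], dtype=float)
        w = halves.var(axis=1, ddof=1).mean()
        b = 2 * halves.mean(axis=1).var(ddof=1)
        expected = np.sqrt((w / 2 + b / 2) / w)
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_distinct_means_flagged(self):
        chains = np.array([[1.0] * 10, [2.0] * 10])
        assert np.isnan(gelman_rubin(chains))

    def test_constant_everything_is_one(self):
        assert gelman_rubin(np.ones((3, 10))) == 1.0

    def test_agrees_with_arviz_split_rhat(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.normal(0, 1, size=(3, 400)) + \
            rng.normal(0, 0.2, size=(3, 1))
        ours = gelman_rubin(chains)
        theirs = float(np.asarray(
            arviz.rhat(arviz.convert_to_dataset(chains),
                       method="split")["x"]))
        assert ours == pytest.approx(theirs, abs=0.01)


@pytest.fixture(scope="module")
def conjugate_fit():
    """Single-component fit against the semi-conjugate closed form."""
    rng = np.random.default_rng(7)
    data = rng.normal(0.11, 0.02, 1000)
    cfg = MixtureConfig(
        k=1, alpha=(1.0,), iterations=30_000, burn_in=3_000, thinning=5,
        seed=3, prior_mean_location=0.0, prior_mean_precision=1e-8,
        precision_shape=0.01, precision_rate=0.01 * 0.02 ** 2,
    )
    return data, run_gibbs(data, cfg)


class TestConjugateOracle:
    def test_posterior_mean_matches_closed_form(self, conjugate_fit):
        """With a flat mean prior, E[mu | data, tau] = xbar exactly for
        every tau, so the marginal posterior mean of mu is xbar."""
        data, draws = conjugate_fit
        mu = draws.mu.ravel()
        n_eff = mu.size / 10  # conservative autocorrelation allowance
        mcse = mu.std() / np.sqrt(n_eff)
        assert abs(mu.mean() - data.mean()) < 3 * mcse

    def test_posterior_precision_matches_closed_form(self, conjugate_fit):
        """tau | mu ~ Gamma(a0 + n/2, b0 + SS(mu)/2); with mu pinned at
        xbar by the data its mean is that of the closed-form gamma."""
        data, draws = conjugate_fit
        tau = draws.precision.ravel()
        n = data.size
        a_post = 0.01 + n / 2
        b_post = 0.01 * 0.02 ** 2 + 0.5 * ((data - data.mean()) ** 2).sum()
        expected = a_post / b_post
        sd = np.sqrt(a_post) / b_post
        n_eff = tau.size / 10
        assert abs(tau.mean() - expected) < 4 * sd / np.sqrt(n_eff) + \
            0.01 * expected

    def test_posterior_spread_of_mean(self, conjugate_fit):
        """sd of mu draws ~ sigma/sqrt(n) for the flat-prior posterior."""
        data, draws = conjugate_fit
        mu = draws.mu.ravel()
        assert mu.std() == pytest.approx(data.std() / np.sqrt(data.size),
                                         rel=0.2)


@pytest.fixture(scope="module")
def k4_draws():
    rng = np.random.default_rng(11)
    data = np.concatenate([
        rng.normal(0.08, 0.01, 100), rng.normal(0.11, 0.01, 250),
        rng.normal(0.14, 0.01, 150),
    ])
    cfg = MixtureConfig(k=3, alpha=(20.0, 50.0, 30.0), seed=5,
                        chains=3, **FAST)
    return run_gibbs(data, cfg)


class TestSamplerInvariants:
    def test_weights_are_simplex_every_draw(self, k4_draws):
        sums = k4_draws.weights.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (k4_draws.weights > 0).all()

    def test_sorted_means_every_retained_draw(self, k4_draws):
        assert k4_draws.sorted_means
        assert (np.diff(k4_draws.mu, axis=2) >= 0).all()

    def test_seed_determinism_bit_identical(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0.1, 0.02, 150)
        cfg = MixtureConfig(k=2, alpha=(20.0, 80.0), seed=17, **FAST)
        a = run_gibbs(data, cfg)
        b = run_gibbs(data, cfg)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.precision, b.precision)
        assert np.array_equal(a.weights, b.weights)

    def test_different_seed_different_draws(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0.1, 0.02, 150)
        cfg = MixtureConfig(k=2, alpha=(20.0, 80.0), seed=17, **FAST)
        a = run_gibbs(data, cfg)
        b = run_gibbs(data, cfg.replace(seed=18))
        assert not np.array_equal(a.mu, b.mu)

    def test_k_exceeding_distinct_values_rejected(self):
        cfg = MixtureConfig(k=4, alpha=(1.0,) * 4, **FAST)
        with pytest.raises(ValueError, match="distinct"):
            run_gibbs([0.1, 0.1, 0.1, 0.2], cfg)

    def test_retained_draw_count(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0.1, 0.02, 50)
        cfg = MixtureConfig(k=1, alpha=(10.0,), iterations=1000,
                            burn_in=100, thinning=7, chains=2, seed=0)
        draws = run_gibbs(data, cfg)
        assert draws.mu.shape == (2, cfg.n_retained, 1)
        assert cfg.n_retained == int(np.ceil(900 / 7))


class TestAlphaSwapSymmetry:
    def test_two_component_summaries_swap_with_alpha(self):
        """Swapping the two hyperpriors (with the weight truth swapped)
        relabels the fit: summaries agree under component exchange.

        Uses overlapping components (the regime the two-component model
        is built for); with well-separated clusters the slot labels
        freeze during burn-in and the property holds only for the
        component set, not per slot.
        """
        rng = np.random.default_rng(9)
        data = np.concatenate([rng.normal(0.10, 0.018, 50),
                               rng.normal(0.12, 0.018, 150)])
        base = dict(iterations=20_000, burn_in=2_000, thinning=5, seed=4)
        fit_ab = summarize_posterior(run_gibbs(
            data, MixtureConfig(k=2, alpha=(20.0, 80.0), **base)))
        fit_ba = summarize_posterior(run_gibbs(
            data, MixtureConfig(k=2, alpha=(80.0, 20.0), **base)))
        np.testing.assert_allclose(
            np.sort(fit_ab.mu_median), np.sort(fit_ba.mu_median),
            atol=0.004)
        np.testing.assert_allclose(
            np.sort(fit_ab.sigma_median), np.sort(fit_ba.sigma_median),
            atol=0.004)


class TestSummaries:
    def test_quantile_definition_by_hand(self):
        draws = np.arange(1.0, 101.0).reshape(1, 100, 1)
        gd_like = type("D", (), {})()
        from coccomix.mixture import GibbsDraws

        gd = GibbsDraws(mu=draws, precision=np.ones_like(draws),
                        weights=np.ones_like(draws), sorted_means=False,
                        data_min=0.0, data_max=1.0)
        s = summarize_posterior(gd, credible_mass=0.68)
        assert s.mu_median[0] == pytest.approx(50.5)
        # numpy linear-interpolation percentiles of 1..100
        assert s.mu_lo[0] == pytest.approx(np.quantile(draws, 0.16))
        assert s.mu_hi[0] == pytest.approx(np.quantile(draws, 0.84))

    def test_constant_draws_degenerate_interval(self):
        from coccomix.mixture import GibbsDraws

        draws = np.full((2, 50, 1), 3.14)
        gd = GibbsDraws(mu=draws, precision=np.full_like(draws, 4.0),
                        weights=np.ones_like(draws), sorted_means=False,
                        data_min=0.0, data_max=1.0)
        s = summarize_posterior(gd)
        assert s.mu_lo[0] == s.mu_median[0] == s.mu_hi[0] == 3.14
        assert s.sigma_median[0] == 0.5  # from per-draw 1/sqrt(tau)

    def test_sigma_summary_uses_per_draw_transform(self, rng):
        from coccomix.mixture import GibbsDraws

        tau = rng.gamma(5.0, 100.0, size=(1, 500, 1))
        gd = GibbsDraws(mu=np.zeros_like(tau), precision=tau,
                        weights=np.ones_like(tau), sorted_means=False,
                        data_min=0.0, data_max=1.0)
        s = summarize_posterior(gd)
        assert s.sigma_median[0] == pytest.approx(
            np.median(tau ** -0.5), rel=1e-12)
        # not the transform of the summarised precision unless symmetric
        assert s.sigma_lo[0] == pytest.approx(np.quantile(tau ** -0.5, 0.16))


class TestModelResults:
    def test_from_sample_filters_and_sets_alpha(self):
        rng = np.random.default_rng(6)
        thickness = np.concatenate([rng.normal(0.12, 0.02, 200), [0.9]])
        counts = {"A": 231, "B": 67, "M": 2}
        model = NormalMixtureModel.from_sample(thickness, counts)
        assert model.morphotypes == ("A", "B")  # M is rare, excluded
        assert model.config.alpha == (231.0, 67.0)
        assert model.config.k == 2
        assert model.data.max() < 0.9  # outlier removed

    def test_fit_reports_summary_and_rhat(self):
        rng = np.random.default_rng(8)
        data = np.concatenate([rng.normal(0.09, 0.01, 80),
                               rng.normal(0.13, 0.01, 220)])
        cfg = MixtureConfig(k=2, alpha=(25.0, 75.0), seed=1, **FAST)
        res = NormalMixtureModel(data, cfg, morphotypes=["B", "A"]).fit()
        assert isinstance(res, MixtureResults)
        text = res.summary()
        assert "B" in text and "A" in text
        assert res.rhat_mu.shape == (2,)
        table = res.posterior_summary().to_frame()
        assert list(table.columns)[:3] == ["mu_lo", "mu_median", "mu_hi"]

    def test_draw_archive_shape(self):
        rng = np.random.default_rng(8)
        data = rng.normal(0.1, 0.02, 100)
        cfg = MixtureConfig(k=2, alpha=(50.0, 50.0), seed=1, chains=2,
                            **FAST)
        res = NormalMixtureModel(data, cfg).fit()
        frame = res.to_frame()
        assert set(frame.columns) == {"chain", "draw", "component", "mu",
                                      "sigma", "weight"}
        assert len(frame) == 2 * cfg.n_retained * 2

    def test_low_mean_draw_fraction_reported(self):
        rng = np.random.default_rng(8)
        data = rng.normal(0.1, 0.02, 100)
        cfg = MixtureConfig(k=2, alpha=(50.0, 50.0), seed=1, **FAST)
        res = NormalMixtureModel(data, cfg).fit()
        frac = res.frac_mu_below_data_min
        assert frac.shape == (2,)
        assert (frac >= 0).all() and (frac <= 1).all()
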