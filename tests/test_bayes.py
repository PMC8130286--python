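import numpy as np
import pytest

import fastripple as fr
from fastripple.bayes import PosteriorDraws


def _fit(data, parameter, seed=0, draws=600, warmup=400):
    prior = fr.build_priors(data, parameter)
    return fr.sample_posterior(
        data, prior, chains=4, draws=draws, warmup=warmup, seed=seed
    )


class TestPriors:
    def test_pooled_moments_by_hand(self):
        prior = fr.build_priors(np.array([10.0, 20.0, 30.0]), "amplitude_pp")
        assert prior.pooled_mean == 20.0
        assert prior.pooled_sd == 10.0
        assert prior.mu_prior_sd == 20.0

    @pytest.mark.parametrize(
        "parameter, expected",
        [("amplitude_pp", (1.0, 150.0)), ("duration_ms", (1.0, 500.0)),
         ("power_frequency", (250.0, 600.0)), ("power", (1.0, 150.0))],
    )
    def test_sigma_ranges_follow_parameter_ranges(self, parameter, expected):
        prior = fr.build_priors(np.array([5.0, 10.0]), parameter)
        assert prior.sigma_range == expected

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            fr.build_priors(np.array([]), "amplitude_pp")

    def test_nu_prior_mean_is_thirty(self):
        prior = fr.build_priors(np.array([5.0, 10.0]), "duration_ms")
        assert prior.nu_prior_mean == 30.0


class TestSampler:
    def test_sigma_draws_respect_prior_support(self):
        rng = np.random.default_rng(3)
        data = 50 + 30 * rng.standard_t(30, size=120)
        post = _fit(data, "amplitude_pp", seed=3)
        assert np.all(post.sigma >= 1.0)
        assert np.all(post.sigma <= 150.0)
        assert np.all(post.nu > 0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        data = 50 + 30 * rng.standard_t(30, size=60)
        a = _fit(data, "amplitude_pp", seed=9)
        b = _fit(data, "amplitude_pp", seed=9)
        np.testing.assert_array_equal(a.mu, b.mu)

    def test_too_few_events_raise(self):
        prior = fr.build_priors(np.array([1.0, 2.0, 3.0]), "amplitude_pp")
        with pytest.raises(ValueError, match="at least 3"):
            fr.sample_posterior(np.array([1.0, 2.0]), prior)

    def test_posterior_sd_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        sds = []
        for n in (20, 80, 320):
            data = 50 + 30 * rng.standard_t(30, size=n)
            sds.append(np.std(_fit(data, "amplitude_pp", seed=n).mu))
        assert sds[0] > sds[1] > sds[2]

    def test_posterior_mean_approaches_sample_mean_for_large_n(self):
        rng = np.random.default_rng(6)
        data = 50 + 30 * rng.standard_t(30, size=400)
        post = _fit(data, "amplitude_pp", seed=6)
        se = np.std(data, ddof=1) / np.sqrt(len(data))
        assert abs(np.mean(post.mu) - np.mean(data)) < se


class TestMapPoint:
    def _draws(self, mu, sigma):
        return PosteriorDraws(
            parameter="amplitude_pp", region="CA1",
            mu=np.asarray(mu, float), sigma=np.asarray(sigma, float),
            nu=np.full(len(mu), 30.0), ess=1e4, rhat=1.0, converged=True,
        )

    def test_degenerate_draws_return_that_point(self):
        post = self._draws(np.full(2000, 42.0), np.full(2000, 28.0))
        assert fr.map_point(post) == (42.0, 28.0)

    def test_too_few_draws_raise(self):
        post = self._draws(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError, match="draws"):
            fr.map_point(post)

    def test_symmetric_bimodal_ties_break_toward_lower_mu(self):
        # exactly mirror-symmetric draws: the two modes have identical
        # density, so the documented tie-break must pick the lower-µ one
        rng = np.random.default_rng(7)
        a = rng.normal(10.0, 0.05, 1000)
        s = rng.normal(5.0, 0.05, 1000)
        mu = np.concatenate([a, 30.0 - a])
        sigma = np.concatenate([s, s])
        got_mu, _ = fr.map_point(self._draws(mu, sigma))
        assert got_mu < 15.0

    def test_map_near_truth_for_simulated_data(self):
        rng = np.random.default_rng(8)
        data = 320 + 50 * rng.standard_t(30, size=500)
        post = _fit(data, "power_frequency", seed=8, draws=1000, warmup=500)
        mu_star, _ = fr.map_point(post)
        assert mu_star == pytest.approx(320.0, abs=10)


class TestSpectralComposition:
    def _posteriors(self, values_by_region, parameter, seed):
        return {
            region: _fit(np.asarray(v, float), parameter, seed=seed)
            for region, v in values_by_region.items()
        }

    def test_single_tone_regime_has_no_shift(self):
        """Events that are pure tones have mean frequency = power frequency."""
        rng = np.random.default_rng(9)
        freqs = 320 + 20 * rng.standard_normal(60)
        pf = self._posteriors({"DG": freqs}, "power_frequency", seed=1)
        mf = self._posteriors({"DG": freqs}, "mean_frequency", seed=2)
        out = fr.spectral_composition(pf, mf)
        assert abs(out["DG"]["delta"]) < 10.0
        assert out["DG"]["joint_mu"].shape[1] == 2

    def test_energy_above_carrier_gives_positive_shift(self):
        rng = np.random.default_rng(10)
        power_freqs = 320 + 20 * rng.standard_normal(60)
        mean_freqs = power_freqs + 60.0 + 5 * rng.standard_normal(60)
        pf = self._posteriors({"CA1": power_freqs}, "power_frequency", seed=3)
        mf = self._posteriors({"CA1": mean_freqs}, "mean_frequency", seed=4)
        out = fr.spectral_composition(pf, mf)
        assert out["CA1"]["delta"] > 30.0

    def test_mismatched_regions_raise(self):
        rng = np.random.default_rng(11)
        freqs = 320 + 20 * rng.standard_normal(30)
        pf = self._posteriors({"DG": freqs}, "power_frequency", seed=5)
        mf = self._posteriors({"CA1": freqs}, "mean_frequency", seed=6)
        with pytest.raises(ValueError, match="regions"):
            fr.spectral_composition(pf, mf)
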