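"""Inference machinery: box prior, adaptive MCMC, pooling, kernel expansion,
second-level prior, and the bootstrap particle filter."""

import numpy as np
import pytest

import gtvpredict as gp
from gtvpredict.inference import DegeneracyError, KernelExpansion


def uniform_particles(thetas):
    m = thetas.shape[0]
    return gp.WeightedParticles(thetas=thetas, weights=np.full(m, 1.0 / m))


class TestPriorSpec:
    def test_defaults_are_box_bounds(self, prior):
        np.testing.assert_array_equal(prior.lower, [-10, 0, -10, -10, -10, -5])
        np.testing.assert_array_equal(prior.upper, [0, 5, 0, 3, 3, 0])

    def test_samples_inside(self, prior, rng):
        draws = prior.sample(500, rng)
        assert prior.contains(draws).all()

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            gp.PriorSpec(lower=np.zeros(6), upper=np.zeros(6))


class TestSilverman:
    def test_scale_factor_formula(self, rng):
        # m = 1000, dim = 6, beta = 2: factor = 2 (4/8000)^(1/10)
        particles = uniform_particles(rng.normal(size=(1000, 6)))
        exp = gp.silverman_covariance(particles, beta=2.0)
        assert exp.scale_factor == pytest.approx(2 * (4 / 8000) ** 0.1, rel=1e-12)
        assert exp.scale_factor == pytest.approx(0.93525, rel=1e-4)
        cov_diag = np.diag(np.cov(particles.thetas.T))
        np.testing.assert_allclose(exp.sigma_eps, exp.scale_factor * cov_diag)

    def test_beta_zero_degenerates(self, rng):
        particles = uniform_particles(rng.normal(size=(100, 6)))
        exp = gp.silverman_covariance(particles, beta=0.0)
        np.testing.assert_array_equal(exp.sigma_eps, 0.0)

    def test_doubling_samples_quadruples_covariance(self, rng):
        thetas = rng.normal(size=(500, 6))
        e1 = gp.silverman_covariance(uniform_particles(thetas))
        e2 = gp.silverman_covariance(uniform_particles(2 * thetas))
        np.testing.assert_allclose(e2.sigma_eps, 4 * e1.sigma_eps, rtol=1e-10)

    def test_degenerate_dimension_rejected(self, rng):
        thetas = rng.normal(size=(50, 6))
        thetas[:, 3] = 1.0
        with pytest.raises(ValueError):
            gp.silverman_covariance(uniform_particles(thetas))


class TestPooling:
    def _posterior(self, draws, pid):
        return gp.inference.PosteriorSamples(
            draws=draws,
            patient_id=pid,
            chain_id=np.zeros(draws.shape[0], dtype=int),
            diagnostics={},
            seed=0,
        )

    def test_two_patients_uniform_weights(self, rng):
        a = self._posterior(rng.normal(size=(100, 6)), "a")
        b = self._posterior(rng.normal(size=(100, 6)), "b")
        pooled = gp.pool_posteriors([a, b])
        assert pooled.m == 200
        np.testing.assert_allclose(pooled.weights, 1 / 200)
        assert set(pooled.patient_ids) == {"a", "b"}

    def test_single_patient_identity(self, rng):
        draws = rng.normal(size=(50, 6))
        pooled = gp.pool_posteriors([self._posterior(draws, "a")])
        np.testing.assert_array_equal(pooled.thetas, draws)

    def test_mixture_mean_is_average_of_means(self, rng):
        a = self._posterior(rng.normal(0.0, 1.0, size=(200, 6)), "a")
        b = self._posterior(rng.normal(3.0, 1.0, size=(200, 6)), "b")
        pooled = gp.pool_posteriors([a, b])
        np.testing.assert_allclose(
            pooled.weights @ pooled.thetas,
            0.5 * (a.draws.mean(0) + b.draws.mean(0)),
            rtol=1e-10,
        )

    def test_unequal_counts_rejected(self, rng):
        a = self._posterior(rng.normal(size=(100, 6)), "a")
        b = self._posterior(rng.normal(size=(90, 6)), "b")
        with pytest.raises(ValueError):
            gp.pool_posteriors([a, b])


class TestSecondLevelPrior:
    def test_all_particles_inside_box(self, small_training):
        p2 = small_training["p2"]
        prior = small_training["prior"]
        assert prior.contains(p2.thetas).all()
        assert p2.provenance == "second_level_prior"

    def test_beta_zero_is_bootstrap_resample(self, small_training):
        pooled = small_training["pooled"]
        prior = small_training["prior"]
        exp = gp.silverman_covariance(pooled, beta=0.0)
        p2 = gp.build_second_level_prior(
            pooled, exp, bounds=prior, seed=3, n_particles=500
        )
        # every output particle must be an exact row of the pooled set
        pooled_rows = {tuple(row) for row in pooled.thetas}
        assert all(tuple(row) in pooled_rows for row in p2.thetas)

    def test_variance_addition_interior_cloud(self, rng, prior):
        """Pre-truncation, output variance = base variance + kernel variance;
        an interior-concentrated cloud makes truncation negligible."""
        center = 0.5 * (prior.lower + prior.upper)
        base = center + rng.normal(0.0, 0.05, size=(4000, 6))
        particles = uniform_particles(base)
        exp = KernelExpansion(
            beta=1.0, m=4000, dim=6, sigma_eps=np.full(6, 0.05**2)
        )
        p2 = gp.build_second_level_prior(
            particles, exp, bounds=prior, seed=4, n_particles=40_000
        )
        np.testing.assert_allclose(
            p2.thetas.var(axis=0), base.var(axis=0) + 0.05**2, rtol=0.10
        )


class TestParticleFilter:
    def test_empty_observations_leave_weights(self, small_training):
        p2 = small_training["p2"]
        out = gp.particle_filter_update(p2, None, small_training["noise"])
        np.testing.assert_array_equal(out.weights, p2.weights)
        assert out.provenance == "filtered"

    def test_two_particle_likelihood_ratio(self, standard):
        """A 3:1 likelihood ratio with uniform prior weights gives (0.75, 0.25)."""
        schedule, _ = standard
        noise = gp.NoiseParams(0.3, 0.0)
        th_a = gp.ModelParams(0.05, 2.0, 0.4, 0.5, 0.01, 0.2).to_log()
        th_b = gp.ModelParams(0.10, 3.0, 0.01, 0.1, 0.01, 0.3).to_log()
        t = np.array([21.0])
        va = gp.simulate(gp.ModelParams.from_log(th_a), schedule, t).V[0]
        vb = gp.simulate(gp.ModelParams.from_log(th_b), schedule, t).V[0]
        # choose v so that exp(ll_a - ll_b) = 3 exactly
        v = (vb**2 - va**2 - 2 * 0.3**2 * np.log(3)) / (2 * (vb - va))
        obs = gp.ObservationSet(
            patient_id="t", times=t, v_obs=np.array([v]), schedule=schedule
        )
        particles = uniform_particles(np.vstack([th_a, th_b]))
        out = gp.particle_filter_update(particles, obs, noise)
        np.testing.assert_allclose(out.weights, [0.75, 0.25], atol=1e-10)

    def test_matches_direct_normalized_product(self, small_training):
        """Brute-force oracle on 10 particles: weights equal the normalized
        prior-times-likelihood computed observation by observation."""
        pooled = small_training["pooled"]
        noise = small_training["noise"]
        pat = gp.generate_patient(pooled, noise=noise, seed=55)
        particles = uniform_particles(pooled.thetas[:10])
        out = gp.particle_filter_update(particles, pat.observations, noise)
        ll = np.array(
            [
                gp.log_likelihood(
                    pat.observations, gp.ModelParams.from_log(t), noise
                )
                for t in particles.thetas
            ]
        )
        w = np.exp(ll - ll.max())
        np.testing.assert_allclose(out.weights, w / w.sum(), rtol=1e-10)

    def test_sequential_coherence(self, small_training):
        """Filtering the full record at once equals incremental weekly
        filtering (static parameters make the update exact)."""
        p2 = small_training["p2"]
        noise = small_training["noise"]
        pat = gp.generate_patient(small_training["pooled"], noise=noise, seed=60)
        batch = gp.particle_filter_update(p2, pat.observations, noise)
        incremental = p2
        for t in pat.observations.times:
            incremental = gp.particle_filter_update(
                p2, pat.observations.truncated(t), noise
            )
        np.testing.assert_allclose(incremental.weights, batch.weights, atol=1e-12)

    def test_degeneracy_raises_when_no_particle_has_support(self, standard):
        # zero measurement sd gives every particle a vanishing likelihood
        schedule, _ = standard
        noise = gp.NoiseParams(0.0, 0.0)
        th = gp.ModelParams(0.05, 2.0, 0.4, 0.5, 0.01, 0.2).to_log()
        obs = gp.ObservationSet(
            patient_id="t",
            times=np.array([21.0]),
            v_obs=np.array([0.9]),
            schedule=schedule,
        )
        with pytest.raises(DegeneracyError):
            gp.particle_filter_update(uniform_particles(th[None, :]), obs, noise)


class TestEffectiveSampleSize:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            (np.full(100, 0.01), 100.0),
            (np.array([1.0, 0.0, 0.0]), 1.0),
            (np.array([0.75, 0.25]), 1.6),
        ],
    )
    def test_values(self, weights, expected):
        assert gp.effective_sample_size(weights) == pytest.approx(expected)


class TestMCMC:
    def test_empty_data_draws_stay_in_box(self, prior):
        post = gp.sample_posterior_mcmc(
            None, prior, None, seed=1, n_iter=2_000, thin_to=400
        )
        assert prior.contains(post.draws).all()
        assert post.draws.shape == (400, 6)

    def test_two_seeds_agree_on_prior_means(self, prior):
        """Marginal means from independent seeds agree within a conservative
        Monte Carlo tolerance under the flat target."""
        kw = dict(n_iter=20_000, thin_to=4_000, check_convergence=False)
        a = gp.sample_posterior_mcmc(None, prior, None, seed=10, **kw)
        b = gp.sample_posterior_mcmc(None, prior, None, seed=20, **kw)
        np.testing.assert_allclose(
            a.draws.mean(0), b.draws.mean(0), atol=0.35
        )

    def test_posterior_concentrates_with_tight_noise(self, prior):
        """With low-noise data the posterior predictive of the final volume
        recovers the truth within 5%."""
        tight = gp.NoiseParams(0.01, 0.01)
        pat = gp.generate_patient(
            prior, noise=tight, seed=42, target_class=gp.ResponseClass.FAST
        )
        post = gp.sample_posterior_mcmc(
            pat.observations, prior, tight, seed=7, n_iter=20_000,
            thin_to=2_000, check_convergence=False,
        )
        particles = uniform_particles(post.draws)
        pred = gp.predict_final_volume(particles, pat.schedule, 53.0)
        truth = gp.simulate(pat.params, pat.schedule, np.array([53.0])).V[0]
        assert pred["mean"] == pytest.approx(truth, abs=0.05)

    def test_weight_invariants(self, small_training):
        for key in ("pooled", "p2"):
            particles = small_training[key]
            assert abs(particles.weights.sum() - 1.0) < 1e-12
            assert np.all(particles.weights >= 0)
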