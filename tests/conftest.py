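import numpy as np
import pytest

import gtvpredict as gp


@pytest.fixture(scope="session")
def prior():
    return gp.PriorSpec()


@pytest.fixture(scope="session")
def fixture_noise():
    return gp.NoiseParams(alpha1=0.05, alpha2=0.10)


@pytest.fixture(scope="session")
def standard():
    schedule, measurements = gp.standard_schedule()
    return schedule, measurements


@pytest.fixture(scope="session")
def small_training(prior, fixture_noise):
    """A small trained state shared across tests: a 5-patient synthetic
    cohort fitted with short chains, pooled, and expanded into a
    second-level prior."""
    cohort = gp.generate_cohort(5, prior, noise=fixture_noise, seed=11)
    posteriors = [
        gp.sample_posterior_mcmc(
            p.observations,
            prior,
            fixture_noise,
            seed=100 + i,
            n_iter=8_000,
            thin_to=1_000,
            check_convergence=False,
        )
        for i, p in enumerate(cohort)
    ]
    pooled = gp.pool_posteriors(posteriors)
    expansion = gp.silverman_covariance(pooled, beta=2.0)
    p2 = gp.build_second_level_prior(
        pooled, expansion, bounds=prior, seed=5, n_particles=20_000
    )
    return {
        "cohort": cohort,
        "posteriors": posteriors,
        "pooled": pooled,
        "p2": p2,
        "noise": fixture_noise,
        "prior": prior,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
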