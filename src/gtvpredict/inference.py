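"""Pseudo-hierarchical Bayesian machinery.

Per-patient posteriors over θ = (log λ, log K, log γ, log ζ, log η, log φ₀)
are sampled with a robust adaptive Metropolis sampler under an independent
uniform box prior p₁(θ). The posteriors of a training cohort are pooled into
a uniform mixture (the full posterior), which is expanded into a second-level
prior p₂(θ) by resampling particles and perturbing them with truncated
multivariate normal kernels whose covariance is Silverman's rule inflated by
a factor β. New patients are then handled with a bootstrap particle filter:
prior particles are reweighted by the patient's likelihood as scans arrive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .noise import NoiseParams, ObservationSet

__all__ = [
    "PriorSpec",
    "PosteriorSamples",
    "WeightedParticles",
    "KernelExpansion",
    "sample_posterior_mcmc",
    "pool_posteriors",
    "silverman_covariance",
    "build_second_level_prior",
    "particle_filter_update",
    "effective_sample_size",
    "split_rhat",
    "DegeneracyError",
    "ConvergenceError",
]

_EMPTY = np.empty(0)

# Table-2 box prior in log space: (log λ, log K, log γ, log ζ, log η, log φ₀)
DEFAULT_PRIOR_LOWER = np.array([-10.0, 0.0, -10.0, -10.0, -10.0, -5.0])
DEFAULT_PRIOR_UPPER = np.array([0.0, 5.0, 0.0, 3.0, 3.0, 0.0])


class DegeneracyError(RuntimeError):
    """All particle weights vanished — the prior does not cover the patient."""


class ConvergenceError(RuntimeError):
    """MCMC diagnostics failed (split-R̂ too large or chain frozen)."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform (box) prior on the log-space parameter vector."""

    lower: np.ndarray = field(default_factory=lambda: DEFAULT_PRIOR_LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: DEFAULT_PRIOR_UPPER.copy())

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float).ravel()
        hi = np.asarray(self.upper, dtype=float).ravel()
        if lo.shape != hi.shape or np.any(lo >= hi):
            raise ValueError("need lower < upper in every dimension")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws with chain diagnostics."""

    draws: np.ndarray  # (S, d) log-space draws (d = 6, or 8 with noise)
    patient_id: str
    chain_id: np.ndarray
    diagnostics: dict
    seed: int


@dataclass
class WeightedParticles:
    """θ particles with normalized weights; represents pooled posteriors,
    second-level priors and filtered posteriors alike."""

    thetas: np.ndarray
    weights: np.ndarray
    provenance: str = "pooled_posterior"
    patient_ids: np.ndarray | None = None

    def __post_init__(self):
        self.thetas = np.atleast_2d(np.asarray(self.thetas, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.thetas.shape[0] < 1:
            raise ValueError("particle count must be >= 1")
        if self.weights.shape[0] != self.thetas.shape[0]:
            raise ValueError("weights must align with particles")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be >= 0 and sum to 1 within 1e-12")

    @property
    def m(self) -> int:
        return self.thetas.shape[0]

    @property
    def ess(self) -> float:
        return effective_sample_size(self.weights)

    def resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(self.m, size=n, p=self.weights)
        return self.thetas[idx]


@dataclass(frozen=True)
class KernelExpansion:
    """Perturbation kernel covariance from Silverman's rule inflated by β:

    Σ_ε = β (4 / (m (d + 2)))^(1/(d+4)) diag(Σ_θ)

    The exponent applies to the covariance (not its square root), matching
    the expansion rule as used for the second-level prior.
    """

    beta: float
    m: int
    dim: int
    sigma_eps: np.ndarray  # diagonal entries of Σ_ε

    @property
    def scale_factor(self) -> float:
        return self.beta * (4.0 / (self.m * (self.dim + 2))) ** (1.0 / (self.dim + 4))


def silverman_covariance(particles: WeightedParticles, beta: float = 2.0) -> KernelExpansion:
    """Silverman-rule diagonal covariance of the particle cloud, inflated by β."""
    if particles.m < 2:
        raise ValueError("need at least 2 particles")
    cov_diag = np.diag(np.cov(particles.thetas.T, aweights=particles.weights))
    if np.any(cov_diag <= 1e-12 * max(cov_diag.max(), 1e-300)):
        raise ValueError("degenerate (zero-variance) parameter dimension")
    m, dim = particles.m, particles.thetas.shape[1]
    factor = beta * (4.0 / (m * (dim + 2))) ** (1.0 / (dim + 4))
    return KernelExpansion(beta=beta, m=m, dim=dim, sigma_eps=factor * cov_diag)


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R̂ per parameter for chains of shape (n_chains, n_draws, d)."""
    c, n, d = chains.shape
    half = n // 2
    split = chains[:, : 2 * half].reshape(2 * c, half, d)
    means = split.mean(axis=1)
    vars_ = split.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / W)


def sample_posterior_mcmc(
    obs: ObservationSet | None,
    prior: PriorSpec,
    noise: NoiseParams | None,
    seed: int,
    n_iter: int = 25_000,
    n_chains: int = 4,
    thin_to: int = 2_500,
    target_accept: float = 0.234,
    rhat_threshold: float = 1.2,
    infer_noise: bool = False,
    noise_upper: float = 0.5,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Robust adaptive Metropolis sampling of a patient posterior.

    The first half of each chain is discarded as burn-in; the remainder is
    thinned so the pooled output has `thin_to` draws. With infer_noise, the
    state is extended by (α₁, α₂) with Uniform(0, noise_upper) priors in
    natural space (used by the cohort-level noise pre-estimation). With
    obs=None (or an empty observation set) the target reduces to the prior.
    """
    lower, upper = prior.lower.copy(), prior.upper.copy()
    if infer_noise:
        lower = np.concatenate([lower, [0.0, 0.0]])
        upper = np.concatenate([upper, [noise_upper, noise_upper]])
    elif noise is None:
        noise = NoiseParams(alpha1=1.0, alpha2=0.0)  # irrelevant for empty obs
    d = lower.size

    if obs is None or obs.n == 0:
        dose_times = _EMPTY
        times = _EMPTY
        v = _EMPTY
        n_obs, use_n = _EMPTY, False
        patient_id = "" if obs is None else obs.patient_id
    else:
        dose_times = obs.schedule.dose_times
        times, v = obs.times, obs.v_obs
        use_n = obs.n_obs is not None
        n_obs = obs.n_obs if use_n else _EMPTY
        patient_id = obs.patient_id

    rng = np.random.default_rng(seed)
    keep = n_iter - n_iter // 2
    chains = []
    acc_rates = []
    for _ in range(n_chains):
        x0 = rng.uniform(lower, upper)
        draws, acc = _core.ram_chain(
            x0,
            lower,
            upper,
            dose_times,
            times,
            v,
            n_obs,
            use_n,
            0.0 if infer_noise else noise.alpha1,
            0.0 if infer_noise else noise.alpha2,
            infer_noise,
            n_iter,
            target_accept,
            int(rng.integers(2**31 - 1)),
        )
        chains.append(draws[n_iter // 2 :])
        acc_rates.append(acc)
    chains = np.array(chains)  # (n_chains, keep, d)

    rhat = split_rhat(chains)
    if check_convergence:
        if max(acc_rates) == 0.0:
            raise ConvergenceError(f"chain frozen for patient {patient_id!r}")
        if np.any(rhat > rhat_threshold):
            raise ConvergenceError(
                f"split-Rhat {rhat.round(3)} exceeds {rhat_threshold} "
                f"for patient {patient_id!r}"
            )

    # thin evenly across chains to thin_to pooled draws
    per_chain = max(1, thin_to // n_chains)
    idx = np.linspace(0, keep - 1, per_chain).round().astype(int)
    pooled = chains[:, idx].reshape(-1, d)
    chain_id = np.repeat(np.arange(n_chains), per_chain)
    return PosteriorSamples(
        draws=pooled,
        patient_id=patient_id,
        chain_id=chain_id,
        diagnostics={
            "acceptance_rate": float(np.mean(acc_rates)),
            "acceptance_rates": acc_rates,
            "split_rhat": rhat,
            "n_iter": n_iter,
            "n_chains": n_chains,
        },
        seed=seed,
    )


def pool_posteriors(
    per_patient: list[PosteriorSamples], weights: np.ndarray | None = None
) -> WeightedParticles:
    """Uniform mixture of per-patient posteriors (the full posterior).

    Requires equal per-patient sample counts (thin first); a non-uniform
    patient weighting may be supplied as a configuration hook.
    """
    if not per_patient:
        raise ValueError("need at least one patient posterior")
    counts = {p.draws.shape[0] for p in per_patient}
    if len(counts) != 1:
        raise ValueError(f"unequal per-patient sample counts {sorted(counts)}; thin first")
    s = counts.pop()
    n = len(per_patient)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    thetas = np.vstack([p.draws[:, :6] for p in per_patient])
    w = np.repeat(weights / s, s)
    ids = np.repeat([p.patient_id for p in per_patient], s)
    return WeightedParticles(
        thetas=thetas, weights=w, provenance="pooled_posterior", patient_ids=ids
    )


def build_second_level_prior(
    pooled: WeightedParticles,
    expansion: KernelExpansion,
    bounds: PriorSpec,
    seed: int,
    n_particles: int = 100_000,
    max_tries: int = 1_000_000,
) -> WeightedParticles:
    """Second-level prior p₂(θ): a truncated-kernel KDE expansion of the
    pooled posterior.

    Each output particle is a weighted draw from the pooled set plus a
    N(0, Σ_ε) perturbation, redrawn (keeping the base particle) until it lies
    inside the first-level prior box — i.e. truncated normal kernels.
    """
    rng = np.random.default_rng(seed)
    base = pooled.resample(n_particles, rng)
    sd = np.sqrt(expansion.sigma_eps)
    out = base + rng.standard_normal(base.shape) * sd
    bad = ~bounds.contains(out)
    tries = 1
    while np.any(bad):
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"{bad.sum()} truncated kernels failed to accept within "
                f"{max_tries} redraws"
            )
        k = int(bad.sum())
        out[bad] = base[bad] + rng.standard_normal((k, base.shape[1])) * sd
        bad[bad] = ~bounds.contains(out[bad])
    return WeightedParticles(
        thetas=out,
        weights=np.full(n_particles, 1.0 / n_particles),
        provenance="second_level_prior",
    )


def particle_filter_update(
    prior_particles: WeightedParticles,
    obs: ObservationSet | None,
    noise: NoiseParams,
) -> WeightedParticles:
    """Bootstrap particle filter: reweight prior particles by the likelihood.

    The parameters are static, so filtering the full record at once is exact;
    incremental weekly updates simply recompute weights from all data so far.
    An empty observation set returns the prior weights unchanged.
    """
    if obs is None or obs.n == 0:
        return WeightedParticles(
            thetas=prior_particles.thetas,
            weights=prior_particles.weights.copy(),
            provenance="filtered",
        )
    use_n = obs.n_obs is not None
    ll = np.empty(prior_particles.m)
    _core.batch_loglik(
        prior_particles.thetas,
        noise.alpha1,
        noise.alpha2,
        obs.schedule.dose_times,
        obs.times,
        obs.v_obs,
        obs.n_obs if use_n else _EMPTY,
        use_n,
        ll,
    )
    finite = np.isfinite(ll)
    if not np.any(finite & (prior_particles.weights > 0)):
        raise DegeneracyError(
            f"all particle weights vanished for patient {obs.patient_id!r}"
        )
    shift = ll[finite].max()
    w = np.where(finite, prior_particles.weights * np.exp(ll - shift), 0.0)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegeneracyError(
            f"all particle weights vanished for patient {obs.patient_id!r}"
        )
    return WeightedParticles(
        thetas=prior_particles.thetas, weights=w / total, provenance="filtered"
    )


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size 1/Σw² of normalized weights."""
    weights = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(weights**2))
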