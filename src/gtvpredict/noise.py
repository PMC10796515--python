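"""Statistical observation model linking model volumes to CT measurements.

Scan measurements are independent and normally distributed about the model
prediction, V_obs ~ N(V, σ²(V)) with σ(V) = α₁ + α₂V: α₁ is an absolute and
α₂ a relative noise contribution. The noise parameters are shared across
patients and are pre-estimated by inferring them jointly with the dynamical
parameters for each patient in a cohort, pooling equal numbers of posterior
samples, and taking the joint marginal mode of (α₁, α₂).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _core
from .model import DoseSchedule, ModelParams

__all__ = [
    "NoiseParams",
    "ObservationSet",
    "noise_sd",
    "add_noise",
    "log_likelihood",
    "estimate_noise_params",
    "NoiseEstimate",
]

_EMPTY = np.empty(0)


@dataclass(frozen=True)
class NoiseParams:
    """σ(V) = alpha1 + alpha2·V; alpha1 in fold-change units, alpha2 unitless."""

    alpha1: float
    alpha2: float

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("noise parameters must be non-negative")
        # alpha1 = alpha2 = 0 is permitted as the degenerate noise-free limit
        # (useful for exact synthetic measurements); the likelihood rejects it.


@dataclass(frozen=True)
class ObservationSet:
    """A patient's measurements plus dose schedule — the unit of inference.

    v_obs is the GTV in fold-change units relative to the first scan;
    initial_volume_cm3 retains the raw scale. n_obs optionally holds necrotic
    volume measurements (fold change) for the joint-observation scenario.
    """

    patient_id: str
    times: np.ndarray
    v_obs: np.ndarray
    schedule: DoseSchedule
    initial_volume_cm3: float = np.nan
    n_obs: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float).ravel()
        v = np.asarray(self.v_obs, dtype=float).ravel()
        if times.shape != v.shape:
            raise ValueError("times and v_obs must align")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError(f"times must be strictly increasing ({self.patient_id})")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite volume for patient {self.patient_id}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "v_obs", v)
        if self.n_obs is not None:
            n = np.asarray(self.n_obs, dtype=float).ravel()
            if n.shape != times.shape:
                raise ValueError("n_obs must align with times")
            object.__setattr__(self, "n_obs", n)

    @property
    def n(self) -> int:
        return self.times.size

    def truncated(self, upto_day: float) -> "ObservationSet":
        """Observations up to and including upto_day (schedule unchanged)."""
        keep = self.times <= upto_day
        return ObservationSet(
            patient_id=self.patient_id,
            times=self.times[keep],
            v_obs=self.v_obs[keep],
            schedule=self.schedule,
            initial_volume_cm3=self.initial_volume_cm3,
            n_obs=None if self.n_obs is None else self.n_obs[keep],
        )


def noise_sd(v, noise: NoiseParams):
    """Measurement standard deviation σ(V) = α₁ + α₂V."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    return noise.alpha1 + noise.alpha2 * v


def add_noise(measurements, noise: NoiseParams, seed) -> np.ndarray:
    """Perturb each measurement by N(0, σ²(v)); draws are not truncated, so
    small volumes can come out negative (as the plain-Normal model implies)."""
    rng = np.random.default_rng(seed)
    v = np.asarray(measurements, dtype=float)
    return v + rng.standard_normal(v.shape) * noise_sd(v, noise)


def log_likelihood(
    obs: ObservationSet, params: ModelParams, noise: NoiseParams
) -> float:
    """Sum of Normal log-densities of the observations about the simulated
    model volumes, with sd σ(V_model). With n_obs present, adds independent
    Normal terms for the necrotic compartment with the same noise parameters.

    Returns −inf when the parameters cannot be simulated (zero particle
    weight) rather than raising.
    """
    use_n = obs.n_obs is not None
    return float(
        _core.loglik(
            params.to_array(),
            noise.alpha1,
            noise.alpha2,
            obs.schedule.dose_times,
            obs.times,
            obs.v_obs,
            obs.n_obs if use_n else _EMPTY,
            use_n,
        )
    )


@dataclass
class NoiseEstimate:
    """Result of the cohort-level noise pre-estimation."""

    params: NoiseParams
    pooled_samples: np.ndarray  # (S, 2) pooled (α₁, α₂) posterior draws
    per_patient_acceptance: list = field(default_factory=list)


def _kde_mode_2d(samples: np.ndarray, grid: int = 200) -> tuple[float, float]:
    """Joint marginal mode of 2-D samples via a Silverman-bandwidth Gaussian
    KDE maximized on a grid over the samples' bounding box."""
    kde = stats.gaussian_kde(samples.T, bw_method="silverman")
    lo = samples.min(axis=0)
    hi = samples.max(axis=0)
    g1 = np.linspace(lo[0], hi[0], grid)
    g2 = np.linspace(lo[1], hi[1], grid)
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    dens = kde(np.vstack([G1.ravel(), G2.ravel()]))
    k = int(np.argmax(dens))
    return float(G1.ravel()[k]), float(G2.ravel()[k])


def estimate_noise_params(
    cohort: list,
    prior,
    seed: int,
    noise_upper: float = 0.5,
    n_iter: int = 25_000,
    n_chains: int = 4,
    samples_per_patient: int = 2_500,
    check_convergence: bool = False,
) -> NoiseEstimate:
    """Pre-estimate (α₁, α₂) from a cohort.

    Runs the joint 8-parameter adaptive MCMC (θ plus α₁, α₂ with independent
    Uniform(0, noise_upper) priors in natural space) for each patient, pools
    an equal number of (α₁, α₂) draws per patient, and returns the joint
    marginal posterior mode from a 2-D kernel density estimate.

    Per-patient posteriors are often multimodal (split-R̂ flags mode
    separation rather than sampler failure), and pooling across patients and
    chains is the point of the procedure — so the convergence check is off by
    default here; enable it to raise on poor diagnostics.
    """
    from .inference import sample_posterior_mcmc

    if len(cohort) < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    pooled = []
    acc = []
    for obs in cohort:
        post = sample_posterior_mcmc(
            obs,
            prior,
            noise=None,
            infer_noise=True,
            noise_upper=noise_upper,
            n_iter=n_iter,
            n_chains=n_chains,
            thin_to=samples_per_patient,
            seed=int(rng.integers(2**31 - 1)),
            check_convergence=check_convergence,
        )
        pooled.append(post.draws[:, 6:8])
        acc.append(post.diagnostics["acceptance_rate"])
    pooled = np.vstack(pooled)
    a1, a2 = _kde_mode_2d(pooled)
    return NoiseEstimate(
        params=NoiseParams(alpha1=max(a1, 0.0), alpha2=max(a2, 0.0)),
        pooled_samples=pooled,
        per_patient_acceptance=acc,
    )
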