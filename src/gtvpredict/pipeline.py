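"""End-to-end workflows: cohort training, real-time prediction, and
leave-one-out cross-validation.

Training runs the noise pre-estimation, per-patient adaptive MCMC under the
first-level box prior, pools the posteriors into the full posterior, and
expands it into the second-level prior. Real-time prediction filters the
second-level prior with a new patient's data up to each scan time and emits
trajectory bands, final-volume summaries and class probabilities. Every run
persists its configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CLASS_LABELS, ClassificationThresholds
from .inference import (
    PriorSpec,
    WeightedParticles,
    build_second_level_prior,
    particle_filter_update,
    pool_posteriors,
    sample_posterior_mcmc,
    silverman_covariance,
)
from .model import standard_schedule
from .noise import NoiseEstimate, NoiseParams, ObservationSet, estimate_noise_params
from .predict import predict_class_probs, predict_final_volume, predict_trajectory

__all__ = ["RunConfig", "TrainingResult", "run_training", "run_realtime_prediction", "run_loocv"]

logger = logging.getLogger("gtvpredict")


@dataclass
class RunConfig:
    """All tunables of the pipeline, serialized alongside every output."""

    prior_lower: tuple = (-10.0, 0.0, -10.0, -10.0, -10.0, -5.0)
    prior_upper: tuple = (0.0, 5.0, 0.0, 3.0, 3.0, 0.0)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    mcmc_iters: int = 25_000
    mcmc_chains: int = 4
    samples_per_patient: int = 2_500
    beta: float = 2.0
    n_p2_particles: int = 100_000
    noise_upper: float = 0.5
    schedule_start_day: float = 14.0
    schedule_weeks: int = 6
    horizon: float = 56.0

    @property
    def prior(self) -> PriorSpec:
        return PriorSpec(np.array(self.prior_lower), np.array(self.prior_upper))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d


@dataclass
class TrainingResult:
    noise: NoiseEstimate
    posteriors: list
    pooled: WeightedParticles
    second_level_prior: WeightedParticles
    config: RunConfig
    seed: int


def run_training(
    cohort: list[ObservationSet],
    config: RunConfig | None = None,
    seed: int = 0,
    outdir=None,
    noise: NoiseParams | None = None,
) -> TrainingResult:
    """Full training pass over a cohort.

    A pre-estimated NoiseParams may be supplied to skip the (costly) joint
    noise inference; otherwise it is estimated from the cohort first.
    """
    config = config or RunConfig()
    if len(cohort) < 2:
        raise ValueError("need at least 2 training patients")
    rng = np.random.default_rng(seed)
    prior = config.prior

    if noise is None:
        logger.info("pre-estimating noise parameters on %d patients", len(cohort))
        noise_est = estimate_noise_params(
            cohort,
            prior,
            seed=int(rng.integers(2**31 - 1)),
            noise_upper=config.noise_upper,
            n_iter=config.mcmc_iters,
            n_chains=config.mcmc_chains,
            samples_per_patient=config.samples_per_patient,
        )
    else:
        noise_est = NoiseEstimate(params=noise, pooled_samples=np.empty((0, 2)))
    logger.info("noise parameters: %s", noise_est.params)

    posteriors = []
    for obs in cohort:
        post = sample_posterior_mcmc(
            obs,
            prior,
            noise_est.params,
            seed=int(rng.integers(2**31 - 1)),
            n_iter=config.mcmc_iters,
            n_chains=config.mcmc_chains,
            thin_to=config.samples_per_patient,
            check_convergence=False,
        )
        logger.info(
            "patient %s: acceptance %.3f, max split-Rhat %.3f",
            obs.patient_id,
            post.diagnostics["acceptance_rate"],
            float(np.max(post.diagnostics["split_rhat"])),
        )
        posteriors.append(post)

    pooled = pool_posteriors(posteriors)
    expansion = silverman_covariance(pooled, beta=config.beta)
    p2 = build_second_level_prior(
        pooled,
        expansion,
        bounds=prior,
        seed=int(rng.integers(2**31 - 1)),
        n_particles=config.n_p2_particles,
    )
    result = TrainingResult(
        noise=noise_est,
        posteriors=posteriors,
        pooled=pooled,
        second_level_prior=p2,
        config=config,
        seed=seed,
    )
    if outdir is not None:
        _persist_training(result, outdir)
    return result


def _persist_training(result: TrainingResult, outdir) -> None:
    from .io import write_particles, write_posterior_samples

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": result.seed,
        "config": result.config.to_dict(),
        "noise": {
            "alpha1": result.noise.params.alpha1,
            "alpha2": result.noise.params.alpha2,
        },
    }
    (outdir / "run_config.json").write_text(json.dumps(meta, indent=1))
    write_posterior_samples(result.posteriors, outdir / "posterior_samples.csv")
    write_particles(result.pooled, outdir / "pooled_particles.csv")
    write_particles(result.second_level_prior, outdir / "second_level_prior.csv")


def run_realtime_prediction(
    patient: ObservationSet,
    prior_particles: WeightedParticles,
    noise: NoiseParams,
    config: RunConfig | None = None,
    prediction_times: np.ndarray | None = None,
    trajectory_grid: np.ndarray | None = None,
) -> dict:
    """Weekly filtered predictions for one patient.

    For each prediction time (defaulting to the patient's scan times,
    including the pre-treatment scan), the second-level prior is reweighted
    by all data up to and including that time, and the filtered particles are
    summarized into a trajectory band, a final-volume summary at the horizon,
    and class probabilities. Returns {"summaries": [...], "class_probs":
    DataFrame}.
    """
    config = config or RunConfig()
    if prediction_times is None:
        prediction_times = patient.times
    if trajectory_grid is None:
        trajectory_grid = np.linspace(0.0, config.horizon, 57)
    schedule, measurements = standard_schedule(
        config.schedule_start_day, config.schedule_weeks
    )
    summaries = []
    prob_rows = []
    for t_pred in np.asarray(prediction_times, dtype=float):
        filtered = particle_filter_update(
            prior_particles, patient.truncated(t_pred), noise
        )
        if filtered.ess < 2.0:
            # degenerate filter: the prior poorly represents this patient;
            # summaries collapse toward the surviving particles
            logger.warning(
                "filter degeneracy for %s at day %.0f (ESS=%.2f)",
                patient.patient_id,
                t_pred,
                filtered.ess,
            )
        traj = predict_trajectory(
            filtered, patient.schedule, trajectory_grid, min_ess=1.0
        )
        final = predict_final_volume(
            filtered, patient.schedule, config.horizon, min_ess=1.0
        )
        probs = predict_class_probs(
            filtered, schedule, measurements, config.thresholds
        )
        summaries.append(
            {
                "prediction_time": float(t_pred),
                "n_obs_used": int((patient.times <= t_pred).sum()),
                "ess": filtered.ess,
                "trajectory": traj,
                "final_volume": final,
                "class_probs": probs,
            }
        )
        prob_rows.append(
            {
                "prediction_time": float(t_pred),
                **{f"p_{c.value}": probs[c.value] for c in CLASS_LABELS},
                "p_eventual": probs["eventual_response"],
            }
        )
    return {"summaries": summaries, "class_probs": pd.DataFrame(prob_rows)}


def run_loocv(
    cohort: list[ObservationSet],
    config: RunConfig | None = None,
    seed: int = 0,
    noise: NoiseParams | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validation over a cohort.

    Each patient is predicted from a pooled posterior trained on the other
    patients; the report lists the retrospective final-volume prediction and
    its interval, plus the posterior class mode.
    """
    config = config or RunConfig()
    if len(cohort) < 3:
        raise ValueError("need at least 3 patients for leave-one-out")
    rows = []
    rng = np.random.default_rng(seed)
    for i, held_out in enumerate(cohort):
        training = [p for p in cohort if p is not held_out]
        assert all(p.patient_id != held_out.patient_id for p in training)
        result = run_training(
            training, config, seed=int(rng.integers(2**31 - 1)), noise=noise
        )
        pred = run_realtime_prediction(
            held_out,
            result.second_level_prior,
            result.noise.params,
            config,
            prediction_times=np.array([held_out.times[-1]]),
        )
        summ = pred["summaries"][-1]
        final = summ["final_volume"]
        probs = summ["class_probs"]
        mode = max(
            (c.value for c in CLASS_LABELS), key=lambda c: probs[c]
        )
        rows.append(
            {
                "patient_id": held_out.patient_id,
                "final_obs": held_out.v_obs[-1],
                "final_pred_mean": final["mean"],
                "final_pred_q025": final["q025"],
                "final_pred_q975": final["q975"],
                "covered": final["q025"] <= held_out.v_obs[-1] <= final["q975"],
                "class_mode": mode,
                "ess": summ["ess"],
            }
        )
    return pd.DataFrame(rows)
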