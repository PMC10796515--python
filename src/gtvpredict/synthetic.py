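"""Synthetic patients and cohorts.

Parameters are drawn either from a box prior or from a weighted particle set
(e.g. a pooled posterior), patients are exposed to the standard six-week
weekday radiotherapy regime with weekly scans, and measurement noise is added
exactly per the observation model V_obs ~ N(V, (α₁+α₂V)²). Class-conditional
patients are produced by rejection on the noise-free classification — the
noise model is never adjusted. Negative noisy volumes are possible under the
plain-Normal model and are kept (their frequency is recorded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (
    CLASS_LABELS,
    ClassificationThresholds,
    ResponseClass,
    classify_thetas,
)
from .inference import PriorSpec, WeightedParticles
from .model import (
    DoseSchedule,
    MeasurementTimes,
    ModelParams,
    simulate,
    standard_schedule,
)
from .noise import NoiseParams, ObservationSet, add_noise

__all__ = [
    "SyntheticPatient",
    "generate_patient",
    "generate_cohort",
    "prior_predictive_class_probs",
    "DEFAULT_FIXTURE_NOISE",
]

# default fixture noise level, declared in every cohort manifest
DEFAULT_FIXTURE_NOISE = NoiseParams(alpha1=0.05, alpha2=0.10)

# initial GTV in cm³ is drawn from a lognormal matched to a clinically
# plausible head-and-neck distribution (mean ~17 cm³, sd ~12 cm³)
_V0_MEAN_CM3 = 17.0
_V0_SD_CM3 = 12.0


@dataclass
class SyntheticPatient:
    """A simulated patient: ground truth plus the noisy observation set."""

    patient_id: str
    params: ModelParams
    schedule: DoseSchedule
    measurements: MeasurementTimes
    v_true: np.ndarray  # noise-free V at measurement times
    n_true: np.ndarray  # noise-free N at measurement times
    observations: ObservationSet
    true_class: ResponseClass
    seed: int

    @property
    def final_volume_true(self) -> float:
        return float(self.v_true[-1])


def _draw_theta(source, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(source, PriorSpec):
        return source.sample(n, rng)
    if isinstance(source, WeightedParticles):
        return source.resample(n, rng)
    raise TypeError(f"source must be PriorSpec or WeightedParticles, got {type(source)}")


def generate_patient(
    source,
    noise: NoiseParams = DEFAULT_FIXTURE_NOISE,
    seed: int = 0,
    target_class: ResponseClass | None = None,
    schedule: DoseSchedule | None = None,
    measurements: MeasurementTimes | None = None,
    thresholds: ClassificationThresholds | None = None,
    patient_id: str = "synthetic",
    with_necrosis: bool = False,
    rejection_cap: int = 1_000_000,
) -> SyntheticPatient:
    """Generate one synthetic patient; regeneration from the seed is
    bit-identical.

    With target_class set, parameter draws are rejected until the noise-free
    simulation classifies as requested (cap `rejection_cap` draws).
    """
    if schedule is None or measurements is None:
        schedule, measurements = standard_schedule()
    rng = np.random.default_rng(seed)
    target_idx = None if target_class is None else CLASS_LABELS.index(target_class)

    batch = 1 if target_idx is None else 256
    drawn = 0
    theta = None
    cls_idx = None
    while theta is None:
        cand = _draw_theta(source, rng, batch)
        drawn += batch
        idx = classify_thetas(cand, schedule, measurements, thresholds)
        if target_idx is None:
            theta, cls_idx = cand[0], int(idx[0])
        else:
            hits = np.where(idx == target_idx)[0]
            if hits.size:
                theta, cls_idx = cand[hits[0]], target_idx
            elif drawn >= rejection_cap:
                raise RuntimeError(
                    f"no draw classified as {target_class.value!r} within "
                    f"{rejection_cap} attempts"
                )
    params = ModelParams.from_log(theta)
    traj = simulate(params, schedule, measurements.times)
    v_noisy = add_noise(traj.V, noise, seed=rng.integers(2**31 - 1))
    n_noisy = None
    if with_necrosis:
        n_noisy = add_noise(traj.N, noise, seed=rng.integers(2**31 - 1))
    v0 = float(
        rng.lognormal(
            mean=np.log(_V0_MEAN_CM3**2 / np.sqrt(_V0_MEAN_CM3**2 + _V0_SD_CM3**2)),
            sigma=np.sqrt(np.log1p(_V0_SD_CM3**2 / _V0_MEAN_CM3**2)),
        )
    )
    obs = ObservationSet(
        patient_id=patient_id,
        times=measurements.times,
        v_obs=v_noisy,
        schedule=schedule,
        initial_volume_cm3=v0,
        n_obs=n_noisy,
    )
    return SyntheticPatient(
        patient_id=patient_id,
        params=params,
        schedule=schedule,
        measurements=measurements,
        v_true=traj.V,
        n_true=traj.N,
        observations=obs,
        true_class=CLASS_LABELS[cls_idx],
        seed=seed,
    )


def generate_cohort(
    n_patients: int,
    source,
    noise: NoiseParams = DEFAULT_FIXTURE_NOISE,
    seed: int = 0,
    class_mix: dict | None = None,
    outdir=None,
    **patient_kwargs,
) -> list[SyntheticPatient]:
    """Generate a cohort; optionally write the patient/schedule CSV schema
    plus a JSON manifest recording seeds, noise level and true parameters.

    class_mix maps class labels to proportions (e.g. {"fast_responder": 1.0});
    unlisted classes get the remaining probability spread as unconditional
    draws.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    targets: list[ResponseClass | None] = []
    if class_mix:
        mix = {ResponseClass(k): float(v) for k, v in class_mix.items()}
        labels = list(mix)
        probs = np.array([mix[k] for k in labels])
        rest = 1.0 - probs.sum()
        if rest < -1e-9:
            raise ValueError("class_mix proportions exceed 1")
        choices = labels + [None]
        p = np.append(probs, max(rest, 0.0))
        draw = rng.choice(len(choices), size=n_patients, p=p / p.sum())
        targets = [choices[k] for k in draw]
    else:
        targets = [None] * n_patients

    cohort = []
    for i in range(n_patients):
        cohort.append(
            generate_patient(
                source,
                noise=noise,
                seed=int(rng.integers(2**31 - 1)),
                target_class=targets[i],
                patient_id=f"synth_{i:03d}",
                **patient_kwargs,
            )
        )
    if outdir is not None:
        from .io import write_cohort

        write_cohort(cohort, outdir, noise=noise, seed=seed)
    return cohort


def prior_predictive_class_probs(
    source,
    n_samples: int = 10_000,
    seed: int = 0,
    schedule: DoseSchedule | None = None,
    measurements: MeasurementTimes | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> dict:
    """Monte Carlo class proportions of noise-free simulations from a prior.

    Samples θ from the box prior (or resamples a particle set), classifies
    each under the standard schedule, and returns per-class proportions, the
    eventual-response proportion, and binomial Monte Carlo standard errors.
    """
    if n_samples < 1000:
        raise ValueError("need at least 1000 samples for stable proportions")
    rng = np.random.default_rng(seed)
    thetas = _draw_theta(source, rng, n_samples)
    idx = classify_thetas(thetas, schedule, measurements, thresholds)
    out = {}
    for k, label in enumerate(CLASS_LABELS):
        prop = float(np.mean(idx == k))
        out[label.value] = prop
        out[label.value + "_se"] = float(np.sqrt(prop * (1 - prop) / n_samples))
    ev = 1.0 - out[ResponseClass.POOR.value]
    out["eventual_response"] = ev
    out["eventual_response_se"] = float(np.sqrt(ev * (1 - ev) / n_samples))
    out["n_samples"] = n_samples
    return out
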