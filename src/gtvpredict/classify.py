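"""Four-class radiotherapy response classification.

Classification operates on *noise-free* model volumes at the standard
classification scans (start of each treatment week plus the final dose),
normalized to the start-of-treatment volume. The pre-treatment scan is never
used. Criteria, applied in order:

poor responder      all measurements above 85% of the start-of-treatment volume
pseudo-progressor   (a responder whose) second post-onset measurement exceeds
                    102% of the first
plateaued response  not a pseudo-progressor; final measurement above 20% with a
                    final rate-of-change below 10% of the maximum rate-of-change
fast responder      any other responder

"Rate-of-change" is the magnitude of the finite difference between successive
classification measurements divided by the time gap; "final" is the last such
difference and "maximum" the largest magnitude in the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model import DoseSchedule, MeasurementTimes, ModelParams, simulate, standard_schedule

__all__ = [
    "ResponseClass",
    "ClassificationThresholds",
    "classify_series",
    "classify_params",
    "classify_thetas",
    "class_proportions",
    "CLASS_LABELS",
]


class ResponseClass(str, Enum):
    FAST = "fast_responder"
    POOR = "poor_responder"
    PLATEAUED = "plateaued"
    PSEUDO = "pseudo_progressor"

    @property
    def eventual_response(self) -> bool:
        """True for every class except a poor responder."""
        return self is not ResponseClass.POOR


CLASS_LABELS = (
    ResponseClass.FAST,
    ResponseClass.POOR,
    ResponseClass.PLATEAUED,
    ResponseClass.PSEUDO,
)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Dimensionless classification thresholds (configurable; the defaults are
    the criteria calibrated against the clinical cohort)."""

    responder_floor: float = 0.85
    pseudo_rise: float = 1.02
    plateau_final_floor: float = 0.20
    plateau_rate_frac: float = 0.10

    def __post_init__(self):
        for name in (
            "responder_floor",
            "pseudo_rise",
            "plateau_final_floor",
            "plateau_rate_frac",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.responder_floor < 1 < self.pseudo_rise:
            raise ValueError("need responder_floor < 1 < pseudo_rise")


def _classify_matrix(
    volumes: np.ndarray,
    times: np.ndarray,
    thresholds: ClassificationThresholds,
) -> np.ndarray:
    """Vectorized classification of rows of `volumes` (already at the
    classification times); returns an integer index into CLASS_LABELS."""
    v = volumes / volumes[:, :1]
    poor = np.all(v > thresholds.responder_floor, axis=1)
    pseudo = ~poor & (v[:, 1] > thresholds.pseudo_rise * v[:, 0])
    dt = np.diff(times)
    rates = np.abs(np.diff(v, axis=1)) / dt
    plateau = (
        ~poor
        & ~pseudo
        & (v[:, -1] > thresholds.plateau_final_floor)
        & (rates[:, -1] < thresholds.plateau_rate_frac * rates.max(axis=1))
    )
    out = np.zeros(v.shape[0], dtype=np.intp)  # fast
    out[poor] = 1
    out[plateau] = 2
    out[pseudo] = 3
    return out


def classify_series(
    times: np.ndarray,
    volumes: np.ndarray,
    thresholds: ClassificationThresholds | None = None,
) -> ResponseClass:
    """Classify one noise-free series of classification measurements.

    `volumes` must be normalized to the start-of-treatment measurement (first
    entry 1); a non-normalized series triggers a warning and is normalized.
    """
    thresholds = thresholds or ClassificationThresholds()
    times = np.asarray(times, dtype=float).ravel()
    volumes = np.asarray(volumes, dtype=float).ravel()
    if volumes.size < 3:
        raise ValueError(
            f"need at least 3 classification measurements, got {volumes.size}"
        )
    if times.shape != volumes.shape:
        raise ValueError("times and volumes must align")
    if abs(volumes[0] - 1.0) > 1e-8:
        warnings.warn(
            "series is not normalized to the start-of-treatment volume; "
            "normalizing by the first measurement",
            stacklevel=2,
        )
    idx = _classify_matrix(volumes[None, :], times, thresholds)[0]
    return CLASS_LABELS[idx]


def classify_params(
    params: ModelParams,
    schedule: DoseSchedule | None = None,
    measurements: MeasurementTimes | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> ResponseClass:
    """Simulate noise-free under the (standard) schedule and classify."""
    if schedule is None or measurements is None:
        schedule, measurements = standard_schedule()
    cls_times = measurements.classification_times
    traj = simulate(params, schedule, cls_times)
    v = traj.V / traj.V[0]
    return classify_series(cls_times, v, thresholds)


def classify_thetas(
    thetas: np.ndarray,
    schedule: DoseSchedule | None = None,
    measurements: MeasurementTimes | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> np.ndarray:
    """Classify many log-parameter vectors at once.

    Returns an integer array indexing CLASS_LABELS; rows whose simulation
    fails raise (all box-prior parameters are simulable).
    """
    from . import _core

    thresholds = thresholds or ClassificationThresholds()
    if schedule is None or measurements is None:
        schedule, measurements = standard_schedule()
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    cls_times = measurements.classification_times
    V = np.empty((thetas.shape[0], cls_times.size))
    _core.batch_volumes(thetas, schedule.dose_times, cls_times, V)
    if np.any(~np.isfinite(V)):
        bad = np.where(~np.isfinite(V).all(axis=1))[0]
        raise ValueError(f"simulation failed for particle rows {bad[:5]}...")
    return _classify_matrix(V, cls_times, thresholds)


def class_proportions(
    particles,
    schedule: DoseSchedule | None = None,
    measurements: MeasurementTimes | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> dict:
    """Weighted response-class proportions of a particle set.

    Accepts a WeightedParticles or a bare (M, 6) array of log parameters
    (uniform weights). Returns {label: proportion} for the four classes plus
    'eventual_response' = 1 − P(poor).
    """
    thetas = getattr(particles, "thetas", None)
    if thetas is None:
        thetas = np.atleast_2d(np.asarray(particles, dtype=float))
        if thetas.shape[0] == 0 or thetas.size == 0:
            raise ValueError("empty particle set")
        weights = np.full(thetas.shape[0], 1.0 / thetas.shape[0])
    else:
        weights = particles.weights
    if thetas.shape[0] == 0:
        raise ValueError("empty particle set")
    idx = classify_thetas(thetas, schedule, measurements, thresholds)
    props = {
        label.value: float(weights[idx == k].sum())
        for k, label in enumerate(CLASS_LABELS)
    }
    props["eventual_response"] = 1.0 - props[ResponseClass.POOR.value]
    return props
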