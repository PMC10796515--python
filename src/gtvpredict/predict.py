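"""Clinical outputs from weighted particle sets, and evaluation statistics.

Trajectory bands and final-volume summaries are weighted means and weighted
quantiles of noise-free model volumes simulated per particle; class
probability traces are weighted class proportions. Goodness-of-fit uses the
Bayesian R² statistic (per posterior sample, summarized by the median), and
cohort summary statistics are compared with Welch's unequal-variance t-test
with fractional counts (probabilistic classification makes the per-class
counts non-integer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _core
from .classify import ClassificationThresholds, class_proportions
from .inference import WeightedParticles
from .model import DoseSchedule, MeasurementTimes, standard_schedule
from .noise import NoiseParams, noise_sd

__all__ = [
    "PredictionSummary",
    "predict_trajectory",
    "predict_final_volume",
    "predict_class_probs",
    "weighted_quantile",
    "bayesian_r2",
    "welch_summary_test",
    "class_volume_stats",
]


@dataclass
class PredictionSummary:
    """Weighted mean and 50%/95% bands of predicted volume over time."""

    times: np.ndarray
    mean: np.ndarray
    q025: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    q975: np.ndarray
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "mean": self.mean,
                "q025": self.q025,
                "q25": self.q25,
                "q75": self.q75,
                "q975": self.q975,
            }
        )


def weighted_quantile(values: np.ndarray, q, weights: np.ndarray) -> np.ndarray:
    """Left-continuous inverse of the weighted empirical CDF.

    Returns the smallest value v with F(v) >= q.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    q = np.atleast_1d(np.asarray(q, dtype=float))
    idx = np.searchsorted(cw, q, side="left")
    idx = np.minimum(idx, v.size - 1)
    out = v[idx]
    return out if out.size > 1 else float(out[0])


def _particle_volumes(
    particles: WeightedParticles, schedule: DoseSchedule, times: np.ndarray
) -> np.ndarray:
    times = np.asarray(times, dtype=float).ravel()
    V = np.empty((particles.m, times.size))
    _core.batch_volumes(particles.thetas, schedule.dose_times, times, V)
    return V


def predict_trajectory(
    particles: WeightedParticles,
    schedule: DoseSchedule,
    times: np.ndarray,
    noise: NoiseParams | None = None,
    noise_seed: int | None = None,
    min_ess: float = 2.0,
) -> PredictionSummary:
    """Weighted mean and quantile bands of the noise-free volume at `times`.

    With `noise` given, the bands are observation-level instead: each
    particle's trajectory is perturbed by one N(0, σ²(V)) draw (seeded), so
    the quantiles describe a future measurement rather than the modelled
    observation mean. Particles whose simulation fails are dropped with the
    remaining weights renormalized (the count is reported).
    """
    if particles.ess < min_ess:
        raise ValueError(
            f"particle set too degenerate to summarize (ESS={particles.ess:.2f})"
        )
    V = _particle_volumes(particles, schedule, times)
    ok = np.all(np.isfinite(V), axis=1)
    n_dropped = int((~ok).sum())
    V = V[ok]
    w = particles.weights[ok]
    w = w / w.sum()
    if noise is not None:
        rng = np.random.default_rng(noise_seed)
        V = V + rng.standard_normal(V.shape) * noise_sd(np.maximum(V, 0.0), noise)
    mean = w @ V
    qs = np.empty((4, V.shape[1]))
    for j in range(V.shape[1]):
        qs[:, j] = weighted_quantile(V[:, j], [0.025, 0.25, 0.75, 0.975], w)
    return PredictionSummary(
        times=np.asarray(times, dtype=float).ravel(),
        mean=mean,
        q025=qs[0],
        q25=qs[1],
        q75=qs[2],
        q975=qs[3],
        n_dropped=n_dropped,
    )


def predict_final_volume(
    particles: WeightedParticles,
    schedule: DoseSchedule,
    horizon: float = 56.0,
    min_ess: float = 2.0,
) -> dict:
    """Weighted mean and 50%/95% intervals of V(horizon)/V(0)."""
    summ = predict_trajectory(particles, schedule, np.array([horizon]), min_ess=min_ess)
    return {
        "horizon": float(horizon),
        "mean": float(summ.mean[0]),
        "q025": float(summ.q025[0]),
        "q25": float(summ.q25[0]),
        "q75": float(summ.q75[0]),
        "q975": float(summ.q975[0]),
    }


def predict_class_probs(
    particles: WeightedParticles,
    schedule: DoseSchedule | None = None,
    measurements: MeasurementTimes | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> dict:
    """Weighted response-class probabilities of a particle set under the
    standard schedule. With prior particles (no data filtered in) this
    reproduces the prior's class proportions."""
    if schedule is None or measurements is None:
        schedule, measurements = standard_schedule()
    return class_proportions(particles, schedule, measurements, thresholds)


def bayesian_r2(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Median over posterior samples of R² = Var(V_fit)/(Var(V_fit)+Var(V_fit−V_obs)).

    `fitted` is (S, T) per-sample fitted values at the T observation times (a
    single (T,) row is allowed); variances are sample (n−1) variances. The
    degenerate 0/0 case (constant fit, zero residual variance) is defined as
    0 with a warning.
    """
    fitted = np.atleast_2d(np.asarray(fitted, dtype=float))
    observed = np.asarray(observed, dtype=float).ravel()
    if observed.size < 2:
        raise ValueError("need at least 2 observations")
    if fitted.shape[1] != observed.size:
        raise ValueError("fitted and observed must align")
    var_fit = fitted.var(axis=1, ddof=1)
    var_res = (fitted - observed).var(axis=1, ddof=1)
    denom = var_fit + var_res
    r2 = np.empty(fitted.shape[0])
    zero = denom == 0
    if np.any(zero):
        warnings.warn("constant fit with zero residual variance; R^2 defined as 0",
                      stacklevel=2)
    r2[zero] = 0.0
    r2[~zero] = var_fit[~zero] / denom[~zero]
    return float(np.median(r2))


def welch_summary_test(
    mean1: float, sd1: float, n1: float, mean2: float, sd2: float, n2: float
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary statistics.

    Counts may be fractional (probabilistic classification); the
    Welch–Satterthwaite degrees of freedom are used without rounding and the
    two-sided p-value comes from the t-distribution with fractional df.
    Returns (t, df, p).
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError("counts must exceed 1")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    se1, se2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def class_volume_stats(
    class_probs: np.ndarray, initial_volumes_cm3: np.ndarray
) -> pd.DataFrame:
    """Per-class fractional counts and weighted initial-volume statistics.

    class_probs is (n_patients, 4) with rows summing to 1 (columns in the
    order fast, poor, plateaued, pseudo). The fractional count of class c is
    Σᵢ p_ic, its mean Σᵢ p_ic vᵢ / count, and its std the weighted standard
    deviation about that mean. Classes with zero count get NaN statistics.
    """
    from .classify import CLASS_LABELS

    p = np.asarray(class_probs, dtype=float)
    v = np.asarray(initial_volumes_cm3, dtype=float).ravel()
    if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] != v.size:
        raise ValueError("class_probs must be (n_patients, 4) aligned with volumes")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("per-patient class probabilities must sum to 1")
    rows = []
    for c, label in enumerate(CLASS_LABELS):
        count = p[:, c].sum()
        if count > 0:
            mean = float(p[:, c] @ v / count)
            std = float(np.sqrt(p[:, c] @ (v - mean) ** 2 / count))
        else:
            mean = std = np.nan
        rows.append(
            {"class": label.value, "count": float(count), "mean": mean, "std": std}
        )
    return pd.DataFrame(rows).set_index("class")
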