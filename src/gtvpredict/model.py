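"""Two-compartment tumour-volume model with impulsive radiotherapy dosing.

The gross tumour volume (GTV) is V(t) = L(t) + N(t), where L is the living
volume and N necrotic debris, both in fold-change units relative to the
initial GTV so that V(0) = 1. Between radiotherapy fractions,

    dL/dt = λ L (1 − L/K) − η L,
    dN/dt = η L − ζ N,

with proliferation rate λ [d⁻¹], carrying capacity K (fold change), necrosis
rate η [d⁻¹] and necrotic decay rate ζ [d⁻¹]. Each fraction at time tᵢ
instantaneously transfers a volume γL from the living to the necrotic
compartment (0 < γ < 1), leaving V continuous across dose instants. The
initial composition is L(0) = 1 − φ₀, N(0) = φ₀.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core

__all__ = [
    "ModelParams",
    "TumourState",
    "DoseSchedule",
    "MeasurementTimes",
    "Trajectory",
    "initial_state",
    "apply_dose",
    "integrate_smooth",
    "simulate",
    "standard_schedule",
]

PARAM_NAMES = ("lam", "K", "gamma", "zeta", "eta", "phi0")
LOG_PARAM_NAMES = tuple(f"log_{n}" for n in PARAM_NAMES)


@dataclass(frozen=True)
class ModelParams:
    """Patient-specific dynamical parameters, all strictly positive.

    lam    proliferation rate [d⁻¹]
    K      carrying capacity (fold change relative to initial GTV)
    gamma  per-fraction radiotherapy transfer fraction, in (0, 1)
    zeta   necrotic decay rate [d⁻¹]
    eta    necrosis rate [d⁻¹]
    phi0   initial necrotic proportion, in (0, 1)
    """

    lam: float
    K: float
    gamma: float
    zeta: float
    eta: float
    phi0: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.gamma >= 1:
            raise ValueError(f"gamma must be < 1, got {self.gamma!r}")
        if self.phi0 >= 1:
            raise ValueError(f"phi0 must be < 1, got {self.phi0!r}")

    def to_array(self) -> np.ndarray:
        """Natural-space vector (λ, K, γ, ζ, η, φ₀)."""
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def to_log(self) -> np.ndarray:
        """Log-space vector θ = (log λ, log K, log γ, log ζ, log η, log φ₀)."""
        return np.log(self.to_array())

    @classmethod
    def from_log(cls, theta: np.ndarray) -> "ModelParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (6,):
            raise ValueError(f"theta must have shape (6,), got {theta.shape}")
        return cls(*np.exp(theta))


@dataclass(frozen=True)
class TumourState:
    """Instantaneous model state: living and necrotic volume at time t [days]."""

    L: float
    N: float
    t: float = 0.0

    def __post_init__(self):
        if self.L < 0 or self.N < 0:
            raise ValueError(f"compartment volumes must be >= 0, got {self}")

    @property
    def V(self) -> float:
        return self.L + self.N


@dataclass(frozen=True)
class DoseSchedule:
    """Radiotherapy fraction times in days (sorted, distinct).

    dose_gy is recorded metadata only (all clinical fractions are 2 Gy); the
    dynamics respond identically to every fraction through γ.
    """

    dose_times: np.ndarray
    dose_gy: float = 2.0

    def __post_init__(self):
        times = np.asarray(self.dose_times, dtype=float).ravel()
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("dose_times must be strictly increasing")
        object.__setattr__(self, "dose_times", times)

    @property
    def n_doses(self) -> int:
        return self.dose_times.size


@dataclass(frozen=True)
class MeasurementTimes:
    """Scan times in days; is_classification flags the scans the response
    classifier uses (the pre-treatment scan at day 0 is excluded)."""

    times: np.ndarray
    is_classification: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float).ravel()
        mask = np.asarray(self.is_classification, dtype=bool).ravel()
        if times.shape != mask.shape:
            raise ValueError("times and is_classification must align")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "is_classification", mask)

    @property
    def classification_times(self) -> np.ndarray:
        return self.times[self.is_classification]


@dataclass(frozen=True)
class Trajectory:
    """Model output at requested times; V = L + N everywhere. At times that
    coincide with a dose, L and N are post-dose (V is unaffected by dosing)."""

    times: np.ndarray
    L: np.ndarray
    N: np.ndarray
    is_dose: np.ndarray = field(default=None)

    @property
    def V(self) -> np.ndarray:
        return self.L + self.N


def initial_state(phi0: float) -> TumourState:
    """Initial composition L = 1 − φ₀, N = φ₀ (fold-change normalization V(0)=1)."""
    if not 0 < phi0 < 1:
        raise ValueError(f"phi0 must lie in (0, 1), got {phi0!r}")
    return TumourState(L=1.0 - phi0, N=phi0, t=0.0)


def apply_dose(state: TumourState, gamma: float) -> TumourState:
    """Instantaneous fraction: L⁺ = (1−γ)L⁻, N⁺ = N⁻ + γL⁻ (V conserved).

    This takes the impulsive transfer "a volume γL moves from living to
    necrotic" literally; the alternative convention L⁺ = e^{−γ}L⁻ obtained by
    integrating dL/L through the delta impulse is deliberately not used, and
    this function is the single place the convention lives.
    """
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma!r}")
    transfer = gamma * state.L
    return TumourState(L=state.L - transfer, N=state.N + transfer, t=state.t)


def integrate_smooth(
    state: TumourState, params: ModelParams, t0: float, t1: float
) -> TumourState:
    """Advance the dose-free dynamics from t0 to t1.

    L is advanced with the closed-form logistic solution and N with an exact
    exponential integrator (composite Gauss–Legendre for the convolution with
    e^{−ζ(t−s)}); accuracy is well below 1e−8 relative for the box-prior
    parameter ranges.
    """
    if t1 < t0:
        raise ValueError(f"t1 must be >= t0, got [{t0}, {t1}]")
    L, N = _core.advance_segment(
        state.L, state.N, params.lam, params.K, params.eta, params.zeta, t1 - t0
    )
    if not (np.isfinite(L) and np.isfinite(N)):
        raise ArithmeticError(
            f"integration failed on [{t0}, {t1}] with params {params}"
        )
    return TumourState(L=L, N=N, t=t1)


def simulate(
    params: ModelParams,
    schedule: DoseSchedule,
    obs_times: np.ndarray,
) -> Trajectory:
    """Simulate the model from t = 0, returning noise-free values at obs_times.

    Alternates smooth integration with instantaneous dose transfers. When an
    observation coincides with a dose, V is unambiguous (conserved across the
    jump) and L, N are reported post-dose.
    """
    obs_times = np.asarray(obs_times, dtype=float).ravel()
    if obs_times.size and obs_times[0] < 0:
        raise ValueError("observation times must be >= 0 (t = 0 is diagnosis)")
    if obs_times.size and np.any(np.diff(obs_times) < 0):
        raise ValueError("observation times must be sorted")
    L = np.empty(obs_times.size)
    N = np.empty(obs_times.size)
    status = _core.simulate_ln(
        params.to_array(), schedule.dose_times, obs_times, L, N
    )
    if status != 0:
        raise ValueError(f"simulation failed (status {status}) for {params}")
    is_dose = np.isin(obs_times, schedule.dose_times)
    return Trajectory(times=obs_times, L=L, N=N, is_dose=is_dose)


def standard_schedule(
    start_day: float = 14.0, weeks: int = 6
) -> tuple[DoseSchedule, MeasurementTimes]:
    """The standard fractionation and scan pattern used for classification.

    Doses on the five weekdays of each treatment week (days start+{0..4},
    start+{7..11}, ...). Measurements at the pre-treatment scan (day 0,
    excluded from classification), at the start of each treatment week, and at
    the time of the final dose.
    """
    if weeks < 1:
        raise ValueError(f"weeks must be >= 1, got {weeks!r}")
    dose_times = np.array(
        [start_day + 7.0 * w + d for w in range(weeks) for d in range(5)]
    )
    week_starts = [start_day + 7.0 * w for w in range(weeks)]
    cls_times = week_starts + [dose_times[-1]]
    all_times = sorted(set([0.0] + cls_times))
    cls_set = set(cls_times)
    is_cls = np.array([t in cls_set and t != 0.0 for t in all_times])
    # if treatment starts at day 0 the first week-start scan doubles as the
    # pre-treatment scan and is still excluded from classification
    if start_day == 0.0:
        is_cls = np.array([t in cls_set for t in all_times])
    return (
        DoseSchedule(dose_times=dose_times),
        MeasurementTimes(times=np.array(all_times), is_classification=is_cls),
    )
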