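"""Numerical core for the two-compartment tumour model.

The living compartment obeys dL/dt = λL(1 − L/K) − ηL between doses, which is
itself a logistic equation with net rate r = λ − η and is advanced with its
closed-form solution. The necrotic compartment obeys the linear equation
dN/dt = ηL − ζN and is advanced with an exact exponential integrator,

    N(t+h) = N(t) e^{−ζh} + η ∫₀ʰ e^{−ζ(h−u)} L(t+u) du,

where the convolution integral is evaluated by composite 5-point
Gauss–Legendre quadrature with sub-steps short relative to every rate in the
problem (λ, η, ζ). Radiotherapy fractions are instantaneous transfers
L⁺ = (1−γ)L⁻, N⁺ = N⁻ + γL⁻ applied between smooth segments.

Everything here is numba-compiled; the public API in `model`, `noise` and
`inference` wraps these kernels.
"""

import math

import numpy as np
from numba import njit

# 5-point Gauss-Legendre nodes/weights on [-1, 1]
_GL_X = np.array(
    [
        -0.906179845938664,
        -0.538469310105683,
        0.0,
        0.538469310105683,
        0.906179845938664,
    ]
)
_GL_W = np.array(
    [
        0.236926885056189,
        0.478628670499366,
        0.568888888888889,
        0.478628670499366,
        0.236926885056189,
    ]
)

# sub-step length satisfies dt * (1 + λ + η + ζ) <= _STEP_SCALE
_STEP_SCALE = 0.25

LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def living_closed_form(L0, lam, K, eta, t):
    """Exact solution of dL/dt = λL(1 − L/K) − ηL at time t from L(0)=L0."""
    if L0 <= 0.0 or t == 0.0:
        return max(L0, 0.0)
    r = lam - eta
    x = r * t
    if x > 700.0:
        # saturated at the effective carrying capacity K(1 − η/λ); the
        # correction is O(e^{-x}) and below machine precision here
        return K * r / lam
    if r == 0.0:
        E = t
    else:
        E = math.expm1(x) / r
    return L0 * (1.0 + r * E) / (1.0 + lam * L0 * E / K)


@njit(cache=True)
def advance_segment(L, N, lam, K, eta, zeta, h):
    """Advance (L, N) across a dose-free interval of length h."""
    if h <= 0.0:
        return L, N
    rate = 1.0 + lam + eta + zeta
    n_steps = int(math.ceil(h * rate / _STEP_SCALE))
    if n_steps < 1:
        n_steps = 1
    dt = h / n_steps
    half = 0.5 * dt
    for _ in range(n_steps):
        acc = 0.0
        for j in range(5):
            u = half * (_GL_X[j] + 1.0)
            acc += _GL_W[j] * math.exp(-zeta * (dt - u)) * living_closed_form(
                L, lam, K, eta, u
            )
        N = N * math.exp(-zeta * dt) + eta * half * acc
        L = living_closed_form(L, lam, K, eta, dt)
    return L, N


@njit(cache=True)
def simulate_ln(params, dose_times, obs_times, out_L, out_N):
    """Simulate the model, writing L and N at obs_times (post-dose on ties).

    params = (λ, K, γ, ζ, η, φ₀) in natural space. dose_times and obs_times
    must be sorted; t = 0 is the initial (diagnosis) scan with V(0) = 1.
    Returns 0 on success, nonzero on invalid input.
    """
    lam, K, gamma, zeta, eta, phi0 = (
        params[0],
        params[1],
        params[2],
        params[3],
        params[4],
        params[5],
    )
    if phi0 <= 0.0 or phi0 >= 1.0 or gamma <= 0.0 or gamma >= 1.0:
        return 1
    L = 1.0 - phi0
    N = phi0
    t = 0.0
    i = 0  # next dose
    k = 0  # next observation
    n_d = dose_times.shape[0]
    n_o = obs_times.shape[0]
    while k < n_o:
        t_obs = obs_times[k]
        if t_obs < 0.0:
            return 2
        # apply all doses at or before t_obs
        while i < n_d and dose_times[i] <= t_obs:
            td = dose_times[i]
            L, N = advance_segment(L, N, lam, K, eta, zeta, td - t)
            t = td
            transfer = gamma * L
            L -= transfer
            N += transfer
            i += 1
        L, N = advance_segment(L, N, lam, K, eta, zeta, t_obs - t)
        t = t_obs
        out_L[k] = L
        out_N[k] = N
        k += 1
    return 0


@njit(cache=True)
def batch_volumes(thetas, dose_times, obs_times, out_V):
    """Noise-free V = L + N at obs_times for each log-parameter row of thetas."""
    m = thetas.shape[0]
    n_o = obs_times.shape[0]
    L = np.empty(n_o)
    N = np.empty(n_o)
    params = np.empty(6)
    for j in range(m):
        for p in range(6):
            params[p] = math.exp(thetas[j, p])
        status = simulate_ln(params, dose_times, obs_times, L, N)
        if status != 0:
            for k in range(n_o):
                out_V[j, k] = np.nan
        else:
            for k in range(n_o):
                out_V[j, k] = L[k] + N[k]


@njit(cache=True)
def loglik(params, a1, a2, dose_times, obs_times, v_obs, n_obs, use_n):
    """Gaussian log-likelihood with sd σ(V) = α₁ + α₂V about the model V.

    With use_n, adds the analogous terms for the necrotic compartment.
    Returns -inf for invalid parameters or non-positive predicted sd.
    """
    n_o = obs_times.shape[0]
    L = np.empty(n_o)
    N = np.empty(n_o)
    status = simulate_ln(params, dose_times, obs_times, L, N)
    if status != 0:
        return -np.inf
    ll = 0.0
    for k in range(n_o):
        V = L[k] + N[k]
        sd = a1 + a2 * V
        if sd <= 0.0 or not np.isfinite(V):
            return -np.inf
        z = (v_obs[k] - V) / sd
        ll += -0.5 * z * z - math.log(sd) - 0.5 * LOG2PI
        if use_n:
            sd_n = a1 + a2 * N[k]
            if sd_n <= 0.0:
                return -np.inf
            zn = (n_obs[k] - N[k]) / sd_n
            ll += -0.5 * zn * zn - math.log(sd_n) - 0.5 * LOG2PI
    return ll


@njit(cache=True)
def batch_loglik(thetas, a1, a2, dose_times, obs_times, v_obs, n_obs, use_n, out):
    """loglik for each log-parameter row of thetas (natural exp applied here)."""
    m = thetas.shape[0]
    params = np.empty(6)
    for j in range(m):
        for p in range(6):
            params[p] = math.exp(thetas[j, p])
        out[j] = loglik(params, a1, a2, dose_times, obs_times, v_obs, n_obs, use_n)


@njit(cache=True)
def ram_chain(
    x0,
    lower,
    upper,
    dose_times,
    obs_times,
    v_obs,
    n_obs,
    use_n,
    fixed_a1,
    fixed_a2,
    infer_noise,
    n_iter,
    target_accept,
    seed,
):
    """Robust adaptive Metropolis (Vihola 2012) targeting the box-prior posterior.

    The state is θ = (log λ, log K, log γ, log ζ, log η, log φ₀) and, when
    infer_noise, additionally (α₁, α₂) in natural space. The prior is uniform
    on [lower, upper]; proposals outside the box are rejected. Returns
    (draws, acceptance_rate).
    """
    np.random.seed(seed)
    d = x0.shape[0]
    draws = np.empty((n_iter, d))
    S = np.zeros((d, d))
    for p in range(d):
        S[p, p] = 0.1 * (upper[p] - lower[p])
    x = x0.copy()
    params = np.empty(6)
    for p in range(6):
        params[p] = math.exp(x[p])
    if infer_noise:
        a1 = x[6]
        a2 = x[7]
    else:
        a1 = fixed_a1
        a2 = fixed_a2
    lp_x = loglik(params, a1, a2, dose_times, obs_times, v_obs, n_obs, use_n)
    n_accept = 0
    u = np.empty(d)
    for it in range(n_iter):
        for p in range(d):
            u[p] = np.random.standard_normal()
        y = x + S @ u
        inside = True
        for p in range(d):
            if y[p] < lower[p] or y[p] > upper[p]:
                inside = False
                break
        if inside:
            for p in range(6):
                params[p] = math.exp(y[p])
            if infer_noise:
                a1 = y[6]
                a2 = y[7]
            lp_y = loglik(params, a1, a2, dose_times, obs_times, v_obs, n_obs, use_n)
            if lp_y - lp_x >= 0.0:
                alpha = 1.0
            else:
                alpha = math.exp(lp_y - lp_x)
        else:
            alpha = 0.0
            lp_y = -np.inf
        if alpha > 0.0 and np.random.random() < alpha:
            x = y.copy()
            lp_x = lp_y
            n_accept += 1
        # covariance adaptation: S S' <- S (I + η (α − α*) uu'/|u|²) S'
        step = min(1.0, d * (it + 1.0) ** (-0.66))
        unorm2 = 0.0
        for p in range(d):
            unorm2 += u[p] * u[p]
        if unorm2 > 0.0:
            coef = step * (alpha - target_accept) / unorm2
            M = np.empty((d, d))
            for p in range(d):
                for q in range(d):
                    M[p, q] = coef * u[p] * u[q]
                M[p, p] += 1.0
            S = np.linalg.cholesky(S @ M @ S.T)
        draws[it] = x
    return draws, n_accept / n_iter
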