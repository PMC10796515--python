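# Methods

## Model

The gross tumour volume (GTV) of a patient undergoing fractionated
radiotherapy is modelled as the sum of a living compartment L(t) and a
necrotic-debris compartment N(t), both in fold-change units relative to the
first scan so that V(0) = L(0) + N(0) = 1. Between fractions,

    dL/dt = λ L (1 − L/K) − η L,
    dN/dt = η L − ζ N,

and each fraction at time tᵢ instantaneously transfers a volume γL from the
living to the necrotic compartment:

    L⁺ = (1 − γ) L⁻,   N⁺ = N⁻ + γ L⁻.

The initial composition is L(0) = 1 − φ₀, N(0) = φ₀. This is a
two-compartment extension of the proliferation–saturation (logistic + dose
loss) family of GTV models: the phenomenological logistic term handles
radiation-free saturation, while the transfer term gives radiotherapy a
mechanistic interpretation (cell kill creates debris that is cleared at rate
ζ rather than disappearing instantly), which is what lets the model produce
plateaued and pseudo-progressive volume curves that one-compartment models
cannot.

### Parameters

| symbol | meaning | units | first-level prior |
|---|---|---|---|
| λ | proliferation rate | d⁻¹ | log λ ~ U(−10, 0) |
| K | carrying capacity | fold change | log K ~ U(0, 5) |
| γ | per-fraction transfer fraction | – | log γ ~ U(−10, 0) |
| ζ | necrotic decay rate | d⁻¹ | log ζ ~ U(−10, 3) |
| η | necrosis rate | d⁻¹ | log η ~ U(−10, 3) |
| φ₀ | initial necrotic proportion | – | log φ₀ ~ U(−5, 0) |

All six parameters vary between patients; inference works in the log-space
vector θ = (log λ, log K, log γ, log ζ, log η, log φ₀) on the box above
(the first-level prior p₁).

### Dose-impulse convention

The impulsive dose term can be read two ways: as the literal transfer of a
volume γL (giving L⁺ = (1−γ)L⁻) or as strict δ-integration of dL/L (giving
L⁺ = e^{−γ}L⁻). We take the literal transfer, which keeps γ interpretable as
"fraction of living volume killed per fraction"; the convention is isolated
in `apply_dose` so it can be swapped. The two agree to first order in γ, and
the prior-predictive classification probabilities are indistinguishable
under either (checked by simulation). γ < 1 is guaranteed by the prior
bound log γ < 0, so both are well defined.

### Numerics

Between doses the living equation is itself logistic with net rate
r = λ − η and is advanced with its closed-form solution (stable
reformulations are used for r ≷ 0 and the r → 0 limit). The necrotic
equation is linear with forcing ηL(t) and is advanced with an exact
exponential integrator; the convolution ∫ e^{−ζ(h−u)} L(u) du is evaluated
by composite 5-point Gauss–Legendre quadrature with sub-steps satisfying
Δt (1 + λ + η + ζ) ≤ 0.25. This is accurate to ~1e−10 relative against a
tight-tolerance adaptive reference integrator across the whole prior box
(which includes stiff regimes, ζ, η up to e³ ≈ 20 d⁻¹), has no adaptive
step-size noise, and is fast enough (µs per trajectory, numba-compiled) to
support MCMC and 10⁵-particle filtering on one CPU. Volume is conserved
across dose instants by construction; a measurement coinciding with a dose
reports the post-dose L and N (V is unaffected).

Time is measured in days with t = 0 at the first (diagnosis) scan. The
standard schedule places fractions on the five weekdays of each treatment
week starting at day 14; the final dose of a six-week course falls on day
53, and the final-volume prediction horizon defaults to day 56. Both are
configurable (some cohorts start treatment at day 12).

## Response classification

A realisation is classified from its noise-free volumes at the standard
classification scans — the start of each treatment week plus the final dose,
normalized to the start-of-treatment scan; the pre-treatment scan is
excluded:

* **poor responder** — every measurement above 85% of the start-of-treatment
  volume;
* otherwise a responder, refined to **pseudo-progressor** if the second
  measurement exceeds 102% of the first, else **plateaued** if the final
  measurement is above 20% with a final rate-of-change below 10% of the
  maximum rate-of-change, else **fast responder**.

"Rate-of-change" is not defined more precisely by the criteria's source; we
use the magnitude of the finite difference between successive classification
measurements divided by their time gap, with "final" the last difference and
"maximum" the largest. The thresholds live in `ClassificationThresholds`
and are configurable, since they were calibrated on a small cohort.

## Observation model

Scans are independent and Gaussian about the model volume,
V_obs ~ N(V, σ²(V)) with σ(V) = α₁ + α₂V: an absolute plus a relative noise
contribution. The noise parameters are shared across patients and
pre-estimated: they are inferred jointly with θ for each patient (an
8-dimensional chain with independent U(0, 0.5) priors on α₁, α₂ in natural
space — volumes are O(1) in fold-change units, so σ beyond 0.5 is
implausible), equal numbers of (α₁, α₂) draws are pooled across patients,
and the estimate is the joint marginal mode from a Silverman-bandwidth 2-D
Gaussian KDE maximized on a 200×200 grid. They are then frozen for all
subsequent inference, which keeps the particle filter valid (it cannot
distinguish parameters that vary between patients from ones that are
fixed).

Normal noise can produce negative measurements at small volumes; they are
kept (the likelihood is a plain Normal, untruncated) and the synthetic
generator records their frequency implicitly through its manifest seeds.
When necrotic-volume measurements are available (the joint-observation
scenario), they contribute analogous independent Normal terms with the same
noise parameters.

## Inference

**Per-patient posteriors.** Robust adaptive Metropolis (Vihola-style
covariance adaptation toward a 0.234 acceptance rate) in log-θ space, with
out-of-box proposals rejected. Defaults: 4 chains × 25,000 iterations,
first half discarded, thinned to 2,500 pooled draws per patient; chains
start at independent prior draws. Split-R̂ and acceptance rates are always
recorded. The posteriors are frequently multimodal — a fast-shrinking
tumour can be explained through either the radiotherapy (γ, ζ) or the
necrosis (η) pathway — so split-R̂ near 1 is not achievable even for a
correctly mixing sampler (we verified that quadrupling the chain length
leaves R̂ ≈ 1.1–1.16 on the necrosis parameters with healthy acceptance).
The convergence check therefore defaults to a lenient R̂ < 1.2 at the
sampler level, and the cohort-level routines record diagnostics and warn
rather than abort; pooling across four independently started chains is
itself the mitigation for mode-trapping.

**Pooling.** The full posterior is the uniform mixture of per-patient
posteriors (equal sample counts per patient; non-uniform patient weights are
exposed as a configuration hook but unused).

**Second-level prior.** p₂(θ) expands the full posterior into a kernel
density estimate with truncated multivariate normal kernels: each of M =
100,000 particles is a resampled pooled particle plus a N(0, Σ_ε)
perturbation, redrawn until it lies inside the first-level box, with

    Σ_ε = β (4 / (m (d+2)))^{1/(d+4)} diag(Σ_θ),   β = 2, d = 6.

The exponent is applied to the covariance as written (the expansion factor β
absorbs the distinction from the textbook bandwidth-squared rule); with
m = 1000 the scalar factor is ≈ 0.935.

**New patients.** A bootstrap particle filter: p₂ particles are reweighted
by the patient's likelihood. Because θ is static, incremental weekly updates
recompute weights from the complete record, which is exact and avoids
resampling noise; filtering everything at once and filtering week by week
give identical final weights. The Kish effective sample size 1/Σw² is
reported at every update as the degeneracy diagnostic. At the pre-treatment
scan every particle predicts V(0) = 1 exactly, so the filtered class
probabilities equal the prior's — predictions before treatment are purely
prior knowledge, as they should be.

## Prediction outputs

Trajectory bands and final-volume summaries are weighted means and weighted
quantiles (left-continuous inverse of the weighted empirical CDF) of
noise-free per-particle volumes — i.e. credible intervals for the modelled
observation mean. Observation-level bands, which add one σ(V) perturbation
per particle, are available as an option. Class-probability traces are
weighted class proportions of the filtered particles under the standard
schedule. Goodness-of-fit is the Bayesian R²,
Var(V_fit) / (Var(V_fit) + Var(V_fit − V_obs)) per posterior sample
(sample variances, n−1), summarized by the median; cohort summary tables
use fractional per-class counts (sums of per-patient class probabilities)
and Welch's unequal-variance t-test with unrounded Welch–Satterthwaite
degrees of freedom, implemented from summary statistics so fractional
counts are handled exactly.

## Synthetic data

The generator emulates the study conditions: parameters drawn from the box
prior (or from a trained particle set), the standard six-week weekday
regime with weekly scans plus the day-0 pre-treatment scan, and Gaussian
measurement noise per the observation model. Fixture noise defaults to
(α₁, α₂) = (0.05, 0.10) — roughly 15% relative error on a pre-treatment
scan — declared in every cohort manifest. Initial volumes in cm³ are drawn
from a lognormal with mean 17 cm³ and sd 12 cm³, matching a plausible
head-and-neck distribution; they scale the CSV output only and do not enter
the dynamics. Class-conditional patients are produced by rejection on the
noise-free classification (the noise model is never adjusted). Noisy
synthetic series are *not* renormalized to their first measurement: the
measurements are exactly what the observation model produces, so the first
noisy scan scatters around 1. The CSV reader, by contrast, normalizes raw
clinical cm³ series by the first scan, which is where the fold-change
convention enters for real data.

What the generator does not emulate: CT segmentation error structure beyond
the linear-σ Gaussian, scan-time jitter, missed scans, dose-plan adaptation,
or inter-patient correlation in noise. Passing tests on synthetic cohorts
therefore demonstrate the statistical machinery is self-consistent (correct
coverage, recovery, classification under the assumed model), not that the
model is well specified for any particular clinical cohort.

## Problem sizes

The test suite and the analysis scripts run everything at desk scale, chosen
so the full pipeline exercises every stage on one CPU: 4–10 patient training
cohorts with 2–4 chains × 4,000–10,000 iterations, second-level priors of
4,000–20,000 particles, 50-patient coverage replicates, and 10,000-sample
prior-predictive Monte Carlo (binomial SE ≈ 0.5 percentage points). The
package defaults (4 × 25,000 iterations, M = 100,000) reproduce the
full-scale configuration. Cohort-level quantities (class proportions of the
full posterior and second-level prior) are split- and cohort-dependent;
on synthetic cohorts they are reported as computed, not compared to any
clinical value.

## Known limitations

* Per-patient posteriors are multimodal and mode weights from a single
  sampler run carry Monte Carlo error; population pooling dilutes but does
  not remove this.
* The particle filter never rejuvenates particles, so a patient genuinely
  outside the training gamut degrades to a few heavy particles (low ESS) —
  reported, not repaired; the β-expanded kernels are the only mitigation.
* The noise model permits negative measurements at small volumes, and the
  classifier is defined only for noise-free series; patient-level class
  probabilities must come from posterior samples, never from classifying
  noisy data directly.
* γ is per-fraction with dose size ignored (all clinical fractions are
  2 Gy); dose-magnitude response is out of scope.
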