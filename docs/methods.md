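# Methods

## The macroscopic models

Four flow–density relations are fitted to per-second (k, q) pairs, where k
is trail density in ants·cm⁻² and q the flow per unit trail width in
ants·cm⁻¹·s⁻¹:

| model | speed v(k) | parameters |
|---|---|---|
| Greenshields | v_f (1 − k/k_j) | v_f, k_j |
| Pipes–Munjal | v_f (1 − (k/k_j)^p) | v_f, k_j, p |
| Underwood | v_f e^(−k/k_m) | v_f, k_m |
| two-phase | — (flow directly: q = v·min(k, k_j)) | v, k_j |

The first three put q = k·v(k) and force q → 0 at high density (jamming);
the two-phase function instead saturates at q_j = v·k_j. Speeds are clamped
at zero beyond the jam density for the two polynomial models. The power
exponent is called `p` to keep it distinct from the pheromone baseline α.
These are the canonical algebraic forms for the models' verbal definitions
(linear, power-law, exponential speed decay); no other parameterization is
assumed.

**Fitting.** The three smooth models go through `scipy.optimize.curve_fit`
(trust-region reflective with positivity bounds, two restarts at halved and
doubled starting values). Auto-initialisation is data-driven: v_f from the
median q/k slope on the lowest-density decile, k_j at 1.2× the largest
observed density, k_m at the median density, p = 2. The two-phase model is
non-smooth at the breakpoint, which defeats plain Gauss–Newton, so it is
fitted by profiling: for each candidate breakpoint on a 0.1-step grid the
slope has the closed-form weighted solution v = Σq·m / Σm² with
m = min(k, k_j), and the best grid point seeds one Nelder–Mead refinement of
(v, k_j) jointly. Standard errors come from the Gauss–Newton covariance with
the almost-everywhere Jacobian (∂q/∂k_j = v·1{k > k_j}). A unit test checks
the profiled fit against an exhaustive SSE search on a fine (v, k_j) lattice.

**Model selection.** Least-squares AIC with unknown Gaussian error variance:
AIC = n·ln(SSE/n) + 2(p+1), the +1 counting the variance. Akaike weights are
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2) with Δ_i = AIC_i − min AIC. Only Δ matters,
so any consistent AIC convention gives the same weights; this one is fixed
for reproducibility. SSE is floored at machine tiny so exact fits yield a
finite AIC.

## The microscopic chain

For ants tracked across a monitored section of length L = 2 cm:

- contacts are linear in density with no intercept, C = c·k (zero density
  forces zero contacts, so the regression is through the origin);
- travel time is linear in contacts, T = T₀ + ΔT·C (ordinary least squares
  with intercept);
- the speed model combines contact friction with a pheromone benefit,

  v(k) = L/(T₀ + ΔT·c·k) · φ(k),  φ(k) = α + β·k·e^(−γ·k),

  where C(k) = c·k is the *average* contact load. φ peaks at exactly
  k = 1/γ (≈ 6.4 ants·cm⁻² at the default γ = 0.156): trails are fastest at
  intermediate density, which is what keeps the flow linear in the first
  phase. The flow q(k) = k·v(k) then converges to L·α/(ΔT·c) ≈ 11.09
  ants·cm⁻¹·s⁻¹ as k → ∞ — a plateau, not a jam.

The pheromone factor is placed as a multiplier on the whole speed (not
inside the denominator); this is the only reading whose analytic limit
equals L·α/(ΔT·c), so it is adopted and checked numerically against
q(k) at k = 10⁶ in the tests and the acceptance script.

**Defaults.** L = 2 cm, T₀ = 0.95 s, ΔT = 0.24 s, c = 0.61 cm²·ant⁻¹,
α = 0.812, β = 0.160, γ = 0.156 — the fitted values for Argentine-ant trail
traffic, used both as generator calibration and as fit starting truths in
recovery tests.

**Fitting (α, β, γ).** With (L, T₀, ΔT, c) fixed, the fit is nonlinear least
squares of *travel time* on density:

T(k) = (T₀ + ΔT·c·k)/φ(k).

Time space is chosen deliberately: in the tracked records both noise sources
— contact-count dispersion around c·k and timing error — enter T additively
with zero mean, so the time-domain estimator is consistent. Regressing
reciprocal speeds L/T instead makes the residual enter through 1/T and
biases all three parameters upward by several standard errors at n = 8000
(Jensen's inequality); this was verified by simulation before the choice was
frozen. Levenberg–Marquardt from (1, 0.1, 0.1) with one fallback restart.

**Free-flow speed and stratified curves.** v_f = L/(T − C·ΔT) removes the
contact cost from each crossing; records where the correction overshoots
(T ≤ C·ΔT) are flagged invalid (NaN) rather than silently dropped. The
travel-time-versus-density curves within each contact stratum use a
hand-written local polynomial regression (degree 2, tricube weights,
span 0.75 — configurable), because the available lowess implementations are
locally linear only and a quadratic is needed to localise the dip at 1/γ.
Strata with fewer than 30 records are skipped with a warning.

U-turning ants never complete the crossing, so they are excluded from every
regression (the U-turn flag is kept on the records; the observed U-turn rate
is ~0.01 per crossing).

## Occupancy

Per-ant area = body length × head width × 1.25, dimensions in mm, ranges
collapsed to midpoints (a printed mean takes precedence over the range for
body length). Occupancy = k × area/100 (mm² → cm²). The species table
reports the area at two decimals and also at one decimal (4.75 → 4.8), and
computes occupancy from the one-decimal area so the reported fractions match
the quoted areas (0.20, 0.48, 0.13, 0.10). The wood-ant rectangle gives
22.14 mm², not the oft-quoted 22.25 mm²; the discrepancy is not reproducible
from the printed dimensions and is left as-is rather than forced. At the
focal species' measured 4.4 mm² (with legs) and the maximum observed density
of 18 ants·cm⁻², occupancy is 0.79 — the colonies stop just short of 0.8.

## Asymmetry response surface

Per second, the outbound share a = n_out/(n_out + n_in); zero-flow seconds
have no defined share and are dropped. The response surface regresses
z-scored flow on five terms built from z-scored predictors: z_k, z_k²,
z_a, z_a², z_k·z_a (standardize first, then form squares and interaction —
the common "standardized beta" convention). Near-zero asymmetry terms mean
the flow is set by density alone. Note a measurement artifact the surface
inherits from its construction: a is computed from the same counts as q, so
low-flow seconds mechanically produce extreme shares, which leaks weight
into the z_a² term on count-noisy data even when the generating flow ignores
direction entirely. The generator-oracle test therefore uses an a drawn
independently of q, and the integration test on generated observations
asserts density dominance rather than exact zeros.

## The synthetic-data generator

The generator emulates the statistical structure of the two table kinds, not
the ants themselves — no positions, lanes, collision geometry, or
pheromone-field dynamics.

- **Density trajectory**: logistic recruitment ramp
  k(t) = k_max/(1 + e^(−(t − t½)/τ)), t½ = ramp/2, τ = ramp/8, reaching
  equilibrium within the default 600 s ramp (the observed flows equilibrate
  in about ten minutes), plus optional Gaussian jitter with SD 5% of the
  level, clipped at zero. The equilibrium fluctuation magnitude is not an
  observed quantity; 5% is a configurable guess. A "uniform" profile (iid
  densities per second) is available for fitting benchmarks where a flat
  density design is wanted. Default k_max = 18 ants·cm⁻², the maximum the
  colonies ever produced; at 4.4 mm² per ant that caps occupancy at 0.79.
- **Macroscopic records**: expected total crossings per second are
  q(k)·width with q from the microscopic model (or any supplied flow
  function, e.g. a planted two-phase curve); counts are Poisson (discrete
  crossing events) or the rounded mean with noise off; the recorded flow is
  identically (n_out + n_in)/width. The outbound fraction decays 1 → 0.5 on
  the same logistic clock: outbound ants dominate until the first foragers
  return.
- **Tracked records**: k from a sampler (default uniform on [0, 16], the
  study's range), C ~ Poisson(c·k) or the mean c·k with contact noise off,
  T = (T₀ + ΔT·C)/φ(k) plus additive normal noise (SD 0.3 s default, floored
  at 0.1·T₀ to keep times physical), random direction, Bernoulli(0.01)
  U-turn flag. With all noise off the records satisfy the model equations
  exactly, which is what makes the 1e-6 planted-parameter oracles possible.

All randomness flows from the config seed through one `numpy` Generator per
call; identical configs give identical tables.

What passing recovery tests show — and what they do not: the generator
produces exactly the mean structure the estimators assume, so recovery
demonstrates correctness of the estimation chain, not robustness to the
features of real trail data it does not emulate (autocorrelated per-second
observations from continuous recordings, density-measurement error,
inter-colony heterogeneity, non-Poisson contact clustering).

## Problem sizes and tolerances

Recovery experiments use 8,000 tracked records and 20,000 macroscopic
seconds — the same order as the tracked sample (7,900 ants) and large enough
that three standard errors separate the planted values cleanly, while the
whole suite runs in seconds. Noiseless fits are asserted to 1e-6 relative;
noisy recoveries to 3 SE; the two-phase breakpoint to ±0.5 of the planted 8;
the two-phase Akaike weight must exceed 0.95 on two-phase-generated data.
The travel-time noise SD (0.3 s) is a calibration knob; at the default it
yields a travel-time R² in the neighbourhood of the ~0.55 observed on real
data, but that resemblance is a sanity check, not a fitted target.

## Known limitations

- The generator's independence assumptions (iid seconds, iid crossings) are
  optimistic relative to video-derived data; fitted standard errors on real
  data would be larger than the nominal NLS ones.
- Two-phase standard errors rely on an almost-everywhere Jacobian; they are
  asymptotic and ignore the non-regularity exactly at the breakpoint.
- The response surface is descriptive (standardized betas), not a causal
  model of how asymmetry affects throughput.
- Head-on and rear-end contacts are pooled, as in the source measurements.
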