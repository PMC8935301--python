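# Methods

## The model family

`ipmcor` implements size-structured integral projection models (IPMs) in
which the vital rates — survival s(m), reproduction b(m), growth g(m′|m)
and offspring size h(m′|m), with m the natural log of body mass — need not
be conditionally independent.  The projection kernel is

    k(x′, z′ | x, z, d_t) = s(·) [ b(·) h(x′, z′ | ·) + g(x′, z′ | ·) ],

with i-state x = m, optional q-state z = (v_b, v_g) (persistent individual
quality), and year conditions d_t.  The baseline ("vanilla", I1)
parameterization is logistic survival and reproduction and Gaussian growth
and offspring size, each linear in m.  Eight variants are supported:

| id  | structure | extra parameters |
|-----|-----------|------------------|
| I1  | independent rates | — |
| I2  | independent random year effects | ν²_b, ν²_g |
| I3  | independent random individual effects | θ²_b, θ²_g |
| D1a | breeding status shifts growth mean | β_g\|r |
| D1b | Gaussian copula joins growth & reproduction | α |
| D2a | observed shared driver q_t | β_bq, β_gq |
| D2b | correlated year effects | ν²_b, ν²_g, ρ |
| D3  | correlated individual effects | θ²_b, θ²_g, ψ |

Setting every dependence/heterogeneity parameter to zero reduces each
variant to I1 exactly; this nesting is enforced by tests.

Births are singletons; twinning, density dependence, age structure and
time-lagged dependence are out of scope.

## The copula joint

To couple a Gaussian growth response Y1 with a Bernoulli reproduction
response Y2, Y2 is made continuous by adding an independent uniform
auxiliary: Y3 = Y2 + X, X ~ U[0,1].  Y3's CDF F3 is piecewise linear on
[0,2] with slope q = Pr(Y2 = 0) below 1 and 1 − q above.  A bivariate
Gaussian copula with correlation α then yields the joint density

    f(y1, y3) = φ_D((y1−μ)/σ, Φ⁻¹(F3(y3))) · f3(y3) / (σ · φ(Φ⁻¹(F3(y3)))).

Numerical choices:

- Φ⁻¹(F3(y3)) is clamped to Φ⁻¹ of [1e−12, 1−1e−12].  The density is
  undefined where the margin CDF hits exactly 0 or 1; that set has measure
  zero and the clamp keeps boundary auxiliaries finite.
- The copula kernel's growth margin is computed by quadrature, not by
  aliasing to the vanilla margin: substituting u = Φ⁻¹(F3(y3)) turns
  ∫f(y1,y3)dy3 into ∫φ(u)·N(y1; μ+σαu, σ²(1−α²))du, evaluated with an
  80-node Gauss–Hermite rule.  Agreement of the copula kernel with the
  vanilla kernel (at machine precision) is therefore a numerical result,
  and the equivalence of growth rates and elasticities follows by
  computation rather than by construction.

The D1a (reproduction-conditional) variant instead treats breeding status
at t+1 as a covariate in the growth model; its marginal growth density is
a two-component Gaussian mixture weighted by b(m), inducing
cov(m′, r′) = β_g|r·b(1−b), maximal in magnitude at b = 0.5.  A
configuration flag can restrict the shift to first-year individuals
(`newborn_only`) or condition on breeding at t instead of t+1
(`lag_previous_breeding`, off by default).  Which individuals count as
"newborns" is supplied by the panel's `newborn` column, so either reading
of the refinement (offspring growth vs. growth of new mothers) can be
expressed through the column mapping.

## Discretization

The midpoint rule on a uniform log-mass grid (default 100 nodes) converts
the kernel to a projection matrix with n_{t+1} = K n_t (target rows,
source columns).  Bounds are set so that one growth step and one
offspring draw from the boundary keep 4 residual SDs inside the mesh —
for the upper bound x(1−β_gm) ≥ β_g0 + 4σ, and at the low end the
fixed point of the inheritance map, lo ≤ (β_h0 − 4σ_h)/(1−β_hm).  Kernel
mass escaping the mesh ("eviction") triggers a warning when the column
outflow deficit exceeds 1e−3; we deliberately do not renormalize, which
would silently distort survival.  Doubling the mesh changes log λ by
< 1e−4 at the defaults (tested).

For I3/D3 the state is extended to (m, v_b, v_g).  The quality grid uses
n_z uniform quantile midpoints per effect (default 7×7), pushed through
the Cholesky factor of the 2×2 effect covariance when ψ ≠ 0; cells carry
equal weight.  Growth is block-diagonal in z (quality is fixed for life);
offspring enter each quality cell with the offspring-effect weight,
independent of the parent's quality.

## Growth rates

Fixed kernels: log of the dominant eigenvalue (dense solver ≤ 500 states,
power iteration above, tolerance 1e−10).

Temporally stochastic kernels (I2, D2a, D2b): the element-selection
estimator — iterate randomly drawn yearly kernels, discard the first L0
years as transient, and average the log abundance increments,
(1/(L−L0))·log(N_L/N_{L0}).  Defaults L = 10,000, L0 = 1,000.  The
population vector starts uniform and is renormalized to total mass one
every step (the accumulated log increments leave the estimator unchanged;
both choices are irrelevant after burn-in and are tested as such).  The
driver for D2a defaults to the winter-NAO distribution N(−0.019, 1.09²).

The reported standard error uses batch means (~√n batches) rather than
sd/√n of the raw increments: yearly increments are serially correlated —
a good breeding year skews the next size distribution toward newborns —
and the naive estimator overstates the error by a factor ~2 at the
calibration parameters, while the batch-means estimator matches the
across-seed spread (ratio ≈ 1.05, tested over 50 seeds).

## Sensitivity and elasticity

Central differencing on the natural λ_s scale with ε = 0.005·β (an
absolute step is available for zero-valued parameters); elasticity
multiplies by β/λ_s.  The scheme is second order; its step error decays
~4× per halving (tested).  For stochastic models both perturbed
evaluations share one set of standard-normal innovations which are
re-transformed under each perturbed parameter set — plain reuse of the
year effects would zero the derivative with respect to variance or
correlation parameters, and without common random numbers the Monte Carlo
noise of order se/ε would swamp the derivative.  The
common-random-numbers flag is recorded in the result object.

## Inference

The likelihood is a sum over individual-year records of Bernoulli terms
(survival; reproduction given survival), Gaussian terms (growth; offspring
size given reproduction), and for D1b the copula log-density of the
augmented pair.  Missing binary responses are marginalized analytically
(b·f(data|r=1) + (1−b)·f(data|r=0); for D1b the margin-preservation
property makes the marginal growth term exactly Gaussian); missing
Gaussian responses drop their term.  A missing predictor m is a
validation error, not an imputation target.

Sampling is adaptive random-walk Metropolis within Gibbs:

- Scalar blocks per parameter, with proposal scales adapted toward 0.44
  acceptance during burn-in only.  Slope updates carry a compensating
  intercept shift (predictor centering) to remove the slope–intercept
  ridge.  Chains initialize at moment estimates (a few Newton steps of
  logistic regression; OLS for the Gaussian blocks) with per-chain jitter.
- Year effects, individual effects and copula auxiliaries are sampled as
  unobserved parameters.  Groups are conditionally independent given the
  parameters, so all years (or individuals, or records) are proposed and
  accepted/rejected in parallel; per-record likelihood deltas aggregate to
  their group via bincount, making a full sweep a handful of array passes.
- Effect SDs get an additional non-centered scale move (θ′ = cθ with the
  standardized effects held fixed, i.e. v′ = cv).  The effect-prior ratio
  cancels the transform Jacobian, leaving the likelihood delta plus the
  half-Normal prior ratio on the log-θ scale.  Without this move the
  weakly identified growth-side SDs (θ_g = 0.03 against σ_g = 0.09) mix
  poorly.
- Priors: Normal(0, 10²) on regression coefficients, half-Normal(0, 5²)
  on SDs, Uniform(−1, 1) on correlations — weakly informative defaults
  that keep every posterior proper.
- Three chains by default, seeded independently from one top-level seed.
  Convergence is assessed with the classic potential-scale-reduction
  statistic (threshold 1.05, floored at 1.0; cross-checked against the
  rank-normalized variant in arviz on drifting chains).

The sampler is a design choice of this package; the likelihoods, not the
sampling algorithm, are the contract.

## Synthetic data

`simulate_population` forward-simulates individuals under any variant:
year effects drawn once per year (bivariate with ρ for D2b; driver for
D2a), individual effects once per individual at birth (bivariate with ψ
for D3, independent of the parent's), survival and reproduction Bernoulli,
growth Gaussian (jointly with reproduction through the copula for D1b;
r-conditional shift for D1a), singleton births with Gaussian offspring
size.  Founders draw log mass from a Gaussian fit to the vanilla kernel's
stable size distribution, avoiding long transients in empirical checks.
An optional missingness rate masks reproduction records (and the attached
offspring mass) to emulate incomplete breeding surveys; the case-study
emulation preset masks 10%.

The generator emulates the panel structure of long-term individual-based
ungulate studies (marked females, annual capture, known maternity).  It
does not emulate observation error on mass, capture failure/detection,
twinning, immigration, or density dependence — so passing recovery tests
show correctness of the likelihood and sampler under the stated model,
not robustness to those real-data features.

## The model-comparison study

`run_simulation_study` draws vital-rate coefficients per replicate from
the calibration distributions (survival intercept N(−4.25, 0.05²), slope
N(1.92, 0.01²); reproduction N(−1.47, 0.05²), N(0.50, 0.01²); growth
N(1.20, 0.05²), N(0.63, 0.01²); offspring size N(0.46, 0.05²),
N(0.57, 0.01²)) with fixed σ_g = 0.09, σ_h = 0.2, ν_g = θ_g = 0.03,
ν_b = θ_b = 0.45 and β_gq = 0.01, then evaluates every requested model on
the same draw.  Contrasts against I1 are paired through the parameter
draw; each stochastic evaluation receives its own environmental sequence,
so the replicate spread reflects both parameter and environmental
variability (pairing the environments across toggle values would suppress
the growth of that spread with ρ).

Toggle values are a package choice (the calibration only fixes β_gq):
ρ, ψ ∈ {0, 0.45, 0.9} and β_bq ∈ {0, 0.1, 0.2} by default.  Elasticity
contrasts (of β_g0, as percent change over I1) are optional because each
costs two extra stochastic evaluations per model per replicate.

Problem sizes used by the test suite and the acceptance script — meshes
of 40–100 nodes (7×7 quality cells), recovery panels of 250–300 founders
over 12–30 years, MCMC runs of 4,000–5,000 iterations × 3 chains, a
20-replicate study — are the package's defaults for desk-scale
verification; all scale up by argument.

## Known limitations

- The Gibbs sampler's random-walk updates need longer runs than gradient
  samplers would for strongly correlated posteriors (notably ψ with many
  short individual histories).
- Eviction is reported, not corrected; extreme parameter sets need
  explicit bounds.
- The D2a driver model treats the driver as exactly observed and
  stationary when simulating growth rates.
- Elasticities for stochastic models inherit Monte-Carlo noise of order
  se/(2ε) even with common random numbers; increase L for tight contrasts.
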