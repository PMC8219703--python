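# Methods

`hyporeact` estimates how quickly organic micropollutants are removed, and
how strongly they are retarded, as surface water carries them along shallow
hyporheic flowpaths through a triangular streambed bedform.  It does so by
inverting porewater breakthrough curves against a one-dimensional reactive
transport model with a multi-chain Bayesian sampler, and reporting half-lives
with detectability thresholds.

## Transport model

Along a single flowpath from the sediment–water interface to a porewater
sampler, concentration `c(x, t)` (µg L⁻¹) obeys

    R ∂c/∂t = D ∂²c/∂x² − v ∂c/∂x − k c

with retardation coefficient `R` (–, ≥ 1), effective hydrodynamic dispersion
`D` (m² h⁻¹), porewater velocity `v` (m h⁻¹) and first-order removal rate
`k` (h⁻¹).  Internal units are metres, hours and µg L⁻¹ throughout; files
use days and convert at the I/O boundary.

Boundary and initial conditions mirror the flume experiment: the measured
surface-water record is imposed as a time-varying Dirichlet (resident)
concentration at the inlet `x = 0`, interpolated piecewise-linearly between
sampling days; a zero-gradient Neumann condition closes the domain at
0.25 m; the sediment starts clean (`c(x, 0) = 0` for `x > 0`).  The
observation point `x = L` lies inside the domain and is read off by linear
interpolation between the bracketing nodes, because `L` itself is an
inferred, continuous parameter.

### Discretization

A θ-scheme on a uniform grid: Crank–Nicolson (θ = ½) with central advection
while the cell Peclet number `v Δx / D` is ≤ 2; above that the solver warns
and switches to first-order upwinding with implicit Euler (θ = 1), whose
M-matrix structure keeps the solution non-negative where central/CN could
oscillate.  Both variants cost one tridiagonal factorization per parameter
set; the time loop is a compiled Thomas-algorithm kernel (numba), with a
dense-propagator numpy fallback.  Default grid: 125 cells over 0.25 m
(Δx = 2 mm) and Δt = 0.1 h over the 21-day fit window; the sampler uses a
coarser 40-cell, 1-h grid whose difference from the fine grid is ~0.01% at
the observation times — negligible against measurement noise.  Verification
is against the closed-form constant-inlet solution of the semi-infinite
advection–dispersion–decay problem (an Ogata–Banks-type erfc expression
extended with decay and retardation), valid while the outlet is unfelt;
agreement is better than 1% of the inlet concentration across the prior
ranges and improves under grid refinement at the scheme's nominal order.

## Flowpath geometry and priors

The four sampler flowpaths carry the median lengths and travel times of the
bedform's hydrodynamic model: a (5 cm, 11.5 h), b (11.1 cm, 24.3 h),
c (16.6 cm, 43.3 h), d (9.2 cm, 20.1 h).  Priors per flowpath:

- `k` ~ Uniform(10⁻⁵, 4) h⁻¹ and `R` ~ Uniform(1, 49) — compound-specific,
  deliberately vague;
- `L` and `v` Gaussian around the medians (v centred on length/travel
  time), truncated positive, default relative sd 20% — the spread of the
  flowpath distributions is broad but unimodal and is not tabulated, so the
  scale is configurable;
- `D` in the calibration pre-run: log-uniform over [10⁻⁶, 10⁻²] m² h⁻¹;
  afterwards Gaussian with sd = IQR/1.349 matched to the pre-run posterior
  (tabulated defaults: a 1.5·10⁻³, b 1.1·10⁻⁴, c 5.3·10⁻⁵, d 2.4·10⁻⁵
  m² h⁻¹).

`L` and `v` are treated as independent; their joint distribution along the
particle bundle is unpublished.  This matters: see *Identifiability* below.

## Inference

The sampler is a self-contained DREAM-style differential-evolution adaptive
Metropolis scheme: 20 chains (2·d+1 minimum for d = 5), proposals formed
from the difference of 1–3 random chain pairs scaled by γ = 2.38/√(2δd′),
restricted to a random crossover subspace (CR uniform on {⅓, ⅔, 1}; the
full adaptive CR selection of the original algorithm is omitted as
unnecessary at this dimension), with 10% of generations at γ = 1 proposing
in the full space for basin hopping, 10% snooker updates (moves along the
line to a random chain with the (d−1)-power volume correction) for ridge
mixing, and outlier-chain correction by the interquartile rule on a
recent-window mean log-density during burn-in only.  Two scale-like
parameters (`k`, `D`) are proposed on the log axis with the exact Jacobian
correction.  During the first fifth of a run the likelihood is annealed in
with a quadratic β ramp (always completed before half of burn-in) so chains
contract from the prior onto sharp posteriors; retained samples always
target the exact posterior.  Default run length mirrors the study scale:
4004 generations, first half discarded, 2002 retained per chain = 40,040
pooled draws.  Correctness checks: with a constant likelihood the sampler
reproduces its priors (KS < 0.05 on both a linear and a log-sampled
parameter); on synthetic data its posterior medians agree with an
independent affine-invariant ensemble sampler run on the same density.

The likelihood treats residuals as independent Gaussians.  Three error
models are available: `jeffreys` (default — single scale integrated out
analytically, marginal ∝ SSR^(−n/2); robust when the measurement scale is
unknown), `fixed` (single absolute σ), and `relative` (σᵢ = rel_sd · obsᵢ,
appropriate when the relative measurement precision is known, as it is for
the synthetic generator and for LC-MS/MS QA/QC).  Left-censored values
enter as their substituted values LOQ·2^(−1/2), mirroring the data
preparation; a proper censored likelihood is a possible extension.

Convergence is declared when the potential scale reduction factor over the
pooled post-burn-in halves is below 1.2 for every parameter (cross-checked
against `arviz.rhat`).

### Two-stage dispersion calibration

Dispersion is a flowpath property, not a compound property.  Stage 1 fits
the most conservative compound (hydrochlorothiazide in the study; the
dataset's designated reference) per flowpath under the wide log-uniform `D`
prior; stage 2 replaces the `D` prior with a Gaussian matched to the
stage-1 posterior (median, IQR/1.349) and fits every other compound
independently per flowpath.  A dataset without the reference compound on
every flowpath is a configuration error.

### Identifiability

Dividing the transport equation by `R` shows the observed curve depends on
the parameters only through `D/R`, `v/R`, `k/R` and `L`: scaling
`(R, v, D, k)` by a common factor leaves `c(L, t)` unchanged.  One
breakthrough curve therefore cannot separate these four — only the priors
on `v`, `L` and `D` break the degeneracy, and the posterior marginals of
`k` and `R` inherit a skew along the scaling ridge whose size tracks the
prior widths.  Consequences adopted here:

- pipeline results report marginal medians and IQRs, as the study does, and
  must be read jointly with the `v`, `L`, `D` priors;
- parameter-recovery experiments that probe the compound-specific pair
  (k, R) pin the hydrodynamic nuisances at their known synthetic values;
  under that protocol the sampler recovers k and R to within a few percent
  at 5% measurement noise;
- the smallest removal rate distinguishable from zero on a flowpath is set
  by the measurement precision through the same construction as the
  reporting threshold, `k_min = −ln(1 − 2·rel_sd)/τ` (≈ 0.009 h⁻¹ on the
  shortest flowpath at 5% precision).  For a truly conservative compound
  the posterior median of `k` under its uniform prior settles near this
  resolution limit — a bound of the experimental design, not of the
  sampler.

## Post-processing

Posterior `k` samples convert samplewise to half-lives DT50 = ln 2 / k; the
map is monotone, so medians and (reflected) quartiles commute with it.  A
half-life is reportable only if the concentration drop it implies over the
flowpath's median travel time τ exceeds twice the relative measurement
precision: medians above `ln 2 · τ / (−ln(1 − 2·rel_sd))` are rendered as
the literal `Inf` with the IQR suppressed (strict inequality at the
threshold; masking is idempotent).  Goodness of fit is the RMSE between
observations and the forward curve at posterior-median parameters, averaged
per compound over the four flowpaths.  The results table is one row per
compound: R (a–d), DT50 (a–d) with IQRs in brackets at three significant
figures, and the average RMSE; missing flowpaths render as explicit gaps.

## Synthetic data generator

The generator emulates the flume injection experiment with known ground
truth: all compounds start at 11.5 µg L⁻¹ in the surface water (the
calculated post-mixing initial concentration) and decline exponentially at
a compound-specific rate; porewater curves follow the forward model on the
fine grid; sampling occurs at days 0, 1, 2, 3, 7, 14, 21; measurement noise
is multiplicative lognormal (median-unbiased) with default 5% coefficient
of variation — concentrations stay positive and LC-MS/MS error is roughly
relative; censoring below the LOQ (default 0.1 µg L⁻¹) substitutes
LOQ·2^(−1/2) and sets a flag.  The surface-water record is emitted only at
sampling days, forcing the pipeline to interpolate exactly as it must with
real data.  The benchmark scenario covers three behavioural archetypes on
all four flowpaths: a conservative reference (k = 0, R = 1.2), a fast
degrader (k = 1 h⁻¹, R = 3) and a retarded moderate degrader
(k = 0.02 h⁻¹, R = 8), with `D` at the tabulated medians.

What the generator does not emulate: surface-water refill/dilution events
(timing unpublished; hooks exist but default off), transformation-product
formation chains, flow-field changes from bedform flattening, and spatially
variable microbial activity.  Passing recovery tests therefore demonstrate
the correctness of the inversion machinery under the stated error model,
not that field data of arbitrary structure will be equally informative —
in particular the smooth exponential surface-water boundary makes `D`
nearly unidentifiable on the dispersion-dominated shortest flowpath,
whereas the real record's fluctuations carried more information.

## Numerical choices and scaled-down defaults

- Sampler test scale: 20 chains × 2500 generations, burn-in 0.6, anneal
  0.4 — chosen so a single fit converges (R̂ < 1.2) in ~25 s; the
  study-scale default (4004 generations) doubles that.
- Inference grid 40 cells × 1 h; generation grid 125 cells × 0.1 h, so the
  inversion never runs on the grid that produced the data.
- SSR floored at n·(10⁻¹²)² in the Jeffreys likelihood so noise-free fits
  stay finite.
- Ties and boundaries: values exactly at the LOQ are not censored; a DT50
  median exactly at the threshold is not masked.
- All randomness flows through `numpy.random.default_rng` seeds; chained
  fits draw child seeds from a `SeedSequence` spawn in a deterministic
  order, so pipeline outputs are bit-reproducible for a given seed.

## Known limitations

- Time-invariant `k`, `v`, `D` over the 21-day window (the study's own
  steady-transport assumption); compounds whose removal responds to the
  evolving redox environment violate it.
- The censored likelihood is substitution-based, matching the data
  preparation, and slightly overweights heavily censored records.
- Marginal medians of `k` and `R` from the full five-parameter fit carry
  the scaling-ridge skew described above; comparisons across compounds on
  the same flowpath (same priors) remain meaningful.
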