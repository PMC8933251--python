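# Methods

## The model

Each physiological rate (whole-colony calcification, dark respiration,
net photosynthesis) is modeled independently as a power law of live 3D
surface area on the natural-log scale, with species-level random
intercepts and slopes:

    ln R_{s,i} ~ Normal(μ_{s,i}, σ)
    μ_{s,i}   = (ln α + ζ[s,1]) + (β + ζ[s,2]) · ln x_i
    ζ_s       = diag(σ_ζ) · L_Ω · δ_s ,  δ_s ~ Normal(0, I₂)

`ln α` and `β` are the among-species mean intercept and scaling
exponent; `ζ` holds each species' additive deviations, built
non-centrally from standardized effects `δ_s`, the deviation SDs `σ_ζ`
(intercept, slope) and the Cholesky factor `L_Ω` of the 2×2 correlation
matrix with off-diagonal ρ. Priors: `β, ln α ~ N(0, 5)`;
`σ, σ_ζ ~ Gamma(shape 2, rate 0.1)` (rate = inverse scale);
`Ω ~ LKJ(1)`, i.e. ρ uniform on (−1, 1). Assumptions worth keeping in
mind: lognormal residuals (multiplicative biological scatter), no
measurement error in ln x, no covariates beyond area, and no cross-rate
covariance (three separate fits).

Derived quantities are per-draw transforms: the area-specific exponent
`1 − β` (0 under isometry, positive under hypo-allometry), the isometry
probability `P(β ≥ 1)` (overall or per species), Bayesian R² on the log
scale (Var(fitted) / (Var(fitted) + Var(residual)), both empirical over
observations within each draw), and posterior (predictive) rates
`exp[(ln α + ζ₁) + (β + ζ₂) ln x]`, optionally with lognormal residual
noise for new-colony prediction.

## Sampling

The posterior is sampled with a collapsed scheme. Conditional on the
scale parameters φ = (σ, σ_ζ, ρ), the model is linear-Gaussian in the
2 + 2S coefficient vector c = (ln α, β, ζ·,₁, ζ·,₂), so c is integrated
out analytically. With V₀ the block-diagonal prior covariance of c
(factored as V₀ = L Lᵀ, valid even at σ_ζ = 0 or |ρ| = 1), Q = XᵀX/σ²
and A = I + Lᵀ Q L, the marginal likelihood uses log|V₀P| = log|A| and
P⁻¹ = L A⁻¹ Lᵀ, which stay finite as the hierarchical SDs shrink — the
"funnel" that hampers non-gradient samplers on the joint space never
appears. An affine-invariant ensemble (emcee, 20 walkers) explores the
smooth 4-dimensional marginal of φ on the unconstrained scale (log SDs,
atanh ρ, with Jacobians); each requested chain is an independent
ensemble whose post-burn-in states are flattened in (step, walker)
order and thinned deterministically to exactly
`draws_per_chain − warmup` draws. For every retained φ draw the
coefficients are then drawn exactly from their multivariate-Gaussian
conditional, so the assembled draws target the full joint posterior
without approximation.

Two profiles are provided: the full profile (3 chains × 5000 draws,
2500 warm-up → 7500 retained) and a reduced profile for tests and
examples (3 × 1000/500 → 1500). The per-chain ensemble runs at least
400 burn-in and 400 sampling steps regardless of the requested draw
count; because one ensemble step advances 20 walkers, the reduced
profile already thins ~8000 post-burn-in states down to 500 per chain.
Convergence is monitored with the classic split potential
scale-reduction factor (split-R̂ of chain-half means and variances, not
the rank-normalized variant) for every reported parameter; a fit with
any R̂ ≥ 1.05 is returned but flagged non-converged with a warning.
Draw bookkeeping (chains × (draws − warmup) retained) is asserted
structurally in the draws container.

Numerical details: overflowed ensemble proposals (|log SD| > 30) get
log-probability −∞ and are rejected; the LKJ(1) density is handled as
an exact constant so ρ → ±1 cannot produce 0·∞; recovering δ from ζ
floors the SDs at 10⁻¹² (δ is unidentified in that limit anyway). In
`log_posterior`, a `σ_ζ` entry of exactly 0 is treated as that
random-effect dimension switched off structurally — its Gamma prior
term is skipped — so the density collapses cleanly to the lower-level
model instead of hitting the boundary −∞.

## Rate extraction

O2 traces: the first 30 min (configurable) are discarded as
stabilization; slope and R² come from ordinary least squares of
concentration on time; the whole-colony flux is
(slope − mean control slope of the same measurement set and phase) ×
chamber volume, with volumes 0.5/1/4 L for size classes S1/S2/S3
(< 100, 100–400, > 400 cm²). The light-phase flux is interpreted as
**net** photosynthesis and gross = net + respiration (the standard
respirometry convention); respiration is the negated dark flux, and a
positive dark flux is flagged implausible and excluded.

Calcification: with A_T in μmol kg⁻¹, the control-corrected drop ΔA_T
over Δt hours gives rate = ΔA_T/(2Δt) · ρ_sw · V (μmol h⁻¹, ρ_sw =
1.025 kg L⁻¹ bridging per-kg alkalinity to per-L volume), × 10⁻⁶ →
mol h⁻¹, ÷ area → mol cm⁻² h⁻¹, × 100.0869 g mol⁻¹ → g cm⁻² h⁻¹. The
internal mass unit is grams throughout; the community stage converts to
mg so both fluxes share units.

QC removes a colony when (a) its calcification is negative
(dissolution), (b) any temperature record of its incubation leaves
[27, 31] °C, or (c) any of its O2 fits has R² < 0.8 (boundary values
pass). Every removal is logged with the rule that fired; the filter is
idempotent. Control pairing is the per-set mean of the blank chambers;
one combined (light-period) alkalinity pair per colony enters the
calcification estimate.

## Community upscaling

Planar areas from visual length/width use the circle approximation
((L + W)/4)² π. For a year with cover c% of a transect (default 10 m²
= 10⁵ cm²), colonies are drawn with replacement from the size pool
until the cumulative planar area first reaches c/100 × transect area;
the crossing colony is included (first-crossing stop rule; an
exclude-overshoot variant is available). The community ratio is
Σ netP(taxon_i, x_i) / Σ G(taxon_i, x_i) with per-colony rates from the
fitted power laws, calcification converted to mg h⁻¹; supplying
posterior draws instead of point estimates propagates parameter
uncertainty into the ratio. Genus-level cover maps one-to-one onto the
fitted taxa (Acropora → A. hyacinthus, etc., configurable). The model
x is the colony's planar area times a per-taxon conversion factor to 3D
area, default 1.0 (no published conversion; flagged in output
metadata). The replicate loop (default 50) reports per-year means and
empirical 95% spreads; no significance test is attached to year-to-year
changes, only those spreads.

Because photosynthesis is (near) isometric and calcification
hypo-allometric, the ratio depends on the colony-size distribution and
barely on cover: sweeping cover 3% → 50% with a fixed pool moves the
expected ratio by under 1% (50 replicates), while shifting the pool
toward larger colonies strictly lowers community calcification per unit
planar area.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with every truth recorded in a manifest: log-log-linear rates with
bivariate-Gaussian species deviations and lognormal colony scatter
(the scatter σ is part of each colony's realized rate, so the
downstream fit sees it as residual variance); O2 traces linear in time
(slope = flux / volume) with a stabilization transient that is exactly
zero from 30 min onward and i.i.d. Gaussian sensor noise (default SD
0.05 mg L⁻¹); alkalinity pairs constructed by inverting the
calcification formula (an exact round trip at zero titration noise;
default titration SD 2 μmol kg⁻¹); a cover trajectory log-linear from
50% down to 3% at the disturbance year and back by the recovery year,
split among six genera by seeded Dirichlet weights; and one shared
lognormal planar-area pool (default log-mean ln 150 cm², log-SD 0.8 —
placeholders, since no distribution parameters are published; override
when real size data exist).

Default truths: calcification ln α = −6.126 **on the mg h⁻¹ scale**
(−6.126 − ln 1000 in the internal g h⁻¹ unit), β = 0.881, σ = 0.3,
σ_ζ = (0.613, 0.075), ρ = −0.58; respiration ln α = −4.154, β = 1.074;
net photosynthesis ln α = −3.971, β = 1.033 (both mg O2 h⁻¹, σ = 0.45).
The mg-scale calibration keeps the implied alkalinity drawdowns at tens
of μmol kg⁻¹ per 3-h incubation — physically sensible for the 0.5–4 L
chambers. Colony areas are log-uniform on [10, 2000] cm² for even
leverage in log space.

What the generator does **not** emulate: tank hydraulics, light cycles
or O2 depletion feedback (traces are unboundedly linear, so an extreme
large colony can push synthetic concentrations below zero), bleaching,
seasonal variation, or taxon-specific size distributions. Passing the
recovery suite therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Problem sizes and reproducibility

Tests run the reduced profile; recovery and discrimination batteries
use 20 replicate fits of ~250 colonies (6 species × 42) each. The
acceptance script runs the full 3 × 5000/2500 profile on a 72-colony
simulated study, 1000-input oracle batteries, and a 50-replicate cover
sweep. All randomness flows from `numpy.random.SeedSequence` fan-out of
one user seed; identical seeds give byte-identical simulated tables and
identical posterior draws.

## Known limitations

* Six species give weak information on σ_ζ and ρ; their posteriors
  lean on the Gamma(2, 0.1) and LKJ priors, and posterior means of the
  deviation SDs sit above the generating values at this group count.
* The planar→3D area conversion in the community stage defaults to 1.0,
  so absolute community fluxes inherit that choice; the P/G ratio is
  less sensitive because both fluxes share the same colonies.
* The community ratio's absolute level depends on the mass-unit
  convention (mg O2 per mg CaCO3 here); comparisons across years and
  taxa are unit-invariant.
* Bayesian R² uses empirical within-draw residual variance; with very
  few observations it is noticeably prior-influenced.
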