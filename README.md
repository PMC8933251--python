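# coralscale

Metabolic scaling of reef-building corals, from raw incubation
measurements to community-level flux ratios.

Colony abundance on reefs is usually recorded as % cover, a metric blind
to colony size. That matters because physiological rates need not scale
proportionally with colony surface area: for a rate R and live 3D
surface area x (cm²), the power law

    R = α · x^β        ⇔        ln R = ln α + β · ln x

is **isometric** when β = 1 (per-area rate constant across sizes) and
**hypo-allometric** when β < 1 (smaller colonies run faster per unit
area; the area-specific rate scales as x^(1−β) inverted, i.e. with
exponent 1 − β). Whether calcification, respiration and photosynthesis
are isometric or allometric decides whether cover alone is enough to
upscale reef functioning — and coral calcification turns out to be
hypo-allometric while the O2 fluxes are isometric, so community
calcification depends on colony-size structure, not just cover.

`coralscale` implements that whole analysis chain as a tested library
for quantitative marine ecologists:

1. **`coralscale.physio`** — respirometry O2 traces (stabilization
   trimming, least-squares slope, blank-chamber correction, volume
   scaling) and alkalinity-anomaly calcification (1 mol CaCO3 per
   2 mol alkalinity drop: rate = −ΔA_T/(2Δt) · ρ_sw · V, converted via
   the CaCO3 molar mass), plus the quality-control rules (negative
   calcification, tank temperature outside 27–31 °C, O2-fit R² < 0.8).
2. **`coralscale.scaling`** — a hierarchical Bayesian log-log
   regression with correlated species-level deviations of intercept and
   slope:

       ln R_{s,i} ~ Normal(μ_{s,i}, σ)
       μ_{s,i}   = (ln α + ζ[s,1]) + (β + ζ[s,2]) · ln x_i
       ζ_s       = diag(σ_ζ) · L_Ω · δ_s ,   δ_s ~ Normal(0, 1)

   with priors β, ln α ~ N(0, 5), σ and σ_ζ ~ Gamma(2, rate 0.1), and
   an LKJ(1) prior on the 2×2 correlation Ω. Sampling is a collapsed
   MCMC (the linear coefficients are marginalized analytically; an
   affine-invariant ensemble explores only the scale parameters), with
   split-R̂ convergence checks and derived quantities: the
   area-specific exponent 1 − β, the isometry probability P(β ≥ 1),
   Bayesian R², and posterior predictive rates.
3. **`coralscale.community`** — cover-matched resampling: colonies are
   drawn from an empirical planar-area pool (planar area ≈
   ((length+width)/4)²·π) until they fill the reported % cover of a
   10 m² transect, and the community ratio of net photosynthesis to
   calcification is propagated through the fitted power laws.
4. **`coralscale.synthdata`** — a generator producing all raw inputs
   with known ground truth, so every stage is testable by parameter
   recovery without any field data.
5. **`coralscale.pipeline`** + a thin `coralscale` CLI — reproducible
   end-to-end runs (`simulate → process → fit → upscale → report`).

## Worked example

Fit the scaling model to a synthetic calcification data set whose truth
is ln α = −6.126, β = 0.881, σ = 0.3 (`examples/03_fit_scaling.py`):

```text
retained 1500 draws (3 chains x 500); max R-hat 1.030, converged=True
parameter  kind   mean   q2.5  q97.5  rhat
 ln_alpha fixed -6.421 -7.753 -4.729 1.002
     beta fixed  0.918  0.806  1.035 1.002
    sigma fixed  0.310  0.283  0.336 1.009

truth: ln_alpha=-6.126, beta=0.881, sigma=0.3

area-specific exponent 1-beta: mean 0.082 [-0.035, 0.194]
P(beta >= 1) = 0.055
```

Every truth value lies inside its 95% credible interval; the small
isometry probability says the data favour hypo-allometry — smaller
colonies calcify faster per cm². The other scripts in `examples/` walk
through input simulation, rate extraction + QC, and the community ratio
time series (which stays flat within ~1% while cover swings 3% → 50%,
because with a fixed size distribution the P/G ratio tracks demography,
not cover).

The same end to end from a shell:

```bash
coralscale all --outdir run1 --seed 1 --profile paper
```

writes the five input tables, the retained-colony and QC-rejection
CSVs, fixed-effect and per-species posterior tables, per-draw posterior
files, the per-year ratio series, and a metadata block with the config
hash and stage seeds.

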