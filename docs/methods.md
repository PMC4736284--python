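# Methods

## Models

Two genomic mixed models share the linear predictor `η = Xβ + Zu + Wp`:

* **Gaussian family.** `y = η + e`, `e ~ N(0, σ²_e I)`. The identity-link
  animal model with genomic relationships.
* **Poisson family.** `yᵢ ~ Poisson(exp(lᵢ))` with a latent record-level
  variable `l = η + e`, `e ~ N(0, σ²_e I)`. A bare Poisson mixed model
  forces the conditional variance to equal the conditional mean; the
  Gaussian residual on the log scale gives over-dispersion somewhere to go.
  The latent distribution is Gaussian (not gamma), so σ²_e is estimated
  directly as a variance component.

`u ~ N(0, σ²_u G)` with the VanRaden genomic relationship matrix
`G = MM′ / 2Σpᵢ(1−pᵢ)`; `p ~ N(0, σ²_p I)` is the permanent-environment
effect, included exactly when the design has repeated records per
individual (litters per sow). Fixed effects get a vague `N(0, 1e10·I)`
prior.

### Variance priors

Each variance component has a scaled inverse chi-square prior
`σ² ~ Scale-inv-χ²(V, S)` with `S = V·σ²*`, where σ²* is the prior
most-likely value taken from earlier variance-component studies of the same
population. Equating the prior mode `VS/(V+2)` to σ²* gives `V² − V − 2 = 0`
with roots −1 and 2; the admissible root V = 2 is used. Built-in σ²*
defaults: stillbirth-like trait (u, p, e) = 0.3575, 0.33, 3.9125; teat-like
trait = 0.43, 0.0221, 0.71. Note this prior is weak in its degrees of
freedom but firm on its lower tail: the `exp(−VS/2σ²)` factor puts
negligible mass far below σ²*, which matters when interpreting latent-scale
residual variance estimates.

## Sampler

β, u, p, and the three variances have closed-form full conditionals
(Gaussian for locations, scaled inverse chi-square for variances) and are
Gibbs-updated in blocks. The u conditional has precision
`Z′Z/σ²_e + G⁻¹/σ²_u`. Because only the two scalars change across
iterations, we compute one generalized eigendecomposition of (Z′Z, G⁻¹) up
front; in the resulting basis the conditional is diagonal, so every sweep
costs O(n²) instead of a fresh O(n³) factorization. The update is exactly
the standard block draw, not an approximation. G is conditioned before
inversion by deterministic blending, `G ← 0.99·G + 0.01·I` (weight
configurable), standing in for the generalized inverse used with
near-singular genomic matrices.

For the Poisson family the latent coordinates are conditionally independent
given the other parameters, with density proportional to
`Poisson(yᵢ|exp(lᵢ)) · N(lᵢ|ηᵢ, σ²_e)`. All coordinates are updated
simultaneously by independent Gaussian random-walk proposals with
per-coordinate step sizes, adapted by Robbins–Monro toward 0.44 acceptance
during burn-in only (adaptation then stops, preserving detailed balance in
the sampling phase). Initialization: `lᵢ = log(yᵢ + 0.5)` — finite at zero
counts, near the conditional mode elsewhere. Proposals above 50 on the log
scale are rejected outright to guard `exp` overflow.

Defaults follow the full analysis profile: 100,000 iterations, 50,000
burn-in, thinning 2 — `floor((n_iter − burn_in)/thin)` = 25,000 retained
samples. A `fix_variances` hook pins any subset of variance components,
enabling exact comparison against the closed-form mixed-model-equations
(MME) solution. Identical seeds give bit-identical chains.

## Marker scan

At each retained iteration the GEBV sample is back-solved through the
SNP-BLUP identity `α⁽ᵏ⁾ = M′(MM′)⁻û⁽ᵏ⁾`; the pseudo-inverse is computed
once (relative singular-value tolerance 1e−10) and reused. When MM′ is full
rank this is an exact projection: `M·α⁽ᵏ⁾ = û⁽ᵏ⁾`. With column-centered M,
MM′ always has the all-ones null vector (rank n−1), so reconstruction then
recovers each û⁽ᵏ⁾ up to its mean — the per-SNP effects are unaffected, but
exact reconstruction checks should use raw 0/1/2 coding (`center=False`).

Per SNP, the retained α chain is summarized by (i) the 95% HPD interval —
the shortest contiguous window of order statistics containing
`ceil(0.95·n)` points, ties broken toward the lowest start; significant
when zero is outside — and (ii) PPN0, the fraction of samples on the side
of zero indicated by the posterior mean (exact zeros counted for neither
side); significant when strictly greater than 0.95, mirroring the stated
rule. Both flags are reported separately and their union is the
"significant" column. Chains failing the Geweke test at 0.01 are flagged,
never dropped.

### Null behaviour of the significance rules

GBLUP is a shrinkage model. On a zero-heritability trait the variance
posterior collapses and the back-solved per-SNP posteriors concentrate on
zero with |mean|/sd rarely above 2, so the HPD rule flags essentially no
SNPs (measured 0–0.4% across estimated- and fixed-variance analyses at
n = 200, N = 500). This is conservatism, not miscalibration: when effects
are drawn from the model itself, the 95% HPD intervals cover the true
per-SNP effects at close to nominal rate (~89–91% measured). Users should
expect false-positive control far better than 5% and correspondingly modest
power at small sample sizes.

## DIC and model comparison

`DIC = D(θ̄) + 2p_D` with `p_D = D̄ − D(θ̄)`. For the Gaussian family the
deviance is `−2 log N(y|η, σ²_e)` evaluated per retained draw and at the
posterior means. For the Poisson family the DIC is focused on the latent
variables: the deviance is the data likelihood given l,
`−2 Σ log Poisson(yᵢ|exp(lᵢ))`, with the posterior mean of l entering θ̄.
This matches the reference MCMC engine for such models; folding the latent
Gaussian density into the deviance instead would add a penalty of order
n_records that makes the count model unable to win any comparison,
contradicting its observed fit advantage on skewed counts. Comparison
labels follow the usual rule of thumb: |ΔDIC| < 2 equivalent, 2–7 weak
preference, > 7 strong preference for the smaller.

## Convergence diagnostics

Geweke's stationarity test compares the means of the first 10% and last 50%
of a chain, each variance estimated by the spectral density at frequency
zero via a Bartlett-windowed autocovariance sum (lag window
`4·(n/100)^{2/9}`). Calibration is verified by Monte Carlo on iid chains
(rejection rate at the 5% level within [2%, 9%] over 200 chains) rather
than by matching any particular reference implementation bit-for-bit.

## Linkage disequilibrium and QTL regions

Two-locus haplotype frequencies come from EM over the double-heterozygote
phase ambiguity (convergence when the largest frequency change is below
1e−8, cap 1,000 iterations; the log-likelihood is non-decreasing by
construction). D′ = D/D_max, and its 95% confidence bounds follow the
Haploview family of methods: the multinomial likelihood of the 2n
haplotypes is evaluated on a 0.001-step D′ grid with margins fixed at their
sample estimates, normalized, and the bounds read where the cumulative mass
crosses 0.05 and 0.95. A pair is in strong LD when the lower bound ≥ 0.70
and the upper ≥ 0.98; a pair is informative when its upper bound is ≥ 0.98
or < 0.90 (evidence either way). QTL regions are maximal runs of
consecutive significant SNPs on one chromosome in which at least 95% of
informative pairs are strong; windows with no informative pair do not
extend. Remaining significant SNPs are reported as singletons, so regions
plus singletons always partition the significant set. Regions and
singletons are extended by 32.5 kb — half the chip's average inter-SNP
spacing — clipped at position 1 and the chromosome end. Internal
coordinates are 1-based inclusive; BED output converts to 0-based half-open
and says so in its header.

## Synthetic data

The generator produces exactly the structures the two models assume, with
ground truth retained for recovery tests.

* **Genotypes.** Gamete-wise draws with per-SNP MAF uniform in a configured
  range. Local LD uses first-order Markov copying: each gamete carries a
  latent uniform copied from the previous SNP with probability `ld_decay`
  and refreshed otherwise, so marginal allele frequencies are exact while
  adjacent-SNP correlation decays geometrically. Positions sit on a 65 kb
  grid (chip-like spacing; half of it is the 32.5 kb flank). Missing
  genotypes are injected only on request (default 0%).
* **Effects.** QTL positions are a uniform draw; their effects are centered
  Gaussians rescaled so that var(M·α) equals the requested additive
  variance, matching the exchangeable-effects assumption of GBLUP, and
  `u = M·α` holds exactly.
* **Traits.** Gaussian records add Gaussian noise on the trait scale (an
  optional rounding flag produces integer teat-like records); Poisson
  records draw `y ~ Poisson(exp(l))` from the latent predictor. Repeated
  records share their individual's u and p. The number of records per
  individual is a fixed configuration value (default 4, close to the
  average parity count of ~3.9 in the motivating population, whose
  distribution across sows is not documented).
* **Default study conditions.** Stillbirth-like: mean count 1.2 via the
  latent intercept (adjusted by half the latent variance), latent variances
  (u, p, e) = 0.15, 0.2, 0.5 — count heritability is low and real litter
  counts with range up to ~16 are clearly over-dispersed (the simulated
  variance/mean ratio is ≈2.5), which is what distinguishes them from a
  bare Poisson. Teat-like: mean 15.3, additive and residual variances 0.43
  and 0.71 on the trait scale, single records.
* **What it does not emulate.** Coalescent-accurate LD, pedigree structure,
  genotyping error, selection, or family stratification. Passing recovery
  tests therefore demonstrate correctness of the estimation machinery under
  the model's own assumptions, not robustness to violations found in real
  chip data.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 75–300 individuals,
150–500 SNPs and chains of 2,000–12,000 iterations — sizes chosen so the
whole suite re-runs in minutes while keeping every Monte Carlo margin wide
(model-recovery counts of 10/10 against a pass mark of 8/10, oracle
correlations ~0.9999 against a 0.999 bar). The full-profile settings remain
the package defaults. Other numerics: pseudo-inverse tolerance 1e−10;
GRM blend weight 0.99; EM tolerance 1e−8; D′ grid step 0.001; MH target
acceptance 0.44 with steps clipped to `exp(±[−5, 3])`; fixed-effect
identifiability by dropping the first level of each factor (reference
coding) rather than leaning on the vague prior alone.

## Known limitations

* Single-trait models only; no negative-binomial or generalized Poisson
  family for counts whose variance-mean link is still wrong after the
  latent residual.
* Per-SNP convergence screening is Geweke-only.
* Binary PLINK (.bed) is not read; use text .ped/.map.
* The QTL-region caller assumes runs of consecutive significant SNPs;
  non-adjacent significant SNPs never join a region.
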