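# Methods

This note records the models, parameter choices and numerical decisions
behind `gwasbench`, and what the synthetic benchmarks do and do not show
about real data.

## Trait model and heritability calibration

Phenotypes are additive: `Y_j = Σ_i a_i S_ij + e_j` with dosages
`S_ij ∈ {0,1,2}` at the causal markers and effects `a_i ~ N(0,1)` by
default (`geometric` draws `r^i` with random sign, ratio r = 0.92, for
studies that assume a declining effect-size series). Residuals are
`N(0, sd²)` with `sd = sqrt(Var(g)·(1/h² − 1))`, where `Var(g)` is the
**sample** variance (denominator n−1) of the realized genetic values across
the simulated individuals. Using the realized rather than the expected
genetic variance makes the calibration exact in finite samples: the mean of
`Var(g)/Var(Y)` over residual replicates recovers `h²` to within ±0.02 at
h² ∈ {0.1, 0.5, 0.9} (tested with 2000 replicates). At `h² = 1` the
residuals are exactly zero. The residual RNG stream is derived from the
architecture seed by a fixed offset so architectures and noise can be
re-drawn independently; a trait is a pure function of (genotypes,
architecture).

Causal markers are drawn uniformly without replacement; no MAF floor is
applied by default (an optional `min_maf` exists, and benchmark fixtures
draw from MAF-filtered panels, mirroring how diversity panels are filtered
before association analysis). Epistasis, dominance and MAF-dependent effect
sizes are out of scope.

## Synthetic populations

The generator emulates the three dataset properties that differentiate real
crop panels — MAF spectrum, population structure, LD decay — without
attempting demographic realism:

- **Differentiation** follows Balding–Nichols: ancestral frequency `p` per
  marker, subpopulation frequency `~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `F`
  acts as FST (verified against a Weir–Cockerham-style estimator,
  ±0.05 at F = 0.3).
- **MAF presets**: `u-shaped` (Beta(0.2, 0.2) truncated to [0.01, 0.99])
  imitates GBS spectra rich in rare alleles; `common-filtered`
  (Uniform(0.1, 0.5)) imitates array or pre-filtered panels.
- **LD** arises from founder-haplotype copying: each individual's haplotype
  is a mosaic over a per-subpopulation founder pool with per-bp
  template-switch probability `1 − exp(−rate·gap)`, giving geometric tract
  lengths and a decay length of roughly `1/rate`. Individuals are fully
  inbred by default (one mosaic doubled), matching inbred crop panels.

Two desk-scale caveats. First, founder haplotypes are sampled site-wise
independently, so the maximum distance-dependent r² is about
`1/n_founders`; with several subpopulations, differentiation adds a
distance-independent r² baseline that can mask decay. LD-decay experiments
therefore use a single subpopulation with a small founder pool
(6 founders), where the half-max decay scale cleanly tracks the switch
rate. Second, overall LD in the default benchmark panel is weaker than in
real GBS data, so the LD-linked true-positive rule fires less often than it
would on a real panel — power numbers here are driven mostly by direct
causal hits. Passing benchmarks demonstrate engine *orderings* under
controlled conditions, not absolute power levels on any real crop panel.

The default benchmark population is 500 individuals × 5000 markers,
3 subpopulations, F = 0.25, switch rate 1e-5/bp, `u-shaped` MAF, then
filtered at MAF ≥ 0.05 (≈ 4600 polymorphic markers) — small enough for
minutes-scale runs while preserving structure that the engines must
control for.

## Mixed linear model (Q+K)

`y = Wα + xβ + u + e` with `W` = intercept + first three PCs of the
marker-standardized dosage matrix, `u ~ N(0, σ_g² K)`, `K` the centered
genomic relationship matrix `XcXcᵀ/M`. REML is profiled to the single ratio
`λ = σ_g²/σ_e²` after one eigendecomposition of K and maximized by bounded
scalar search on `log10 λ ∈ [−5, 5]` (tolerance 1e-6; boundary solutions
flagged, not rejected). The default `approx` scan reuses the null λ for
every marker and runs as one vectorized generalized-least-squares pass
(Wald t-test, two-sided, df = n − c − 1); `exact` re-optimizes λ per
marker and is used to validate the approximation (−log10 p agreement
within 15% for top markers on moderately polygenic traits; the
approximation is intentionally not checked on single-dominant-marker
traits, where the null fit's σ_g² absorbs the marker's own effect — the
known cost of the single-null-fit shortcut). With `K = I` the scan reduces
exactly to covariate-adjusted OLS (agreement to 1e-8 relative).

A subtlety worth recording: under a pure-noise trait, λ̂ shrinks to the
boundary only when K's informative eigendirections remain in the model.
When the same leading structure is also included as fixed-effect PCs, those
directions are projected out of the REML contrasts and λ becomes weakly
identified — its null distribution is then diffuse rather than
concentrated at zero. The null-shrinkage check therefore fits K without PC
covariates.

## Multi-locus circulating scan

The fixed-effect half is OLS with intercept + 3 PCs + current pseudo-QTN
dosages (collinear pseudo-QTN columns dropped with a warning); each
pseudo-QTN reports its own covariate t-test p-value. The random-effect half
bins markers (bin sizes 5e5/5e6/5e7 bp, counts 10–100 by 10), keeps the
best-p marker per bin, prunes mutual LD r² > 0.7, and scores each candidate
set by the REML likelihood of `y ~ intercept` plus a random effect whose
covariance is a VanRaden kinship built from the candidate markers only; the
maximizing set becomes the next pseudo-QTN set.

Three stabilizers govern the circulation:

- **Stop threshold** 0.01/M on the minimum p of the first scan: if nothing
  reaches it, the engine returns the plain covariate-adjusted scan. This is
  the engine's null protection — on pure-noise traits it keeps p-values
  uniform and Bonferroni calls at zero (≥ 95% of seeds).
- **Entry threshold** 0.01 on candidate markers (exposed in config).
- **Likelihood hysteresis**: a newly selected set is accepted only if it
  improves the standing set's REML score by > 0.01 log-units; otherwise the
  circulation has converged. Without this, conditioned scans keep
  refreshing weakly-supported candidates and the pseudo-QTN set drifts
  indefinitely on weak-LD panels. Exact repetition of a previous set (cycle
  detection) also terminates; 10 iterations is the hard cap, with a flag on
  non-convergence.

Scoring candidate sets against the no-QTN null is *not* a usable null
check: candidates are selected for association with y, so their in-sample
REML support is inflated by construction.

## BayesCπ

Spike-and-slab regression with a common effect variance: per sweep, each
marker's inclusion indicator is sampled from its full conditional with the
effect integrated out, then the effect given inclusion; `σ_β²` and `σ_e²`
have scaled-inverse-χ² full conditionals (df 4 each — the df is a package
choice, exposed in config); `π ~ Beta(M−m+1, m+1)` under a uniform prior.
The sampler is a numba kernel, seed-deterministic, O(M·N) per sweep. No
population-structure covariates enter the sampler by default (an optional
PC pre-adjustment of y exists but is off, matching how such samplers are
typically run); this contributes to its higher Type-I error on structured
panels.

Priors: the production defaults are chain 11000 / burn-in 1000 / π start
0.9999; benchmarks use shortened chains (2000/200 production, 1000/100
pilot) to keep runs at desk scale. The pilot chain runs with genetic and
residual variance priors of 1 and its posterior means seed the production
chain's priors (two-step procedure) — this is essential whenever the trait
scale is far from 1, and all benchmark runs use it.

Mapping the total-genetic-variance prior `V_g` to the per-effect slab uses
`σ_β² = V_g / (n_eff · mean Var(x))` with `n_eff = max((1−π)·M, 10)`. The
floor matters at desk scale: with a few thousand markers, π = 0.9999
implies well under one causal variant, and the unfloored map hands each
marker the entire genetic variance as slab — so wide that small-effect
markers can never enter and the chain freezes in the null basin. With the
floor, the sampler reproduces both regimes of interest: accurate counts for
simple, heritable traits (n̂ ≈ 8–10 for 8 QTNs at h² = 0.9) and the
characteristic over-estimation for complex, weakly heritable traits
(median n̂ ≫ 256 for 256 QTNs at h² = 0.3, the model soaking residual
noise with extra markers). In that overfit regime the heritability
estimate saturates as well; ĥ² is reliable in the sparse/heritable regime
and increasingly optimistic as the polygenic mode takes over. At moderate
heritability the sparse and polygenic posterior modes genuinely compete,
and short chains can land in either — a bistability worth knowing about
when interpreting single runs.

Ranking uses posterior model frequency with ties broken by per-marker
genetic variance, then marker index. A 3-marker exhaustive
Bayesian-model-averaging oracle (closed-form marginal likelihoods at fixed
variances and π) validates the sampler's stationary distribution.

## Evaluation

A positive is a true positive if it is causal or has `r² > 0.6`
(strictly greater) with a causal marker on the same chromosome within
10 Mb; positives linked to the same causal variant collapse to one credit
and the effective positive count shrinks accordingly; a positive linked to
two causal variants credits only the highest-r² one. FDR at zero positives
is reported as 0 with a flag to keep curves plottable. The Type-I
denominator is `M − n_causal` exactly. Power changes by < 0.1 absolute
across matching thresholds 0.6–0.9 on the synthetic panels.

## Sweep machinery

Per-cell seeds derive from the base seed by a splitmix64 mix of
(n_qtn, h², replicate), keeping all seeds distinct, below 2³¹, and stable
under grid extension. The default design (QTN counts 2¹..2¹⁰ ×
heritabilities 0.1..1.0 × 10 replicates) enumerates exactly 1000 phenotype
datasets per population. Cells are resumable via per-cell artifacts; an
engine failure flags its cell and the sweep continues. K grids default to
1..2·n_qtn with log-spaced thinning above 100.

## Problem sizes

Benchmark experiments run at deliberately modest sizes chosen for
minutes-scale turnaround: the 500 × 5000 panel for kinship agreement,
power orderings and architecture estimation; 250 × 1000 for null
calibration; 200 × 1000 for the OLS-collapse oracle; shortened MCMC chains
as above. These sizes are the package's CI-scale defaults; the same code
paths scale to panel sizes typical of real studies.
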