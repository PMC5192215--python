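# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, and what the synthetic-data generators do and
do not emulate.

## Tree algebra

A `Phylogeny` is a rooted tree with branch lengths in absolute time; tips
are indexed first, the root last. The Brownian covariance scaffold is
`C[i,j] = depth(MRCA(i,j))` with root-to-tip depths on the diagonal.
Pagel's λ multiplies the off-diagonal entries only, so λ = 0 is a star
phylogeny (independent residuals) and λ = 1 the full Brownian structure.
Ultrametry is tested at relative tolerance 1e-6; OU fitting requires an
ultrametric tree (the stationarity and root conventions below are only
identifiable there), while PGLS accepts non-ultrametric trees with a
warning. Polytomies are accepted as hard polytomies. Newick parsing
requires a branch length on every non-root edge — there is no silent
default — and zero-length branches are surfaced in the reconciliation
report rather than modified. Tip matching between trees and trait tables
is exact-string, with all drops reported.

## PGLS with maximum-likelihood λ

The model is y = Xβ + ε, ε ~ N(0, σ²C(λ)). β̂ and σ̂² have closed forms at
fixed λ, so the search is one-dimensional on the profile log-likelihood
over [0, 1]: a 21-point scan followed by bounded refinement, with a
boundary tie broken toward the interior when the log-likelihood difference
is below 1e-6. For ultrametric trees C(λ) = λC + (1−λ)T·I shares C's
eigenvectors, so the entire profile costs a single symmetric
eigendecomposition; otherwise each λ evaluation performs a Cholesky
factorisation.

Conventions: coefficient SEs use the unbiased scale RSS/(n−p) and t tests
use n−p degrees of freedom; the reported log-likelihood uses the ML scale
RSS/n. AICc counts p coefficients plus two variance-structure parameters
(σ², λ). R² is computed in the whitened (V^{-1/2}) space against the
intercept-only model, and the partial R² against the body-size-only model
re-evaluates the reduced design under the full model's λ, so the two RSS
values are comparable. Missing data are dropped listwise per model with a
per-fit attrition report.

All-subsets model selection enumerates every combination of candidate
predictors (capped at 15) with forced predictors (body size) in every
model; per-variable importance is the sum of Akaike weights of models
containing the variable.

## Phylogenetic PCA

The evolutionary mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and covariance
R = (X−1a)ᵀC⁻¹(X−1a)/(n−1) are eigendecomposed; correlation mode (the
default, since CVs and snow weeks live on different scales) standardises by
√diag(R) first. Loadings are reported as ordinary correlations between
variables and scores, and each component is sign-flipped so its
largest-magnitude loading is positive. Raw scores are C⁻¹-orthogonal by
construction; a z-standardised copy is exposed separately for use as
regression covariates, because standardising in the ordinary (non-GLS)
metric would otherwise destroy that orthogonality. The default covariance
is Brownian (λ = 1) with a λ option.

## Regime classification and stochastic mapping

Residents are binned by |breeding latitude| with band edges at 23.5° and
50° (boundaries belong to the poleward bin); migrants split at 2,000 km
(≥ rule). These defaults are conventions, echoed in every output so a run
is auditable, and should be set explicitly when matching a particular
study design.

The Mk model is fitted by the pruning algorithm with per-branch matrix
exponentials; the default structure is equal-rates (ER) with symmetric
(SYM) and all-rates-different (ARD) options, and the root prior defaults to
the stationary distribution of the fitted generator (flat available). Rates
are searched in log space from three deterministic starts spanning ~0.3 to
~30 expected changes per tree.

Stochastic maps are drawn exactly: partial likelihoods give each node's
conditional state distribution (root from its posterior, children given
sampled parents), and each branch path is an endpoint-conditioned CTMC
bridge — rejection sampling capped at 10,000 tries with a uniformization
bridge fallback, which guarantees termination on stiff branches. Sampled
maps preserve observed tip states by construction (asserted). Transition
summaries report medians and 2.5/97.5 percentiles (linear interpolation)
of ordered-pair change counts across maps. The exact unconditional
expectation of change counts (occupancy integrated with an augmented
matrix exponential) is exposed as a diagnostic oracle.

Interval-coverage checks compare the across-map interval to the realized
change counts of the generating history. That is the calibrated-coverage
property conditional sampling can honestly satisfy; intervals conditioned
on one tip realisation are not expected to cover the unconditional prior
mean.

## Multi-regime BM/OU models

Along a branch segment in regime r, dx = α(θ_r − x)dt + σ_r dW. Moments
are accumulated per root-to-tip path: with A(t) the integrated pull, each
segment contributes e^{−(A(T)−A(t₁))} − e^{−(A(T)−A(t₀))} to its regime's
optimum weight and an analogous e^{−2(·)} integral to the variance, and
tip covariance discounts the shared-path variance by the decay on both
descending paths. Brownian families are the exact α → 0 limit of the same
recursion. The likelihood is the exact multivariate normal at these
moments; the simulator draws from the same per-segment Gaussian
transitions (no Euler discretisation), so simulator and likelihood share
one distributional truth.

Conventions and parameter counts: the root trait sits at the root regime's
optimum (free-root option available); BM1 = 2, BMS = 1+k, OU1 = 3,
OUM = k+2, OUMV = 2k+1 parameters; AICc/BIC use n = number of tips.
Optima and the overall variance scale are profiled analytically (GLS), so
the numeric search is over log α (OU1/OUM: scan of six log-spaced pulls
plus bounded refinement) and log rate ratios (BMS/OUMV: Nelder-Mead;
OUMV starts from the OUM pull estimate plus one moderate-pull start).
α is bounded to αT ∈ [1e-3, 200]. A fit is flagged when α lands on a
search bound or any |θ̂| exceeds 10× the trait range — the runaway-optimum
screen. OUMVA (per-regime α) is implemented but disabled by default for
exactly that pathology; enabling it is an explicit opt-in.

Ensemble summaries fit every family on every map, exclude flagged fits
(with counts), compute Akaike weights per map over that map's surviving
fits, and average the weights across maps; optima are summarised per
family and regime as mean, SE and 2.5–97.5% percentiles across maps.
AICc is computed per map with n = tips (not tips × maps); cross-map
support is expressed through the averaged weights.

## Environmental metrics

Aggregation is spatial-first: greenness is averaged over the range cells
for each (year, period), then temporal statistics are computed on that
series; a per-cell-then-average variant exists for sensitivity analysis.
CVs use the population SD — they describe a fixed climatological profile.
The within-year CV acts on the across-year mean 23-period profile; the
among-year CV on annual means. A period counts as snow-covered when ≥50%
of range cells are flagged; period counts convert to weeks via
365.25/23/7 and are averaged over years; logs are natural, as log(x+1).
Range centroids are unit-vector means on the sphere (antimeridian-safe);
migratory distance is the haversine between breeding and wintering
centroids with Earth radius 6371.0088 km. Seasonal extremes are the means
of the 4 highest / 4 lowest climatological periods — a convention, since
"summer/winter window" has no canonical width. Dietary breadth is the
similarity-weighted inverse Simpson index 1/Σᵢⱼ pᵢpⱼsᵢⱼ; the shipped
default similarity matrix is a synthetic block structure over broad
trophic groups and should be replaced by a study-specific matrix when one
exists.

## Synthetic-data generator

The raster model is
EVI(cell, year, p) = M(lat)·(1 + A(lat)cos(2πp/23))·(1 + m(lat)·η_year) + ε
with 23 periods per year over 15 years (the 16-day composite convention),
amplitude A(lat) growing linearly with |lat| (so seasonality is stronger
toward the poles), baseline M(lat) declining mildly with latitude, a
shared yearly anomaly η with a latitude-dependent multiplier m(lat)
(settable to 1 for a latitude-free anomaly), and optional observation
noise. Snow is flagged where the winter half of the cosine falls below a
latitude-shifted threshold, so snow duration lengthens poleward. Ranges
are rectangular latitude bands; migrants get separate breeding and
wintering bands.

The full-study generator ties the pieces together: a Yule tree normalised
to depth 1, an equal-rates five-regime history (rate 0.4 per unit time —
a few dozen transitions per 200-species tree), relative brain size under
OUM with optima (0, 0.15, 0.3, −0.05, −0.15) ordered low → high latitude
and migrant regimes below residents, pull α = 2 and diffusion σ² = 0.05
per unit time (stationary SD ≈ 0.11, so the largest optimum contrast is
≈ 3 stationary SDs), and an allometry with slope 0.59, intercept −2.5,
residual λ = 0.9 and residual variance 0.03 on body-size variance 2 —
magnitudes chosen to echo large cross-species avian brain-body datasets.
Breeding latitudes are drawn per regime around band centres (10°, 37°,
57°, 45°, 50° ± 4°), and migratory distances around 1,200 km
(short-distance) and 3,500 km (long-distance).

What the generator does **not** emulate: real biogeography (ranges are
rectangles, not polygons), spatially correlated anomaly fields,
measurement error in brain/body volumes, diversification heterogeneity,
or trait-dependent diversification. Passing recovery tests therefore shows
the estimators are correct and calibrated under the assumed generative
models, not that those models capture every feature of field data.

## Problem sizes and tolerances

Recovery experiments run at the sizes the analyses target: 100 replicates
of 835 tips for the PGLS slope/λ recovery, 100 replicates of 500 tips for
OU model selection, and 1,000 maps on 200 tips for transition-interval
coverage. Oracle equivalences are exact-arithmetic checks (pruning vs.
enumeration at 1e-10; PGLS vs. explicit GLS inversion at 1e-8; OU→BM
limit below 1e-4 relative at α = 1e-6/T). Monte-Carlo comparisons state
their error in SE units; joint comparisons over many statistics use a
Bonferroni-adjusted per-coordinate threshold that preserves the
family-wise error of a single 3-SE test. Covariance factorisations add a
relative jitter of 1e-12 of the mean diagonal before Cholesky; a
numerically non-PSD OU covariance yields an explicit −∞ log-likelihood
rather than an exception mid-optimisation.

## Known limitations

- PGLS assumes a single λ for the residuals; no measurement-error or
  within-species variance component.
- The Mk fit and the mapping share one Q̂ per tree; mapping uncertainty in
  Q is addressed across the tree ensemble, not within a single tree.
- OUMV with rare regimes can be weakly identified; the boundary screen
  flags rather than repairs such fits.
- The synthetic tree ensemble emulates phylogenetic uncertainty with
  independent Yule draws over the same tip set, which is more conservative
  than a posterior sample around one topology.
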