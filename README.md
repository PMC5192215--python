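# phyloenv

Phylogenetic comparative analysis of environmental variation and trait
evolution, built around the question of whether lineages exposed to stronger
seasonal and inter-annual fluctuations in resource availability evolve
larger relative brain sizes — the cognitive buffer hypothesis, tested
comparatively in birds.

The package is aimed at comparative biologists who have (or want to
simulate) three kinds of data: a time-calibrated phylogeny, a per-species
trait table (log brain volume, log body size, geography, migration), and a
gridded vegetation-greenness / snow time series with species range masks.
It provides every stage of the analysis as an importable library, a set of
narrative example scripts under `examples/`, and a thin `phyloenv` command
line for end-to-end runs.

## What it computes

**Environmental variation per species.** Range-mean greenness series are
reduced to a within-year coefficient of variation (seasonality), an
among-year CV (inter-annual unpredictability), and weeks of snow cover;
geography yields breeding-range centroids and great-circle migratory
distances.

**PGLS with Pagel's λ.** Regression y = Xβ + ε with
ε ~ N(0, σ²·C(λ)), where C is the shared-path-length matrix of the tree and
C(λ) scales its off-diagonals by λ ∈ [0, 1]. β and σ² are profiled
analytically and λ is maximised on its profile likelihood. R² is reported
both for the full model and with the body-size effect removed.

**Phylogenetic PCA.** Orthogonal axes of environmental variation from the
evolutionary correlation matrix R = (X − 1a)ᵀC⁻¹(X − 1a)/(n − 1), with a the
GLS mean.

**Stochastic character mapping.** Species are classified into five
selective regimes (resident low/medium/high latitude, migrant
short/long distance), an Mk model is fitted to the tip regimes by maximum
likelihood (pruning algorithm), and full histories with changes along
branches are sampled conditional on the tips — forward-filter /
backward-sample node states, then endpoint-conditioned CTMC bridges per
branch (rejection sampling with a uniformization fallback).

**Multi-regime trait models.** Relative brain size (PGLS residuals of log
brain on log body) is fitted under BM1, BMS, OU1, OUM and OUMV:
dx = α(θ_r − x)dt + σ_r dW with regime-specific optima θ_r and rates σ²_r.
Likelihoods are exact multivariate normals from closed-form path integrals
over the painted tree; families are ranked by AICc and BIC, and parameters
are summarised across an ensemble of maps with 2.5–97.5% intervals.

**Synthetic data.** Every generator (Yule trees, CTMC regime histories,
exact-transition OU/BM traits, allometric datasets, seasonal rasters with
latitude-dependent amplitude) carries known ground truth, so each stage has
a parameter-recovery test surface with no external downloads.

## Worked example

```python
import numpy as np
from phyloenv import (simulate_yule_tree, pgls_fit)
from phyloenv.synthetic import scale_tree, simulate_allometric_dataset

tree = scale_tree(simulate_yule_tree(300, seed=5), 1.0)
data = simulate_allometric_dataset(tree, beta1=0.59, lambda_resid=0.9, seed=6)
fit = pgls_fit(data["log_brain"], data[["log_body"]], tree)
print(fit.summary())
```

```
PGLS fit (n=300, lambda=0.914, logLik=267.92, R2=0.933, AICc=-527.71)
           estimate       se      t          p
intercept    -2.508  0.08605 -29.14  3.102e-89
log_body     0.5951 0.009271  64.19 1.583e-176
```

The slope estimate (0.595 ± 0.010) and the residual phylogenetic signal
(λ̂ = 0.91) recover the generating values 0.59 and 0.9: brain volume scales
allometrically with body size and the residual variation is strongly
phylogenetically structured. Each script in `examples/` walks one
capability the same way (environmental metrics, PPCA, stochastic mapping,
OU model comparison, full pipeline).

A complete end-to-end run on synthetic data:

```bash
phyloenv run-all --seed 11 --out results/demo
```

writes the trait table, environmental metrics, PGLS blocks, PPCA loadings,
transition-count summaries, OU model weights and a reproducibility manifest.

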