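# carsae

Bayesian small-area estimation of prevalence on areal data, built around
conditionally autoregressive (CAR) spatial mixed models.

## The problem

Administrative prevalence data — here, the share of children assessed as
developmentally vulnerable when they enter school — are reported for
hundreds of small regions with wildly uneven sample sizes: a metropolitan
region may assess thousands of children while a remote one assesses a
handful (or none, in which case the count is suppressed). The crude
("direct") estimate p̂ᵣ = yᵣ/Nᵣ is unbiased but useless in sparse regions:
its coefficient of variation can approach 100 %. Spatial smoothing borrows
strength from neighbouring regions and from an area-level
socio-economic-disadvantage covariate to produce stable region-level
estimates everywhere, including regions with no reportable data at all.

`carsae` is for biostatisticians and population-health analysts who want
this machinery — adjacency construction, direct estimation, the spatial
model, missing-data handling, and precision diagnostics — as plain Python
with no external spatial stack.

## The model

For region r = 1, …, R with Nᵣ children assessed and yᵣ vulnerable,

    yᵣ ~ Binomial(Nᵣ, pᵣ)
    logit(pᵣ) = α + Xᵣᵀβ + uᵣ + vᵣ

with vᵣ ~ N(0, τᵥ²) iid overdispersion and u a structured spatial effect
in the Leroux CAR family over the Queen-contiguity graph W:

    uⱼ | u₋ⱼ ~ N( ρ Σᵢ wⱼᵢ uᵢ / (ρ dⱼ + 1 − ρ),  τᵤ² / (ρ dⱼ + 1 − ρ) )

where dⱼ = Σᵢ wⱼᵢ. ρ = 1 is the intrinsic CAR (the BYM model); ρ = 0 is
independence; ρ is given a uniform prior and estimated in the default
`leroux` variant. Precisions 1/τᵤ², 1/τᵥ² carry gamma(1, 0.5) and
gamma(1, 0.01) priors. Fitting is a from-scratch Metropolis-within-Gibbs
sampler (see `docs/methods.md`).

Regions whose response is suppressed get the plug-in predictor
pᵣ(β̂, 0, 0); regions with no computable covariate first get a score
imputed by a Gaussian BYM smoother over the same graph.

## Worked example

```python
import numpy as np
from carsae import ModelConfig, generate_study, inject_missingness, run_pipeline

study = generate_study(335, seed=1)                      # census-like synthetic study
study = inject_missingness(study, n_response_missing=2,
                           n_covariate_missing=2, seed=1)
cfg = ModelConfig(n_iterations=8000, burn_in=3000, thinning=5, seed=2)
res = run_pipeline(study.graph, study.N, study.y,
                   np.where(study.covariate_missing, np.nan, study.score),
                   response_missing=study.response_missing, config=cfg)

cmp = res.comparison.dropna(subset=["cv_difference"])
print(res.estimates.to_frame()["provenance"].value_counts().to_dict())
print("share of regions with model CV <= direct CV:",
      round(float((cmp.cv_model <= cmp.cv_direct).mean()), 3))
print("mean CV improvement (percentage points):",
      round(float(cmp.cv_difference.mean()), 2))
```

prints

```
{'fitted': 331, 'imputed-covariate': 2, 'plug-in': 2}
share of regions with model CV <= direct CV: 0.976
mean CV improvement (percentage points): 3.11
```

Every one of the 335 regions gets an estimate: 331 fitted directly, 2
predicted out-of-sample because their responses were suppressed, and 2
fitted with a spatially imputed covariate. The model-based estimator is
at least as precise as the direct one in ~98 % of comparable regions, and
the average CV improvement of ~3 percentage points concentrates in the
smallest regions — exactly the shrinkage behaviour that justifies
model-based small-area estimation.

A thin CLI wraps the same pipeline:

```
carsae simulate --n-regions 335 --seed 1 --out study/
carsae fit --regions study/regions.csv --edges study/edges.csv --out results/
```

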