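# Methods

## Model

The observation model is binomial: the count of vulnerable children in
region r is yᵣ ~ Binomial(Nᵣ, pᵣ), which is appropriate for a
near-census assessment (no survey weights) and copes with the
overdispersion typical of areal counts through the random effects. The
linear predictor on the logit scale is

    logit(pᵣ) = α + Xᵣᵀβ + uᵣ + vᵣ  (+ log eᵣ, optional offset)

* `α` — overall level; with a standardized covariate and centred random
  effects it is the logit prevalence of a typical region.
* `β` — fixed effect(s) of the area covariate (a SEIFA-IRSD-like
  disadvantage index in the motivating application).
* `uᵣ` — spatially structured effect, Leroux CAR prior.
* `vᵣ` — iid N(0, τᵥ²) unstructured effect.

An offset parameterisation (log expected count, giving a relative-risk
reading of the intercept) is supported but off by default: the model is
fitted and reported on the prevalence scale, and mixing an offset with a
free intercept on near-census data adds nothing while complicating
interpretation.

### The CAR prior

The Leroux full conditional for uⱼ is

    uⱼ | u₋ⱼ ~ N( ρ Σᵢ wⱼᵢuᵢ / (ρ dⱼ + 1 − ρ), τᵤ² / (ρ dⱼ + 1 − ρ) )

equivalently a zero-mean multivariate normal with precision
τᵤ⁻²[ρ(D − W) + (1 − ρ)I]. ρ = 1 is the intrinsic CAR / BYM structured
effect; ρ = 0 is independence. Model variants:

| variant     | structured u | unstructured v | ρ            |
|-------------|--------------|----------------|--------------|
| `leroux`    | yes          | yes            | uniform(0,1), sampled |
| `bym`       | yes          | yes            | fixed at 1   |
| `icar_only` | yes          | no             | fixed at 1   |
| `iid_only`  | no           | yes            | —            |

The default keeps the unstructured term alongside the Leroux effect
because the linear predictor includes both components; users who prefer
the single-effect Leroux formulation (as in CARBayes) can select a
variant without `v`.

The ICAR prior is improper (flat along the constant vector, one per
connected component); identifiability is restored by re-centring u to
sum to zero every sweep and reporting the intercept separately. The
prior's effective rank in the variance full conditional is n − (number
of components) at ρ = 1 and n otherwise.

### Hyperpriors

Gamma(shape, rate) priors on the precisions (equivalently inverse-gamma
on the variances): shape 1 with rate 0.5 for the structured precision
and rate 0.01 for the unstructured one; zero-mean normal with sd 10 on
the intercept and fixed effects, intended for a standardized covariate.
These are weakly informative at the scale of logit prevalences; the
`sensitivity_refit` diagnostic refits under alternatives and on
well-populated data the prevalence surface moves by ≪ 0.01 when the
unstructured rate changes tenfold.

## Sampler

Metropolis-within-Gibbs, single chain, fully seeded:

* **Fixed effects** — joint random-walk Metropolis. The proposal
  covariance is the inverse Fisher information from a short IRLS
  (logistic GLM) fit at initialisation, so correlated coefficients are
  proposed along the posterior's local geometry.
* **u** — single-site random-walk Metropolis. Sites are partitioned by
  a greedy graph colouring into independent sets; within a colour class
  no two regions are adjacent, their full conditionals are mutually
  independent, and the whole class is updated in one vectorised step.
  This is exactly the single-site kernel, just executed blockwise, and
  is what makes 335-region fits run in seconds of pure NumPy.
* **v** — all sites at once (conditionally independent given the rest).
* **τᵤ², τᵥ²** — conjugate draws: the precision's full conditional is
  gamma(shape + rank/2, rate + Q/2) with Q the CAR quadratic form.
* **ρ** (`leroux`) — random-walk Metropolis on logit(ρ) with the
  uniform(0,1) prior and its Jacobian; the log-determinant of the
  Leroux precision is evaluated from the precomputed eigenvalues of the
  graph Laplacian, so each evaluation is O(n).

Proposal scales adapt toward a 30–50 % acceptance rate during burn-in
only and are frozen afterwards, preserving detailed balance for the
retained draws. Library defaults are 50,000 iterations, 10,000 burn-in,
thinning 10 — deliberately generous for final analyses; the test-suite
and reproduction runs use 5,000–8,000 iterations with 2,000–3,000
burn-in, which the recovery experiments below show is sufficient at
these problem sizes (a few hundred regions, a single covariate).

Regions with suppressed responses remain in the graph: their random
effects are drawn from the prior conditionals and they contribute
nothing to the likelihood. Their prevalence is then predicted by the
plug-in pᵣ(β̂, 0, 0) — per retained draw, inverse-logit(α + Xᵣᵀβ) with
both random effects at zero; the default pushes the full posterior of
the fixed effects through the link (a point-estimate-only variant
exists). The plug-in interval therefore reflects fixed-effect
uncertainty only, not random-effect variance.

### Covariate imputation

Missing area scores are filled by a Gaussian-response BYM smoother on
the same graph: zᵣ ~ N(α + uᵣ + vᵣ, σ²) for observed regions, ICAR u,
iid v, everything conjugate (pure Gibbs, no tuning). The posterior-mean
surface is plugged in for missing regions; observed scores are never
altered, and imputation uncertainty is not propagated into the main
model (plug-in convention; a multiple-imputation loop can be layered on
top by re-running the pipeline over smoother draws).

## Direct estimation and diagnostics

The direct estimator is p̂ᵣ = yᵣ/Nᵣ with binomial standard error
√(p̂(1−p̂)/N) and a normal-approximation 95 % interval truncated to
[0, 1] (Wilson available behind a flag for small N). Regions with
N below the reporting minimum (default 15) are suppressed but retained
as flagged rows. Precision is compared by the percent coefficient of
variation CV = σ/p̂ × 100 and the improvement by CV_direct − CV_model;
consistency by the relative bias (p̂_model − p̂_direct)/p̂_model × 100.
Comparison metrics are computed only where both estimators exist; the
excluded regions are listed explicitly. Map-ready tables bin each
metric at its 20/40/60/80th percentiles (linear interpolation; a value
exactly on a cutpoint goes to the lower bin, for bit-exact
reproducibility). The q–q straightness score (correlation of ordered
posterior-mean effects with Blom-position normal quantiles) checks the
normality assumption on the random effects.

## Synthetic studies

The generator emulates the structure of a national early-development
census joined to an area-disadvantage index at ~335 mid-level regions:

* **Geography** — Queen-contiguity lattice (or a symmetrised
  nearest-neighbour graph of random points for irregular layouts).
* **Sample sizes** — lognormal(meanlog 6.4177, sdlog 0.85) rounded and
  capped at 4,500: mean ≈ 878, interquartile range ≈ 680, long right
  tail, occasional near-empty regions.
* **Covariate** — each region averages its own and its neighbours' iid
  normal draws, rescaled to mean 1000 / sd 80 (a SEIFA-like scale with
  genuine spatial autocorrelation).
* **Random effects** — u drawn exactly from the Leroux/ICAR prior via
  the Laplacian eigendecomposition (null space removed at ρ = 1) and
  then centred: alongside a free intercept only the mean-zero part of u
  is identifiable, so the generator keeps the overall level in the
  intercept, making the generating intercept the estimand that the
  fitted intercept targets. Defaults β = (−2.2, −0.5), τᵤ² = 0.2,
  τᵥ² = 0.05, ρ = 0.9 give prevalences around 7–12 % with a clear
  disadvantage gradient.
* **Counts** — yᵣ ~ Binomial(Nᵣ, pᵣ), or aggregated child-level
  Bernoulli records when unit-level data are requested.
* **Scores and cut-offs** — child development scores in [0, 10] are
  classified against reference-cohort cut-offs: lowest 10 % vulnerable,
  10–25 % at-risk; cut-offs sit midway between the bracketing order
  statistics so tie-free reference cohorts split exactly, and they stay
  frozen when later cohorts are classified.
* **Missingness** — responses are suppressed wherever N falls under the
  reporting minimum (exact counts can be forced for reproducible
  patterns, e.g. the canonical 2 suppressed + 2 covariate-missing);
  covariate missingness hits a configurable set of regions. The truth
  is always retained for evaluation.

What the generator does **not** emulate: correlated outcome domains,
within-region covariate heterogeneity, measurement error in the index,
informative missingness, or the coastline-concentrated population
geography of real administrative lattices. Passing tests therefore
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

## Numerical choices and reproduction sizes

* All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give bit-identical studies and chains.
* Queen contiguity uses exact shapely predicates (an optional distance
  tolerance handles sliver-ridden boundary files); a Rook flag requires
  shared edges of positive length.
* Standardization uses the n−1 denominator; only the affine transform
  matters downstream and the parameters are returned for out-of-sample
  use.
* Degenerate inputs are flagged, not silently dropped: zero direct
  estimates have undefined CV, constant vectors collapse quantile bins,
  zero-spread effect vectors yield a NaN q–q score.
* Reproduction problem sizes: the pipeline and shrinkage numbers use
  one 335-region study at 8,000 iterations; fixed-effect recovery uses
  20 replicates of 225-region (15×15) studies; the imputation hold-out
  uses 10 replicates of 120-region studies with 12 hidden scores; all
  chosen as the smallest sizes at which the Monte-Carlo error is
  clearly below the effects being measured.

## Known limitations

* Single-chain inference; convergence is assessed by acceptance-rate
  monitoring and the recovery experiments rather than multi-chain
  statistics.
* The plug-in predictions understate uncertainty for suppressed regions
  (no random-effect variance) — the convention is stated, not hidden.
* The Leroux variant with both u and v can be weakly identified when
  spatial signal is faint; the variance hyperpriors then matter more,
  which is why the sensitivity refit is part of the diagnostics module.
* Planar coordinates are assumed; no projection handling.
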