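"""Two distinct missing-data mechanisms for small-area prevalence.

Administrative areal data go missing in two different ways:

* *missing responses* — the outcome count was suppressed (too few
  children assessed for the reporting rule). The region's covariate is
  known, so its prevalence is predicted out-of-sample from the fixed
  effects alone, with the random effects set to zero (a plug-in
  predictor).
* *missing covariates* — the region is so sparsely populated that no
  disadvantage score could be computed. The score is imputed by
  spatially smoothing the observed scores over the adjacency graph with
  a Gaussian BYM model, then plugged into the main model.

Both mechanisms are treated as ignorable: they arise from
administrative reporting rules, not from the outcome itself.
"""

from __future__ import annotations

import numpy as np

from carsae.car_model import PosteriorSamples, gaussian_car_smooth
from carsae.geography import RegionGraph

__all__ = ["predict_out_of_sample", "impute_covariate"]


def predict_out_of_sample(
    samples: PosteriorSamples,
    x_row,
    *,
    level: float = 0.95,
    point_estimate: bool = False,
):
    """Plug-in prevalence prediction for a region with a suppressed response.

    Computes inverse-logit(alpha + x' beta) with both random effects set
    to zero. By default every retained posterior draw of the fixed
    effects is pushed through the link, giving a predictive mean and
    central interval; ``point_estimate=True`` instead uses only the
    posterior-mean coefficients (the literal plug-in with a degenerate
    interval).

    Returns ``(mean, sd, ci_low, ci_high)``.
    """
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float))
    if np.isnan(x_row).any():
        raise ValueError(
            "covariate missing for this region; impute it first "
            "(wrong mechanism for plug-in prediction)"
        )
    xd = np.concatenate([[1.0], x_row])  # intercept-first design row
    if xd.size != samples.coef.shape[1]:
        raise ValueError("covariate row length does not match the fitted model")
    if point_estimate:
        eta = float(samples.coef.mean(axis=0) @ xd)
        p = 1.0 / (1.0 + np.exp(-eta))
        return p, 0.0, p, p
    eta = samples.coef @ xd
    p = 1.0 / (1.0 + np.exp(-eta))
    a = (1 - level) / 2
    lo, hi = np.quantile(p, [a, 1 - a])
    sd = float(p.std(ddof=1)) if p.size > 1 else 0.0
    return float(p.mean()), sd, float(lo), float(hi)


def impute_covariate(
    scores,
    graph: RegionGraph,
    *,
    n_iterations: int = 3000,
    burn_in: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing covariate entries by spatial (BYM) smoothing.

    Observed entries pass through untouched; missing entries are
    replaced with the posterior-mean smoothed surface. Imputation
    uncertainty is not propagated into the main model — the posterior
    mean is plugged in.

    Returns ``(completed_vector, imputed_flags)``.
    """
    scores = np.asarray(scores, dtype=float)
    missing = np.isnan(scores)
    if missing.all():
        raise ValueError("all covariate values are missing; nothing to smooth from")
    if not missing.any():
        return scores.copy(), missing
    smoothed = gaussian_car_smooth(
        scores, graph, n_iterations=n_iterations, burn_in=burn_in, seed=seed
    )
    completed = np.where(missing, smoothed, scores)
    return completed, missing
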