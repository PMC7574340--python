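"""Model checking and direct-vs-model comparison metrics.

The precision gain of small-area estimation is summarised by the
difference in percent coefficients of variation, CV_direct − CV_model
(positive when shrinkage pays off), and the consistency of the two
estimators by the relative bias (model − direct) / model × 100 %.
Binned (quintile) tables back choropleth maps rendered by external
tools; a q–q straightness score checks the normality assumption on the
random effects; and a refit-under-alternative-priors helper quantifies
prior sensitivity.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from carsae.car_model import ModelConfig, posterior_prevalence, run_mcmc

__all__ = [
    "cv_difference",
    "relative_bias",
    "quantile_bins",
    "random_effect_normality",
    "sensitivity_refit",
    "comparison_report",
]


def cv_difference(cv_direct, cv_model) -> np.ndarray:
    """CV_direct − CV_model in percentage points; NaN where either is undefined."""
    cv_direct = np.asarray(cv_direct, dtype=float)
    cv_model = np.asarray(cv_model, dtype=float)
    return cv_direct - cv_model


def relative_bias(p_model, p_direct) -> np.ndarray:
    """(p_model − p_direct) / p_model × 100.

    Positive values mean the direct estimate under-estimates the
    prevalence relative to the model. Undefined (NaN) where the model
    estimate is zero or either input is missing.
    """
    p_model = np.asarray(p_model, dtype=float)
    p_direct = np.asarray(p_direct, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = np.where(p_model > 0, (p_model - p_direct) / p_model * 100.0, np.nan)
    return rb


def quantile_bins(values, percentiles=(20, 40, 60, 80)) -> tuple[np.ndarray, np.ndarray]:
    """Assign each defined value to one of len(percentiles)+1 ordered bins.

    Cutpoints are the given percentiles of the *defined* values (linear
    interpolation between order statistics). Bins are left-closed /
    right-open except the last, so a value exactly on a cutpoint goes to
    the upper bin boundary's lower side deterministically. Returns
    ``(labels, cutpoints)`` where labels are integer bins 0..k (−1 for
    missing values). Degenerate (tied) cutpoints collapse bins.
    """
    values = np.asarray(values, dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size < len(percentiles) + 1:
        raise ValueError(
            f"need at least {len(percentiles) + 1} defined values, got {defined.size}"
        )
    cuts = np.percentile(defined, percentiles)
    labels = np.full(values.shape, -1, dtype=int)
    ok = ~np.isnan(values)
    # side='left' => a value exactly on a cutpoint stays in the lower bin
    labels[ok] = np.searchsorted(cuts, values[ok], side="left")
    return labels, cuts


def random_effect_normality(effects) -> tuple[float, pd.DataFrame]:
    """Q–Q straightness score for posterior-mean random effects.

    Correlates the ordered effects with the corresponding standard
    normal quantiles (Blom plotting positions). Values near 1 support
    the normality assumption; returns the ordered pairs for plotting.
    """
    effects = np.asarray(effects, dtype=float)
    effects = effects[~np.isnan(effects)]
    n = effects.size
    if n < 10:
        raise ValueError("need at least 10 effects for a q-q diagnostic")
    if np.ptp(effects) == 0:
        return float("nan"), pd.DataFrame(
            {"theoretical": [], "observed": []}
        )  # degenerate: zero spread
    ordered = np.sort(effects)
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(probs)
    score = float(np.corrcoef(theo, ordered)[0, 1])
    return score, pd.DataFrame({"theoretical": theo, "observed": ordered})


def sensitivity_refit(data, graph, config: ModelConfig, alternate_priors) -> pd.DataFrame:
    """Refit under alternative hyperprior settings and compare estimates.

    ``alternate_priors`` is a list of dicts of ModelConfig field
    overrides (e.g. ``{"beta_v": 0.1}``). Reports, per setting, the
    maximum absolute change in posterior prevalence means relative to
    the baseline config.
    """
    base = posterior_prevalence(run_mcmc(data, graph, config), data, config)
    rows = []
    for overrides in alternate_priors:
        cfg = replace(config, **overrides)
        est = posterior_prevalence(run_mcmc(data, graph, cfg), data, cfg)
        rows.append(
            {
                **{k: v for k, v in overrides.items()},
                "max_abs_change": float(np.max(np.abs(est.mean - base.mean))),
                "mean_abs_change": float(np.mean(np.abs(est.mean - base.mean))),
            }
        )
    return pd.DataFrame(rows)


def comparison_report(
    region_ids, direct_frame: pd.DataFrame, model_frame: pd.DataFrame
) -> tuple[pd.DataFrame, list]:
    """Join direct and model estimates into a per-region comparison table.

    Regions lacking a direct estimate (suppressed / no sample) are
    excluded from the CV-difference and relative-bias columns and listed
    explicitly, mirroring standard practice of comparing only where both
    estimators exist.
    """
    df = pd.DataFrame(index=pd.Index(region_ids, name="region_id"))
    df["p_direct"] = direct_frame["estimate"].to_numpy()
    df["p_model"] = model_frame["estimate"].to_numpy()
    df["cv_direct"] = direct_frame["cv"].to_numpy()
    df["cv_model"] = model_frame["cv"].to_numpy()
    both = df[["cv_direct", "cv_model"]].notna().all(axis=1)
    df["cv_difference"] = np.where(
        both, cv_difference(df["cv_direct"], df["cv_model"]), np.nan
    )
    has_direct = df["p_direct"].notna()
    df["relative_bias"] = np.where(
        has_direct, relative_bias(df["p_model"], df["p_direct"]), np.nan
    )
    excluded = df.index[~has_direct].tolist()
    for metric in ("cv_difference", "relative_bias"):
        vals = df[metric].to_numpy(dtype=float)
        if (~np.isnan(vals)).sum() >= 5:
            labels, _ = quantile_bins(vals)
            df[f"{metric}_bin"] = labels
    return df, excluded
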