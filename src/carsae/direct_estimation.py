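"""Crude (direct) prevalence estimation and reporting suppression.

The direct estimator is the unweighted proportion y_r / N_r with its
binomial standard error — no pooling across regions. It is the baseline
against which the model-based small-area estimates are judged, and it is
the quantity that administrative reporting rules suppress when too few
children were assessed in a region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DirectEstimates",
    "direct_prevalence",
    "coefficient_of_variation",
    "apply_suppression",
]

#: administrative reporting floor: estimates based on fewer assessed
#: children than this are suppressed
DEFAULT_SUPPRESSION_MINIMUM = 15


@dataclass(frozen=True)
class DirectEstimates:
    """Per-region direct estimates with uncertainty and flags.

    ``cv`` is the percent coefficient of variation, NaN where the
    estimate is zero (CV undefined). ``no_sample`` marks regions with
    N = 0. Suppressed regions are retained as rows, never dropped, so
    downstream missing-data handling can act on them.
    """

    estimate: np.ndarray
    se: np.ndarray
    cv: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    suppressed: np.ndarray
    no_sample: np.ndarray

    def to_frame(self, region_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "estimate": self.estimate,
                "se": self.se,
                "cv": self.cv,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "suppressed": self.suppressed,
                "no_sample": self.no_sample,
            }
        )
        if region_ids is not None:
            df.index = pd.Index(region_ids, name="region_id")
        return df


def direct_prevalence(
    y,
    N,
    *,
    suppression_minimum: int = DEFAULT_SUPPRESSION_MINIMUM,
    interval: str = "normal",
    level: float = 0.95,
) -> DirectEstimates:
    """Direct prevalence y/N with binomial standard error.

    The default interval is the normal approximation
    p ± z·sqrt(p(1−p)/N) truncated to [0, 1]; ``interval="wilson"``
    gives the Wilson score interval, more robust at small N.
    Regions failing the reporting minimum get suppressed=True and NaN
    estimates.
    """
    y = np.asarray(y, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(y < 0) or np.any(N < 0):
        raise ValueError("negative counts")
    if np.any(y > N):
        raise ValueError("y > N for some region")
    if interval not in ("normal", "wilson"):
        raise ValueError(f"unknown interval method {interval!r}")

    suppressed = apply_suppression(N, minimum=suppression_minimum)
    no_sample = N == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(N > 0, y / np.maximum(N, 1), np.nan)
        se = np.where(N > 0, np.sqrt(p * (1 - p) / np.maximum(N, 1)), np.nan)
    z = stats.norm.ppf(0.5 + level / 2)
    if interval == "normal":
        lo = np.clip(p - z * se, 0.0, 1.0)
        hi = np.clip(p + z * se, 0.0, 1.0)
    else:
        denom = 1 + z**2 / N
        centre = (p + z**2 / (2 * N)) / denom
        half = z * np.sqrt(p * (1 - p) / N + z**2 / (4 * N**2)) / denom
        lo = np.clip(centre - half, 0.0, 1.0)
        hi = np.clip(centre + half, 0.0, 1.0)

    cv = coefficient_of_variation(p, se)
    for arr in (p, se, cv, lo, hi):
        arr[suppressed] = np.nan
    return DirectEstimates(p, se, cv, lo, hi, suppressed, no_sample)


def coefficient_of_variation(estimate, spread) -> np.ndarray:
    """Percent CV: spread / estimate × 100; NaN where the estimate is 0.

    Scale-free: multiplying both arguments by the same positive constant
    leaves the CV unchanged.
    """
    estimate = np.asarray(estimate, dtype=float)
    spread = np.asarray(spread, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(estimate > 0, spread / estimate * 100.0, np.nan)
    return cv


def apply_suppression(N, minimum: int = DEFAULT_SUPPRESSION_MINIMUM) -> np.ndarray:
    """Flag regions whose assessed count falls below the reporting minimum."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("negative counts")
    return N < minimum
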