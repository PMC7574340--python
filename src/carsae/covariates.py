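"""Region-level disadvantage covariate construction.

Area-level socio-economic indices (SEIFA-IRSD-like scores) are published
at a sub-regional level; the region score is the population-weighted mean
of its sub-region scores. Regions whose total population falls below a
reporting minimum cannot be scored and are flagged missing, to be filled
later by spatial imputation. A standardisation helper puts the covariate
on a mean-0 / sd-1 scale for MCMC stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["aggregate_weighted", "standardize", "Standardizer"]


class CovariateError(ValueError):
    pass


def aggregate_weighted(
    table: pd.DataFrame,
    region_ids: Sequence,
    *,
    min_population: int = 10,
    allow_missing: bool = True,
) -> pd.Series:
    """Population-weighted mean of sub-region scores within each region.

    Parameters
    ----------
    table
        Columns ``sub_id``, ``region_id``, ``score``, ``population``.
    region_ids
        The full ordered region list; regions absent from the table (or
        whose total population is below ``min_population``) get NaN when
        ``allow_missing``, else raise.
    min_population
        Regions with fewer residents than this cannot be scored (the
        administrative reporting floor); their score is missing.

    Returns
    -------
    pandas.Series indexed by region id, NaN marking missing scores.
    """
    required = {"sub_id", "region_id", "score", "population"}
    if not required.issubset(table.columns):
        raise CovariateError(f"table must have columns {sorted(required)}")
    if table["sub_id"].duplicated().any():
        dups = table.loc[table["sub_id"].duplicated(), "sub_id"].tolist()
        raise CovariateError(f"duplicate sub_id values: {dups}")
    if (table["population"] < 0).any():
        raise CovariateError("negative population")
    known = set(region_ids)
    unknown = set(table["region_id"]) - known
    if unknown:
        raise CovariateError(f"unknown parent region ids: {sorted(map(str, unknown))}")

    out = pd.Series(np.nan, index=pd.Index(region_ids, name="region_id"), name="score")
    for rid, grp in table.groupby("region_id", sort=False):
        pop = grp["population"].to_numpy(dtype=float)
        total = pop.sum()
        if total < min_population:
            if not allow_missing:
                raise CovariateError(
                    f"region {rid!r} has total population {total:g} < {min_population}"
                )
            continue
        out.loc[rid] = float(np.average(grp["score"], weights=pop))
    if not allow_missing and out.isna().any():
        missing = out.index[out.isna()].tolist()
        raise CovariateError(f"regions without sub-region data: {missing}")
    return out


@dataclass(frozen=True)
class Standardizer:
    """Affine transform parameters so new values map onto the same scale."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(x) -> tuple[np.ndarray, Standardizer]:
    """Z-score a vector over its non-missing entries (ddof=1).

    Missing (NaN) entries propagate unchanged. Returns the transformed
    vector and the fitted :class:`Standardizer`.
    """
    x = np.asarray(x, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise CovariateError("need at least 2 non-missing values")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0:
        raise CovariateError("zero spread: cannot standardize a constant vector")
    scaler = Standardizer(mean, sd)
    return scaler.transform(x), scaler
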