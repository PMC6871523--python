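"""Correlation of population risk scores with prevalence, with empirical significance.

The headline statistic is the Pearson correlation r between per-population
unweighted genetic risk scores and pooled age-adjusted prevalences, together
with r^2 (the share of between-population prevalence variance the scored
variants can account for).  Significance is the one-sided exceedance
fraction over the matched random SNP null: the proportion of null sets whose
score-prevalence correlation is strictly larger than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .matched_null import empirical_p_greater
from .risk_variants import ValidationError


@dataclass(frozen=True)
class AssociationResult:
    populations: tuple[str, ...]
    r: float
    r_squared: float
    empirical_p: float
    null_r_range: tuple[float, float]
    n_null_sets: int

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "r": self.r,
            "r_squared": self.r_squared,
            "empirical_p": self.empirical_p,
            "null_r_min": self.null_r_range[0],
            "null_r_max": self.null_r_range[1],
            "n_null_sets": self.n_null_sets,
        }


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (>= 3 points,
    both with nonzero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y have different lengths")
    if x.size < 3:
        raise ValidationError("correlation needs at least 3 points")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValidationError("correlation undefined: zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def variance_explained(r: float) -> float:
    """r^2, the variance share attributable to the linear relation."""
    if abs(r) > 1.0:
        raise ValidationError(f"|r| = {abs(r)} exceeds 1")
    return r * r


def _null_correlations(null_grs: pd.DataFrame, y: np.ndarray, pops: list[str]) -> np.ndarray:
    """Pearson r of each null set's scores against y, vectorised over sets."""
    x = null_grs[pops].to_numpy(float)  # n_sets x n_pops
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (xc * yc).sum(axis=1) / denom, np.nan)


def correlate_with_null(
    grs_by_pop: Mapping[str, float],
    prevalence_by_pop: Mapping[str, float],
    null_grs: pd.DataFrame,
    two_sided: bool = False,
) -> AssociationResult:
    """Observed score-prevalence correlation plus its empirical p-value.

    ``null_grs`` is the per-set population score matrix of a matched null
    collection, with population columns already merged the same way as the
    observed scores.  Population keys must align exactly across the three
    inputs; the comparison is one-sided (larger null correlation counts)
    unless ``two_sided``, which counts |null r| > |observed r|.
    """
    pops = sorted(grs_by_pop)
    prev_keys = set(prevalence_by_pop)
    null_keys = set(null_grs.columns)
    mismatch = (set(pops) ^ prev_keys) | (set(pops) - null_keys)
    if mismatch:
        raise ValidationError(f"population keys do not align: {sorted(mismatch)}")
    x = np.array([grs_by_pop[p] for p in pops], dtype=float)
    y = np.array([prevalence_by_pop[p] for p in pops], dtype=float)
    r = pearson_r(x, y)
    null_r = _null_correlations(null_grs, y, pops)
    null_r = null_r[~np.isnan(null_r)]
    if null_r.size == 0:
        raise ValidationError("no defined null correlations")
    if two_sided:
        p = empirical_p_greater(abs(r), np.abs(null_r))
    else:
        p = empirical_p_greater(r, null_r)
    return AssociationResult(
        populations=tuple(pops),
        r=r,
        r_squared=variance_explained(r),
        empirical_p=p,
        null_r_range=(float(null_r.min()), float(null_r.max())),
        n_null_sets=int(null_r.size),
    )
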