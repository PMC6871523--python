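"""Weir-Cockerham fixation-index (Fst) estimation and percentile significance.

Implements the Weir & Cockerham (1984) moment estimator theta for a biallelic
site observed in r populations.  With per-population diploid sample sizes
n_i, counted-allele frequencies p_i and observed heterozygote proportions
h_i, define

    n_bar = mean n_i
    n_c   = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r n_bar)
    s2    = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
    h_bar = sum n_i h_i / (r n_bar)

and the variance components

    a = (n_bar/n_c) [ s2 - (1/(n_bar-1)) ( p_bar(1-p_bar)
                                           - s2 (r-1)/r - h_bar/4 ) ]
    b = (n_bar/(n_bar-1)) [ p_bar(1-p_bar) - s2 (r-1)/r
                            - h_bar (2 n_bar - 1)/(4 n_bar) ]
    c = h_bar / 2

with theta = a / (a + b + c).  theta may be negative in finite samples and is
never clipped; sites monomorphic across all populations have a zero
denominator and an undefined (NaN) theta.  Two set-level summaries are
reported: the arithmetic mean of per-site theta (the headline statistic) and
the ratio of summed numerators to summed denominators.

Significance of an observed set-mean Fst is assessed against the empirical
distribution of set-mean Fst over frequency-matched random SNP sets, using
the 2.5th and 97.5th percentiles (linear interpolation between order
statistics): below the lower bound the populations are *more* similar than
expected, above the upper bound *less*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .risk_variants import GenotypePanel, RiskVariantTable, ValidationError

log = logging.getLogger(__name__)

_AUTOSOME = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$", re.IGNORECASE)


@dataclass(frozen=True)
class SiteCounts:
    """Per-population counts at one biallelic site: diploid sample sizes ``n``,
    counted-allele frequencies ``p``, heterozygote proportions ``h``."""

    n: np.ndarray
    p: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        p = np.asarray(self.p, dtype=float)
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "h", h)
        if not (n.shape == p.shape == h.shape):
            raise ValidationError("n, p, h must have matching shapes")
        if (n < 1).any():
            raise ValidationError("each population needs at least one diploid sample")
        if ((p < 0) | (p > 1)).any() or ((h < 0) | (h > 1)).any():
            raise ValidationError("frequencies and heterozygosities must lie in [0, 1]")
        if (h > 2 * np.minimum(p, 1 - p) + 1e-9).any():
            raise ValidationError("heterozygote proportion exceeds 2*min(p, 1-p)")

    @property
    def r(self) -> int:
        return int(self.n.size)


@dataclass(frozen=True)
class FstEstimate:
    """Variance components of one site: ``numerator`` a, ``denominator``
    a+b+c, and their ratio ``theta`` (NaN when the denominator is zero)."""

    numerator: float
    denominator: float
    theta: float


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Weir-Cockerham components a, b, c.

    ``p`` and ``h`` have population as the last axis (shape (..., r)); ``n``
    broadcasts against them.  Returns arrays of shape (...,).
    """
    n = np.broadcast_to(np.asarray(n, dtype=float), np.asarray(p).shape)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = p.shape[-1]
    if r < 2:
        raise ValidationError("Fst requires at least two populations")
    n_sum = n.sum(axis=-1)
    n_bar = n_sum / r
    n_c = (n_sum - (n**2).sum(axis=-1) / n_sum) / (r - 1)
    p_bar = (n * p).sum(axis=-1) / n_sum
    s2 = (n * (p - p_bar[..., None]) ** 2).sum(axis=-1) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=-1) / n_sum
    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - s2 * (r - 1) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def wc_site_fst(counts: SiteCounts) -> FstEstimate:
    """Weir-Cockerham theta at one site over r >= 2 populations."""
    if counts.r < 2:
        raise ValidationError("Fst requires at least two populations")
    if (counts.n < 2).all():
        raise ValidationError("at least one population needs n >= 2")
    a, b, c = wc_components(counts.n, counts.p, counts.h)
    num = float(a)
    den = float(a + b + c)
    theta = num / den if den != 0.0 else float("nan")
    return FstEstimate(numerator=num, denominator=den, theta=theta)


def global_site_fst(counts: SiteCounts) -> FstEstimate:
    """Fst of one site across all supplied populations jointly (same
    estimator, r = number of populations)."""
    return wc_site_fst(counts)


@dataclass
class FstSetSummary:
    """Set-level Fst over multiple sites for one population pair (or
    'global'): per-site thetas, their mean, the ratio-of-sums estimate, and
    (optionally) percentile-test results against a matched null."""

    pair: tuple[str, str] | str
    thetas: np.ndarray
    mean_fst: float
    weighted_fst: float
    n_sites_used: int
    significance: str | None = None
    percentile_bounds: tuple[float, float] | None = None


def summarize_sites(
    estimates: Sequence[FstEstimate], pair: tuple[str, str] | str
) -> FstSetSummary:
    """Combine per-site estimates: arithmetic mean of defined thetas (the
    headline value) plus the ratio of summed components."""
    thetas = np.array([e.theta for e in estimates], dtype=float)
    defined = ~np.isnan(thetas)
    if not defined.any():
        raise ValidationError(f"{pair}: no site with a defined Fst")
    n_skipped = int((~defined).sum())
    if n_skipped:
        log.info("%s: skipped %d monomorphic site(s)", pair, n_skipped)
    num = sum(e.numerator for e in estimates)
    den = sum(e.denominator for e in estimates)
    return FstSetSummary(
        pair=pair,
        thetas=thetas,
        mean_fst=float(thetas[defined].mean()),
        weighted_fst=float(num / den) if den != 0.0 else float("nan"),
        n_sites_used=int(defined.sum()),
    )


def pairwise_mean_fst(sites: Sequence[SiteCounts], pair: tuple[str, str] = ("A", "B")) -> FstSetSummary:
    """Mean Fst over a set of sites for one population pair."""
    return summarize_sites([wc_site_fst(s) for s in sites], pair)


SIGNIFICANT_LOW = "significant_low"
SIGNIFICANT_HIGH = "significant_high"
NOT_SIGNIFICANT = "not_significant"


def empirical_fst_test(
    observed: float,
    null_means: Sequence[float],
    alpha_tails: tuple[float, float] = (0.025, 0.975),
) -> tuple[str, tuple[float, float]]:
    """Classify an observed set-mean Fst against the empirical null:
    below the lower percentile -> significant_low (more similar than random
    matched SNPs), above the upper -> significant_high.  Percentiles use
    linear interpolation between order statistics."""
    null_arr = np.asarray(null_means, dtype=float)
    if null_arr.size == 0:
        raise ValidationError("empty null distribution")
    lo, hi = np.percentile(null_arr, [100 * alpha_tails[0], 100 * alpha_tails[1]], method="linear")
    if observed < lo:
        label = SIGNIFICANT_LOW
    elif observed > hi:
        label = SIGNIFICANT_HIGH
    else:
        label = NOT_SIGNIFICANT
    return label, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# builders


def panel_site_counts(
    panel: GenotypePanel, table: RiskVariantTable | None = None
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Observed per-population counts from a genotype panel.

    Returns (populations, n, p, h) with n shape (sites, r) (non-missing
    diploid counts), p and h shape (sites, r).  If a variant table is given,
    non-autosomal variants are rejected: the estimator assumes diploid
    autosomal counts.
    """
    if table is not None:
        bad = [v.rsid for v in table if not _AUTOSOME.match(v.chrom)]
        if bad:
            raise ValidationError(f"non-autosomal variants not supported: {', '.join(bad)}")
    pops = panel.population_labels
    n_sites = panel.dosage.shape[1]
    n = np.zeros((n_sites, len(pops)))
    p = np.full((n_sites, len(pops)), np.nan)
    h = np.zeros((n_sites, len(pops)))
    for k, pop in enumerate(pops):
        sub = panel.dosage[panel.sample_index(pop), :]
        called = ~np.isnan(sub)
        n[:, k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.nansum(sub, axis=0) / (2.0 * n[:, k])
            h[:, k] = np.sum(sub == 1.0, axis=0) / n[:, k]
    return pops, n, p, h


def pairwise_theta_per_site(
    n: np.ndarray, p: np.ndarray, h: np.ndarray, i: int, j: int
) -> np.ndarray:
    """Per-site theta for the population pair (i, j) from (sites x pops)
    count arrays; NaN where the denominator vanishes."""
    a, b, c = wc_components(n[:, [i, j]], p[:, [i, j]], h[:, [i, j]])
    den = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0.0, a / den, np.nan)


def hwe_heterozygosity(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg expected heterozygote proportion 2p(1-p).

    Used when only allele frequencies are available (e.g. scoring matched
    random SNP sets drawn from a frequency table rather than genotypes)."""
    return 2.0 * p * (1.0 - p)
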