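"""Weighted and unweighted genetic risk scores for individuals and populations.

The unweighted score of an individual is the mean risk-allele count over the
scored SNPs, GRS = (sum_i X_i) / n, so it lives on [0, 2].  The weighted score
uses log-odds-ratio weights, wGRS = (sum_i w_i X_i) / n (note the division by
the number of SNPs, which keeps the two scores on comparable scales).

A population's score is the expected individual score under its allele
frequencies: GRS = (sum_i 2 raf_i) / n and likewise for wGRS.  Under complete
genotype data this equals the average of the per-individual scores exactly;
the closed form is used because it is what makes scoring thousands of random
SNP sets cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .risk_variants import PopulationFrequencyTable, RiskVariantTable, ValidationError


class UndefinedScoreError(ValidationError):
    """Score requested where every dosage is missing."""


@dataclass(frozen=True)
class PopulationScore:
    population: str
    grs: float
    wgrs: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.grs <= 2.0:
            raise ValidationError(f"{self.population}: GRS {self.grs} outside [0, 2]")
        if self.n_samples < 1:
            raise ValidationError(f"{self.population}: n_samples must be >= 1")


def individual_grs(dosages: Sequence[float]) -> float:
    """Mean risk-allele count over non-missing variants.

    Missing dosages are dropped from numerator and denominator (so a sample
    genotyped at m of n SNPs is scored over its m called SNPs).
    """
    d = np.asarray(dosages, dtype=float)
    called = ~np.isnan(d)
    if not called.any():
        raise UndefinedScoreError("all dosages missing; score undefined")
    return float(d[called].sum() / called.sum())


def individual_wgrs(dosages: Sequence[float], weights: Sequence[float]) -> float:
    """Log-OR-weighted risk-allele sum divided by the number of called variants."""
    d = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise ValidationError("dosages and weights have different lengths")
    called = ~np.isnan(d)
    if not called.any():
        raise UndefinedScoreError("all dosages missing; score undefined")
    return float((w[called] * d[called]).sum() / called.sum())


def population_mean_grs(
    freqs: PopulationFrequencyTable,
    population: str,
    table: RiskVariantTable,
    n_samples: int | None = None,
) -> PopulationScore:
    """Population score from allele frequencies (closed form).

    Requires a frequency for the population at every variant of the table;
    missing frequencies raise an error listing the offending rsids.
    """
    if population not in freqs.raf.index:
        raise ValidationError(f"no frequencies for population {population!r}")
    raf = freqs.raf.loc[population, table.rsids].to_numpy(float)
    bad = [r for r, v in zip(table.rsids, raf) if np.isnan(v)]
    if bad:
        raise ValidationError(f"{population}: missing frequency at {', '.join(bad)}")
    n = table.n
    grs = float(2.0 * raf.sum() / n)
    wgrs = float(2.0 * (table.weights * raf).sum() / n)
    if n_samples is None:
        n_samples = int(round(freqs.called.loc[population].max() / 2.0)) or 1
    return PopulationScore(population=population, grs=grs, wgrs=wgrs, n_samples=n_samples)


def population_scores(
    freqs: PopulationFrequencyTable,
    table: RiskVariantTable,
    sample_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Scores for every population in the frequency table, as a DataFrame
    with columns population, n_samples, grs, wgrs."""
    rows = []
    for pop in freqs.populations:
        n = sample_sizes.get(pop) if sample_sizes else None
        score = population_mean_grs(freqs, pop, table, n_samples=n)
        rows.append(
            {"population": pop, "n_samples": score.n_samples, "grs": score.grs, "wgrs": score.wgrs}
        )
    return pd.DataFrame(rows)


def grouped_population_grs(
    scores: Sequence[PopulationScore],
    sizes: Sequence[int] | None = None,
    name: str | None = None,
) -> PopulationScore:
    """Merge populations: the group score is the sample-size-weighted mean of
    the member scores (sizes default to each member's own n_samples)."""
    if not scores:
        raise ValidationError("cannot group an empty list of scores")
    if sizes is None:
        sizes = [s.n_samples for s in scores]
    if len(sizes) != len(scores):
        raise ValidationError("scores and sizes have different lengths")
    sizes_arr = np.asarray(sizes, dtype=float)
    if (sizes_arr <= 0).any():
        raise ValidationError("group sizes must be positive")
    total = sizes_arr.sum()
    grs = float(np.dot(sizes_arr, [s.grs for s in scores]) / total)
    wgrs = float(np.dot(sizes_arr, [s.wgrs for s in scores]) / total)
    return PopulationScore(
        population=name or "+".join(s.population for s in scores),
        grs=grs,
        wgrs=wgrs,
        n_samples=int(total),
    )


def group_scores(
    scores: pd.DataFrame, grouping: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Apply a grouping map (analysis population -> member populations) to a
    population-score table.  Populations not covered by the map pass through
    under their own code."""
    scores = scores.set_index("population", drop=False)
    grouped_members = {m for members in grouping.values() for m in members}
    rows = []
    for group, members in grouping.items():
        missing = [m for m in members if m not in scores.index]
        if missing:
            raise ValidationError(f"group {group!r}: unknown populations {missing}")
        member_scores = [
            PopulationScore(m, scores.at[m, "grs"], scores.at[m, "wgrs"], int(scores.at[m, "n_samples"]))
            for m in members
        ]
        merged = grouped_population_grs(member_scores, name=group)
        rows.append(
            {
                "population": group,
                "n_samples": merged.n_samples,
                "grs": merged.grs,
                "wgrs": merged.wgrs,
            }
        )
    for pop in scores.index:
        if pop not in grouped_members:
            rows.append(scores.loc[pop, ["population", "n_samples", "grs", "wgrs"]].to_dict())
    return pd.DataFrame(rows).reset_index(drop=True)


def group_score_matrix(
    values: pd.DataFrame,
    grouping: Mapping[str, Sequence[str]],
    sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Group the columns of a (rows x populations) score matrix by
    sample-size-weighted averaging; ungrouped populations pass through.

    Used to apply the same population merging to the per-set scores of a null
    collection that is applied to the observed scores.
    """
    grouped_members = {m for members in grouping.values() for m in members}
    out = {}
    for group, members in grouping.items():
        w = np.array([sizes[m] for m in members], dtype=float)
        out[group] = values[list(members)].to_numpy(float) @ (w / w.sum())
    for pop in values.columns:
        if pop not in grouped_members:
            out[pop] = values[pop].to_numpy(float)
    return pd.DataFrame(out, index=values.index)
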