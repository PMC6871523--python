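"""Frequency-matched random SNP sets and empirical null distributions.

A correlation between population risk scores and disease prevalence could
arise for any set of SNPs with the right frequency profile, not just the
disease-associated ones.  The empirical null addresses this: draw many sets
of random SNPs, each set containing one SNP per risk variant whose allele
frequency in the reference population is within a tolerance (default < 0.01,
strict) of that risk variant's risk-allele frequency, score every set in
every population, and compare the observed statistic against the resulting
distribution.

Matching is per target: each slot of a null set is tied to one specific risk
variant and filled uniformly at random from the candidates inside the
tolerance band, without reuse within a set.  For unassociated SNPs there is
no defined "risk" allele, so matching and scoring use the frequency of the
counted (ALT) allele of the frequency source as supplied.

The empirical p-value convention is the plain exceedance fraction
``#{null > observed} / #null`` (strict inequality, no +1 correction), so
3 exceedances among 10,000 sets give p = 0.0003.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .risk_variants import PopulationFrequencyTable, RiskVariantTable, ValidationError

log = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.01
DEFAULT_N_SETS = 10_000


class InfeasibleMatchingError(ValidationError):
    """No unused candidate within tolerance for some target variant."""


@dataclass
class CandidatePool:
    """Random-SNP candidates with reference and per-population frequencies.

    ``pop_raf`` rows align with ``rsids``; ``ref_raf`` is the counted-allele
    frequency in the reference population (one of ``pop_raf``'s columns).
    Risk-variant rsids are excluded at construction.
    """

    rsids: np.ndarray
    ref_raf: np.ndarray
    pop_raf: pd.DataFrame
    reference_population: str

    def __post_init__(self) -> None:
        if len(self.rsids) == 0:
            raise ValidationError("empty candidate pool")
        if len(set(self.rsids)) != len(self.rsids):
            raise ValidationError("candidate pool contains duplicate rsids")
        if ((self.ref_raf < 0) | (self.ref_raf > 1)).any():
            raise ValidationError("candidate reference frequencies outside [0, 1]")

    @property
    def size(self) -> int:
        return len(self.rsids)

    @property
    def populations(self) -> list[str]:
        return list(self.pop_raf.columns)

    def eligible_indices(
        self, targets: RiskVariantTable, tolerance: float = DEFAULT_TOLERANCE
    ) -> list[np.ndarray]:
        """Per-target arrays of pool indices within the (strict) tolerance of
        the target's reference risk-allele frequency."""
        out = []
        for v in targets:
            if np.isnan(v.reference_raf):
                raise ValidationError(f"{v.rsid}: reference_raf required for matching")
            idx = np.flatnonzero(np.abs(self.ref_raf - v.reference_raf) < tolerance)
            if idx.size == 0:
                raise InfeasibleMatchingError(
                    f"no candidate within {tolerance} of {v.rsid} "
                    f"(reference RAF {v.reference_raf:.4f})"
                )
            out.append(idx)
        return out


def read_pool_tsv(path: str | Path, reference_population: str) -> pd.DataFrame:
    """Read a genome-wide frequency TSV: rsid, chrom, pos, allele, then one
    frequency column per population."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    fixed = {"rsid", "chrom", "pos", "allele"}
    missing = fixed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: pool TSV missing columns {sorted(missing)}")
    if reference_population not in df.columns:
        raise ValidationError(f"{path}: no frequency column for {reference_population!r}")
    pop_cols = [c for c in df.columns if c not in fixed]
    bad = df[pop_cols].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header occupies line 1
        raise ValidationError(f"{path}: malformed frequency value on line {line}")
    return df


def build_candidate_pool(
    freq_source: PopulationFrequencyTable | pd.DataFrame | str | Path,
    reference_population: str,
    exclude: RiskVariantTable | None = None,
) -> CandidatePool:
    """Build the candidate pool from a frequency table, excluding the risk
    variants themselves."""
    if isinstance(freq_source, (str, Path)):
        freq_source = read_pool_tsv(freq_source, reference_population)
    if isinstance(freq_source, PopulationFrequencyTable):
        pop_raf = freq_source.raf.T.copy()  # rows: rsids, columns: populations
        rsids = np.array(pop_raf.index, dtype=object)
    else:
        fixed = [c for c in ("rsid", "chrom", "pos", "allele") if c in freq_source.columns]
        pop_cols = [c for c in freq_source.columns if c not in fixed]
        pop_raf = freq_source[pop_cols].astype(float)
        rsids = freq_source["rsid"].to_numpy(dtype=object)
        pop_raf.index = rsids
    if reference_population not in pop_raf.columns:
        raise ValidationError(f"no frequencies for reference population {reference_population!r}")
    if exclude is not None:
        keep = ~np.isin(rsids, exclude.rsids)
        rsids = rsids[keep]
        pop_raf = pop_raf.loc[rsids]
    if len(rsids) == 0:
        raise ValidationError("candidate pool is empty after excluding risk variants")
    return CandidatePool(
        rsids=rsids,
        ref_raf=pop_raf[reference_population].to_numpy(float),
        pop_raf=pop_raf,
        reference_population=reference_population,
    )


def sample_matched_set(
    pool: CandidatePool,
    targets: RiskVariantTable,
    tolerance: float = DEFAULT_TOLERANCE,
    rng: np.random.Generator | None = None,
    eligible: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Draw one matched set: pool indices, one per target, uniform among the
    candidates inside the tolerance band, distinct within the set.

    ``eligible`` may carry precomputed :meth:`CandidatePool.eligible_indices`
    output to amortise the tolerance scan over many draws.
    """
    rng = rng or np.random.default_rng()
    if eligible is None:
        eligible = pool.eligible_indices(targets, tolerance)
    chosen = np.empty(targets.n, dtype=int)
    used: set[int] = set()
    for j, idx in enumerate(eligible):
        pick = int(idx[rng.integers(idx.size)])
        if pick in used:
            avail = np.setdiff1d(idx, np.fromiter(used, dtype=int), assume_unique=False)
            if avail.size == 0:
                raise InfeasibleMatchingError(
                    f"no unused candidate within {tolerance} of {targets.variants[j].rsid}"
                )
            pick = int(avail[rng.integers(avail.size)])
        chosen[j] = pick
        used.add(pick)
    return chosen


@dataclass
class NullSetCollection:
    """Matched random SNP sets with per-set per-population unweighted GRS.

    ``sets`` holds pool indices (n_sets x n_targets); ``grs`` is the per-set
    unweighted population score matrix (n_sets x populations), computed from
    frequencies as 2 x mean counted-allele frequency over the set.
    """

    sets: np.ndarray
    grs: pd.DataFrame
    pool: CandidatePool
    seed: int | None

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    def rsids(self, set_index: int) -> list[str]:
        return [str(r) for r in self.pool.rsids[self.sets[set_index]]]

    def to_frame(self) -> pd.DataFrame:
        n_sets, n_slots = self.sets.shape
        return pd.DataFrame(
            {
                "set_index": np.repeat(np.arange(n_sets), n_slots),
                "slot_index": np.tile(np.arange(n_slots), n_sets),
                "rsid": self.pool.rsids[self.sets.ravel()],
            }
        )


def generate_null_collection(
    pool: CandidatePool,
    targets: RiskVariantTable,
    n_sets: int = DEFAULT_N_SETS,
    tolerance: float = DEFAULT_TOLERANCE,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullSetCollection:
    """Draw ``n_sets`` independent matched sets and score each in every
    population.  Reproducible from ``seed``; candidates are reused across
    sets but never within one."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eligible = pool.eligible_indices(targets, tolerance)
    sets = np.empty((n_sets, targets.n), dtype=int)
    for k in range(n_sets):
        sets[k] = sample_matched_set(pool, targets, tolerance, rng, eligible=eligible)
    raf = pool.pop_raf.to_numpy(float)  # pool_size x populations
    grs = 2.0 * raf[sets].mean(axis=1)  # n_sets x populations
    return NullSetCollection(
        sets=sets,
        grs=pd.DataFrame(grs, columns=pool.populations),
        pool=pool,
        seed=seed,
    )


def empirical_p_greater(observed: float, null_values: Sequence[float]) -> float:
    """Exceedance p-value: fraction of null values strictly greater than the
    observed statistic (no +1 correction)."""
    null_arr = np.asarray(null_values, dtype=float)
    if null_arr.size == 0:
        raise ValidationError("empty null distribution")
    return float(np.count_nonzero(null_arr > observed) / null_arr.size)
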