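"""Literature prevalence studies: eligibility filtering, age adjustment, pooling.

Disease prevalence estimates from the literature are heterogeneous: studies
cover different age windows, some are restricted to one sex or to comorbid
clinic populations, and sample sizes vary over orders of magnitude.  This
module implements the harmonisation used before correlating prevalence with
population genetic risk scores:

* eligibility — keep studies of the general (non-comorbid) population, both
  sexes, with at least 100 participants;
* age adjustment — divide the observed prevalence by the relative
  contribution of the study's age window to all-ages prevalence, computed
  from a reference age-specific prevalence curve and reference population age
  structure (the working assumption is that the *shape* of prevalence over
  age is shared across countries, while its level differs);
* pooling — sample-size-weighted mean over a population's eligible studies,
  with a pooled binomial standard error.

The relative contribution of an age window [lo, hi] is

    r = (E[prevalence | age in window]) / (E[prevalence])

with both expectations taken under the reference curve p_d and reference age
counts n_d; windows partially covering a bin prorate that bin's count
linearly by years of overlap.  A study covering the full reference range has
r = 1 and is unadjusted; a study with no stated age range is left unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .risk_variants import ValidationError

# exclusion reason codes, checked in this order
REASON_SMALL_SAMPLE = "small_sample"
REASON_SINGLE_SEX = "single_sex"
REASON_COMORBID = "comorbid"
REASON_NOT_GENERAL = "not_general_population"

MIN_SAMPLE_SIZE = 100


class AdjustmentUndefinedError(ValidationError):
    """Reference prevalence is identically zero over the study's age window."""


@dataclass(frozen=True)
class PrevalenceStudy:
    study_id: str
    population_key: str
    prevalence: float
    sample_size: int
    age_min: float = math.nan
    age_max: float = math.nan
    sexes: str = "both"  # both | male | female
    comorbid: bool = False
    general_population: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(f"{self.study_id}: prevalence outside [0, 1]")
        if self.sample_size < 1:
            raise ValidationError(f"{self.study_id}: sample_size must be positive")
        if self.sexes not in ("both", "male", "female"):
            raise ValidationError(f"{self.study_id}: sexes must be both|male|female")
        if (
            not math.isnan(self.age_min)
            and not math.isnan(self.age_max)
            and not self.age_min < self.age_max
        ):
            raise ValidationError(f"{self.study_id}: need age_min < age_max")

    @property
    def has_age_range(self) -> bool:
        return not (math.isnan(self.age_min) and math.isnan(self.age_max))


@dataclass
class AgeReference:
    """Contiguous age bins with reference prevalence and population counts."""

    age_lo: np.ndarray
    age_hi: np.ndarray
    ref_prevalence: np.ndarray
    pop_count: np.ndarray

    def __post_init__(self) -> None:
        self.age_lo = np.asarray(self.age_lo, dtype=float)
        self.age_hi = np.asarray(self.age_hi, dtype=float)
        self.ref_prevalence = np.asarray(self.ref_prevalence, dtype=float)
        self.pop_count = np.asarray(self.pop_count, dtype=float)
        if not (self.age_lo[1:] == self.age_hi[:-1]).all():
            raise ValidationError("age bins must be contiguous and non-overlapping")
        if (self.age_hi <= self.age_lo).any():
            raise ValidationError("age bins must have positive width")
        if ((self.ref_prevalence < 0) | (self.ref_prevalence > 1)).any():
            raise ValidationError("reference prevalences outside [0, 1]")
        if (self.pop_count < 0).any() or self.pop_count.sum() <= 0:
            raise ValidationError("population counts must be non-negative with positive sum")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.age_lo[0]), float(self.age_hi[-1])

    def overall_prevalence(self) -> float:
        return float(np.dot(self.ref_prevalence, self.pop_count) / self.pop_count.sum())


@dataclass(frozen=True)
class PopulationPrevalence:
    population_key: str
    pooled_prevalence: float
    standard_error: float
    n_studies: int
    total_sample_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pooled_prevalence <= 1.0:
            raise ValidationError(f"{self.population_key}: pooled prevalence outside [0, 1]")


def filter_studies(
    studies: Iterable[PrevalenceStudy],
) -> tuple[list[PrevalenceStudy], list[tuple[PrevalenceStudy, str]]]:
    """Split studies into eligible ones and excluded ones with reason codes.

    Eligible: sample_size >= 100, both sexes, general non-comorbid population.
    When several rules fail, the first failing rule (in the order sample size,
    sex coverage, comorbidity, population type) is reported.
    """
    eligible: list[PrevalenceStudy] = []
    excluded: list[tuple[PrevalenceStudy, str]] = []
    for s in studies:
        if s.sample_size < MIN_SAMPLE_SIZE:
            excluded.append((s, REASON_SMALL_SAMPLE))
        elif s.sexes != "both":
            excluded.append((s, REASON_SINGLE_SEX))
        elif s.comorbid:
            excluded.append((s, REASON_COMORBID))
        elif not s.general_population:
            excluded.append((s, REASON_NOT_GENERAL))
        else:
            eligible.append(s)
    return eligible, excluded


def relative_contribution(ref: AgeReference, age_min: float, age_max: float) -> float:
    """Ratio of expected prevalence inside [age_min, age_max] to expected
    prevalence over all ages, under the reference curve and age structure.

    Open-ended windows (NaN bound) extend to the corresponding end of the
    reference range; the window is clipped to the reference span.  Partial
    bin coverage prorates the bin's population count by years of overlap.
    """
    lo_ref, hi_ref = ref.span
    lo = lo_ref if math.isnan(age_min) else max(age_min, lo_ref)
    hi = hi_ref if math.isnan(age_max) else min(age_max, hi_ref)
    if hi <= lo:
        raise ValidationError(f"age window [{age_min}, {age_max}] does not overlap reference bins")
    overlap_years = np.clip(np.minimum(ref.age_hi, hi) - np.maximum(ref.age_lo, lo), 0.0, None)
    frac = overlap_years / (ref.age_hi - ref.age_lo)
    w = ref.pop_count * frac
    if w.sum() <= 0:
        raise ValidationError("age window covers no reference population")
    window_prev = float(np.dot(ref.ref_prevalence, w) / w.sum())
    overall = ref.overall_prevalence()
    if overall == 0.0:
        raise AdjustmentUndefinedError("reference prevalence is identically zero")
    r = window_prev / overall
    if r == 0.0:
        raise AdjustmentUndefinedError(
            f"reference prevalence is zero over [{lo}, {hi}]; adjustment undefined"
        )
    return r


def age_adjust(study: PrevalenceStudy, ref: AgeReference) -> float:
    """All-ages prevalence estimate: observed prevalence divided by the
    relative contribution of the study's age window.  Studies without a
    stated age range are returned unadjusted."""
    if not study.has_age_range:
        return study.prevalence
    r = relative_contribution(ref, study.age_min, study.age_max)
    return study.prevalence / r


def pool_prevalence(
    adjusted: Sequence[tuple[float, int]], population_key: str = ""
) -> PopulationPrevalence:
    """Sample-size-weighted mean of (prevalence, sample_size) pairs with the
    pooled binomial standard error sqrt(p(1-p)/N_total)."""
    if not adjusted:
        raise ValidationError("cannot pool an empty study list")
    p = np.array([a[0] for a in adjusted], dtype=float)
    s = np.array([a[1] for a in adjusted], dtype=float)
    total = s.sum()
    pooled = float(np.dot(p, s) / total)
    pooled_clipped = min(max(pooled, 0.0), 1.0)
    se = math.sqrt(pooled_clipped * (1.0 - pooled_clipped) / total)
    return PopulationPrevalence(
        population_key=population_key,
        pooled_prevalence=pooled_clipped,
        standard_error=se,
        n_studies=len(adjusted),
        total_sample_size=int(total),
    )


def population_prevalences(
    studies: Iterable[PrevalenceStudy], ref: AgeReference
) -> tuple[pd.DataFrame, list[tuple[PrevalenceStudy, str]]]:
    """Filter, age-adjust, and pool studies into one prevalence per analysis
    population.  Returns the pooled table plus the exclusion list."""
    eligible, excluded = filter_studies(studies)
    by_pop: dict[str, list[tuple[float, int]]] = {}
    for s in eligible:
        by_pop.setdefault(s.population_key, []).append((age_adjust(s, ref), s.sample_size))
    rows = []
    for pop in by_pop:
        pooled = pool_prevalence(by_pop[pop], population_key=pop)
        rows.append(
            {
                "population": pop,
                "pooled_prevalence": pooled.pooled_prevalence,
                "standard_error": pooled.standard_error,
                "n_studies": pooled.n_studies,
                "total_sample_size": pooled.total_sample_size,
            }
        )
    return pd.DataFrame(rows), excluded


def read_studies_tsv(path: str | Path) -> list[PrevalenceStudy]:
    """Read a study table TSV: study_id, population_key, prevalence,
    sample_size, age_min, age_max, sexes, comorbid, general_population."""
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "population_key": str})
    studies = []
    for row in df.itertuples(index=False):
        studies.append(
            PrevalenceStudy(
                study_id=row.study_id,
                population_key=row.population_key,
                prevalence=float(row.prevalence),
                sample_size=int(row.sample_size),
                age_min=float(row.age_min) if not pd.isna(row.age_min) else math.nan,
                age_max=float(row.age_max) if not pd.isna(row.age_max) else math.nan,
                sexes=str(row.sexes),
                comorbid=bool(row.comorbid),
                general_population=bool(row.general_population),
            )
        )
    return studies


def read_age_reference(path: str | Path) -> AgeReference:
    """Read an age-reference TSV: age_lo, age_hi, ref_prevalence, pop_count."""
    df = pd.read_csv(path, sep="\t")
    return AgeReference(
        age_lo=df["age_lo"].to_numpy(),
        age_hi=df["age_hi"].to_numpy(),
        ref_prevalence=df["ref_prevalence"].to_numpy(),
        pop_count=df["pop_count"].to_numpy(),
    )


def default_age_reference() -> AgeReference:
    """Synthetic decade-binned reference: monotone-increasing prevalence with
    age and a population pyramid thinning at high ages.

    This is a stand-in with the qualitative shape of published age-specific
    prevalence curves for age-progressive disease, NOT digitised from any
    published figure; analyses of real data should supply a measured curve.
    """
    age_lo = np.arange(0, 90, 10, dtype=float)
    age_hi = age_lo + 10.0
    ref_prevalence = np.array([0.0, 0.001, 0.004, 0.01, 0.03, 0.07, 0.14, 0.22, 0.30])
    pop_count = np.array([1100, 1200, 1250, 1300, 1250, 1150, 900, 550, 250], dtype=float)
    return AgeReference(age_lo, age_hi, ref_prevalence, pop_count)


def write_age_reference(ref: AgeReference, path: str | Path) -> None:
    pd.DataFrame(
        {
            "age_lo": ref.age_lo,
            "age_hi": ref.age_hi,
            "ref_prevalence": ref.ref_prevalence,
            "pop_count": ref.pop_count,
        }
    ).to_csv(path, sep="\t", index=False)
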