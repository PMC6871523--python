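"""Risk-variant tables, genotype panels, and per-population risk-allele frequencies.

The analyses in this package start from a table of disease-associated SNPs
(identifier, location, risk/other allele, per-allele odds ratio) and a
multi-population diploid genotype panel (VCF plus a sample->population map in
the 1000 Genomes integrated-panel dialect).  This module reads and validates
both and reduces them to per-population risk-allele frequencies (RAFs), the
primitive every downstream statistic is built from.

Orientation handling: the VCF may store either allele as REF.  Dosages always
count copies of the *risk* allele; records whose REF is the risk allele are
complemented (``2 - ALT count``).  Any other allele configuration is an error,
never silently flipped, because a silent strand/orientation flip corrupts RAFs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Input data violates a documented contract."""


class AlleleMismatchError(ValidationError):
    """VCF alleles match neither (risk, other) nor their swap."""


@dataclass(frozen=True)
class RiskVariant:
    """One biallelic risk SNP with its per-allele odds ratio.

    ``weight`` is the natural log of the odds ratio, the weight used by the
    weighted genetic risk score.  ``reference_raf`` is the risk-allele
    frequency in the reference (score-discovery) population when known.
    """

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float
    weight: float = field(default=math.nan)
    reference_raf: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValidationError(f"{self.rsid}: odds_ratio must be > 0, got {self.odds_ratio}")
        for allele in (self.risk_allele, self.other_allele):
            if allele not in VALID_BASES:
                raise ValidationError(f"{self.rsid}: malformed allele {allele!r}")
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: risk and other allele are identical")
        if math.isnan(self.weight):
            object.__setattr__(self, "weight", math.log(self.odds_ratio))
        if not math.isnan(self.reference_raf) and not 0.0 <= self.reference_raf <= 1.0:
            raise ValidationError(f"{self.rsid}: reference_raf outside [0, 1]")


class RiskVariantTable:
    """Ordered collection of :class:`RiskVariant` with unique rsids."""

    def __init__(self, variants: Sequence[RiskVariant]):
        if len(variants) < 1:
            raise ValidationError("risk-variant table is empty")
        rsids = [v.rsid for v in variants]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsids: {', '.join(dupes)}")
        self.variants: tuple[RiskVariant, ...] = tuple(variants)

    @property
    def n(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)

    @property
    def reference_raf(self) -> np.ndarray:
        return np.array([v.reference_raf for v in self.variants], dtype=float)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "risk_allele": [v.risk_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "odds_ratio": [v.odds_ratio for v in self.variants],
                "weight": [v.weight for v in self.variants],
                "reference_raf": [v.reference_raf for v in self.variants],
            }
        )


REQUIRED_VARIANT_COLUMNS = ("rsid", "chrom", "pos", "risk_allele", "other_allele", "odds_ratio")


def read_variant_table(path: str | Path) -> RiskVariantTable:
    """Read a tab-separated risk-variant table; row order is preserved.

    Required columns: rsid, chrom, pos, risk_allele, other_allele, odds_ratio.
    An optional ``reference_raf`` column carries the risk-allele frequency in
    the reference population (used for frequency matching of null SNP sets).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    has_ref = "reference_raf" in df.columns
    variants = [
        RiskVariant(
            rsid=row.rsid,
            chrom=str(row.chrom),
            pos=int(row.pos),
            risk_allele=str(row.risk_allele),
            other_allele=str(row.other_allele),
            odds_ratio=float(row.odds_ratio),
            reference_raf=float(row.reference_raf) if has_ref else math.nan,
        )
        for row in df.itertuples(index=False)
    ]
    return RiskVariantTable(variants)


@dataclass
class GenotypePanel:
    """Per-sample risk-allele dosages with population labels.

    ``dosage`` is a float matrix (samples x variants) with values in
    {0, 1, 2} and NaN for missing genotypes; columns follow the order of the
    risk-variant table the panel was read against.
    """

    samples: list[str]
    populations: Mapping[str, str]
    super_populations: Mapping[str, str]
    dosage: np.ndarray
    rsids: list[str]

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.rsids)):
            raise ValidationError("dosage matrix shape does not match samples x variants")
        missing = [s for s in self.samples if s not in self.populations]
        if missing:
            raise ValidationError(f"samples without population assignment: {missing[:5]}")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0, 1, 2} or missing")

    @property
    def population_labels(self) -> list[str]:
        """Population codes in order of first appearance among samples."""
        return list(pd.unique(np.array([self.populations[s] for s in self.samples])))

    def sample_index(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=int,
        )

    def population_sizes(self) -> dict[str, int]:
        return {p: len(self.sample_index(p)) for p in self.population_labels}


def read_panel_file(path: str | Path) -> pd.DataFrame:
    """Read a sample->population map TSV with columns sample, pop, super_pop."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in ("sample", "pop", "super_pop"):
        if col not in df.columns:
            raise ValidationError(f"{path}: panel file missing column {col!r}")
    return df


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_genotype_panel(
    vcf_path: str | Path, panel_path: str | Path, table: RiskVariantTable
) -> GenotypePanel:
    """Read risk-allele dosages for the table's variants from a VCF.

    Records are matched by rsid first, then by (chrom, pos).  Variants absent
    from the VCF yield missing dosages with a logged warning.  Multiallelic
    records and allele configurations other than (risk, other) or its swap
    are rejected.
    """
    panel_df = read_panel_file(panel_path)
    populations = dict(zip(panel_df["sample"], panel_df["pop"]))
    super_pops = dict(zip(panel_df["pop"], panel_df["super_pop"]))

    by_rsid = {v.rsid: i for i, v in enumerate(table.variants)}
    by_pos = {(_norm_chrom(v.chrom), v.pos): i for i, v in enumerate(table.variants)}

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in populations]
    if absent:
        raise ValidationError(f"VCF samples absent from panel file: {absent[:5]}")

    dosage = np.full((len(samples), table.n), np.nan)
    seen = np.zeros(table.n, dtype=bool)
    for record in vcf:
        idx = by_rsid.get(record.ID) if record.ID else None
        if idx is None:
            idx = by_pos.get((_norm_chrom(record.CHROM), record.POS))
        if idx is None:
            continue
        variant = table.variants[idx]
        if len(record.ALT) != 1:
            raise ValidationError(f"{variant.rsid}: multiallelic record (ALT={record.ALT})")
        ref, alt = record.REF, record.ALT[0]
        # gt_types codes: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = record.gt_types.astype(float)
        alt_count = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        if (ref, alt) == (variant.other_allele, variant.risk_allele):
            dosage[:, idx] = alt_count
        elif (ref, alt) == (variant.risk_allele, variant.other_allele):
            dosage[:, idx] = 2.0 - alt_count
        else:
            raise AlleleMismatchError(
                f"{variant.rsid}: VCF alleles {ref}/{alt} match neither "
                f"({variant.other_allele}/{variant.risk_allele}) nor their swap"
            )
        seen[idx] = True
    for i, variant in enumerate(table.variants):
        if not seen[i]:
            log.warning("variant %s not found in VCF; dosages set to missing", variant.rsid)
    return GenotypePanel(
        samples=samples,
        populations=populations,
        super_populations=super_pops,
        dosage=dosage,
        rsids=table.rsids,
    )


@dataclass
class PopulationFrequencyTable:
    """Per-population risk-allele frequencies with called-allele counts.

    ``raf`` and ``called`` are aligned DataFrames (populations x rsids); NaN
    marks (population, variant) cells with zero called alleles.
    """

    raf: pd.DataFrame
    called: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.raf.index.equals(self.called.index) or not self.raf.columns.equals(
            self.called.columns
        ):
            raise ValidationError("raf and called tables are not aligned")
        vals = self.raf.to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValidationError("risk-allele frequencies outside [0, 1]")
        counts = vals * self.called.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(counts - np.round(counts)), initial=0.0) > 1e-6:
                raise ValidationError("raf * called_alleles is not integral")

    @property
    def populations(self) -> list[str]:
        return list(self.raf.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.raf.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: population, rsid, raf, called_alleles."""
        long = self.raf.stack(future_stack=True).rename("raf").reset_index()
        long.columns = ["population", "rsid", "raf"]
        long["called_alleles"] = self.called.stack(future_stack=True).to_numpy()
        return long

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def population_raf(panel: GenotypePanel, table: RiskVariantTable) -> PopulationFrequencyTable:
    """Per-population risk-allele frequency: non-missing allele count over
    2 x non-missing sample count (complete-allele analysis)."""
    if not panel.samples:
        raise ValidationError("empty genotype panel")
    pops = panel.population_labels
    raf = np.full((len(pops), table.n), np.nan)
    called = np.zeros((len(pops), table.n))
    for k, pop in enumerate(pops):
        sub = panel.dosage[panel.sample_index(pop), :]
        n_called = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            raf[k] = np.nansum(sub, axis=0) / (2.0 * n_called)
        raf[k, n_called == 0] = np.nan
        called[k] = 2.0 * n_called
    return PopulationFrequencyTable(
        raf=pd.DataFrame(raf, index=pops, columns=table.rsids),
        called=pd.DataFrame(called, index=pops, columns=table.rsids, dtype=float),
    )


def pool_frequencies(
    freqs: PopulationFrequencyTable, grouping: Mapping[str, Sequence[str]]
) -> PopulationFrequencyTable:
    """Pool member populations into groups by recounting alleles.

    The pooled frequency is the called-allele-count-weighted mean of member
    frequencies, identical to recomputing the frequency over the union of
    samples.  Used for super-population summaries and merged analysis
    populations.
    """
    rows_raf, rows_called, index = [], [], []
    for group, members in grouping.items():
        missing = [m for m in members if m not in freqs.raf.index]
        if missing:
            raise ValidationError(f"group {group!r}: unknown populations {missing}")
        raf = freqs.raf.loc[list(members)].to_numpy(float)
        called = freqs.called.loc[list(members)].to_numpy(float)
        counts = np.nansum(raf * called, axis=0)
        total = np.nansum(np.where(np.isnan(raf), 0.0, called), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = counts / total
        rows_raf.append(pooled)
        rows_called.append(total)
        index.append(group)
    return PopulationFrequencyTable(
        raf=pd.DataFrame(rows_raf, index=index, columns=freqs.raf.columns),
        called=pd.DataFrame(rows_called, index=index, columns=freqs.raf.columns),
    )
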