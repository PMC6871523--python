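"""Synthetic inputs with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here so the whole analysis
runs and is validated without any external download:

* population structure — allele frequencies follow the Balding-Nichols
  model: around an ancestral frequency p drawn uniform on (0.05, 0.95), each
  population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with its own
  differentiation parameter F (F = 0 copies the ancestral frequency).  The
  default F gradient (0 to 0.15) mirrors the spread seen between closely
  related and strongly diverged human populations;
* genotypes — two independent allele draws per sample (Hardy-Weinberg within
  population), emitted as a plain VCF 4.2 plus a sample->population panel
  TSV, with random REF/ALT orientation so the readers' complement rule is
  exercised;
* a candidate SNP pool anchored at the reference population, constructed so
  that every risk variant has at least 30 frequency-matched candidates
  (matching is feasible by design);
* literature-style prevalence studies — each population's true prevalence is
  a linear function of its unweighted score plus Gaussian noise; studies
  observe it through a random age window (so age adjustment has something to
  invert) and binomial sampling.

All generators are deterministic under a fixed seed, and every emitted file
round-trips through the corresponding reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prevalence import (
    AgeReference,
    PrevalenceStudy,
    default_age_reference,
    relative_contribution,
    write_age_reference,
)
from .risk_variants import (
    GenotypePanel,
    RiskVariant,
    RiskVariantTable,
    ValidationError,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic inputs.

    Defaults emulate the scale of the real analysis: 26 risk variants,
    ~100 diploid samples per population, ten analysis populations spanning a
    differentiation gradient, and a candidate pool 100x the risk-variant
    count.  ``prevalence_link`` is (intercept, slope, noise_sd) on the
    prevalence scale; when None, the link is calibrated at generation time to
    plant a score-prevalence correlation of ``link_target_r`` at noise
    ``link_noise_sd`` around a mean prevalence of ``link_mean_prevalence``.
    """

    n_populations: int = 10
    samples_per_population: int = 100
    n_risk_variants: int = 26
    n_pool_snps: int = 2600
    differentiation: Sequence[float] | float = (
        0.0, 0.003, 0.005, 0.01, 0.02, 0.03, 0.05, 0.08, 0.12, 0.15,
    )
    or_range: tuple[float, float] = (1.1, 1.7)
    prevalence_link: tuple[float, float, float] | None = None
    link_target_r: float = 0.9
    link_noise_sd: float = 0.01
    link_mean_prevalence: float = 0.08
    include_ineligible: bool = True
    population_labels: Sequence[str] | None = None
    grouping: Mapping[str, Sequence[str]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        f = self.f_values
        if ((f < 0) | (f >= 1)).any():
            raise ValidationError("differentiation F must lie in [0, 1)")
        if self.or_range[0] <= 0:
            raise ValidationError("odds ratios must be positive")
        if self.prevalence_link is not None and self.prevalence_link[2] < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.population_labels is not None and len(self.population_labels) != self.n_populations:
            raise ValidationError("population_labels length != n_populations")

    @property
    def f_values(self) -> np.ndarray:
        if np.isscalar(self.differentiation):
            return np.full(self.n_populations, float(self.differentiation))
        f = np.asarray(self.differentiation, dtype=float)
        if f.size != self.n_populations:
            raise ValidationError("differentiation length != n_populations")
        return f

    @property
    def labels(self) -> list[str]:
        if self.population_labels is not None:
            return list(self.population_labels)
        return [f"POP{k+1:02d}" for k in range(self.n_populations)]

    @property
    def reference_population(self) -> str:
        """The first population plays the score-discovery reference role."""
        return self.labels[0]


def balding_nichols(
    ancestral: np.ndarray, f_values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-population frequencies (pops x sites) around ancestral frequencies."""
    ancestral = np.asarray(ancestral, dtype=float)
    out = np.empty((f_values.size, ancestral.size))
    for k, f in enumerate(f_values):
        if f == 0.0:
            out[k] = ancestral
        else:
            out[k] = rng.beta(ancestral * (1 - f) / f, (1 - ancestral) * (1 - f) / f)
    return out


@dataclass
class SimulatedFrequencies:
    """Per-population frequencies with the ancestral truth retained."""

    ancestral: np.ndarray
    raf: pd.DataFrame  # populations x site ids


def simulate_frequencies(
    config: SimulationConfig,
    n_sites: int | None = None,
    site_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedFrequencies:
    """Draw Balding-Nichols structured frequencies for every population."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if n_sites is None:
        n_sites = config.n_risk_variants
    ancestral = rng.uniform(0.05, 0.95, size=n_sites)
    raf = balding_nichols(ancestral, config.f_values, rng)
    if site_ids is None:
        site_ids = [f"rsS{i+1:06d}" for i in range(n_sites)]
    return SimulatedFrequencies(
        ancestral=ancestral,
        raf=pd.DataFrame(raf, index=config.labels, columns=list(site_ids)),
    )


def simulate_risk_variants(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[RiskVariantTable, SimulatedFrequencies]:
    """Risk-variant table (random distinct allele pairs, log-uniform odds
    ratios) plus structured per-population risk-allele frequencies; the
    table's reference_raf column is the reference population's frequency."""
    sim = simulate_frequencies(config, n_sites=config.n_risk_variants, rng=rng)
    lo, hi = config.or_range
    ors = np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_risk_variants))
    ref_raf = sim.raf.loc[config.reference_population].to_numpy(float)
    variants = []
    for i, rsid in enumerate(sim.raf.columns):
        risk, other = rng.choice(_BASES, size=2, replace=False)
        variants.append(
            RiskVariant(
                rsid=str(rsid),
                chrom="1",
                pos=10_000 + 5_000 * i,
                risk_allele=str(risk),
                other_allele=str(other),
                odds_ratio=float(ors[i]),
                reference_raf=float(ref_raf[i]),
            )
        )
    return RiskVariantTable(variants), sim


def _super_population(index: int, n_populations: int) -> str:
    return f"SP{1 + (index * 3) // max(n_populations, 1)}"


def simulate_panel(
    frequencies: pd.DataFrame,
    table: RiskVariantTable,
    samples_per_population: int,
    rng: np.random.Generator,
    vcf_path: str | Path | None = None,
    panel_path: str | Path | None = None,
) -> GenotypePanel:
    """Hardy-Weinberg genotypes from per-population frequencies; optionally
    emitted as VCF 4.2 + panel TSV round-trippable through the readers.

    Half the VCF records (in expectation) are written with the risk allele as
    REF, so reading exercises the dosage complement rule.
    """
    pops = list(frequencies.index)
    samples, sample_pop = [], {}
    dosage_rows = []
    for pop in pops:
        p = frequencies.loc[pop, table.rsids].to_numpy(float)
        d = rng.binomial(1, p, size=(samples_per_population, table.n)) + rng.binomial(
            1, p, size=(samples_per_population, table.n)
        )
        dosage_rows.append(d.astype(float))
        for j in range(samples_per_population):
            name = f"{pop}_S{j+1:04d}"
            samples.append(name)
            sample_pop[name] = pop
    dosage = np.vstack(dosage_rows)
    super_map = {pop: _super_population(k, len(pops)) for k, pop in enumerate(pops)}
    panel = GenotypePanel(
        samples=samples,
        populations=sample_pop,
        super_populations=super_map,
        dosage=dosage,
        rsids=table.rsids,
    )
    if vcf_path is not None:
        swap = rng.random(table.n) < 0.5
        write_vcf(panel, table, vcf_path, swap_orientation=swap)
    if panel_path is not None:
        pd.DataFrame(
            {
                "sample": samples,
                "pop": [sample_pop[s] for s in samples],
                "super_pop": [super_map[sample_pop[s]] for s in samples],
            }
        ).to_csv(panel_path, sep="\t", index=False)
    return panel


def write_vcf(
    panel: GenotypePanel,
    table: RiskVariantTable,
    path: str | Path,
    swap_orientation: np.ndarray | None = None,
) -> None:
    """Emit the panel as a minimal valid VCF 4.2 (GT only, unphased).

    ``swap_orientation[i]`` writes variant i with the risk allele as REF (the
    reader must complement); default writes risk as ALT throughout.
    """
    if swap_orientation is None:
        swap_orientation = np.zeros(table.n, dtype=bool)
    gt_by_alt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for i, v in enumerate(table.variants):
            if swap_orientation[i]:
                ref, alt = v.risk_allele, v.other_allele
                alt_count = 2.0 - panel.dosage[:, i]
            else:
                ref, alt = v.other_allele, v.risk_allele
                alt_count = panel.dosage[:, i]
            gts = [gt_by_alt.get(a, "./.") for a in alt_count]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def simulate_candidate_pool(
    config: SimulationConfig,
    table: RiskVariantTable,
    rng: np.random.Generator,
    min_candidates: int = 30,
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Genome-wide-style frequency table guaranteeing matching feasibility.

    The first ``min_candidates`` pool SNPs per risk variant are anchored
    within 0.009 of the variant's reference frequency; the rest are uniform.
    Non-reference population frequencies follow Balding-Nichols around the
    reference frequency with each population's F.  Raises before writing if
    the design cannot provide ``min_candidates`` matches per target.
    """
    if config.n_pool_snps < 50 * table.n:
        raise ValidationError(
            f"pool of {config.n_pool_snps} SNPs too small for {table.n} targets "
            f"(need >= {50 * table.n})"
        )
    targets = table.reference_raf
    if np.isnan(targets).any():
        raise ValidationError("risk variants need reference_raf for pool construction")
    anchored = np.concatenate(
        [
            np.clip(t + rng.uniform(-0.009, 0.009, size=min_candidates), 1e-3, 1 - 1e-3)
            for t in targets
        ]
    )
    if (np.abs(anchored - np.repeat(targets, min_candidates)) >= tolerance).any():
        raise ValidationError("pool construction infeasible: anchors clipped out of tolerance")
    n_free = config.n_pool_snps - anchored.size
    if n_free < 0:
        raise ValidationError("n_pool_snps smaller than the anchored candidates alone")
    ref_raf = np.concatenate([anchored, rng.uniform(0.05, 0.95, size=n_free)])
    rng.shuffle(ref_raf)
    raf = balding_nichols(ref_raf, config.f_values, rng)
    raf[list(config.labels).index(config.reference_population)] = ref_raf
    pool = pd.DataFrame(
        {
            "rsid": [f"rsP{i+1:06d}" for i in range(config.n_pool_snps)],
            "chrom": "2",
            "pos": 10_000 + 1_000 * np.arange(config.n_pool_snps),
            "allele": rng.choice(_BASES, size=config.n_pool_snps),
        }
    )
    for k, pop in enumerate(config.labels):
        pool[pop] = raf[k]
    return pool


def linear_link_for_r(
    grs_values: Sequence[float],
    target_r: float,
    noise_sd: float,
    mean_prevalence: float,
) -> tuple[float, float, float]:
    """Slope/intercept planting an expected score-prevalence correlation.

    With slope s and noise sd sigma, the population correlation is
    s*sd(g)/sqrt(s^2 var(g) + sigma^2); solving for s gives
    s = sigma * r/sqrt(1-r^2) / sd(g).  The intercept centres prevalence at
    ``mean_prevalence`` for the mean score.
    """
    if not -1.0 < target_r < 1.0:
        raise ValidationError("target correlation must lie strictly inside (-1, 1)")
    g = np.asarray(grs_values, dtype=float)
    sd_g = g.std()
    if sd_g == 0:
        raise ValidationError("cannot plant a correlation on constant scores")
    slope = noise_sd * target_r / math.sqrt(1.0 - target_r**2) / sd_g
    intercept = mean_prevalence - slope * g.mean()
    return float(intercept), float(slope), float(noise_sd)


def simulate_prevalence_studies(
    population_grs: Mapping[str, float],
    config: SimulationConfig,
    age_reference: AgeReference | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[PrevalenceStudy], dict[str, float]]:
    """Literature-style studies whose observed prevalence the pipeline can
    invert back to a planted truth.

    True prevalence per population is clamp(intercept + slope*GRS + noise,
    [0, 1]).  Each population gets 1-3 studies; a study observes the truth
    through the relative-contribution factor of its random age window (full
    range, missing, or a restricted window) and binomial sampling at its
    sample size.  Optionally appends ineligible decoy studies (small sample,
    single sex) to exercise the filters.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ref = age_reference if age_reference is not None else default_age_reference()
    link = config.prevalence_link
    if link is None:
        link = linear_link_for_r(
            list(population_grs.values()),
            config.link_target_r,
            config.link_noise_sd,
            config.link_mean_prevalence,
        )
    intercept, slope, noise_sd = link
    truth: dict[str, float] = {}
    studies: list[PrevalenceStudy] = []
    counter = 0
    for pop, grs in population_grs.items():
        true_prev = float(np.clip(intercept + slope * grs + rng.normal(0.0, noise_sd), 0.0, 1.0))
        truth[pop] = true_prev
        for _ in range(int(rng.integers(1, 4))):
            counter += 1
            u = rng.random()
            if u < 0.2:
                age_min, age_max = math.nan, math.nan
                r = 1.0
            elif u < 0.4:
                age_min, age_max = ref.span
                r = 1.0
            else:
                age_min = float(rng.choice([20.0, 30.0, 40.0, 50.0]))
                age_max = float(rng.choice([70.0, 80.0, 90.0]))
                r = relative_contribution(ref, age_min, age_max)
            n = int(rng.integers(300, 5000))
            expected = float(np.clip(true_prev * r, 0.0, 1.0))
            observed = rng.binomial(n, expected) / n
            studies.append(
                PrevalenceStudy(
                    study_id=f"study{counter:03d}",
                    population_key=pop,
                    prevalence=observed,
                    sample_size=n,
                    age_min=age_min,
                    age_max=age_max,
                )
            )
    if config.include_ineligible and studies:
        first_pop = next(iter(population_grs))
        studies.append(
            PrevalenceStudy(
                study_id="decoy_small", population_key=first_pop,
                prevalence=0.5, sample_size=50,
            )
        )
        studies.append(
            PrevalenceStudy(
                study_id="decoy_male", population_key=first_pop,
                prevalence=0.3, sample_size=1000, sexes="male",
            )
        )
    return studies, truth


def studies_to_frame(studies: Sequence[PrevalenceStudy]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "population_key": [s.population_key for s in studies],
            "prevalence": [s.prevalence for s in studies],
            "sample_size": [s.sample_size for s in studies],
            "age_min": [s.age_min for s in studies],
            "age_max": [s.age_max for s in studies],
            "sexes": [s.sexes for s in studies],
            "comorbid": [s.comorbid for s in studies],
            "general_population": [s.general_population for s in studies],
        }
    )


@dataclass
class SyntheticBundle:
    """Paths to a complete generated input set, plus the planted truths."""

    variants: Path
    vcf: Path
    panel: Path
    pool: Path
    studies: Path
    age_reference: Path
    true_frequencies: pd.DataFrame
    true_prevalence: dict[str, float]
    true_grs: dict[str, float]
    reference_population: str


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> SyntheticBundle:
    """Generate and write every pipeline input into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    table, sim = simulate_risk_variants(config, rng)
    variants_path = outdir / "variants.tsv"
    table.to_frame().to_csv(variants_path, sep="\t", index=False)

    vcf_path = outdir / "genotypes.vcf"
    panel_path = outdir / "panel.tsv"
    simulate_panel(
        sim.raf, table, config.samples_per_population, rng,
        vcf_path=vcf_path, panel_path=panel_path,
    )

    pool_path = outdir / "pool.tsv"
    simulate_candidate_pool(config, table, rng).to_csv(pool_path, sep="\t", index=False)

    ref = default_age_reference()
    age_path = outdir / "age_reference.tsv"
    write_age_reference(ref, age_path)

    true_grs = {
        pop: float(2.0 * sim.raf.loc[pop, table.rsids].to_numpy(float).sum() / table.n)
        for pop in config.labels
    }
    # prevalence studies are keyed at the analysis-population level: merged
    # populations share one literature prevalence, linked to their
    # sample-size-weighted (here equal-size) mean score
    analysis_grs = dict(true_grs)
    if config.grouping:
        for group, members in config.grouping.items():
            analysis_grs[group] = float(np.mean([analysis_grs.pop(m) for m in members]))
    studies, truth = simulate_prevalence_studies(analysis_grs, config, ref, rng)
    studies_path = outdir / "studies.tsv"
    studies_to_frame(studies).to_csv(studies_path, sep="\t", index=False)
    return SyntheticBundle(
        variants=variants_path,
        vcf=vcf_path,
        panel=panel_path,
        pool=pool_path,
        studies=studies_path,
        age_reference=age_path,
        true_frequencies=sim.raf,
        true_prevalence=truth,
        true_grs=true_grs,
        reference_population=config.reference_population,
    )
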