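"""End-to-end orchestration: files in, statistical result bundle out.

Stages: read inputs -> per-population risk-allele frequencies -> population
scores (with optional merging of populations that share a single literature
prevalence) -> filtered/age-adjusted/pooled prevalences -> matched null
collection -> score-prevalence correlation with empirical p -> pairwise and
global Fst with percentile significance -> run manifest.

Population merging applies to scores and prevalence only; Fst comparisons
stay at the panel-population level, since differentiation is a property of
the genotyped populations themselves.

The set-mean Fst of the matched random SNP sets is computed from the pool's
allele frequencies with Hardy-Weinberg expected heterozygosity, since the
pool carries frequencies rather than genotypes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationResult, correlate_with_null
from .fst import (
    empirical_fst_test,
    panel_site_counts,
    pairwise_theta_per_site,
    wc_components,
)
from .grs import group_score_matrix, group_scores, population_scores
from .matched_null import (
    DEFAULT_N_SETS,
    DEFAULT_TOLERANCE,
    NullSetCollection,
    build_candidate_pool,
    generate_null_collection,
)
from .prevalence import population_prevalences, read_age_reference, read_studies_tsv
from .risk_variants import (
    ValidationError,
    population_raf,
    read_genotype_panel,
    read_variant_table,
)

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    variants: Path
    vcf: Path
    panel: Path
    pool: Path
    studies: Path
    age_reference: Path
    outdir: Path
    reference_population: str = "GBR"
    grouping: Mapping[str, Sequence[str]] = field(default_factory=dict)
    n_sets: int = DEFAULT_N_SETS
    tolerance: float = DEFAULT_TOLERANCE
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("variants", "vcf", "panel", "pool", "studies", "age_reference"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise ValidationError(f"input file for {name!r} does not exist: {p}")
        self.outdir = Path(self.outdir)
        members = [m for v in self.grouping.values() for m in v]
        if len(members) != len(set(members)):
            raise ValidationError("grouping map assigns a population to more than one group")

    def echo(self) -> dict:
        return {
            "variants": str(self.variants),
            "vcf": str(self.vcf),
            "panel": str(self.panel),
            "pool": str(self.pool),
            "studies": str(self.studies),
            "age_reference": str(self.age_reference),
            "outdir": str(self.outdir),
            "reference_population": self.reference_population,
            "grouping": {k: list(v) for k, v in self.grouping.items()},
            "n_sets": self.n_sets,
            "tolerance": self.tolerance,
            "seed": self.seed,
        }


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a flat ``key = value`` config file.

    Grouping entries use ``group.<name> = POP1,POP2``; keyword overrides win
    over file values.
    """
    values: dict = {}
    grouping: dict[str, list[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("group."):
            grouping[key[len("group."):]] = [p.strip() for p in value.split(",") if p.strip()]
        else:
            values[key] = value
    kwargs: dict = {"grouping": grouping}
    for key in ("variants", "vcf", "panel", "pool", "studies", "age_reference", "outdir"):
        if key in values:
            kwargs[key] = Path(values.pop(key))
    if "reference_population" in values:
        kwargs["reference_population"] = values.pop("reference_population")
    if "n_sets" in values:
        kwargs["n_sets"] = int(values.pop("n_sets"))
    if "tolerance" in values:
        kwargs["tolerance"] = float(values.pop("tolerance"))
    if "seed" in values:
        kwargs["seed"] = int(values.pop("seed"))
    if values:
        raise ValidationError(f"{path}: unknown config keys {sorted(values)}")
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@dataclass
class RunResult:
    raf: pd.DataFrame
    scores: pd.DataFrame
    grouped_scores: pd.DataFrame
    prevalence: pd.DataFrame
    association: AssociationResult
    fst_summary: pd.DataFrame
    fst_global: pd.DataFrame
    null_collection: NullSetCollection
    outdir: Path


def _null_mean_fst_by_population(
    collection: NullSetCollection,
    sample_sizes: Mapping[str, int],
    reference: str,
    populations: Sequence[str],
    seed: int | None,
) -> dict[str, np.ndarray]:
    """Per-population arrays (n_sets,) of set-mean pairwise Fst vs the
    reference for every null set.

    The pool carries allele frequencies, not genotypes, so genotype counts
    are drawn parametrically (Hardy-Weinberg at each population's panel
    sample size) before estimation.  This gives the null estimates the same
    finite-sample noise and bias as the observed panel estimates; using the
    frequencies directly would misplace the null near zero differentiation.
    """
    rng = np.random.default_rng(None if seed is None else [seed, 1])
    pops = [reference] + [p for p in populations if p != reference]
    p_freq = collection.pool.pop_raf[pops].to_numpy(float)  # pool_size x pops
    n_sites = p_freq.shape[0]
    n = np.array([sample_sizes[q] for q in pops], dtype=float)
    p_hat = np.empty_like(p_freq)
    h_hat = np.empty_like(p_freq)
    for k, pop in enumerate(pops):
        pk = p_freq[:, k]
        probs = np.stack([(1 - pk) ** 2, 2 * pk * (1 - pk), pk**2], axis=-1)
        counts = rng.multinomial(int(n[k]), probs)  # sites x 3 genotype classes
        p_hat[:, k] = (counts[:, 1] + 2 * counts[:, 2]) / (2.0 * n[k])
        h_hat[:, k] = counts[:, 1] / n[k]
    out: dict[str, np.ndarray] = {}
    for j, pop in enumerate(pops[1:], start=1):
        theta = pairwise_theta_per_site(
            np.broadcast_to(n[[0, j]], (n_sites, 2)).copy(),
            p_hat[:, [0, j]],
            h_hat[:, [0, j]],
            0,
            1,
        )
        out[pop] = np.nanmean(theta[collection.sets], axis=1)
    return out


def run_full_analysis(config: RunConfig) -> RunResult:
    """Run every stage and write the result bundle under ``config.outdir``."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    # --- genotypes and frequencies ------------------------------------------------
    try:
        table = read_variant_table(config.variants)
        panel = read_genotype_panel(config.vcf, config.panel, table)
        freqs = population_raf(panel, table)
        if config.reference_population not in freqs.populations:
            raise ValidationError(
                f"reference population {config.reference_population!r} not in panel"
            )
        freqs.write(outdir / "population_raf.tsv")
        sizes = panel.population_sizes()
        log.info("frequencies: %d variants x %d populations", table.n, len(freqs.populations))
    except Exception as e:  # noqa: BLE001 - stage labelling
        raise PipelineStageError("frequencies", e) from e

    # --- population scores --------------------------------------------------------
    try:
        scores = population_scores(freqs, table, sample_sizes=sizes)
        scores["super_population"] = [
            panel.super_populations.get(p, "") for p in scores["population"]
        ]
        scores.to_csv(outdir / "grs.tsv", sep="\t", index=False)
        grouped = group_scores(scores[["population", "n_samples", "grs", "wgrs"]], config.grouping)
        grouped.to_csv(outdir / "grs_grouped.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineStageError("grs", e) from e

    # --- prevalence ---------------------------------------------------------------
    try:
        studies = read_studies_tsv(config.studies)
        ref_curve = read_age_reference(config.age_reference)
        prev_table, excluded = population_prevalences(studies, ref_curve)
        for study, reason in excluded:
            log.info("excluded study %s (%s): %s", study.study_id, study.population_key, reason)
        log.info("prevalence: %d studies kept, %d excluded", sum(prev_table["n_studies"]), len(excluded))
        prev_table.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineStageError("prevalence", e) from e

    # --- matched null -------------------------------------------------------------
    try:
        pool_df = pd.read_csv(config.pool, sep="\t", dtype={"rsid": str, "chrom": str})
        ref_raf = freqs.raf.loc[config.reference_population]
        # matching targets use the risk-allele frequency observed in the panel
        # reference population unless the table supplies reference_raf itself
        if np.isnan(table.reference_raf).any():
            from .risk_variants import RiskVariant, RiskVariantTable

            table = RiskVariantTable(
                [
                    RiskVariant(
                        rsid=v.rsid, chrom=v.chrom, pos=v.pos,
                        risk_allele=v.risk_allele, other_allele=v.other_allele,
                        odds_ratio=v.odds_ratio,
                        reference_raf=float(ref_raf[v.rsid]),
                    )
                    for v in table
                ]
            )
        pool = build_candidate_pool(pool_df, config.reference_population, exclude=table)
        collection = generate_null_collection(
            pool, table, n_sets=config.n_sets, tolerance=config.tolerance, seed=config.seed
        )
        collection.to_frame().to_csv(outdir / "null_sets.tsv", sep="\t", index=False)
        collection.grs.to_csv(outdir / "null_grs.tsv", sep="\t", index_label="set_index")
    except Exception as e:
        raise PipelineStageError("null", e) from e

    # --- association --------------------------------------------------------------
    try:
        grouped_idx = grouped.set_index("population")
        prev_idx = prev_table.set_index("population")
        common = [p for p in prev_idx.index if p in grouped_idx.index]
        missing = [p for p in prev_idx.index if p not in grouped_idx.index]
        if missing:
            raise ValidationError(
                f"prevalence populations without scores: {missing} "
                "(check the grouping map)"
            )
        null_grouped = group_score_matrix(collection.grs, config.grouping, sizes)
        association = correlate_with_null(
            grouped_idx.loc[common, "grs"].to_dict(),
            prev_idx.loc[common, "pooled_prevalence"].to_dict(),
            null_grouped[common],
        )
        (outdir / "association.json").write_text(json.dumps(association.to_dict(), indent=2))
    except Exception as e:
        raise PipelineStageError("association", e) from e

    # --- Fst ----------------------------------------------------------------------
    try:
        pops, n, p, h = panel_site_counts(panel, table)
        ref_idx = pops.index(config.reference_population)
        null_fst = _null_mean_fst_by_population(
            collection, sizes, config.reference_population, pops, config.seed
        )
        rows = []
        per_site_rows = []
        for j, pop in enumerate(pops):
            if j == ref_idx:
                continue
            theta = pairwise_theta_per_site(n, p, h, ref_idx, j)
            defined = ~np.isnan(theta)
            if not defined.any():
                raise ValidationError(
                    f"no defined Fst site for {config.reference_population} vs {pop}"
                )
            mean_fst = float(theta[defined].mean())
            a, b, c = wc_components(n[:, [ref_idx, j]], p[:, [ref_idx, j]], h[:, [ref_idx, j]])
            weighted = float(a.sum() / (a + b + c).sum())
            label, bounds = empirical_fst_test(mean_fst, null_fst[pop])
            rows.append(
                {
                    "population": pop,
                    "mean_fst": mean_fst,
                    "weighted_fst": weighted,
                    "n_sites_used": int(defined.sum()),
                    "null_2.5": bounds[0],
                    "null_97.5": bounds[1],
                    "significance": label,
                }
            )
            for rsid, t in zip(table.rsids, theta):
                per_site_rows.append(
                    {
                        "rsid": rsid,
                        "pair": f"{config.reference_population}-{pop}",
                        "theta": t,
                    }
                )
        fst_summary = pd.DataFrame(rows)
        fst_summary.to_csv(outdir / "fst_summary.tsv", sep="\t", index=False)
        pd.DataFrame(per_site_rows).to_csv(outdir / "fst_per_site.tsv", sep="\t", index=False)

        a, b, c = wc_components(n, p, h)
        den = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            theta_global = np.where(den != 0.0, a / den, np.nan)
        fst_global = pd.DataFrame({"rsid": table.rsids, "global_fst": theta_global})
        fst_global.to_csv(outdir / "fst_global.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineStageError("fst", e) from e

    # --- manifest -----------------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "n_variants": table.n,
        "n_populations": len(pops),
        "n_null_sets": collection.n_sets,
        "n_studies_excluded": len(excluded),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(
        raf=freqs.to_frame(),
        scores=scores,
        grouped_scores=grouped,
        prevalence=prev_table,
        association=association,
        fst_summary=fst_summary,
        fst_global=fst_global,
        null_collection=collection,
        outdir=outdir,
    )
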