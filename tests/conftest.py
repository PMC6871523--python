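import numpy as np
import pytest

from ddgrs.pipeline import RunConfig, run_full_analysis
from ddgrs.synthetic_data import SimulationConfig, simulate_bundle

GROUPING = {"GRP": ["POP05", "POP06"]}


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study conditions for fast end-to-end runs."""
    return SimulationConfig(
        n_populations=6,
        samples_per_population=40,
        n_risk_variants=10,
        n_pool_snps=600,
        differentiation=(0.0, 0.005, 0.02, 0.05, 0.1, 0.15),
        grouping=GROUPING,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    return simulate_bundle(small_config, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    config = RunConfig(
        variants=small_bundle.variants,
        vcf=small_bundle.vcf,
        panel=small_bundle.panel,
        pool=small_bundle.pool,
        studies=small_bundle.studies,
        age_reference=small_bundle.age_reference,
        outdir=tmp_path_factory.mktemp("run"),
        reference_population=small_bundle.reference_population,
        grouping=GROUPING,
        n_sets=200,
        seed=3,
    )
    return config, run_full_analysis(config)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def variant_tsv(tmp_path):
    """Writer for small risk-variant tables."""

    def _write(rows, header=("rsid", "chrom", "pos", "risk_allele", "other_allele", "odds_ratio")):
        return write_tsv(tmp_path / "variants.tsv", header, rows)

    return _write


@pytest.fixture
def toy_vcf(tmp_path):
    """Writer for small hand-specified VCFs."""

    def _write(samples, records, name="toy.vcf"):
        path = tmp_path / name
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        ]
        for chrom, pos, rsid, ref, alt, gts in records:
            lines.append(
                f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def panel_tsv(tmp_path):
    def _write(assignments, name="panel.tsv"):
        rows = [(s, p, sp) for s, p, sp in assignments]
        return write_tsv(tmp_path / name, ("sample", "pop", "super_pop"), rows)

    return _write


def rng(seed=0):
    return np.random.default_rng(seed)
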