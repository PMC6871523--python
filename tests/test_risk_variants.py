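"""Risk-variant table reading, dosage orientation, and population frequencies."""

import math

import numpy as np
import pytest

from ddgrs.risk_variants import (
    AlleleMismatchError,
    GenotypePanel,
    RiskVariant,
    RiskVariantTable,
    ValidationError,
    pool_frequencies,
    population_raf,
    read_genotype_panel,
    read_variant_table,
)
from ddgrs.synthetic_data import SimulationConfig, simulate_frequencies, simulate_panel, write_vcf


def make_table(n=3, seed=0):
    rng = np.random.default_rng(seed)
    variants = []
    for i in range(n):
        risk, other = rng.choice(list("ACGT"), size=2, replace=False)
        variants.append(
            RiskVariant(f"rs{i+1}", "1", 1000 + i * 100, str(risk), str(other), float(rng.uniform(1.1, 2.0)))
        )
    return RiskVariantTable(variants)


class TestVariantTable:
    @pytest.mark.parametrize(
        "odds_ratio,expected_weight",
        [(1.0, 0.0), (math.e, 1.0), (2.0, math.log(2.0))],
    )
    def test_weight_is_natural_log_of_odds_ratio(self, variant_tsv, odds_ratio, expected_weight):
        path = variant_tsv([("rs1", "1", 100, "A", "G", odds_ratio)])
        table = read_variant_table(path)
        assert table.variants[0].weight == pytest.approx(expected_weight, abs=1e-12)

    def test_reads_26_rows_preserving_order(self, variant_tsv):
        rows = [(f"rs{i}", "1", 100 + i, "A", "G", 1.2) for i in range(26)]
        table = read_variant_table(variant_tsv(rows))
        assert table.n == 26
        assert table.rsids == [f"rs{i}" for i in range(26)]

    @pytest.mark.parametrize(
        "rows",
        [
            [("rs1", "1", 100, "A", "G", 1.2), ("rs1", "1", 200, "C", "T", 1.3)],  # dup rsid
            [("rs1", "1", 100, "A", "G", -0.5)],  # non-positive OR
            [("rs1", "1", 100, "A", "G", 0.0)],
            [("rs1", "1", 100, "N", "G", 1.2)],  # malformed allele
            [("rs1", "1", 100, "A", "A", 1.2)],  # identical alleles
        ],
    )
    def test_invalid_rows_rejected(self, variant_tsv, rows):
        with pytest.raises(ValidationError):
            read_variant_table(variant_tsv(rows))


class TestGenotypeReading:
    def test_toy_vcf_dosages_hand_enumerated(self, variant_tsv, toy_vcf, panel_tsv):
        # rs2 is written in swapped orientation (REF is the risk allele)
        table = read_variant_table(
            variant_tsv(
                [
                    ("rs1", "1", 100, "A", "G", 1.2),
                    ("rs2", "1", 200, "C", "T", 1.3),
                    ("rs3", "1", 300, "T", "A", 1.4),
                ]
            )
        )
        vcf = toy_vcf(
            ["S1", "S2"],
            [
                ("1", 100, "rs1", "G", "A", ["1/1", "0/1"]),
                ("1", 200, "rs2", "C", "T", ["0/1", "1/1"]),
                ("1", 300, "rs3", "A", "T", ["0/0", "./."]),
            ],
        )
        panel = panel_tsv([("S1", "POP1", "SP1"), ("S2", "POP2", "SP1")])
        gp = read_genotype_panel(vcf, panel, table)
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 0.0, np.nan]])
        np.testing.assert_array_equal(gp.dosage, expected)

    def test_allele_mismatch_names_rsid(self, variant_tsv, toy_vcf, panel_tsv):
        table = read_variant_table(variant_tsv([("rs9", "1", 100, "A", "G", 1.2)]))
        vcf = toy_vcf(["S1"], [("1", 100, "rs9", "C", "G", ["0/1"])])
        panel = panel_tsv([("S1", "POP1", "SP1")])
        with pytest.raises(AlleleMismatchError, match="rs9"):
            read_genotype_panel(vcf, panel, table)

    def test_multiallelic_record_rejected(self, variant_tsv, toy_vcf, panel_tsv):
        table = read_variant_table(variant_tsv([("rs9", "1", 100, "A", "G", 1.2)]))
        vcf = toy_vcf(["S1"], [("1", 100, "rs9", "G", "A,T", ["0/1"])])
        panel = panel_tsv([("S1", "POP1", "SP1")])
        with pytest.raises(ValidationError, match="multiallelic"):
            read_genotype_panel(vcf, panel, table)

    def test_vcf_sample_missing_from_panel(self, variant_tsv, toy_vcf, panel_tsv):
        table = read_variant_table(variant_tsv([("rs1", "1", 100, "A", "G", 1.2)]))
        vcf = toy_vcf(["S1", "S2"], [("1", 100, "rs1", "G", "A", ["0/0", "0/1"])])
        panel = panel_tsv([("S1", "POP1", "SP1")])
        with pytest.raises(ValidationError, match="S2"):
            read_genotype_panel(vcf, panel, table)

    def test_absent_record_yields_missing_with_warning(self, variant_tsv, toy_vcf, panel_tsv, caplog):
        table = read_variant_table(
            variant_tsv([("rs1", "1", 100, "A", "G", 1.2), ("rs2", "1", 200, "C", "T", 1.3)])
        )
        vcf = toy_vcf(["S1"], [("1", 100, "rs1", "G", "A", ["0/1"])])
        panel = panel_tsv([("S1", "POP1", "SP1")])
        with caplog.at_level("WARNING"):
            gp = read_genotype_panel(vcf, panel, table)
        assert np.isnan(gp.dosage[0, 1])
        assert any("rs2" in rec.message for rec in caplog.records)

    def test_complement_rule_round_trip(self, tmp_path, panel_tsv):
        """Flipping REF/ALT orientation of every record leaves dosages unchanged."""
        config = SimulationConfig(
            n_populations=2, samples_per_population=8, n_risk_variants=5,
            n_pool_snps=250, differentiation=0.05, seed=5,
        )
        rng = np.random.default_rng(5)
        from ddgrs.synthetic_data import simulate_risk_variants

        table, sim = simulate_risk_variants(config, rng)
        panel = simulate_panel(sim.raf, table, 8, rng)
        panel_path = panel_tsv(
            [(s, panel.populations[s], "SP1") for s in panel.samples], name="rt_panel.tsv"
        )
        n = table.n
        paths = []
        for name, swap in (("fwd.vcf", np.zeros(n, bool)), ("rev.vcf", np.ones(n, bool))):
            path = tmp_path / name
            write_vcf(panel, table, path, swap_orientation=swap)
            paths.append(path)
        fwd = read_genotype_panel(paths[0], panel_path, table)
        rev = read_genotype_panel(paths[1], panel_path, table)
        np.testing.assert_array_equal(fwd.dosage, rev.dosage)
        np.testing.assert_array_equal(fwd.dosage, panel.dosage)


class TestPopulationFrequencies:
    def make_panel(self, dosage, pops):
        samples = [f"S{i}" for i in range(len(pops))]
        return GenotypePanel(
            samples=samples,
            populations=dict(zip(samples, pops)),
            super_populations={p: "SP1" for p in pops},
            dosage=np.asarray(dosage, dtype=float),
            rsids=[f"rs{j}" for j in range(np.asarray(dosage).shape[1])],
        )

    def test_simple_counts(self):
        table = RiskVariantTable(
            [RiskVariant("rs0", "1", 100, "A", "G", 1.2), RiskVariant("rs1", "1", 200, "C", "T", 1.2)]
        )
        panel = self.make_panel([[2, 1], [2, 0]], ["P1", "P1"])
        freqs = population_raf(panel, table)
        assert freqs.raf.loc["P1", "rs0"] == pytest.approx(1.0)
        assert freqs.raf.loc["P1", "rs1"] == pytest.approx(0.25)
        assert freqs.called.loc["P1", "rs0"] == 4

    def test_matches_brute_force_with_missing_data(self):
        rng = np.random.default_rng(42)
        n_samples, n_variants = 30, 4
        dosage = rng.integers(0, 3, size=(n_samples, n_variants)).astype(float)
        dosage[rng.random(dosage.shape) < 0.15] = np.nan
        pops = [f"P{i % 3}" for i in range(n_samples)]
        table = RiskVariantTable(
            [RiskVariant(f"rs{j}", "1", 100 + j, "A", "G", 1.2) for j in range(n_variants)]
        )
        freqs = population_raf(self.make_panel(dosage, pops), table)
        for pop in set(pops):
            rows = [i for i, p in enumerate(pops) if p == pop]
            for j in range(n_variants):
                vals = [dosage[i, j] for i in rows if not np.isnan(dosage[i, j])]
                expected = sum(vals) / (2 * len(vals))
                assert freqs.raf.loc[pop, f"rs{j}"] == pytest.approx(expected)
                # frequency equals mean dosage over called samples divided by 2
                assert freqs.raf.loc[pop, f"rs{j}"] == pytest.approx(np.mean(vals) / 2)

    def test_pooled_frequency_is_count_weighted_mean(self):
        rng = np.random.default_rng(7)
        dosage = rng.integers(0, 3, size=(40, 3)).astype(float)
        pops = [f"P{i % 4}" for i in range(40)]
        table = RiskVariantTable(
            [RiskVariant(f"rs{j}", "1", 100 + j, "A", "G", 1.2) for j in range(3)]
        )
        panel = self.make_panel(dosage, pops)
        freqs = population_raf(panel, table)
        pooled = pool_frequencies(freqs, {"ALL": sorted(set(pops))})
        # oracle: recount over the union of samples
        for j in range(3):
            expected = dosage[:, j].sum() / (2 * len(pops))
            assert pooled.raf.loc["ALL", f"rs{j}"] == pytest.approx(expected)
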