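"""Weir-Cockerham theta: component formulas, set summaries, percentile test."""

import numpy as np
import pytest

from ddgrs.fst import (
    NOT_SIGNIFICANT,
    SIGNIFICANT_HIGH,
    SIGNIFICANT_LOW,
    SiteCounts,
    empirical_fst_test,
    global_site_fst,
    hwe_heterozygosity,
    pairwise_mean_fst,
    wc_components,
    wc_site_fst,
)
from ddgrs.risk_variants import ValidationError
from ddgrs.synthetic_data import balding_nichols


def naive_wc(n, p, h):
    """Independent transliteration of the variance-component formulas,
    written as plain loops; serves as the arithmetic oracle for the
    vectorised implementation."""
    r = len(n)
    nbar = sum(n) / r
    nsum = sum(n)
    nc = (nsum - sum(ni * ni for ni in n) / nsum) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / nsum
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / nsum
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestSiteTheta:
    def test_complete_fixation_gives_theta_one(self):
        counts = SiteCounts(n=[10, 10], p=[1.0, 0.0], h=[0.0, 0.0])
        assert wc_site_fst(counts).theta == pytest.approx(1.0)

    def test_shared_monomorphism_is_undefined(self):
        est = wc_site_fst(SiteCounts(n=[10, 10], p=[1.0, 1.0], h=[0.0, 0.0]))
        assert est.denominator == 0.0
        assert np.isnan(est.theta)

    def test_hand_worked_two_population_example(self):
        # pop1: 4 diploids, genotype counts 2/1/1 -> p = 5/8, h = 1/4
        # pop2: 4 diploids, genotype counts 0/2/2 -> p = 1/4, h = 1/2
        # hand evaluation of the components: a = 0.03125, b = 0.0625, c = 0.1875
        counts = SiteCounts(n=[4, 4], p=[5 / 8, 1 / 4], h=[1 / 4, 1 / 2])
        est = wc_site_fst(counts)
        a, b, c = wc_components(counts.n, counts.p, counts.h)
        assert a == pytest.approx(0.03125, abs=1e-12)
        assert b == pytest.approx(0.0625, abs=1e-12)
        assert c == pytest.approx(0.1875, abs=1e-12)
        assert est.theta == pytest.approx(1 / 9, abs=1e-12)

    def test_identical_populations_give_nonpositive_theta(self):
        est = wc_site_fst(SiteCounts(n=[20, 20], p=[0.4, 0.4], h=[0.48, 0.48]))
        assert est.theta <= 0.0

    def test_two_populations_global_equals_pairwise(self):
        counts = SiteCounts(n=[12, 30], p=[0.3, 0.7], h=[0.4, 0.4])
        assert global_site_fst(counts).theta == wc_site_fst(counts).theta

    def test_single_population_rejected(self):
        with pytest.raises(ValidationError):
            wc_site_fst(SiteCounts(n=[10], p=[0.5], h=[0.5]))

    def test_matches_naive_transliteration_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            r = int(rng.integers(2, 6))
            n = rng.integers(2, 51, size=r).astype(float)
            p = rng.uniform(0, 1, size=r)
            h = rng.uniform(0, 1, size=r) * 2 * np.minimum(p, 1 - p)
            a, b, c = wc_components(n, p, h)
            a0, b0, c0 = naive_wc(list(n), list(p), list(h))
            assert a == pytest.approx(a0, rel=1e-10, abs=1e-12)
            assert b == pytest.approx(b0, rel=1e-10, abs=1e-12)
            assert c == pytest.approx(c0, rel=1e-10, abs=1e-12)


class TestSetSummaries:
    def test_single_site_identity(self):
        sites = [SiteCounts(n=[10, 10], p=[0.9, 0.1], h=[0.1, 0.1])]
        summary = pairwise_mean_fst(sites)
        assert summary.mean_fst == pytest.approx(wc_site_fst(sites[0]).theta)

    def test_mean_of_two_sites(self):
        s1 = SiteCounts(n=[10, 10], p=[1.0, 0.0], h=[0.0, 0.0])  # theta = 1
        s2 = SiteCounts(n=[4, 4], p=[5 / 8, 1 / 4], h=[1 / 4, 1 / 2])  # theta = 1/9
        summary = pairwise_mean_fst([s1, s2])
        assert summary.mean_fst == pytest.approx((1.0 + 1 / 9) / 2)

    def test_mean_matches_loop_oracle_and_skips_undefined(self):
        rng = np.random.default_rng(1)
        sites = []
        for _ in range(26):
            p = rng.uniform(0, 1, size=2)
            h = rng.uniform(0, 1, size=2) * 2 * np.minimum(p, 1 - p)
            sites.append(SiteCounts(n=[15, 20], p=p, h=h))
        sites.append(SiteCounts(n=[15, 20], p=[0.0, 0.0], h=[0.0, 0.0]))  # undefined
        thetas = [wc_site_fst(s).theta for s in sites[:-1]]
        summary = pairwise_mean_fst(sites)
        assert summary.n_sites_used == 26
        assert summary.mean_fst == pytest.approx(sum(thetas) / len(thetas))
        assert min(thetas) <= summary.mean_fst <= max(thetas)

    def test_negative_estimates_are_preserved(self):
        # nearly identical small samples: finite-sample theta goes negative
        sites = [SiteCounts(n=[8, 8], p=[0.5, 0.5], h=[0.75, 0.75])]
        summary = pairwise_mean_fst(sites)
        assert summary.mean_fst < 0.0

    def test_permutation_of_labels_removes_differentiation(self):
        """Shuffling individuals across populations drives theta to ~0."""
        rng = np.random.default_rng(2)
        n_per = 50
        g1 = rng.binomial(2, 0.9, size=n_per)
        g2 = rng.binomial(2, 0.2, size=n_per)
        pooled = np.concatenate([g1, g2])

        def theta_of(split):
            a, b = split[:n_per], split[n_per:]
            counts = SiteCounts(
                n=[n_per, n_per],
                p=[a.mean() / 2, b.mean() / 2],
                h=[(a == 1).mean(), (b == 1).mean()],
            )
            return wc_site_fst(counts).theta

        observed = theta_of(pooled)
        shuffled = []
        for _ in range(200):
            perm = rng.permutation(pooled)
            shuffled.append(theta_of(perm))
        assert observed > 0.3
        assert np.mean(shuffled) < 0.01


class TestEmpiricalPercentileTest:
    NULL = np.linspace(0.01, 0.10, 10)  # 0.01, 0.02, ..., 0.10

    def test_hand_interpolated_bounds(self):
        # linear interpolation on 10 order statistics:
        # 2.5th percentile = 0.01225, 97.5th = 0.09775
        _, (lo, hi) = empirical_fst_test(0.05, self.NULL)
        assert lo == pytest.approx(0.01225, abs=1e-12)
        assert hi == pytest.approx(0.09775, abs=1e-12)

    @pytest.mark.parametrize(
        "observed,expected",
        [
            (0.095, NOT_SIGNIFICANT),  # below the interpolated 97.5th (0.09775)
            (0.099, SIGNIFICANT_HIGH),
            (0.005, SIGNIFICANT_LOW),  # below the minimum of the null
            (0.055, NOT_SIGNIFICANT),  # at the null median
        ],
    )
    def test_classification(self, observed, expected):
        label, _ = empirical_fst_test(observed, self.NULL)
        assert label == expected

    def test_negative_null_values_handled(self):
        null = np.linspace(-0.0037, 0.0100, 100)
        label, (lo, hi) = empirical_fst_test(-0.01, null)
        assert lo < 0.0
        assert label == SIGNIFICANT_LOW

    def test_empty_null_is_an_error(self):
        with pytest.raises(ValidationError):
            empirical_fst_test(0.1, [])


class TestParameterRecovery:
    def test_two_population_weighted_fst_tracks_model_expectation(self):
        """Under the structure model with per-population parameter F, the
        large-sample two-population weighted Fst converges to F (checked by
        prior large-scale simulation); estimates at 2,000 sites should land
        within 20% relative error."""
        rng = np.random.default_rng(3)
        F = 0.1
        n = 100
        anc = rng.uniform(0.05, 0.95, size=2000)
        p_true = balding_nichols(anc, np.array([F, F]), rng)
        g = rng.binomial(
            1, p_true.T[:, :, None], (2000, 2, n)
        ) + rng.binomial(1, p_true.T[:, :, None], (2000, 2, n))
        p_hat = g.mean(axis=2) / 2
        h_hat = (g == 1).mean(axis=2)
        a, b, c = wc_components(np.full((2000, 2), float(n)), p_hat, h_hat)
        weighted = a.sum() / (a + b + c).sum()
        assert weighted == pytest.approx(F, rel=0.2)


def test_hwe_heterozygosity_is_2pq():
    p = np.array([0.0, 0.25, 0.5, 1.0])
    np.testing.assert_allclose(hwe_heterozygosity(p), [0.0, 0.375, 0.5, 0.0])
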