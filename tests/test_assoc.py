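"""Association scan, QC, genomic control, MDS, heterogeneity, power."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest, norm

from _oracles import hwe_enumeration_oracle

from archpipe.assoc import (
    QCConfig,
    genomic_control_lambda,
    heterogeneity_test,
    hwe_exact_p,
    logistic_lrt_scan,
    mds_components,
    power_trend,
    qc_filter,
)
from archpipe.cohort import MISSING, ArchitectureSpec, Cohort, simulate_cohort


class TestHWE:
    def test_monomorphic_convention(self):
        assert hwe_exact_p(100, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 55) == 1.0

    def test_excess_heterozygotes_small_p(self):
        assert hwe_exact_p(0, 200, 0) < 1e-10

    def test_matches_enumeration_oracle(self, rng):
        assert hwe_exact_p(57, 14, 50) == pytest.approx(
            hwe_enumeration_oracle(57, 14, 50), abs=1e-12
        )
        for _ in range(200):
            n = int(rng.integers(1, 500))
            n_AA = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_AA + 1))
            n_aa = n - n_AA - n_Aa
            assert hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
                hwe_enumeration_oracle(n_AA, n_Aa, n_aa), abs=1e-12
            )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)


class TestQCFilter:
    def test_no_exclusions_at_zero_thresholds(self, small_cohort):
        filtered, report = qc_filter(
            small_cohort, QCConfig(min_call_rate=0.0, min_maf=0.0, hwe_alpha=0.0)
        )
        assert filtered.n_snps == small_cohort.n_snps
        assert report["pass"].all()

    def test_planted_violations_caught(self, small_cohort):
        c = small_cohort.copy()
        g = c.genotypes.copy()
        rng = np.random.default_rng(0)
        # SNP 0: 6% missing; SNP 1: all heterozygous (gross HWE violation)
        miss = rng.choice(c.n_samples, int(0.06 * c.n_samples), replace=False)
        g[miss, 0] = MISSING
        g[:, 1] = 1
        c.genotypes = g
        _, report = qc_filter(c, QCConfig(min_call_rate=0.97, hwe_alpha=1e-6))
        assert "call_rate" in report.loc[0, "fails"]
        assert "hwe" in report.loc[1, "fails"]

    def test_idempotent(self, small_cohort):
        qc = QCConfig(min_call_rate=0.95, min_maf=0.05, hwe_alpha=1e-4)
        once, _ = qc_filter(small_cohort, qc)
        twice, rep = qc_filter(once, qc)
        assert twice.n_snps == once.n_snps
        assert rep["pass"].all()


class TestLogisticScan:
    def test_null_scan_p_uniform(self, null_cohort):
        scan = logistic_lrt_scan(null_cohort, ("sex", "age"))
        assert kstest(scan["p_lrt"], "uniform").pvalue > 0.01
        lam = genomic_control_lambda(scan["p_lrt"].to_numpy())
        assert lam == pytest.approx(1.0, abs=0.15)

    def test_matches_statsmodels_on_table_input(self):
        # 2x3 table: genotype counts for controls / cases
        counts = {(0, 0): 120, (0, 1): 60, (0, 2): 20, (1, 0): 40, (1, 1): 45, (1, 2): 25}
        y, g = [], []
        for (cls, dose), k in counts.items():
            y += [cls] * k
            g += [dose] * k
        y, g = np.array(y), np.array(g, dtype=np.int8)
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(y))], "status": y,
             "sex": 0, "age": 50.0, "platform": "v1", "ancestry": 0.0}
        )
        snps = pd.DataFrame(
            {"snp_id": ["rs1"], "chrom": ["1"], "pos": [100], "allele_major": ["A"],
             "allele_minor": ["G"], "maf": [0.3], "true_beta": [0.0]}
        )
        cohort = Cohort(samples=samples, genotypes=g[:, None], snps=snps)
        scan = logistic_lrt_scan(cohort, ())
        import statsmodels.api as sm

        fit = sm.Logit(y, sm.add_constant(g.astype(float))).fit(disp=0)
        assert scan.loc[0, "beta"] == pytest.approx(fit.params[1], abs=1e-6)
        lrt_p = chi2.sf(2 * (fit.llf - sm.Logit(y, np.ones_like(y, dtype=float)).fit(disp=0).llf), 1)
        assert scan.loc[0, "p_lrt"] == pytest.approx(lrt_p, rel=1e-4)

    def test_planted_causal_snp_detected(self):
        # one SNP carries all the genetic variance: it must clear Bonferroni
        spec = ArchitectureSpec(
            m=50, m_causal=1, h2_l=0.3, K=0.1, maf_dist=("uniform", 0.2, 0.5), seed=99
        )
        c = simulate_cohort(spec, 250, 500)
        scan = logistic_lrt_scan(c, ("sex", "age"))
        beta_true = c.snps["true_beta"].to_numpy()
        j = int(np.argmax(np.abs(beta_true)))
        row = scan.iloc[j]
        assert row["p_lrt"] < 0.05 / c.n_snps
        # OR direction matches the true minor-allele effect
        assert np.sign(np.log(row["or"])) == np.sign(beta_true[j])

    def test_missing_genotypes_drop_samples(self, small_cohort):
        c = small_cohort.copy()
        g = c.genotypes.copy()
        g[:25, 0] = MISSING
        c.genotypes = g
        scan = logistic_lrt_scan(c, ())
        assert scan.loc[0, "n_used"] == c.n_samples - 25

    def test_separation_flagged_with_firth_fallback(self):
        rng = np.random.default_rng(3)
        n = 200
        g = np.zeros(n, dtype=np.int8)
        y = rng.integers(0, 2, n)
        carriers = np.flatnonzero(y == 1)[:6]
        g[carriers] = 1  # minor allele appears only in cases: separation
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "status": y, "sex": 0,
             "age": 50.0, "platform": "v1", "ancestry": 0.0}
        )
        snps = pd.DataFrame(
            {"snp_id": ["rs1"], "chrom": ["1"], "pos": [1], "allele_major": ["A"],
             "allele_minor": ["G"], "maf": [0.015], "true_beta": [0.0]}
        )
        scan = logistic_lrt_scan(Cohort(samples=samples, genotypes=g[:, None], snps=snps), ())
        assert bool(scan.loc[0, "firth"])
        assert np.isfinite(scan.loc[0, "beta"]) and abs(scan.loc[0, "beta"]) < 15


class TestGenomicControl:
    def test_uniform_p_near_one(self, rng):
        p = rng.uniform(size=20000)
        assert genomic_control_lambda(p) == pytest.approx(1.0, abs=0.03)

    def test_all_half(self):
        assert genomic_control_lambda(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_inflation_detected(self, rng):
        stats = chi2.rvs(1, size=5000, random_state=rng) * 1.4
        p = chi2.sf(stats, 1)
        assert genomic_control_lambda(p) > 1.2


class TestMDS:
    def _two_pop(self, rng, n=80, m=300):
        maf_a = rng.uniform(0.1, 0.5, m)
        maf_b = np.clip(maf_a + rng.choice([-0.25, 0.25], m), 0.02, 0.98)
        ga = rng.binomial(2, maf_a, size=(n, m))
        gb = rng.binomial(2, maf_b, size=(n, m))
        return np.vstack([ga, gb]).astype(np.int8)

    def test_first_component_separates_populations(self, rng):
        g = self._two_pop(rng)
        coords = mds_components(g, 2)
        label = np.r_[np.zeros(80), np.ones(80)]
        r = np.corrcoef(coords[:, 0], label)[0, 1]
        assert abs(r) > 0.9

    def test_duplicate_samples_coincide(self, rng):
        g = rng.binomial(2, 0.3, size=(30, 200)).astype(np.int8)
        g[1] = g[0]
        coords = mds_components(g, 2)
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_snp_order_invariance(self, rng):
        g = self._two_pop(rng, n=30, m=100)
        coords = mds_components(g, 2)
        perm = rng.permutation(g.shape[1])
        coords_p = mds_components(g[:, perm], 2)
        assert np.allclose(np.abs(coords), np.abs(coords_p), atol=1e-8)


class TestHeterogeneity:
    def test_equal_effects(self):
        assert heterogeneity_test(0.3, 0.1, 0.3, 0.2) == pytest.approx(1.0)

    def test_known_z_value(self):
        p = heterogeneity_test(0.2, 0.1, -0.2, 0.1)
        assert p == pytest.approx(2 * norm.sf(2.8284), abs=1e-4)
        assert p == pytest.approx(0.0047, abs=2e-4)

    def test_symmetry(self):
        assert heterogeneity_test(0.1, 0.05, 0.4, 0.2) == heterogeneity_test(
            0.4, 0.2, 0.1, 0.05
        )

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            heterogeneity_test(0.1, 0.0, 0.2, 0.1)


class TestPower:
    def test_null_or_gives_alpha(self):
        assert power_trend(1.0, 0.3, 1000, 1000, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n_and_effect(self):
        p_small = power_trend(1.3, 0.2, 500, 500, alpha=1e-4)
        p_large = power_trend(1.3, 0.2, 5000, 5000, alpha=1e-4)
        assert p_large > p_small
        assert power_trend(1.6, 0.2, 500, 500, alpha=1e-4) > p_small
        # a protective allele is also detectable, though not with exactly
        # symmetric power (the case-genotype tilt is not symmetric in OR)
        assert power_trend(1 / 1.3, 0.2, 500, 500, alpha=1e-4) > 0.02

    def test_against_simulated_scans(self, rng):
        or_, maf, n1, n0, alpha = 1.2, 0.3, 3426, 29624, 5e-8
        analytic = power_trend(or_, maf, n1, n0, alpha)
        p0 = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        w = p0 * or_ ** np.arange(3)
        p1 = w / w.sum()
        gvals = np.arange(3.0)
        B = 2000
        c1 = rng.multinomial(n1, p1, size=B)
        c0 = rng.multinomial(n0, p0, size=B)
        mu1 = c1 @ gvals / n1
        mu0 = c0 @ gvals / n0
        tot = c1 + c0
        pmix = tot / (n1 + n0)
        varmix = pmix @ gvals**2 - (pmix @ gvals) ** 2
        z = (mu1 - mu0) / np.sqrt(varmix * (1 / n1 + 1 / n0))
        empirical = float((np.abs(z) > norm.isf(alpha / 2)).mean())
        assert analytic == pytest.approx(empirical, abs=0.01 + 3 * np.sqrt(empirical * (1 - empirical) / B))
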