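"""Elastic-net risk models: solver correctness, E[FP] calibration, scoring."""

import numpy as np
import pandas as pd
import pytest
from _oracles import elastic_net_oracle
from archpipe.cohort import MISSING, ArchitectureSpec, Cohort, simulate_cohort
from archpipe.sparse import (
    SparseModel,
    bias_corrected_refit,
    count_regions,
    default_lambda2,
    fit_model_series,
    fit_sparse_logistic,
    lambda1_for_efp,
    matched_cv_folds,
    predict_scores,
    profile_score_from_or_table,
)


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(5)
    n, m = 200, 50
    X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    beta = np.zeros(m)
    beta[:5] = [0.5, -0.4, 0.3, 0.6, -0.5]
    eta = -1 + X @ beta
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestSolver:
    @pytest.mark.parametrize("lam1,lam2", [(8.0, 0.2), (2.0, 0.0), (0.0, 1.0)])
    def test_matches_independent_convex_solver(self, design, lam1, lam2):
        X, y = design
        model = fit_sparse_logistic(X, y, lam1, lam2)
        assert model.objective == pytest.approx(
            elastic_net_oracle(X, y, lam1, lam2), abs=1e-6
        )
        assert model.kkt_residual < 1e-6 * len(y)

    def test_unpenalized_matches_newton(self, design):
        X, y = design
        model = fit_sparse_logistic(X, y, 0.0, 0.0)
        from archpipe.assoc import fit_logistic

        beta_ref, _, _, conv = fit_logistic(np.column_stack([np.ones(len(y)), X]), y)
        assert conv
        dense = np.zeros(X.shape[1])
        for s, b in zip(model.entries["snp"], model.entries["beta"]):
            dense[int(s[3:])] = b
        assert np.max(np.abs(np.r_[model.intercept, dense] - beta_ref)) < 1e-5

    def test_huge_l1_gives_intercept_only(self, design):
        X, y = design
        model = fit_sparse_logistic(X, y, 1e6, 0.0)
        assert model.size == 0
        ybar = y.mean()
        assert model.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_missing_dosages_mean_imputed(self, design):
        X, y = design
        Xm = X.copy()
        Xm[:10, 0] = np.nan
        model = fit_sparse_logistic(Xm, y, 5.0, 0.1)
        assert np.isfinite(model.objective)

    def test_negative_penalties_rejected(self, design):
        X, y = design
        with pytest.raises(ValueError):
            fit_sparse_logistic(X, y, -1.0, 0.0)


class TestEFPCalibration:
    def test_target_at_m_saturates(self, design):
        X, y = design
        with pytest.warns(UserWarning):
            assert lambda1_for_efp(X, y, X.shape[1]) == 0.0

    def test_scale_equivariance(self, design):
        X, y = design
        l1 = lambda1_for_efp(X, y, 5.0)
        assert lambda1_for_efp(2 * X, y, 5.0) == pytest.approx(2 * l1, rel=1e-6)

    def test_bound_holds_on_null_replicates(self):
        sizes = []
        for s in range(25):
            rng = np.random.default_rng(900 + s)
            X = rng.binomial(2, 0.3, size=(300, 200)).astype(float)
            y = rng.integers(0, 2, 300).astype(float)
            lam = lambda1_for_efp(X, y, 5.0)
            sizes.append(fit_sparse_logistic(X, y, lam, default_lambda2(300)).size)
        assert np.mean(sizes) <= 5 + 2 * np.sqrt(5)


class TestModelSeries:
    def test_path_sizes_and_nesting(self, small_cohort):
        models = fit_model_series(small_cohort, (0.5, 5.0, 50.0))
        sizes = [m.size for m in models]
        assert sizes == sorted(sizes)
        supports = [set(m.entries["snp"]) for m in models]
        for a, b in zip(supports, supports[1:]):
            assert len(a - b) <= max(1, int(0.1 * max(len(a), 1)))

    def test_small_bound_overlaps_bonferroni_hits(self):
        spec = ArchitectureSpec(
            m=200, m_causal=5, h2_l=0.45, K=0.2, maf_dist=("uniform", 0.2, 0.5), seed=17
        )
        c = simulate_cohort(spec, 400, 800)
        from archpipe.assoc import logistic_lrt_scan

        scan = logistic_lrt_scan(c, ())
        bonf = set(scan.loc[scan["p_lrt"] < 0.05 / c.n_snps, "snp"])
        model = fit_model_series(c, (0.05,))[0]
        selected = set(model.entries["snp"])
        if bonf:
            assert len(selected & bonf) / len(bonf) >= 0.6

    def test_grid_must_increase(self, small_cohort):
        with pytest.raises(ValueError):
            fit_model_series(small_cohort, (5.0, 0.5))


class TestBiasCorrection:
    def test_refit_of_empty_model_is_intercept_only(self, design):
        X, y = design
        empty = fit_sparse_logistic(X, y, 1e6, 0.0)
        refit = bias_corrected_refit(empty, X, y)
        assert refit.size == 0 and refit.bias_corrected

    def test_support_unchanged_and_effects_grow(self, design):
        X, y = design
        model = fit_sparse_logistic(X, y, 10.0, 0.1)
        assert model.size > 0
        refit = bias_corrected_refit(model, X, y, lambda2=0.1)
        assert list(refit.entries["snp"]) == list(model.entries["snp"])
        assert (
            refit.entries["beta"].abs().mean() >= model.entries["beta"].abs().mean()
        )

    def test_refit_closer_to_truth(self):
        spec = ArchitectureSpec(
            m=100, m_causal=4, h2_l=0.45, K=0.2, maf_dist=("uniform", 0.2, 0.5), seed=23
        )
        c = simulate_cohort(spec, 500, 1000)
        X = c.dosage_float()
        y = c.status.astype(float)
        lam = lambda1_for_efp(X, y, 0.5)
        model = fit_sparse_logistic(
            X, y, lam, 1.0, snp_ids=c.snps["snp_id"].to_numpy()
        )
        assert model.size > 0
        refit = bias_corrected_refit(
            model, X, y, snp_ids=c.snps["snp_id"].to_numpy(), lambda2=1.0
        )
        # liability-scale truth is not the logistic-scale target, but the
        # shrunken fit must be farther from the (scaled) truth than the refit
        truth = c.snps.set_index("snp_id")["true_beta"]
        t = truth[model.entries["snp"]].to_numpy()
        rmse_pen = np.sqrt(np.mean((model.entries["beta"].to_numpy() - 2.2 * t) ** 2))
        rmse_ref = np.sqrt(np.mean((refit.entries["beta"].to_numpy() - 2.2 * t) ** 2))
        assert rmse_ref <= rmse_pen


class TestProfileScore:
    TABLE = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(5)],
            "risk_allele": list("ACGTA"),
            "OR": [1.0, 2.0, 0.5, 1.5, 1.2],
        }
    )
    FREQS = {f"rs{i}": f for i, f in zip(range(5), [0.1, 0.2, 0.3, 0.4, 0.25])}

    def test_unit_ors_drop_out(self):
        model = profile_score_from_or_table(self.TABLE, self.FREQS)
        assert "rs0" not in set(model.entries["snp"])  # OR=1 contributes nothing

    def test_single_snp_score_difference(self):
        tab = pd.DataFrame({"snp": ["rs1"], "risk_allele": ["C"], "OR": [2.0]})
        model = profile_score_from_or_table(tab, {"rs1": 0.3})
        b = model.entries["beta"].iloc[0]
        assert 2 * b - 0 * b == pytest.approx(2 * np.log(2))

    def test_matches_hand_computed_toy(self):
        model = profile_score_from_or_table(self.TABLE, self.FREQS)
        by_snp = model.entries.set_index("snp")
        # dosages rs1=2, rs2=1, rs3=0, rs4=1 -> log(2^2 * 0.5 * 1.2)
        expect = np.log(2.0**2) + np.log(0.5) + np.log(1.2)
        got = 2 * by_snp.loc["rs1", "beta"] + 1 * by_snp.loc["rs2", "beta"] + 1 * by_snp.loc["rs4", "beta"]
        assert got == pytest.approx(expect, abs=1e-12)
        # w_miss is the mean-dosage contribution
        assert by_snp.loc["rs1", "w_miss"] == pytest.approx(np.log(2) * 2 * 0.2)

    def test_missing_frequency_is_an_error(self):
        with pytest.raises(KeyError):
            profile_score_from_or_table(self.TABLE, {"rs1": 0.2})


class TestScoring:
    def _toy_cohort(self):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "status": [1, 0, 1], "sex": [0, 1, 0],
             "age": [60.0, 50.0, 55.0], "platform": "v1", "ancestry": 0.0}
        )
        snps = pd.DataFrame(
            {"snp_id": ["rs1", "rs2"], "chrom": ["1", "2"], "pos": [100, 200],
             "allele_major": ["A", "C"], "allele_minor": ["G", "T"],
             "maf": [0.3, 0.2], "true_beta": [0.0, 0.0]}
        )
        g = np.array([[0, 2], [1, MISSING], [2, 1]], dtype=np.int8)
        return Cohort(samples=samples, genotypes=g, snps=snps)

    def _model(self, ea=("G", "T")):
        entries = pd.DataFrame(
            {"snp": ["rs1", "rs2"], "effect_allele": list(ea),
             "beta": [0.4, -0.3], "w_miss": [0.4 * 0.6, -0.3 * 0.4]}
        )
        return SparseModel(intercept=-1.0, entries=entries)

    def test_exact_linear_predictor(self):
        c = self._toy_cohort()
        scores = predict_scores(self._model(), c)
        assert scores[0] == pytest.approx(-1.0 + 0.4 * 0 + (-0.3) * 2)
        assert scores[2] == pytest.approx(-1.0 + 0.4 * 2 + (-0.3) * 1)

    def test_missing_uses_w_miss(self):
        c = self._toy_cohort()
        scores = predict_scores(self._model(), c)
        assert scores[1] == pytest.approx(-1.0 + 0.4 * 1 + (-0.3 * 0.4))

    def test_major_allele_orientation_flips_dosage(self):
        c = self._toy_cohort()
        scores = predict_scores(self._model(ea=("A", "T")), c)
        assert scores[0] == pytest.approx(-1.0 + 0.4 * 2 + (-0.3) * 2)

    def test_strict_strand_rejects_ambiguous(self):
        c = self._toy_cohort()
        c.snps.loc[0, ["allele_major", "allele_minor"]] = ["A", "T"]
        model = self._model(ea=("T", "T"))
        with pytest.raises(KeyError):
            predict_scores(model, c, strand="strict")

    def test_unknown_snp_policy(self):
        c = self._toy_cohort()
        entries = pd.DataFrame(
            {"snp": ["nope"], "effect_allele": ["A"], "beta": [1.0], "w_miss": [0.0]}
        )
        model = SparseModel(intercept=0.0, entries=entries)
        with pytest.raises(KeyError):
            predict_scores(model, c)
        with pytest.warns(UserWarning):
            scores = predict_scores(model, c, on_unresolvable="skip")
        assert np.allclose(scores, 0.0)


class TestSerialization:
    def test_roundtrip_exact(self, tmp_path, design):
        X, y = design
        model = fit_sparse_logistic(X, y, 6.0, 0.3, efp_bound=5.0)
        path = tmp_path / "model.tsv"
        model.to_tsv(path)
        back = SparseModel.from_tsv(path)
        assert back.intercept == model.intercept
        assert back.lambda1 == model.lambda1
        assert back.efp_bound == model.efp_bound
        assert np.array_equal(back.entries["beta"].to_numpy(), model.entries["beta"].to_numpy())
        assert np.array_equal(back.entries["w_miss"].to_numpy(), model.entries["w_miss"].to_numpy())


class TestFolds:
    def test_fold_balance(self, small_cohort):
        plan = matched_cv_folds(small_cohort, 5, seed=3)
        assert set(plan.fold) == {1, 2, 3, 4, 5}
        global_frac = small_cohort.status.mean()
        for f in range(1, 6):
            sel = plan.fold == f
            frac = small_cohort.status[sel].mean()
            assert frac == pytest.approx(global_frac, rel=0.10)

    def test_stratum_counts_near_equal_across_folds(self, small_cohort):
        plan = matched_cv_folds(small_cohort, 5, seed=3)
        for st in np.unique(plan.stratum):
            sel = plan.stratum == st
            counts = np.bincount(plan.fold[sel], minlength=6)[1:]
            assert counts.max() - counts.min() <= 2

    def test_deterministic(self, small_cohort):
        a = matched_cv_folds(small_cohort, 5, seed=11).fold
        b = matched_cv_folds(small_cohort, 5, seed=11).fold
        assert np.array_equal(a, b)

    def test_min_folds(self, small_cohort):
        with pytest.raises(ValueError):
            matched_cv_folds(small_cohort, 1)


class TestRegions:
    SNPS = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(6)],
            "chrom": ["1", "1", "1", "2", "2", "3"],
            "pos": [100_000, 200_000, 1_300_000, 50_000, 90_000, 10_000],
        }
    )

    def _model(self, ids):
        entries = pd.DataFrame(
            {"snp": ids, "effect_allele": "A", "beta": 0.1, "w_miss": 0.0}
        )
        return SparseModel(intercept=0.0, entries=entries)

    def test_single_snp(self):
        assert count_regions(self._model(["rs0"]), self.SNPS) == 1

    def test_distant_snps_split(self):
        assert count_regions(self._model(["rs0", "rs2"]), self.SNPS, 250.0) == 2

    def test_chain_merges(self):
        chain = pd.DataFrame(
            {
                "snp_id": [f"c{i}" for i in range(5)],
                "chrom": "1",
                "pos": 100_000 + 100_000 * np.arange(5),
            }
        )
        assert count_regions(self._model([f"c{i}" for i in range(5)]), chain, 250.0) == 1

    def test_chromosomes_never_merge(self):
        assert count_regions(self._model(["rs3", "rs5"]), self.SNPS, 10_000.0) == 2

    def test_empty_model(self):
        entries = pd.DataFrame(columns=["snp", "effect_allele", "beta", "w_miss"])
        assert count_regions(SparseModel(0.0, entries), self.SNPS) == 0
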