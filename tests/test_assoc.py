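"""PCA determinism and structure detection; linear/logistic association
against independent oracles (closed-form normal equations, statsmodels);
GWAS driver behaviour on generator truth."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pleiocfdr import (SimulationConfig, assoc_linear, assoc_logistic,
                       genomic_inflation, genotype_pca, run_gwas,
                       simulate_genotypes, simulate_phenotypes)

from conftest import make_genotypes


class TestGenotypePCA:
    def test_two_subpopulations_separate_on_pc1(self):
        cfg = SimulationConfig(n_samples=400, n_snps=500, n_blocks=50,
                               two_subpop=True, subpop_maf_shift=0.15,
                               seed=3)
        G = simulate_genotypes(cfg)
        pcs = genotype_pca(G, k=4)
        group = G.sample_groups.astype(float)
        r = np.corrcoef(pcs.scores[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_cohort_has_no_dominant_pc(self, small_cohort):
        G, _ = small_cohort
        pcs = genotype_pca(G, k=5)
        evr = pcs.explained_variance_ratio
        assert evr[0] < 2 * evr[1]
        assert (np.diff(evr) <= 1e-12).all()  # non-increasing

    def test_duplicate_rows_get_identical_scores(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(40, 60)).astype(np.int8)
        d[11] = d[3]
        pcs = genotype_pca(make_genotypes(d), k=3)
        assert np.allclose(pcs.scores[11], pcs.scores[3], atol=1e-8)

    def test_scores_orthogonal_and_deterministic(self, small_cohort):
        G, _ = small_cohort
        pcs = genotype_pca(G, k=6)
        s = pcs.scores - pcs.scores.mean(axis=0)
        gram = s.T @ s / len(s)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.abs(np.diag(gram)).max() < 1e-8
        pcs2 = genotype_pca(G, k=6)
        assert np.array_equal(pcs.scores, pcs2.scores)

    def test_k_out_of_range_rejected(self, small_cohort):
        G, _ = small_cohort
        with pytest.raises(ValueError):
            genotype_pca(G, k=10_000)


class TestAssocLinear:
    def test_noiseless_slope_recovered(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        res = assoc_linear(2.0 * g, g)
        assert res.beta == pytest.approx(2.0, abs=1e-12)
        assert res.p <= 1e-30

    def test_matches_normal_equations_oracle(self):
        """Random small instances against explicit (X'X)^-1 X'y with a
        t-test — the textbook closed form, built independently here."""
        rng = np.random.default_rng(4)
        for _ in range(300):
            n = rng.integers(8, 40)
            g = rng.integers(0, 3, n).astype(float)
            if np.ptp(g) == 0:
                continue
            c = rng.normal(size=(n, rng.integers(0, 3)))
            y = rng.normal(size=n)
            res = assoc_linear(y, g, c)
            X = np.column_stack([np.ones(n), c, g])
            xtx_inv = np.linalg.inv(X.T @ X)
            coef = xtx_inv @ X.T @ y
            resid = y - X @ coef
            df = n - X.shape[1]
            se = np.sqrt(resid @ resid / df * xtx_inv[-1, -1])
            p = 2 * stats.t.sf(abs(coef[-1] / se), df)
            assert res.beta == pytest.approx(coef[-1], abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_orthogonal_covariate_leaves_slope_unchanged(self):
        rng = np.random.default_rng(5)
        n = 200
        g = rng.integers(0, 3, n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        c = rng.normal(size=n)
        # residualize the new covariate against [1, g, y]
        X = np.column_stack([np.ones(n), g, y])
        c_orth = c - X @ np.linalg.lstsq(X, c, rcond=None)[0]
        r0 = assoc_linear(y, g)
        r1 = assoc_linear(y, g, c_orth[:, None])
        assert r1.beta == pytest.approx(r0.beta, abs=1e-8)

    def test_constant_dosage_flagged(self):
        res = assoc_linear(np.random.default_rng(0).normal(size=20),
                           np.ones(20))
        assert res.status == "constant"
        assert np.isnan(res.p)


class TestAssocLogistic:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        c = rng.normal(size=(n, 2))
        eta = -1.5 + 0.4 * g + 0.2 * c[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = assoc_logistic(y, g, c)
        X = sm.add_constant(np.column_stack([c, g]))
        fit = sm.Logit(y, X).fit(disp=0)
        assert res.beta == pytest.approx(fit.params[-1], abs=1e-6)
        assert res.se == pytest.approx(fit.bse[-1], abs=1e-6)
        assert res.p == pytest.approx(fit.pvalues[-1], rel=1e-5)

    def test_null_type_one_error_calibrated(self):
        """y independent of g at ~4.6% case fraction: rejection rate at
        0.05 stays within [0.03, 0.07] over 2,000 replicates."""
        rng = np.random.default_rng(7)
        n = 2_000
        rejections = 0
        n_rep = 2_000
        for _ in range(n_rep):
            y = (rng.random(n) < 0.046).astype(float)
            if y.sum() < 2:
                continue
            g = rng.binomial(2, 0.3, n).astype(float)
            res = assoc_logistic(y, g)
            rejections += res.status == "ok" and res.p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_odds_ratio_recovered(self):
        """OR 1.5 at MAF 0.3: mean slope over 200 replicates within 5%
        of log(1.5)."""
        rng = np.random.default_rng(8)
        betas = []
        for _ in range(200):
            n = 20_000
            g = rng.binomial(2, 0.3, n).astype(float)
            eta = -2.5 + np.log(1.5) * g
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            betas.append(assoc_logistic(y, g).beta)
        assert np.mean(betas) == pytest.approx(np.log(1.5), rel=0.05)

    def test_constant_and_separation_flags(self):
        y = np.r_[np.zeros(15), np.ones(15)]
        assert assoc_logistic(y, np.ones(30)).status == "constant"
        g = np.r_[np.zeros(15), np.full(15, 2.0)]
        assert assoc_logistic(y, g).status == "separation"


class TestRunGwas:
    def test_causal_snps_enriched_at_small_p(self):
        cfg = SimulationConfig(n_samples=4_000, n_snps=2_000,
                               n_blocks=200, pi_shared=0.0,
                               pi_trait1_only=0.005, pi_trait2_only=0.0,
                               h2_trait1=0.5, seed=9)
        G = simulate_genotypes(cfg)
        ph = simulate_phenotypes(G, cfg)
        ss = run_gwas(G, ph.data, "aam")
        causal = set(ph.truth["id"])
        is_causal = ss["id"].isin(causal).to_numpy()
        u = stats.mannwhitneyu(ss.loc[is_causal, "p"],
                               ss.loc[~is_causal, "p"],
                               alternative="less")
        assert u.pvalue < 1e-6
        assert len(ss) == G.n_snps
        assert (ss["p"].dropna() > 0).all()

    def test_zero_heritability_lambda_near_one(self):
        cfg = SimulationConfig(n_samples=2_000, n_snps=2_000,
                               n_blocks=2_000, h2_trait1=0.0,
                               block_ld_rho=0.0, seed=10)
        G = simulate_genotypes(cfg)
        ph = simulate_phenotypes(G, cfg)
        ss = run_gwas(G, ph.data, "aam")
        lam = genomic_inflation(ss["p"].to_numpy())
        assert 0.93 <= lam <= 1.07

    def test_single_snp_and_unknown_trait(self, small_cohort):
        G, cfg = small_cohort
        ph = simulate_phenotypes(G, cfg)
        one = G.subset(snp_mask=np.arange(G.n_snps) == 0)
        ss = run_gwas(one, ph.data, "bfp")
        assert len(ss) == 1
        with pytest.raises(ValueError, match="nope"):
            run_gwas(G, ph.data, "nope")

    def test_logistic_trait_uses_wald_and_runs(self, small_cohort):
        G, cfg = small_cohort
        ph = simulate_phenotypes(G, cfg)
        few = G.subset(snp_mask=np.arange(G.n_snps) < 30)
        ss = run_gwas(few, ph.data, "t2dm")
        ok = ss["status"] == "ok"
        assert ok.any()
        assert (ss.loc[ok, "se"] > 0).all()
        assert ((ss.loc[ok, "p"] > 0) & (ss.loc[ok, "p"] <= 1)).all()
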