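"""Per-SNP association scans, candidate-SNP models and trait transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import malecotmap as mm
from malecotmap.exceptions import DegenerateInputError, StratificationError
from malecotmap.scan import (
    candidate_snp_models,
    inverse_normal_transform,
    mean_correct,
    single_snp_scan,
)
from malecotmap.synthetic import CovariateSpec


class TestInverseNormal:
    def test_blom_definition(self):
        x = np.arange(20.0)
        out = inverse_normal_transform(x)
        expected = stats.norm.ppf((np.arange(1, 21) - 0.375) / 20.25)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=200)
        np.testing.assert_allclose(
            inverse_normal_transform(x), inverse_normal_transform(np.log(x)),
            atol=1e-12,
        )

    def test_lognormal_input_standardised(self):
        rng = np.random.default_rng(2)
        out = inverse_normal_transform(rng.lognormal(sigma=2.0, size=1000))
        assert abs(out.mean()) < 0.05
        assert 0.95 < out.std() < 1.05

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            inverse_normal_transform(np.ones(50))

    def test_ties_share_scores_and_nan_preserved(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, np.nan] * 4)
        out = inverse_normal_transform(x)
        assert np.isnan(out[4])
        tied = out[np.asarray(x == 2.0).nonzero()]
        assert np.allclose(tied, tied[0])


class TestMeanCorrect:
    def test_linear_function_of_age_gives_r2_one(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(20, 80, 100)
        cov = pd.DataFrame({"age": age})
        resid, r2 = mean_correct(3.0 + 0.5 * age, cov)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_independent_trait_gives_small_r2(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"age": rng.uniform(20, 80, 1000)})
        resid, r2 = mean_correct(rng.normal(size=1000), cov)
        assert r2 < 0.02
        assert abs(np.nanmean(resid)) < 1e-10

    def test_insulin_like_covariates_explain_r2_018(self, cohort):
        """Generator calibration: age/sex/year explain R^2 ~ 0.18."""
        spec = CovariateSpec.insulin_like()
        truth = mm.TruthRecord(0, float(cohort.positions_kb[0]), 0.05, 0.0)
        r2s = []
        for rep in range(20):
            tab = mm.simulate_phenotypes(
                cohort, truth, "quantitative", covariate_spec=spec, seed=600 + rep
            )
            _, r2 = mean_correct(
                tab["trait"].to_numpy(), tab[["age", "sex", "year"]]
            )
            r2s.append(r2)
        assert np.mean(r2s) == pytest.approx(0.18, abs=0.05)


class TestSingleSnpScan:
    def test_null_type_one_error_calibrated(self, cohort):
        """Fraction of per-SNP p < 0.05 under the null sits near 5%."""
        rng = np.random.default_rng(5)
        hits, total = 0, 0
        for _ in range(100):
            y = rng.normal(size=cohort.n_individuals)
            scan = single_snp_scan(cohort, y)
            hits += int((scan["p_value"] < 0.05).sum())
            total += len(scan)
        assert 0.03 < hits / total < 0.07

    def test_null_pvalues_uniform(self, cohort):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(100):
            y = rng.normal(size=cohort.n_individuals)
            ps.append(single_snp_scan(cohort, y)["p_value"].to_numpy())
        # thin to roughly independent draws before the KS check
        ps = np.concatenate(ps)[::25]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_effect_tops_the_window(self, panel):
        """A 0.15 SD/allele effect at MAF 0.3 (n = 2000) tops the window.

        In an LD panel the top statistic may land on a near-proxy of the
        causal SNP, so a hit counts if the winner is the causal SNP or a
        marker with r^2 > 0.8 to it.
        """
        maf = np.minimum(panel.allele_freqs, 1 - panel.allele_freqs)
        causal = int(np.argmin(np.abs(maf - 0.3)))
        spec = CovariateSpec(age_beta=0.0, year_effects=(0.0,) * 5)
        wins = 0
        for rep in range(40):
            geno = mm.pair_haplotypes(panel, 2000, seed=700 + rep)
            truth = mm.TruthRecord(causal, float(geno.positions_kb[causal]), 0.15, 0.0)
            tab = mm.simulate_phenotypes(
                geno, truth, "quantitative", covariate_spec=spec, seed=800 + rep
            )
            scan = single_snp_scan(geno, tab["trait"].to_numpy())
            top = scan["chi2"].idxmax()
            r = np.corrcoef(geno.genotypes[:, top], geno.genotypes[:, causal])[0, 1]
            wins += int(top == causal or r**2 > 0.8)
        assert wins >= 0.8 * 40

    def test_z_invariant_to_affine_phenotype_rescaling(self, cohort):
        rng = np.random.default_rng(7)
        y = rng.normal(size=cohort.n_individuals)
        z1 = single_snp_scan(cohort, y)["z"]
        z2 = single_snp_scan(cohort, 3.0 * y - 7.0)["z"]
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_binary_score_scan_matches_logistic_fit(self, cohort):
        """Score chi2 tracks the full logistic Wald chi2 at modest effects."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        g = cohort.genotypes[:, 50]
        eta = 0.3 * g - 0.5
        y = (rng.random(g.size) < 1 / (1 + np.exp(-eta))).astype(float)
        scan = single_snp_scan(cohort, y)
        X = sm.add_constant(g)
        full = sm.Logit(y, X).fit(disp=0)
        wald = (full.params[1] / full.bse[1]) ** 2
        assert scan["chi2"][50] == pytest.approx(wald, rel=0.15)

    def test_cluster_robust_se_exceeds_naive_on_twins(self, cohort):
        truth = mm.TruthRecord(0, float(cohort.positions_kb[0]), 0.0, 0.0)
        tab = mm.simulate_phenotypes(cohort, truth, "quantitative", seed=71)
        geno2, tab2 = mm.synthetic.add_twin_structure(
            cohort, tab, "trait", fraction=0.8, shared_sd=1.5, seed=72
        )
        y = tab2["trait"].to_numpy()
        naive = single_snp_scan(geno2, y)
        robust = single_snp_scan(
            geno2, y, cluster=tab2["cluster_id"].to_numpy(), cluster_aware=True
        )
        ratio = (robust["se"] / naive["se"]).to_numpy()
        assert np.median(ratio) > 1.0

    def test_monomorphic_snp_flagged_not_fatal(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        g[:, 1] = 0.0
        geno = mm.GenotypeMatrix(g, np.array([0.0, 5.0, 10.0]))
        scan = single_snp_scan(geno, rng.normal(size=100))
        assert scan["flag"][1] == "monomorphic"
        assert np.isnan(scan["p_value"][1])
        assert scan["flag"][0] == ""

    def test_permuted_phenotype_preserves_z_distribution(self, cohort):
        """Exchangeability: z pooled over permutations is distribution-stable."""
        rng = np.random.default_rng(10)
        y = rng.normal(size=cohort.n_individuals)
        za = np.concatenate(
            [single_snp_scan(cohort, rng.permutation(y))["z"] for _ in range(25)]
        )
        zb = np.concatenate(
            [single_snp_scan(cohort, rng.permutation(y))["z"] for _ in range(25)]
        )
        assert stats.ks_2samp(za, zb).pvalue > 0.01


class TestCandidateModels:
    @staticmethod
    def _simulate(slope_ref, slope_carrier, n=2400, seed=0, binary=False):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, n).astype(float)
        age = rng.uniform(30, 80, n)
        year = rng.integers(0, 5, n)
        slope = np.where(g > 0, slope_carrier, slope_ref)
        eta = slope * (age - 55.0) + 0.1 * year
        if binary:
            y = (rng.random(n) < 1 / (1 + np.exp(-(eta - 2.5)))).astype(float)
        else:
            y = eta + rng.normal(0, 2.5, n)
        return g, y, age, year

    def test_wald_contrast_calibrated_under_equal_slopes(self):
        rejections = 0
        for rep in range(60):
            g, y, age, year = self._simulate(0.12, 0.12, seed=100 + rep)
            res = candidate_snp_models(g, y, age, year)
            rejections += int(res.wald_p < 0.05)
        assert stats.binomtest(rejections, 60, 0.05).pvalue > 0.01

    def test_wald_contrast_detects_doubled_slope(self):
        rejections = 0
        for rep in range(20):
            g, y, age, year = self._simulate(0.12, 0.24, seed=200 + rep)
            res = candidate_snp_models(g, y, age, year)
            rejections += int(res.wald_p < 0.05)
        assert rejections > 10  # power > 50%

    def test_null_snp_effect_within_two_se(self):
        g, y, age, year = self._simulate(0.12, 0.12, seed=300)
        res = candidate_snp_models(g, y, age, year)
        assert abs(res.beta_snp) < 2 * res.se_snp

    def test_binary_model_reports_odds_ratio(self):
        g, y, age, year = self._simulate(0.04, 0.04, seed=400, binary=True)
        res = candidate_snp_models(g, y, age, year)
        assert res.binary
        assert res.odds_ratio_snp == pytest.approx(np.exp(res.beta_snp))
        assert "OR" in res.summary()

    def test_empty_stratum_rejected(self):
        g = np.ones(100) * 2
        rng = np.random.default_rng(11)
        with pytest.raises(StratificationError):
            candidate_snp_models(
                g, rng.normal(size=100), rng.uniform(30, 70, 100),
                rng.integers(0, 3, 100),
            )
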