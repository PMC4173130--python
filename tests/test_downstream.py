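"""Meta-analysis, eQTL cascade, multiplicity corrections, quartile contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import malecotmap as mm
from malecotmap.data import ExpressionMatrix
from malecotmap.downstream import (
    bonferroni_threshold,
    effective_tests,
    fisher_combine,
    probe_phenotype_cascade,
    quartile_prevalence,
)
from malecotmap.exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidConfigurationError,
)
from malecotmap.synthetic import simulate_cascade_dataset


class TestFisher:
    def test_published_style_triple_combines_to_3e7(self):
        res = fisher_combine([3e-6, 0.01, 0.04])
        assert res.df == 6
        assert f"{res.p_combined:.0e}" == "3e-07"

    def test_uninformative_inputs_give_p_one(self):
        res = fisher_combine([1.0, 1.0])
        assert res.chi2 == 0.0
        assert res.p_combined == 1.0

    def test_null_combination_is_uniform(self):
        rng = np.random.default_rng(1)
        p = rng.random((10_000, 3))
        chi2 = -2 * np.log(p).sum(axis=1)
        combined = stats.chi2.sf(chi2, 6)
        single = fisher_combine(p[0])
        assert single.p_combined == pytest.approx(combined[0])
        assert stats.kstest(combined, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("bad", [[0.5], [0.0, 0.5], [0.5, 1.2], [0.5, np.nan]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InvalidConfigurationError):
            fisher_combine(bad)

    @given(
        p=st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=6),
        k=st.integers(0, 5),
        factor=st.floats(0.1, 0.99),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_permutation_invariant(self, p, k, factor):
        base = fisher_combine(p).p_combined
        assert fisher_combine(p[::-1]).p_combined == pytest.approx(base)
        q = list(p)
        q[k % len(q)] *= factor  # decreasing any input p ...
        assert fisher_combine(q).p_combined <= base + 1e-12


class TestEffectiveTests:
    def test_identity_matrix_keeps_all_tests(self):
        res = effective_tests(np.eye(6))
        assert res.m_eff == 6

    def test_perfect_correlation_collapses_to_one(self):
        res = effective_tests(np.ones((6, 6)))
        assert res.m_eff == 1

    def test_six_probes_at_r06_give_four_tests(self):
        R = np.full((6, 6), 0.6)
        np.fill_diagonal(R, 1.0)
        assert effective_tests(R).m_eff == 4

    def test_five_phenotypes_at_r07_give_three_tests(self):
        R = np.full((5, 5), 0.7)
        np.fill_diagonal(R, 1.0)
        assert effective_tests(R).m_eff == 3

    def test_crossed_families_multiply(self):
        R = np.full((6, 6), 0.6)
        np.fill_diagonal(R, 1.0)
        res = effective_tests(R, family_alpha=0.05, cross_factor=3)
        assert res.corrected_alpha == pytest.approx(0.05 / 12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            effective_tests(np.array([[1.0, 2.0], [0.5, 1.0]]))
        with pytest.raises(InvalidConfigurationError):
            effective_tests(np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.2]]))

    @given(r=st.floats(0.0, 0.99), d=st.integers(2, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_count_bounded_by_dimension(self, r, d):
        R = np.full((d, d), r)
        np.fill_diagonal(R, 1.0)
        res = effective_tests(R)
        assert 1 <= res.m_eff <= d


class TestBonferroni:
    @pytest.mark.parametrize(
        "n, alpha, expected",
        [(5000, 0.05, 1e-5), (12, 0.05, 0.05 / 12), (1, 0.05, 0.05)],
    )
    def test_threshold_arithmetic(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConfigurationError):
            bonferroni_threshold(0, 0.05)
        with pytest.raises(InvalidConfigurationError):
            bonferroni_threshold(10, 1.5)


class TestQuartilePrevalence:
    def test_all_cases_in_top_quartile(self):
        e = np.arange(100.0)
        s = np.zeros(100)
        s[-10:] = 1.0  # all cases in the top expression quartile
        res = quartile_prevalence(e, s)
        assert res.prevalence[3] == pytest.approx(0.4)
        assert np.all(res.prevalence[:3] == 0.0)
        assert res.prevalence[3] == pytest.approx(4 * s.mean())
        assert res.df == 3

    def test_null_association_not_significant_typically(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(100):
            e = rng.normal(size=200)
            s = (rng.random(200) < 0.1).astype(float)
            if s.sum() == 0:
                continue
            ps.append(quartile_prevalence(e, s).p_value)
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_planted_monotone_risk_detected(self):
        """Top-vs-bottom prevalence ratio ~3 with n = 820 and ~37 cases."""
        rng = np.random.default_rng(3)
        # monotone risk by quartile, mean prevalence 4.5% (~37 cases)
        quartile_risk = np.array([0.0225, 0.0375, 0.0525, 0.0675])
        hits = 0
        for _ in range(40):
            e = rng.normal(size=820)
            q = np.searchsorted(np.quantile(e, [0.25, 0.5, 0.75]), e, side="left")
            s = (rng.random(820) < quartile_risk[q]).astype(float)
            hits += int(quartile_prevalence(e, s).p_value < 0.05)
        assert hits >= 20  # power >= 50%

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            quartile_prevalence(np.arange(30.0), np.ones(30))
        with pytest.raises(DegenerateInputError):
            quartile_prevalence(np.arange(50.0), np.zeros(50))


class TestEqtlScan:
    def test_planted_eqtl_located_near_truth(self, panel, ref_map):
        geno = mm.pair_haplotypes(panel, 700, seed=61)
        truth = mm.TruthRecord(50, float(geno.positions_kb[50]), 0.0, 0.5)
        rng = np.random.default_rng(62)
        batch = rng.integers(0, 4, 700)
        tab = mm.simulate_phenotypes(geno, truth, "expression", seed=63)
        fit = mm.eqtl_probe_scan(
            geno, tab["expression"].to_numpy(), ref_map, batch=batch
        )
        assert fit.p_value < 1e-3
        assert abs(fit.S_hat_kb - truth.causal_kb) < 200.0

    def test_batch_residualisation_leaves_location_stable(self, panel, ref_map):
        geno = mm.pair_haplotypes(panel, 700, seed=64)
        truth = mm.TruthRecord(50, float(geno.positions_kb[50]), 0.0, 0.6)
        tab = mm.simulate_phenotypes(geno, truth, "expression", seed=65)
        e = tab["expression"].to_numpy()
        rng = np.random.default_rng(66)
        batch = rng.integers(0, 4, 700)  # orthogonal to genotype
        shifts = np.array([0.0, 1.5, -1.0, 0.7])
        fit_clean = mm.eqtl_probe_scan(geno, e, ref_map, batch=batch)
        fit_batch = mm.eqtl_probe_scan(geno, e + shifts[batch], ref_map, batch=batch)
        assert abs(fit_clean.S_hat_ldu - fit_batch.S_hat_ldu) < 0.05

    def test_too_few_individuals_rejected(self, cohort, ref_map):
        with pytest.raises(DegenerateInputError):
            mm.eqtl_probe_scan(
                cohort, np.full(cohort.n_individuals, np.nan), ref_map
            )


class TestCascade:
    def test_conditional_analysis_retains_only_the_driver(self):
        """Focal probe drives the trait; an r = -0.38 bystander does not."""
        expr, tab = simulate_cascade_dataset(
            n=700, beta_focal=0.19, r_bystander=-0.38, binary=False, seed=5
        )
        res = probe_phenotype_cascade(
            expr, tab, focal_probe="focal_probe", phenotype_columns=["trait"]
        )
        retained = res.retained_probes("trait")
        assert "focal_probe" in retained

    def test_binary_cascade_recovers_logit_effect(self):
        """Planted log-odds 1.34/SD comes back within 2 SE (OR ~ 3.8)."""
        expr, tab = simulate_cascade_dataset(
            n=820, beta_focal=1.34, r_bystander=-0.38, binary=True, seed=6
        )
        res = probe_phenotype_cascade(
            expr, tab, focal_probe="focal_probe", phenotype_columns=["status"]
        )
        row = res.panel_b[res.panel_b["probe"] == "focal_probe"].iloc[0]
        assert abs(row["beta"] - 1.34) < 2 * row["se"]
        assert row["or_ci95_low"] < np.exp(1.34) < row["or_ci95_high"]

    def test_orthogonal_conditional_probes_leave_beta_unchanged(self):
        """Panel-B betas equal Panel-A betas for exactly orthogonal probes."""
        rng = np.random.default_rng(7)
        n = 400
        raw = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        probes = q * np.sqrt(n)  # orthogonal, unit-variance probes
        ids = [f"i{k}" for k in range(n)]
        expr = ExpressionMatrix(
            values=pd.DataFrame(
                probes.T, index=["focal_probe", "p2", "p3"], columns=ids
            ),
            batch=pd.Series(np.zeros(n, int), index=ids),
        )
        tab = pd.DataFrame(
            {
                "individual_id": ids,
                "age": np.zeros(n),
                "trait": probes @ np.array([0.5, 0.3, 0.0]) + rng.normal(size=n),
            }
        )
        res = probe_phenotype_cascade(
            expr,
            tab,
            focal_probe="focal_probe",
            phenotype_columns=["trait"],
            conditional_probes=["p2", "p3"],
            covariate_columns=(),
        )
        a = res.panel_a.set_index("probe").loc["focal_probe", "beta"]
        b = res.panel_b.set_index("probe").loc["focal_probe", "beta"]
        assert b == pytest.approx(a, abs=1e-8)

    def test_near_collinear_conditional_probe_rejected(self):
        rng = np.random.default_rng(8)
        n = 300
        focal = rng.normal(size=n)
        clone = focal + 1e-4 * rng.normal(size=n)
        ids = [f"i{k}" for k in range(n)]
        expr = ExpressionMatrix(
            values=pd.DataFrame(
                [focal, clone], index=["focal_probe", "clone"], columns=ids
            ),
            batch=pd.Series(np.zeros(n, int), index=ids),
        )
        tab = pd.DataFrame(
            {
                "individual_id": ids,
                "age": rng.uniform(30, 70, n),
                "trait": focal + rng.normal(size=n),
            }
        )
        with pytest.raises(CollinearityError):
            probe_phenotype_cascade(
                expr,
                tab,
                focal_probe="focal_probe",
                phenotype_columns=["trait"],
                conditional_probes=["clone"],
            )

    def test_null_probes_rarely_pass_corrected_threshold(self):
        """With all effects zero, the corrected alpha keeps the family clean."""
        R = np.full((4, 4), 0.3)
        np.fill_diagonal(R, 1.0)
        alpha = effective_tests(R, cross_factor=1).corrected_alpha
        clean = 0
        for rep in range(30):
            expr, tab = simulate_cascade_dataset(
                n=300, beta_focal=0.0, r_bystander=0.3, binary=False, seed=100 + rep
            )
            res = probe_phenotype_cascade(
                expr, tab, focal_probe="focal_probe", phenotype_columns=["trait"]
            )
            clean += int((res.panel_a["p_value"] >= alpha).all())
        assert clean >= 0.9 * 30
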