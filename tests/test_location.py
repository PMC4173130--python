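"""Malecot location model: identifiability, inference and concordance."""

import numpy as np
import pandas as pd
import pytest

import malecotmap as mm
from malecotmap.exceptions import (
    IncomparableFitsError,
    InvalidConfigurationError,
    LocationUnidentifiableError,
)
from malecotmap.ldu import LDUMap
from malecotmap.location import MalecotLocationModel, compare_locations


def make_map(seed=0, n=40, span_kb=400.0, total_ldu=8.0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, span_kb, n))
    eps = rng.gamma(0.4, 1.0, n - 1)
    eps *= total_ldu / np.sum(eps * np.diff(pos))
    cum = np.concatenate(([0.0], np.cumsum(eps * np.diff(pos))))
    return LDUMap(positions_kb=pos, cumulative_ldu=cum, epsilon_hat=eps)


def scan_from_model(ldu_map, s_ldu, M=0.3, L=0.05, n=2000, noise=0.0, rng=None):
    z = M * np.exp(-np.abs(s_ldu - ldu_map.cumulative_ldu)) + L
    if noise:
        z = np.abs(z + rng.normal(0, noise, z.size))
    return pd.DataFrame(
        {
            "snp_id": ldu_map.snp_ids,
            "position_kb": ldu_map.positions_kb,
            "z": z,
            "n_used": np.full(z.size, n),
        }
    )


class TestFit:
    def test_noiseless_profile_recovers_location(self):
        ldu_map = make_map()
        s_true = float(ldu_map.cumulative_ldu[17])
        scan = scan_from_model(ldu_map, s_true)
        fit = mm.fit_location_model(scan, ldu_map)
        assert abs(fit.S_hat_ldu - s_true) < 0.01
        assert fit.M_hat == pytest.approx(0.3, abs=0.01)
        assert fit.L_hat == pytest.approx(0.05, abs=0.01)
        assert fit.p_value < 1e-6

    def test_rss_model_never_exceeds_null(self):
        rng = np.random.default_rng(1)
        ldu_map = make_map(1)
        for _ in range(10):
            scan = scan_from_model(ldu_map, 3.0, M=0.0, L=0.05, noise=0.02, rng=rng)
            fit = mm.fit_location_model(scan, ldu_map)
            assert fit.rss_model <= fit.rss_null + 1e-12

    def test_grid_refine_matches_exhaustive_fine_grid(self):
        """Grid-then-refine equals a 0.001-LDU exhaustive search."""
        rng = np.random.default_rng(2)
        for k in range(20):
            ldu_map = make_map(seed=10 + k)
            s_true = rng.uniform(1.0, 7.0)
            scan = scan_from_model(
                ldu_map, s_true, M=0.25, L=0.05, noise=0.03, rng=rng
            )
            coarse = MalecotLocationModel.from_scan(scan, ldu_map)
            fine = MalecotLocationModel.from_scan(
                scan, ldu_map, grid_step_ldu=0.001
            )
            s_coarse, _ = coarse._argmin_S()
            s_fine, _ = fine._argmin_S(refine=False)
            assert abs(s_coarse - s_fine) < 0.005

    def test_lambda_invariant_to_kb_origin_shift(self):
        ldu_map = make_map(3)
        scan = scan_from_model(
            ldu_map, 4.0, noise=0.02, rng=np.random.default_rng(3)
        )
        fit1 = mm.fit_location_model(scan, ldu_map)
        shifted = LDUMap(
            positions_kb=ldu_map.positions_kb + 1000.0,
            cumulative_ldu=ldu_map.cumulative_ldu,
            epsilon_hat=ldu_map.epsilon_hat,
        )
        scan2 = scan.copy()
        scan2["position_kb"] = scan2["position_kb"] + 1000.0
        fit2 = mm.fit_location_model(scan2, shifted)
        assert fit1.lambda_stat == pytest.approx(fit2.lambda_stat, rel=1e-9)
        assert fit2.S_hat_kb == pytest.approx(fit1.S_hat_kb + 1000.0, abs=1e-6)

    def test_flat_map_is_unidentifiable(self):
        pos = np.linspace(0, 100, 20)
        flat = LDUMap(
            positions_kb=pos,
            cumulative_ldu=np.zeros(20),
            epsilon_hat=np.zeros(19),
        )
        scan = pd.DataFrame(
            {
                "position_kb": pos,
                "z": np.full(20, 0.1),
                "n_used": np.full(20, 500),
            }
        )
        with pytest.raises(LocationUnidentifiableError):
            MalecotLocationModel.from_scan(scan, flat)

    def test_too_few_markers_rejected(self):
        ldu_map = make_map(4)
        scan = scan_from_model(ldu_map, 2.0).iloc[:5]
        with pytest.raises(InvalidConfigurationError):
            mm.fit_location_model(scan, ldu_map)

    def test_window_restricts_search(self):
        ldu_map = make_map(5)
        s_true = float(ldu_map.cumulative_ldu[30])
        scan = scan_from_model(ldu_map, s_true)
        lo = float(ldu_map.positions_kb[0])
        hi = float(ldu_map.positions_kb[18])
        fit = mm.fit_location_model(scan, ldu_map, window_kb=(lo, hi))
        assert lo <= fit.S_hat_kb <= hi
        assert fit.boundary  # optimum pushed to the window edge

    def test_ci_contains_point_estimate(self, cohort, ref_map):
        rng = np.random.default_rng(6)
        y = rng.normal(size=cohort.n_individuals)
        scan = mm.single_snp_scan(cohort, y)
        fit = mm.fit_location_model(
            scan, ref_map, genotypes=cohort, phenotype=y, n_boot=50, seed=1
        )
        assert fit.ci95_kb[0] <= fit.S_hat_kb <= fit.ci95_kb[1]
        assert fit.settings["ci_method"] == "bootstrap"
        assert fit.se_S_ldu > 0

    def test_mvn_null_calibration_used_with_scan_attrs(self, cohort, ref_map):
        rng = np.random.default_rng(7)
        scan = mm.single_snp_scan(cohort, rng.normal(size=cohort.n_individuals))
        fit = mm.fit_location_model(scan, ref_map)
        assert fit.settings["null_calibration"] == "mvn"
        scan2 = scan.copy()  # copies drop attrs -> chi2 fallback
        scan2.attrs = {}
        fit2 = mm.fit_location_model(scan2, ref_map)
        assert fit2.settings["null_calibration"] == "chi2"
        assert fit.lambda_stat == pytest.approx(fit2.lambda_stat, rel=1e-9)

    def test_fit_json_round_trip(self, tmp_path, cohort, ref_map):
        import json

        rng = np.random.default_rng(8)
        scan = mm.single_snp_scan(cohort, rng.normal(size=cohort.n_individuals))
        fit = mm.fit_location_model(scan, ref_map)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        with open(path) as fh:
            payload = json.load(fh)
        assert payload["S_hat_kb"] == pytest.approx(fit.S_hat_kb)
        assert payload["ci95_kb"][0] <= payload["S_hat_kb"] <= payload["ci95_kb"][1]
        assert len(payload["residuals"]["z"]) == fit.n_snps


class TestPermutation:
    def test_add_one_rule_bounds_and_determinism(self, cohort, ref_map):
        rng = np.random.default_rng(9)
        y = rng.normal(size=cohort.n_individuals)
        with pytest.warns(UserWarning):
            p1, lam1, lams1 = mm.permutation_pvalue(
                cohort, y, ref_map, n_perm=59, seed=5
            )
        assert 1 / 60 <= p1 <= 1.0
        assert lams1.size == 59
        with pytest.warns(UserWarning):
            p2, lam2, _ = mm.permutation_pvalue(
                cohort, y, ref_map, n_perm=59, seed=5
            )
        assert p1 == p2 and lam1 == lam2

    def test_planted_signal_beats_all_permutations(self, panel, ref_map):
        geno = mm.pair_haplotypes(panel, 1500, seed=91)
        truth = mm.TruthRecord(50, float(geno.positions_kb[50]), 0.4, 0.0)
        tab = mm.simulate_phenotypes(geno, truth, "quantitative", seed=92)
        with pytest.warns(UserWarning):
            p, lam, lams = mm.permutation_pvalue(
                geno, tab["trait"].to_numpy(), ref_map, n_perm=99, seed=6
            )
        assert p == pytest.approx(1 / 100)
        assert lam > lams.max()


class TestConcordance:
    def _fit(self, ldu_map, seed, s_ldu=4.0):
        rng = np.random.default_rng(seed)
        scan = scan_from_model(ldu_map, s_ldu, noise=0.02, rng=rng)
        return mm.fit_location_model(scan, ldu_map)

    def test_identical_fits_fully_concordant(self):
        ldu_map = make_map(20)
        f = self._fit(ldu_map, 1)
        rep = compare_locations([f, f])
        assert rep.delta_kb.iloc[0, 1] == 0.0
        assert rep.ci_overlap.all().all()

    def test_pooled_se_not_larger_than_best_individual(self):
        ldu_map = make_map(21)
        fits = [self._fit(ldu_map, s) for s in (1, 2, 3)]
        rep = compare_locations(fits, reference_map=ldu_map)
        assert rep.pooled_se_ldu <= min(f.se_S_ldu for f in fits) + 1e-12

    def test_replicate_fits_agree_on_location(self):
        ldu_map = make_map(22)
        fits = [self._fit(ldu_map, s) for s in range(5)]
        rep = compare_locations(fits, reference_map=ldu_map)
        off = rep.delta_kb.to_numpy()[np.triu_indices(5, 1)]
        assert np.median(off) < 40.0

    def test_single_fit_rejected(self):
        ldu_map = make_map(23)
        with pytest.raises(IncomparableFitsError):
            compare_locations([self._fit(ldu_map, 1)])
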