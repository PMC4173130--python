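"""Multimarker Malecot location mapping.

Given a per-SNP association profile z_i (|partial correlation| in [0, 1])
and an LDU map, the location model

    z_i = M * exp(-|LDU(S) - LDU_i|) + L_z

is fitted by weighted least squares over the markers of an analytical
window.  The decay rate on the LDU scale is fixed at one per LDU - the
defining property of the LDU metric is that association declines by a
factor e per unit - so the free parameters are the amplitude M, the
baseline L_z and the putative functional-variant location S.  S is found
by a dense grid over the window's LDU range (the amplitude/baseline pair
has a closed form at each candidate S) followed by bounded 1-D
refinement.

Region-wide test.  The fit is compared with the flat null M = 0 through

    lambda = (RSS_null - RSS_model) / (RSS_model / (m - 3)).

Because the z_i of markers in LD are strongly correlated, lambda is *not*
chi^2_2 under the null; the default reference instead simulates the
asymptotic null directly - z-profiles drawn from |MVN(0, R)| / sqrt(n),
with R the score-statistic correlation carried over from the scan - and
smooths the simulated lambda distribution with a moment-matched gamma.
``null_calibration="chi2"`` retains the 2-df convention, and
:func:`permutation_pvalue` gives a fully empirical alternative.

Confidence interval for S.  The profiled-RSS curvature gives a valid SE
only when the profile is locally quadratic and unimodal; with block-step
LD the argmin can jump between competing blocks, so when raw genotype and
phenotype data are available the 95% CI comes from a stratified
case-resampling bootstrap of S-hat (percentiles on the LDU scale, mapped
to kb with the plateau convention).  Without raw data the curvature CI is
reported and flagged as optimistic in the settings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .data import GenotypeMatrix
from .exceptions import (
    IncomparableFitsError,
    InvalidConfigurationError,
    LocationUnidentifiableError,
)
from .ldu import LDUMap
from .scan import single_snp_scan

__all__ = [
    "MalecotLocationModel",
    "MalecotLocationFit",
    "fit_location_model",
    "permutation_pvalue",
    "compare_locations",
]


@dataclass
class MalecotLocationFit:
    """Fitted location model: the results object returned by ``fit()``."""

    S_hat_ldu: float
    S_hat_kb: float
    S_hat_kb_interval: tuple[float, float]
    se_S_ldu: float
    ci95_kb: tuple[float, float]
    M_hat: float
    L_hat: float
    rss_model: float
    rss_null: float
    lambda_stat: float
    df: int
    p_value: float
    n_snps: int
    boundary: bool
    converged: bool
    settings: dict = field(default_factory=dict)
    residuals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.rss_model > self.rss_null + 1e-9:
            raise InvalidConfigurationError("rss_model must not exceed rss_null")

    @property
    def ci95_width_kb(self) -> float:
        return self.ci95_kb[1] - self.ci95_kb[0]

    def summary(self) -> str:
        lines = [
            "Malecot multimarker location fit",
            "=" * 48,
            f"S_hat:        {self.S_hat_kb:,.1f} kb  ({self.S_hat_ldu:.3f} LDU)",
            f"SE(S):        {self.se_S_ldu:.3f} LDU  "
            f"({self.settings.get('ci_method', 'curvature')})",
            f"95% CI (kb):  {self.ci95_kb[0]:,.1f} - {self.ci95_kb[1]:,.1f}",
            f"M_hat:        {self.M_hat:.4f}",
            f"L_hat:        {self.L_hat:.4f}",
            f"markers:      {self.n_snps}",
            f"lambda:       {self.lambda_stat:.3f}  "
            f"({self.settings.get('null_calibration', 'chi2')} reference)",
            f"P:            {self.p_value:.3g}",
            f"boundary optimum: {self.boundary}",
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            k: getattr(self, k)
            for k in (
                "S_hat_ldu",
                "S_hat_kb",
                "se_S_ldu",
                "M_hat",
                "L_hat",
                "rss_model",
                "rss_null",
                "lambda_stat",
                "df",
                "p_value",
                "n_snps",
                "boundary",
                "converged",
                "settings",
            )
        }
        payload["S_hat_kb_interval"] = list(self.S_hat_kb_interval)
        payload["ci95_kb"] = list(self.ci95_kb)
        if self.residuals is not None:
            payload["residuals"] = self.residuals.to_dict(orient="list")
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class MalecotLocationModel:
    """Weighted LS fit of the Malecot location model on the LDU scale.

    Parameters
    ----------
    z, n_used, positions_kb
        Per-SNP association magnitudes in [0, 1], sample sizes (rescaled
        to mean-one weights) and marker kb positions.
    ldu_map
        Fitted LDU map covering the window.
    window_kb
        (start, end) of the analytical window; markers outside are
        dropped and S is constrained inside it.
    score_corr
        Optional m x m correlation matrix of the per-SNP score statistics
        (attached to scan results as ``attrs["score_corr"]``); enables
        the Monte-Carlo null calibration.
    L_mode
        ``"fitted"`` profiles the baseline L_z freely; ``"predicted"``
        fixes it at the null expectation of |r|, ``sqrt(2 / (pi n))``
        averaged over markers.
    """

    def __init__(
        self,
        z: np.ndarray,
        n_used: np.ndarray,
        positions_kb: np.ndarray,
        ldu_map: LDUMap,
        window_kb: tuple[float, float] | None = None,
        grid_step_ldu: float = 0.05,
        min_snps: int = 10,
        score_corr: np.ndarray | None = None,
        L_mode: str = "fitted",
    ) -> None:
        z = np.asarray(z, float)
        n_used = np.asarray(n_used, float)
        pos = np.asarray(positions_kb, float)
        if L_mode not in ("fitted", "predicted"):
            raise InvalidConfigurationError("L_mode must be 'fitted' or 'predicted'")
        if window_kb is None:
            window_kb = (float(ldu_map.positions_kb[0]), float(ldu_map.positions_kb[-1]))
        lo = max(window_kb[0], float(ldu_map.positions_kb[0]))
        hi = min(window_kb[1], float(ldu_map.positions_kb[-1]))
        if not lo < hi:
            raise InvalidConfigurationError("window does not overlap the map")
        ok = np.isfinite(z) & (pos >= lo) & (pos <= hi)
        if ok.sum() < min_snps:
            raise InvalidConfigurationError(
                f"need >= {min_snps} SNPs with valid z inside the window"
            )
        self.map = ldu_map
        self.window_kb = (lo, hi)
        self._marker_mask = ok
        self.z = z[ok]
        self.pos = pos[ok]
        self.n_used = n_used[ok]
        self.w = self.n_used / self.n_used.mean()
        self.ldu = np.asarray(ldu_map.interpolate(self.pos), float)
        self.ldu_lo = float(ldu_map.interpolate(lo))
        self.ldu_hi = float(ldu_map.interpolate(hi))
        if self.ldu_hi - self.ldu_lo <= 1e-9:
            raise LocationUnidentifiableError(
                "window has no LDU extent; location is unidentifiable"
            )
        self.grid_step_ldu = float(grid_step_ldu)
        self.L_mode = L_mode
        self.L_fixed = (
            float(np.mean(np.sqrt(2.0 / (np.pi * self.n_used))))
            if L_mode == "predicted"
            else None
        )
        if score_corr is not None:
            score_corr = np.asarray(score_corr, float)
            if score_corr.shape[0] == ok.size:
                score_corr = score_corr[np.ix_(ok, ok)]
            if score_corr.shape != (self.z.size, self.z.size):
                raise InvalidConfigurationError("score_corr shape mismatch")
        self.score_corr = score_corr

    # -- profiled objective ----------------------------------------------
    def _profile_rss(self, s: np.ndarray, z: np.ndarray | None = None):
        """RSS minimised over (M, L_z) at each candidate S.

        Vectorised over both the grid of candidate locations and, when
        ``z`` is a (B, m) stack, over profile draws (for the null
        calibration).
        """
        s = np.atleast_1d(np.asarray(s, float))
        single = z is None
        Z = self.z[None, :] if single else np.atleast_2d(z)
        K = self.w
        E = np.exp(-np.abs(s[:, None] - self.ldu[None, :]))  # (G, m)
        sw = K.sum()
        sz = Z @ K  # (B,)
        szz = (Z * Z) @ K
        se_ = E @ K  # (G,)
        see = (E * E) @ K
        sez = E @ (K * Z).T  # (G, B)
        if self.L_fixed is None:
            det = sw * see - se_**2  # (G,)
            with np.errstate(divide="ignore", invalid="ignore"):
                M = (sw * sez - se_[:, None] * sz[None, :]) / np.where(
                    det > 1e-12, det, np.inf
                )[:, None]
                L = (sz[None, :] - M * se_[:, None]) / sw
            neg_m = M < 0
            M = np.where(neg_m, 0.0, M)
            L = np.where(neg_m, sz[None, :] / sw, L)
            neg_l = L < 0
            M = np.where(
                neg_l, np.maximum(sez / np.maximum(see, 1e-12)[:, None], 0.0), M
            )
            L = np.where(neg_l, 0.0, L)
        else:
            L = np.full((s.size, Z.shape[0]), self.L_fixed)
            M = (sez - self.L_fixed * se_[:, None]) / np.maximum(see, 1e-12)[:, None]
            M = np.maximum(M, 0.0)
        rss = (
            szz[None, :]
            - 2 * M * sez
            - 2 * L * sz[None, :]
            + M**2 * see[:, None]
            + 2 * M * L * se_[:, None]
            + L**2 * sw
        )
        if single:
            return rss[:, 0], M[:, 0], L[:, 0]
        return rss, M, L

    def rss_profile(self) -> pd.DataFrame:
        """RSS-vs-S profile over the search grid (for plotting)."""
        grid = self._grid()
        rss, M, L = self._profile_rss(grid)
        kb = [float(np.mean(self.map.invert(s))) for s in grid]
        return pd.DataFrame({"S_ldu": grid, "S_kb": kb, "rss": rss, "M": M, "L": L})

    def _grid(self) -> np.ndarray:
        span = self.ldu_hi - self.ldu_lo
        n = max(int(np.ceil(span / self.grid_step_ldu)) + 1, 25)
        return np.linspace(self.ldu_lo, self.ldu_hi, n)

    def _rss_null(self, z: np.ndarray | None = None):
        Z = self.z[None, :] if z is None else np.atleast_2d(z)
        K = self.w
        if self.L_fixed is None:
            zbar = (Z @ K) / K.sum()
            out = ((Z - zbar[:, None]) ** 2) @ K
        else:
            out = ((Z - self.L_fixed) ** 2) @ K
        return float(out[0]) if z is None else out

    @property
    def rss_null(self) -> float:
        return self._rss_null()

    def _argmin_S(self, refine: bool = True) -> tuple[float, float]:
        grid = self._grid()
        rss_g, _, _ = self._profile_rss(grid)
        k = int(np.argmin(rss_g))
        if not refine:
            return float(grid[k]), float(max(rss_g[k], 0.0))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        res = minimize_scalar(
            lambda s: float(self._profile_rss(np.array([s]))[0][0]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if res.fun <= rss_g[k]:
            return float(res.x), float(max(res.fun, 0.0))
        return float(grid[k]), float(max(rss_g[k], 0.0))

    def _lambda(self, rss_model: float, rss_null: float) -> float:
        sigma2 = rss_model / max(self.z.size - 3, 1)
        return max(rss_null - rss_model, 0.0) / max(sigma2, 1e-300)

    # -- null calibration -------------------------------------------------
    def simulate_null_lambdas(self, n_null: int, seed: int) -> np.ndarray:
        """Draw region statistics under the asymptotic null.

        Null z-profiles are |t| / sqrt(n) with t ~ MVN(0, R); lambda is
        recomputed for each draw with the same grid search used for the
        observed statistic.
        """
        if self.score_corr is None:
            raise InvalidConfigurationError("score_corr needed for the MVN null")
        R = np.nan_to_num(self.score_corr, nan=0.0)
        np.fill_diagonal(R, 1.0)
        vals, vecs = np.linalg.eigh(R)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        rng = np.random.default_rng(seed)
        T = rng.standard_normal((n_null, R.shape[0])) @ root.T
        Zs = np.abs(T) / np.sqrt(self.n_used)[None, :]
        grid = self._grid()
        rss, _, _ = self._profile_rss(grid, z=Zs)  # (G, B)
        rss_model = rss.min(axis=0)
        rss_null = self._rss_null(Zs)
        sigma2 = rss_model / max(self.z.size - 3, 1)
        return np.maximum(rss_null - rss_model, 0.0) / np.maximum(sigma2, 1e-300)

    def _null_pvalue(
        self, lam: float, calibration: str, n_null: int, seed: int
    ) -> float:
        if calibration == "chi2":
            return float(stats.chi2.sf(lam, 2))
        lams = self.simulate_null_lambdas(n_null, seed)
        mean, var = float(lams.mean()), float(lams.var())
        if var <= 1e-12:
            return float((1 + np.sum(lams >= lam)) / (n_null + 1))
        shape = mean**2 / var
        scale = var / mean
        return float(stats.gamma.sf(lam, shape, scale=scale))

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        null_calibration: str | None = None,
        n_null: int = 400,
        seed: int = 0,
        ci_method: str = "curvature",
    ) -> MalecotLocationFit:
        """Fit the model; see the module docstring for the test and CI.

        ``null_calibration`` defaults to ``"mvn"`` when the score
        correlation is available and ``"chi2"`` otherwise.
        """
        if null_calibration is None:
            null_calibration = "mvn" if self.score_corr is not None else "chi2"
        if null_calibration == "mvn" and self.score_corr is None:
            raise InvalidConfigurationError("MVN calibration needs score_corr")

        s_hat, rss_model = self._argmin_S()
        _, M_arr, L_arr = self._profile_rss(np.array([s_hat]))
        M_hat, L_hat = float(M_arr[0]), float(L_arr[0])
        rss_null = self.rss_null
        lam = self._lambda(rss_model, rss_null)
        p = self._null_pvalue(lam, null_calibration, n_null, seed)

        span = self.ldu_hi - self.ldu_lo
        boundary = (s_hat - self.ldu_lo < 1e-3 * span) or (
            self.ldu_hi - s_hat < 1e-3 * span
        )
        sigma2 = rss_model / max(self.z.size - 3, 1)
        se_s = self._curvature_se(s_hat, sigma2)
        s_lo = max(s_hat - 1.96 * se_s, 0.0)
        s_hi = min(s_hat + 1.96 * se_s, self.map.total_ldu)
        kb_int = self.map.invert(s_hat)
        ci_kb = (self.map.invert(s_lo)[0], self.map.invert(s_hi)[1])
        resid = pd.DataFrame(
            {
                "position_kb": self.pos,
                "ldu": self.ldu,
                "z": self.z,
                "fitted": M_hat * np.exp(-np.abs(s_hat - self.ldu)) + L_hat,
                "weight": self.w,
            }
        )
        return MalecotLocationFit(
            S_hat_ldu=s_hat,
            S_hat_kb=float(np.mean(kb_int)),
            S_hat_kb_interval=(float(kb_int[0]), float(kb_int[1])),
            se_S_ldu=se_s,
            ci95_kb=(float(ci_kb[0]), float(ci_kb[1])),
            M_hat=M_hat,
            L_hat=L_hat,
            rss_model=rss_model,
            rss_null=rss_null,
            lambda_stat=float(lam),
            df=2,
            p_value=p,
            n_snps=self.z.size,
            boundary=bool(boundary),
            converged=True,
            settings={
                "window_kb": list(self.window_kb),
                "grid_step_ldu": self.grid_step_ldu,
                "decay_per_ldu": 1.0,
                "null_calibration": null_calibration,
                "n_null": n_null if null_calibration == "mvn" else 0,
                "ci_method": ci_method,
                "L_mode": self.L_mode,
            },
            residuals=resid,
        )

    def _curvature_se(self, s_hat: float, sigma2: float) -> float:
        """SE of S from the local curvature of the profiled RSS.

        Optimistic whenever the profile has competing minima; kept as the
        no-raw-data fallback and for the plateau-free noiseless case.
        """
        for h in (self.grid_step_ldu, 2 * self.grid_step_ldu, 4 * self.grid_step_ldu):
            a = max(s_hat - h, self.ldu_lo)
            b = min(s_hat + h, self.ldu_hi)
            pts = np.array([a, (a + b) / 2, b])
            q = self._profile_rss(pts)[0]
            hh = (pts[2] - pts[0]) / 2
            if hh <= 0:
                continue
            curv = (q[0] - 2 * q[1] + q[2]) / hh**2
            if curv > 1e-10:
                return float(np.sqrt(2 * sigma2 / curv))
        return float(self.ldu_hi - self.ldu_lo)  # flat profile: maximal width

    @classmethod
    def from_scan(
        cls,
        scan: pd.DataFrame,
        ldu_map: LDUMap,
        window_kb: tuple[float, float] | None = None,
        **kwargs,
    ) -> "MalecotLocationModel":
        kwargs.setdefault("score_corr", scan.attrs.get("score_corr"))
        return cls(
            z=scan["z"].to_numpy(),
            n_used=scan["n_used"].to_numpy(),
            positions_kb=scan["position_kb"].to_numpy(),
            ldu_map=ldu_map,
            window_kb=window_kb,
            **kwargs,
        )


def _bootstrap_indices(
    rng: np.random.Generator,
    y: np.ndarray,
    binary: bool,
    cluster: np.ndarray | None,
) -> np.ndarray:
    n = y.size
    if cluster is not None:
        codes, _ = pd.factorize(np.asarray(cluster))
        groups = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
        pick = rng.integers(0, len(groups), len(groups))
        return np.concatenate([groups[k] for k in pick])
    if binary:
        cases = np.flatnonzero(y == 1)
        ctrls = np.flatnonzero(y == 0)
        return np.concatenate(
            [rng.choice(cases, cases.size), rng.choice(ctrls, ctrls.size)]
        )
    return rng.integers(0, n, n)


def fit_location_model(
    scan: pd.DataFrame,
    ldu_map: LDUMap,
    window_kb: tuple[float, float] | None = None,
    genotypes: GenotypeMatrix | None = None,
    phenotype: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    cluster: np.ndarray | None = None,
    n_boot: int = 0,
    seed: int = 0,
    **kwargs,
) -> MalecotLocationFit:
    """Fit the location model, optionally with a bootstrap CI for S.

    With ``n_boot > 0`` and raw ``genotypes``/``phenotype`` supplied, the
    scan and fit are repeated on ``n_boot`` case-resampled datasets
    (stratified by status for binary traits, by cluster when labels are
    given) and the 95% CI comes from the percentiles of the bootstrap
    S-hat distribution; ``se_S_ldu`` is then the bootstrap SD.
    """
    fit_opts = {
        k: kwargs.pop(k) for k in ("null_calibration", "n_null") if k in kwargs
    }
    model = MalecotLocationModel.from_scan(scan, ldu_map, window_kb, **kwargs)
    fit = model.fit(seed=seed, **fit_opts)
    if n_boot <= 0:
        return fit
    if genotypes is None or phenotype is None:
        raise InvalidConfigurationError("bootstrap CI needs genotypes and phenotype")

    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, float)
    vals = np.unique(y[~np.isnan(y)])
    binary = vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()
    G = genotypes.genotypes
    mask = model._marker_mask
    grid = model._grid()
    if not np.isnan(G).any() and not np.isnan(y).any():
        # fast path: fixed design matrix and grid kernel, z-only rescans
        from .scan import _design, _scan_z

        X = _design(covariates, y.size)
        Zs = np.empty((n_boot, int(mask.sum())))
        for b in range(n_boot):
            idx = _bootstrap_indices(rng, y, binary, cluster)
            zb = _scan_z(G[idx], y[idx], X[idx], binary)
            Zs[b] = np.nan_to_num(zb[mask])
        rss_b, _, _ = model._profile_rss(grid, z=Zs)  # (G, B)
        s_hats = grid[np.argmin(rss_b, axis=0)]
    else:
        s_hats = np.empty(n_boot)
        for b in range(n_boot):
            idx = _bootstrap_indices(rng, y, binary, cluster)
            cov_b = (
                covariates.iloc[idx].reset_index(drop=True)
                if covariates is not None
                else None
            )
            scan_b = single_snp_scan(
                genotypes.subset_individuals(idx), y[idx], covariates=cov_b
            )
            model_b = MalecotLocationModel.from_scan(
                scan_b, ldu_map, window_kb, **kwargs
            )
            s_hats[b], _ = model_b._argmin_S(refine=False)
    lo_l, hi_l = np.quantile(s_hats, [0.025, 0.975])
    lo_l = min(lo_l, fit.S_hat_ldu)
    hi_l = max(hi_l, fit.S_hat_ldu)
    fit.ci95_kb = (
        float(ldu_map.invert(lo_l)[0]),
        float(ldu_map.invert(hi_l)[1]),
    )
    fit.se_S_ldu = float(np.std(s_hats, ddof=1))
    fit.settings["ci_method"] = "bootstrap"
    fit.settings["n_boot"] = n_boot
    return fit


def permutation_pvalue(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    ldu_map: LDUMap,
    n_perm: int,
    seed: int,
    covariates: pd.DataFrame | None = None,
    cluster: np.ndarray | None = None,
    window_kb: tuple[float, float] | None = None,
    **kwargs,
) -> tuple[float, float, np.ndarray]:
    """Empirical region-test p by phenotype permutation.

    Permutes the phenotype (within equal-sized cluster blocks when
    ``cluster`` labels are given), reruns the scan and the location fit
    each time, and applies the add-one rule.  Returns ``(p_empirical,
    lambda_observed, permuted_lambdas)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse empirical p", stacklevel=2)
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, float)

    def region_lambda(yv: np.ndarray) -> float:
        scan = single_snp_scan(genotypes, yv, covariates=covariates)
        model = MalecotLocationModel.from_scan(scan, ldu_map, window_kb, **kwargs)
        _, rss_model = model._argmin_S(refine=False)
        return model._lambda(rss_model, model.rss_null)

    lam_obs = region_lambda(y)
    if cluster is not None:
        codes, _ = pd.factorize(np.asarray(cluster))
        groups = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
        by_size: dict[int, list[np.ndarray]] = {}
        for g in groups:
            by_size.setdefault(len(g), []).append(g)
    lams = np.empty(n_perm)
    for b in range(n_perm):
        if cluster is None:
            yp = rng.permutation(y)
        else:
            yp = y.copy()
            for same_size in by_size.values():
                src = np.concatenate(same_size)
                order = rng.permutation(len(same_size))
                dst = np.concatenate([same_size[i] for i in order])
                yp[dst] = y[src]
        lams[b] = region_lambda(yp)
    p_emp = (1.0 + np.sum(lams >= lam_obs)) / (n_perm + 1.0)
    return float(p_emp), float(lam_obs), lams


@dataclass
class LocationConcordance:
    """Cross-sample agreement of location fits on a shared kb axis."""

    delta_kb: pd.DataFrame
    ci_overlap: pd.DataFrame
    pooled_S_ldu: float
    pooled_se_ldu: float
    pooled_S_kb: float
    pooled_ci95_kb: tuple[float, float]

    def summary(self) -> str:
        off_diag = self.delta_kb.to_numpy()[np.triu_indices(len(self.delta_kb), 1)]
        return (
            "Location concordance across samples\n"
            f"max |dS|: {off_diag.max():,.1f} kb\n"
            f"pooled S: {self.pooled_S_kb:,.1f} kb "
            f"(95% CI {self.pooled_ci95_kb[0]:,.1f} - {self.pooled_ci95_kb[1]:,.1f})"
        )


def compare_locations(
    fits: list[MalecotLocationFit], reference_map: LDUMap | None = None
) -> LocationConcordance:
    """Pairwise |dS| (kb), CI overlap, and an inverse-variance pooled S.

    Pooling happens on the LDU scale of ``reference_map`` when given
    (fits from different population maps are first placed on it via their
    kb estimates); otherwise each fit's own LDU coordinate is used, which
    requires the fits to share one map.
    """
    if len(fits) < 2:
        raise IncomparableFitsError("need at least 2 fits to compare")
    windows = [tuple(f.settings.get("window_kb", (-np.inf, np.inf))) for f in fits]
    w_lo = max(w[0] for w in windows)
    w_hi = min(w[1] for w in windows)
    if w_lo >= w_hi:
        raise IncomparableFitsError("fits have disjoint analytical windows")

    n = len(fits)
    dmat = np.zeros((n, n))
    omat = np.zeros((n, n), bool)
    for a in range(n):
        for b in range(n):
            dmat[a, b] = abs(fits[a].S_hat_kb - fits[b].S_hat_kb)
            omat[a, b] = not (
                fits[a].ci95_kb[1] < fits[b].ci95_kb[0]
                or fits[b].ci95_kb[1] < fits[a].ci95_kb[0]
            )
    names = [f"fit{k + 1}" for k in range(n)]
    delta = pd.DataFrame(dmat, index=names, columns=names)
    overlap = pd.DataFrame(omat, index=names, columns=names)

    if reference_map is not None:
        s_ldu = np.array([reference_map.interpolate(f.S_hat_kb) for f in fits])
        the_map = reference_map
    else:
        s_ldu = np.array([f.S_hat_ldu for f in fits])
        the_map = None
    var = np.array([max(f.se_S_ldu, 1e-9) ** 2 for f in fits])
    wts = 1.0 / var
    pooled = float(np.sum(wts * s_ldu) / wts.sum())
    pooled_se = float(np.sqrt(1.0 / wts.sum()))
    if the_map is None:
        kb_pooled = float(
            np.sum(wts * np.array([f.S_hat_kb for f in fits])) / wts.sum()
        )
        half = 1.96 * pooled_se * _kb_per_ldu(fits)
        return LocationConcordance(
            delta, overlap, pooled, pooled_se, kb_pooled,
            (kb_pooled - half, kb_pooled + half),
        )
    pooled = min(max(pooled, 0.0), the_map.total_ldu)
    kb_int = the_map.invert(pooled)
    lo_kb = the_map.invert(max(pooled - 1.96 * pooled_se, 0.0))[0]
    hi_kb = the_map.invert(min(pooled + 1.96 * pooled_se, the_map.total_ldu))[1]
    return LocationConcordance(
        delta, overlap, pooled, pooled_se, float(np.mean(kb_int)), (lo_kb, hi_kb)
    )


def _kb_per_ldu(fits: list[MalecotLocationFit]) -> float:
    """Crude kb-per-LDU scale from each fit's own CI, for map-less pooling."""
    scales = []
    for f in fits:
        if f.se_S_ldu > 0:
            scales.append(f.ci95_width_kb / (2 * 1.96 * f.se_S_ldu))
    return float(np.median(scales)) if scales else 1.0
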