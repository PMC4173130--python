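"""Per-SNP association scans and trait preprocessing.

Quantitative traits use ordinary least squares on additive dosage with
optional covariates; binary traits use the logistic score test against a
covariate-only null (equivalent to one Newton step of the full logistic
fit, and fast enough to run per SNP across a window).  Family/twin
structure is handled with cluster-robust (sandwich) standard errors over
``cluster_id`` rather than a variance-components fit: the point estimates
are identical and no covariance structure needs to be assumed.

The association magnitude fed to the location model is ``z = |r|``, the
absolute (partial) phenotype-genotype correlation, a common [0, 1] scale
for quantitative and case-control inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data import GenotypeMatrix
from .exceptions import DegenerateInputError, StratificationError

__all__ = [
    "single_snp_scan",
    "candidate_snp_models",
    "mean_correct",
    "inverse_normal_transform",
    "CandidateModelResult",
]


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal scores with the Blom offset.

    Maps value ranks to ``Phi^-1((rank - 3/8) / (n + 1/4))``; ties share
    averaged ranks and NaNs are preserved.  Any monotone transform of the
    input yields identical output.
    """
    v = np.asarray(values, float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    x = v[ok]
    if x.size < 10:
        raise DegenerateInputError("need at least 10 non-missing values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical; transform undefined")
    ranks = stats.rankdata(x, method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
    return out


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept + covariates, with year/batch expanded to dummies."""
    cols = [np.ones(n)]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if name in ("year", "batch") or col.dtype == object:
                dummies = pd.get_dummies(col, drop_first=True).to_numpy(float)
                if dummies.size:
                    cols.append(dummies)
            else:
                cols.append(col.to_numpy(float)[:, None])
    X = np.column_stack(cols)
    # drop collinear columns via QR rank reveal
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
    return X[:, keep]


def mean_correct(
    trait: np.ndarray, covariates: pd.DataFrame
) -> tuple[np.ndarray, float]:
    """Residualise a trait on covariates; returns (residuals, R^2)."""
    y = np.asarray(trait, float)
    ok = ~np.isnan(y)
    X = _design(covariates, y.size)
    if X.shape[1] < 2:
        raise DegenerateInputError("need at least 2 distinct covariate patterns")
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    fitted = X[ok] @ beta
    resid = np.full(y.shape, np.nan)
    resid[ok] = y[ok] - fitted
    tss = float(np.sum((y[ok] - y[ok].mean()) ** 2))
    rss = float(np.sum(resid[ok] ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return resid, float(np.clip(r2, 0.0, 1.0))


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project columns of M off the span of X."""
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Plain Newton/IRLS logistic fit (small fixed design)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        grad = X.T @ (y - p)
        H = X.T @ (X * w[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _scan_z(G: np.ndarray, y: np.ndarray, X: np.ndarray, binary: bool) -> np.ndarray:
    """Fast |partial correlation|-scale z for a complete-data matrix.

    Matches the z of :func:`single_snp_scan` for NaN-free genotypes; used
    by the location model's bootstrap where the full scan's bookkeeping
    would dominate the runtime.
    """
    if binary:
        beta0 = _logistic_irls(X, y)
        p0 = 1.0 / (1.0 + np.exp(-(X @ beta0)))
        w = p0 * (1 - p0)
        resid = y - p0
        Xw = X * w[:, None]
        XtWX_inv = np.linalg.inv(X.T @ Xw)
        GtWX = G.T @ Xw
        U = G.T @ resid
        V = (G * G * w[:, None]).sum(axis=0) - np.einsum(
            "mp,pq,mq->m", GtWX, XtWX_inv, GtWX
        )
        z = np.where(V > 1e-10, U * U / np.maximum(V, 1e-10), 0.0)
        return np.sqrt(np.clip(z / y.size, 0.0, 1.0))
    yr = _residualize(y[:, None], X)[:, 0]
    Gr = _residualize(G, X)
    sy = float(np.sqrt(np.sum(yr**2)))
    sg = np.sqrt(np.sum(Gr**2, axis=0))
    ok = (sg > 1e-10) & (sy > 0)
    r = np.zeros(G.shape[1])
    r[ok] = (Gr[:, ok].T @ yr) / (sg[ok] * sy)
    return np.clip(np.abs(r), 0.0, 1.0)


def _cluster_se(
    scores: np.ndarray, bread: np.ndarray, cluster: np.ndarray
) -> np.ndarray:
    """Sandwich SE for scalar per-SNP slopes; scores (n, m), bread (m,)."""
    codes, _ = pd.factorize(cluster)
    C = codes.max() + 1
    sums = np.zeros((C, scores.shape[1]))
    np.add.at(sums, codes, scores)
    meat = np.sum(sums**2, axis=0)
    dfc = C / max(C - 1, 1)
    return np.sqrt(dfc * meat) / bread


def single_snp_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    binary: bool | None = None,
    cluster: np.ndarray | None = None,
    cluster_aware: bool = False,
    min_n: int = 30,
) -> pd.DataFrame:
    """Additive-coding association for every SNP.

    Returns a DataFrame with one row per SNP: ``snp_id, position_kb,
    beta, se, chi2, p_value, z, n_used, flag``.  Monomorphic SNPs are
    kept as rows but flagged ``"monomorphic"`` with NaN statistics;
    likewise ``"separation"`` for degenerate logistic fits and
    ``"low_n"`` below ``min_n`` complete pairs.
    """
    y = np.asarray(phenotype, float)
    G = genotypes.genotypes
    n, m = G.shape
    if y.size != n:
        raise DegenerateInputError("phenotype length does not match genotypes")
    if binary is None:
        vals = np.unique(y[~np.isnan(y)])
        binary = vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()
    if cluster_aware and cluster is None:
        raise DegenerateInputError("cluster_aware=True requires cluster labels")

    ok = ~np.isnan(y)
    if covariates is not None:
        cov_arr = covariates.select_dtypes(include=[np.number]).to_numpy(float)
        ok &= ~np.isnan(cov_arr).any(axis=1)
    Gna = np.isnan(G)
    have_missing_g = Gna.any()

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    chi2 = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    zmag = np.full(m, np.nan)
    n_used = np.zeros(m, int)
    flag = np.array([""] * m, dtype=object)

    yv = y[ok]
    X = _design(covariates.loc[ok] if covariates is not None else None, int(ok.sum()))
    Gv = G[ok]
    if have_missing_g:
        Gv = np.where(np.isnan(Gv), np.nanmean(Gv, axis=0), Gv)
        # complete-case counts still reported; mean imputation only enters
        # the vectorised path when missingness was explicitly injected
    n_used[:] = (~Gna[ok]).sum(axis=0)

    mono = np.nanstd(G[ok], axis=0) == 0
    low = n_used < min_n
    flag[mono] = "monomorphic"
    flag[low & ~mono] = "low_n"
    use = ~(mono | low)

    if binary:
        if np.unique(yv).size < 2:
            raise DegenerateInputError("binary phenotype has a single class")
        fam = sm.families.Binomial()
        null = sm.GLM(yv, X, family=fam).fit()
        p0 = null.fittedvalues
        w = p0 * (1 - p0)
        resid = yv - p0
        Xw = X * w[:, None]
        XtWX_inv = np.linalg.inv(X.T @ Xw)
        GtWX = Gv.T @ Xw  # (m, p)
        U = Gv.T @ resid
        V = (Gv * Gv * w[:, None]).sum(axis=0) - np.einsum(
            "mp,pq,mq->m", GtWX, XtWX_inv, GtWX
        )
        good = use & (V > 1e-10)
        flag[use & ~good] = "separation"
        chi2[good] = U[good] ** 2 / V[good]
        beta[good] = U[good] / V[good]  # one-step estimate
        if cluster_aware:
            # sandwich over the efficient per-individual scores
            scores = (Gv - (GtWX @ XtWX_inv @ Xw.T).T) * resid[:, None]
            se_beta = _cluster_se(scores, V, np.asarray(cluster)[ok])
            se[good] = se_beta[good]
            chi2[good] = (beta[good] / se_beta[good]) ** 2
        else:
            se[good] = 1.0 / np.sqrt(V[good])
        pval[good] = stats.chi2.sf(chi2[good], 1)
        zmag[good] = np.sqrt(chi2[good] / n_used[good])
    else:
        yr = _residualize(yv[:, None], X)[:, 0]
        Gr = _residualize(Gv, X)
        sy = float(np.sqrt(np.sum(yr**2)))
        sg = np.sqrt(np.sum(Gr**2, axis=0))
        good = use & (sg > 1e-10) & (sy > 0)
        r = np.zeros(m)
        r[good] = (Gr[:, good].T @ yr) / (sg[good] * sy)
        df = yv.size - X.shape[1] - 1
        t = r * np.sqrt(np.maximum(df, 1) / np.maximum(1 - r**2, 1e-12))
        beta[good] = (Gr[:, good].T @ yr) / (sg[good] ** 2)
        if cluster_aware:
            e = yr[:, None] - Gr * beta[np.newaxis, :]
            scores = Gr * e
            se[good] = _cluster_se(scores[:, good], (sg[good] ** 2), np.asarray(cluster)[ok])
            tt = beta[good] / se[good]
            chi2[good] = tt**2
            pval[good] = stats.chi2.sf(chi2[good], 1)
        else:
            se[good] = np.abs(beta[good] / np.where(t[good] == 0, np.inf, t[good]))
            se[good] = np.where(
                t[good] == 0, sy / (sg[good] * np.sqrt(max(df, 1))), se[good]
            )
            chi2[good] = t[good] ** 2
            pval[good] = 2 * stats.t.sf(np.abs(t[good]), max(df, 1))
        zmag[good] = np.abs(r[good])

    zmag = np.clip(zmag, 0.0, 1.0)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "position_kb": genotypes.positions_kb,
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p_value": pval,
            "z": zmag,
            "n_used": n_used,
            "flag": flag,
        }
    )
    # correlation of the per-SNP score statistics (the residualised,
    # variance-weighted dosages); the location model uses it to simulate
    # the null distribution of its region statistic
    if binary:
        Geff = (Gv - (GtWX @ XtWX_inv @ Xw.T).T) * np.sqrt(w)[:, None]
    else:
        Geff = Gr
    good_idx = np.flatnonzero(good)
    R = np.full((m, m), np.nan)
    if good_idx.size >= 2:
        R[np.ix_(good_idx, good_idx)] = np.corrcoef(Geff[:, good_idx], rowvar=False)
    out.attrs["score_corr"] = R
    return out


@dataclass
class CandidateModelResult:
    """Main-effect and SNP-by-age interaction analyses for one candidate SNP."""

    binary: bool
    beta_snp: float
    se_snp: float
    p_snp: float
    beta_age: float
    se_age: float
    p_age: float
    slope_ref: float  # age slope within the reference (dosage 0) stratum
    se_ref: float
    slope_alt: float  # age slope within the pooled carrier stratum
    se_alt: float
    wald_chi2: float
    wald_p: float
    n_used: int

    @property
    def odds_ratio_snp(self) -> float | None:
        return float(np.exp(self.beta_snp)) if self.binary else None

    def summary(self) -> str:
        kind = "logistic" if self.binary else "linear"
        lines = [
            f"Candidate-SNP biometric model ({kind}), n = {self.n_used}",
            "Panel A (main effect, adjusted for age and year of visit):",
            f"  SNP    beta = {self.beta_snp:+.4f}  SE = {self.se_snp:.4f}  "
            f"P = {self.p_snp:.3g}",
            f"  age    beta = {self.beta_age:+.4f}  SE = {self.se_age:.4f}  "
            f"P = {self.p_age:.3g}",
            "Panel B (age slopes by genotype stratum):",
            f"  ref homozygotes   slope = {self.slope_ref:+.4f}  SE = {self.se_ref:.4f}",
            f"  carriers          slope = {self.slope_alt:+.4f}  SE = {self.se_alt:.4f}",
            f"  Wald chi2_1 = {self.wald_chi2:.3f}  P = {self.wald_p:.3g}",
        ]
        if self.binary:
            lines.insert(3, f"  SNP    OR = {self.odds_ratio_snp:.3f}")
        return "\n".join(lines)


def candidate_snp_models(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    age: np.ndarray,
    year_of_visit: np.ndarray,
    binary: bool | None = None,
) -> CandidateModelResult:
    """Main-effect and stratified-interaction models for a candidate SNP.

    Panel A regresses the phenotype on dosage adjusted for age and
    year-of-visit.  Panel B fits a single interaction model giving the
    age slope within the reference-homozygote stratum and within the
    pooled carrier (dosage 1 or 2) stratum, plus a Wald chi^2_1 contrast
    of the two slopes.
    """
    df = pd.DataFrame(
        {
            "g": np.asarray(genotype, float),
            "y": np.asarray(phenotype, float),
            "age": np.asarray(age, float),
            "year": pd.Categorical(year_of_visit),
        }
    ).dropna()
    if binary is None:
        vals = df["y"].unique()
        binary = vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()
    df["strat"] = np.where(df["g"] > 0, "carrier", "ref")
    if (df["strat"] == "ref").sum() == 0 or (df["strat"] == "carrier").sum() == 0:
        raise StratificationError("a genotype stratum is empty")

    fit_fn = smf.logit if binary else smf.ols
    main = fit_fn("y ~ g + age + C(year)", data=df).fit(disp=0) if binary else fit_fn(
        "y ~ g + age + C(year)", data=df
    ).fit()
    inter = (
        fit_fn("y ~ C(strat) + C(strat):age + C(year)", data=df).fit(disp=0)
        if binary
        else fit_fn("y ~ C(strat) + C(strat):age + C(year)", data=df).fit()
    )
    name_ref = 'C(strat)[ref]:age'
    name_alt = 'C(strat)[carrier]:age'
    wald = inter.wald_test(f"{name_ref} = {name_alt}", use_f=False, scalar=True)
    return CandidateModelResult(
        binary=bool(binary),
        beta_snp=float(main.params["g"]),
        se_snp=float(main.bse["g"]),
        p_snp=float(main.pvalues["g"]),
        beta_age=float(main.params["age"]),
        se_age=float(main.bse["age"]),
        p_age=float(main.pvalues["age"]),
        slope_ref=float(inter.params[name_ref]),
        se_ref=float(inter.bse[name_ref]),
        slope_alt=float(inter.params[name_alt]),
        se_alt=float(inter.bse[name_alt]),
        wald_chi2=float(wald.statistic),
        wald_p=float(wald.pvalue),
        n_used=int(len(df)),
    )
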