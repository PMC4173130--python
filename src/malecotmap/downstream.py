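"""Downstream statistics: meta-analysis, the eQTL cascade and corrections.

Covers Fisher's method for combining per-sample region p-values, running
the Malecot location machinery on batch-residualised expression probes,
the probe-to-phenotype regression cascade (univariate and conditional),
the effective-number-of-tests multiplicity correction, and the
expression-quartile disease-prevalence contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import ExpressionMatrix, GenotypeMatrix
from .exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidConfigurationError,
)
from .ldu import LDUMap
from .location import MalecotLocationFit, fit_location_model
from .scan import single_snp_scan

__all__ = [
    "MetaResult",
    "fisher_combine",
    "eqtl_probe_scan",
    "probe_phenotype_cascade",
    "CascadeResult",
    "effective_tests",
    "EffectiveTests",
    "quartile_prevalence",
    "QuartilePrevalence",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class MetaResult:
    """Fisher's-method combination of k independent p-values."""

    chi2: float
    df: int
    p_combined: float
    k: int

    def summary(self) -> str:
        return (
            f"Fisher meta-analysis of {self.k} p-values: "
            f"chi2_{self.df} = {self.chi2:.2f}, combined P = {self.p_combined:.3g}"
        )


def fisher_combine(p_values) -> MetaResult:
    """chi2 = -2 sum ln p on 2k df; assumes the p-values are independent."""
    p = np.asarray(list(p_values), float)
    if p.size < 2:
        raise InvalidConfigurationError("need at least 2 p-values to combine")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise InvalidConfigurationError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return MetaResult(chi2=chi2, df=df, p_combined=float(stats.chi2.sf(chi2, df)), k=p.size)


def _residualize_on_batch(values: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Residuals of a vector on batch dummies; no-op for a single level."""
    levels = pd.unique(batch)
    if levels.size < 2:
        return values - values.mean()
    X = pd.get_dummies(pd.Categorical(batch)).to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def eqtl_probe_scan(
    genotypes: GenotypeMatrix,
    expression: pd.Series | np.ndarray,
    ldu_map: LDUMap,
    batch: np.ndarray | pd.Series | None = None,
    window_kb: tuple[float, float] | None = None,
    min_individuals: int = 100,
    **fit_kwargs,
) -> MalecotLocationFit:
    """Locate a regulatory variant for one expression probe.

    The probe is residualised on recorded experimental batch, then passed
    through the ordinary per-SNP scan and the Malecot location fit
    unchanged, so an eQTL is mapped with exactly the machinery used for
    disease and quantitative traits.
    """
    e = np.asarray(expression, float)
    if np.sum(~np.isnan(e)) < min_individuals:
        raise DegenerateInputError(
            f"probe measured for fewer than {min_individuals} genotyped individuals"
        )
    if batch is not None:
        e = _residualize_on_batch(e, np.asarray(batch))
    scan = single_snp_scan(genotypes, e)
    return fit_location_model(scan, ldu_map, window_kb, **fit_kwargs)


@dataclass
class CascadeResult:
    """Univariate (A) and conditional (B) probe-phenotype regressions."""

    panel_a: pd.DataFrame
    panel_b: pd.DataFrame
    focal_probe: str
    conditional_probes: list[str]
    alpha: float

    def retained_probes(self, phenotype: str) -> list[str]:
        sub = self.panel_b[self.panel_b["phenotype"] == phenotype]
        return list(sub.loc[sub["p_value"] < self.alpha, "probe"])

    def summary(self) -> str:
        lines = ["Probe-phenotype cascade", "=" * 40, "Panel A (univariate):"]
        lines.append(self.panel_a.to_string(index=False, float_format="%.4g"))
        lines.append("Panel B (conditional on co-entered probes):")
        lines.append(self.panel_b.to_string(index=False, float_format="%.4g"))
        return "\n".join(lines)


def _one_regression(
    y: np.ndarray, probes: pd.DataFrame, covars: pd.DataFrame, binary: bool
) -> pd.DataFrame:
    X = pd.concat([probes, covars], axis=1)
    X = sm.add_constant(X.astype(float), has_constant="add")
    ok = ~(np.isnan(y) | np.isnan(X.to_numpy()).any(axis=1))
    if binary:
        model = sm.Logit(y[ok], X.loc[ok])
        res = model.fit(disp=0, maxiter=200)
    else:
        res = sm.OLS(y[ok], X.loc[ok]).fit()
    rows = []
    for name in probes.columns:
        b = float(res.params[name])
        s = float(res.bse[name])
        rows.append(
            {
                "probe": name,
                "beta": b,
                "se": s,
                "p_value": float(res.pvalues[name]),
                "odds_ratio": float(np.exp(b)) if binary else np.nan,
                "or_ci95_low": float(np.exp(b - 1.96 * s)) if binary else np.nan,
                "or_ci95_high": float(np.exp(b + 1.96 * s)) if binary else np.nan,
                "n_used": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def probe_phenotype_cascade(
    expression: ExpressionMatrix,
    phenotypes: pd.DataFrame,
    focal_probe: str,
    phenotype_columns: list[str],
    conditional_probes: list[str] | None = None,
    alpha: float = 0.05,
    covariate_columns: tuple[str, ...] = ("age",),
) -> CascadeResult:
    """Regress each phenotype on each probe (A), then conditionally (B).

    Panel A fits ``phenotype ~ probe + age + batch`` for every probe and
    phenotype (logistic when the phenotype is binary 0/1).  Panel B
    refits each phenotype on the focal probe plus the other probes that
    were nominally significant for it in Panel A (or an explicit
    ``conditional_probes`` list), flagging which survive conditioning.
    Wald odds-ratio intervals ``exp(b +/- 1.96 SE)`` are attached for
    binary phenotypes.
    """
    shared = [i for i in expression.individual_ids if i in set(phenotypes["individual_id"])]
    if len(shared) < 100:
        raise InvalidConfigurationError("probes and phenotypes share < 100 individuals")
    ph = phenotypes.set_index("individual_id").loc[shared]
    probes_all = expression.values[shared].T  # individuals x probes
    batch = pd.get_dummies(
        pd.Categorical(expression.batch.loc[shared]), drop_first=True, prefix="batch"
    )
    covars = pd.concat(
        [ph[[c for c in covariate_columns if c in ph.columns]].reset_index(drop=True),
         batch.reset_index(drop=True)],
        axis=1,
    )
    if focal_probe not in probes_all.columns:
        raise InvalidConfigurationError(f"unknown focal probe {focal_probe!r}")

    rows_a = []
    for pheno in phenotype_columns:
        y = ph[pheno].to_numpy(float)
        vals = np.unique(y[~np.isnan(y)])
        binary = vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()
        for probe in probes_all.columns:
            one = _one_regression(
                y,
                probes_all[[probe]].reset_index(drop=True),
                covars,
                binary,
            )
            one.insert(0, "phenotype", pheno)
            one["binary"] = binary
            rows_a.append(one)
    panel_a = pd.concat(rows_a, ignore_index=True)

    rows_b = []
    cond_used: set[str] = set()
    for pheno in phenotype_columns:
        sub = panel_a[panel_a["phenotype"] == pheno]
        binary = bool(sub["binary"].iloc[0])
        if conditional_probes is None:
            extra = [
                p
                for p in sub.loc[sub["p_value"] < alpha, "probe"]
                if p != focal_probe
            ]
        else:
            extra = [p for p in conditional_probes if p != focal_probe]
        cond_used.update(extra)
        cols = [focal_probe] + extra
        sel = probes_all[cols].reset_index(drop=True)
        if extra:
            corr = sel.corr().to_numpy()
            off = np.abs(corr[0, 1:])
            if np.any(off > 0.99):
                raise CollinearityError(
                    "conditional probe nearly collinear with the focal probe"
                )
        y = ph[pheno].to_numpy(float)
        one = _one_regression(y, sel, covars, binary)
        one.insert(0, "phenotype", pheno)
        one["binary"] = binary
        rows_b.append(one)
    panel_b = pd.concat(rows_b, ignore_index=True)
    return CascadeResult(
        panel_a=panel_a,
        panel_b=panel_b,
        focal_probe=focal_probe,
        conditional_probes=sorted(cond_used),
        alpha=alpha,
    )


@dataclass(frozen=True)
class EffectiveTests:
    """Effective number of independent tests among correlated measures."""

    m_eff_raw: float
    m_eff: int
    corrected_alpha: float
    estimator: str = "eigenvalue-dispersion (1 + (d-1)(1 - Var(lambda)/d), floored)"


def effective_tests(
    correlation_matrix: np.ndarray, family_alpha: float = 0.05, cross_factor: int = 1
) -> EffectiveTests:
    """Eigenvalue-dispersion estimate of the effective test count.

    ``M_eff = 1 + (d - 1) * (1 - Var(lambda)/d)`` over the eigenvalues of
    the correlation matrix, rounded down to an integer (identity -> d;
    perfect correlation -> 1).  ``corrected_alpha`` divides the family
    alpha by ``M_eff * cross_factor`` so two crossed families (e.g.
    probes x phenotypes) multiply their effective counts.
    """
    R = np.asarray(correlation_matrix, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InvalidConfigurationError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise InvalidConfigurationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise InvalidConfigurationError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(R)
    if lam.min() < -1e-8:
        raise InvalidConfigurationError("correlation matrix is not positive semidefinite")
    d = R.shape[0]
    var = float(np.var(lam))  # population variance, denominator d
    m_raw = 1.0 + (d - 1.0) * (1.0 - var / d)
    m_eff = int(np.floor(m_raw + 1e-9))
    m_eff = int(np.clip(m_eff, 1, d))
    return EffectiveTests(
        m_eff_raw=float(m_raw),
        m_eff=m_eff,
        corrected_alpha=family_alpha / (m_eff * cross_factor),
    )


@dataclass(frozen=True)
class QuartilePrevalence:
    """Disease prevalence by expression quartile with a 3-df chi-square."""

    counts: np.ndarray  # (4, 2) quartile x (controls, cases)
    prevalence: np.ndarray  # (4,)
    chi2: float
    df: int
    p_value: float

    def summary(self) -> str:
        rows = [
            f"  Q{q + 1}: n = {int(self.counts[q].sum()):4d}  "
            f"prevalence = {100 * self.prevalence[q]:.1f}%"
            for q in range(4)
        ]
        return (
            "Prevalence by expression quartile\n"
            + "\n".join(rows)
            + f"\n  chi2_{self.df} = {self.chi2:.2f}, P = {self.p_value:.3g}"
        )


def quartile_prevalence(
    expression: np.ndarray, status: np.ndarray
) -> QuartilePrevalence:
    """Cut at quartile boundaries (ties to the lower quartile) and test.

    The 4 x 2 quartile-by-status table is tested with a 3-df chi-square;
    the headline contrast is top- versus bottom-quartile prevalence.
    """
    e = np.asarray(expression, float)
    s = np.asarray(status, float)
    ok = ~(np.isnan(e) | np.isnan(s))
    e, s = e[ok], s[ok]
    if e.size < 40:
        raise DegenerateInputError("need at least 40 individuals")
    if np.unique(s).size < 2:
        raise DegenerateInputError("both disease classes must be present")
    bounds = np.quantile(e, [0.25, 0.5, 0.75])
    q = np.searchsorted(bounds, e, side="left")  # ties fall to the lower quartile
    counts = np.zeros((4, 2))
    np.add.at(counts, (q, s.astype(int)), 1)
    if np.any(counts.sum(axis=1) == 0):
        raise DegenerateInputError("a quartile is empty after tie-handling")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    prev = counts[:, 1] / counts.sum(axis=1)
    return QuartilePrevalence(
        counts=counts, prevalence=prev, chi2=float(chi2), df=int(df), p_value=float(p)
    )


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Plain Bonferroni: family alpha divided by the number of tests."""
    if n_tests < 1:
        raise InvalidConfigurationError("n_tests must be >= 1")
    if not (0 < family_alpha < 1):
        raise InvalidConfigurationError("family_alpha must be in (0, 1)")
    return family_alpha / n_tests
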