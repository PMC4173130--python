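"""Synthetic genotype / phenotype / expression generator.

The generator emulates the data a candidate-gene fine-mapping study of a
~800 kb window would see: 100-200 SNPs whose linkage disequilibrium has a
block-step structure (LD blocks separated by recombination hotspots),
one planted causal variant that both raises disease risk and up-regulates
an expression probe, and phenotype tables with age / sex / year-of-visit /
batch covariate structure.

Haplotypes come from a first-order Markov "lineage retention" process:
each haplotype carries a latent uniform variate along the chromosome which
survives interval ``k`` with probability ``exp(-eps_k * d_k)``; alleles are
thresholded from the surviving variate.  Under this construction the
expected signed D' between markers ``i < j`` is exactly
``exp(-sum_k eps_k d_k)``, i.e. the Malecot decline with amplitude M = 1
and baseline L = 0, which is the model the map-fitting stage assumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data import ExpressionMatrix, GenotypeMatrix
from .exceptions import GenerationFailureError, InvalidConfigurationError

__all__ = [
    "RecombinationProfile",
    "HaplotypePanel",
    "TruthRecord",
    "CovariateSpec",
    "simulate_recombination_profile",
    "simulate_haplotypes",
    "pair_haplotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_case_control",
    "add_twin_structure",
    "simulate_cascade_dataset",
]


@dataclass(frozen=True)
class RecombinationProfile:
    """True per-interval LD decay rates for a marker grid.

    ``epsilon_true[k]`` is the decay rate (per kb) on the interval between
    markers ``k`` and ``k+1``; zero inside blocks, large at hotspot steps.
    """

    positions_kb: np.ndarray
    epsilon_true: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions_kb", np.asarray(self.positions_kb, float))
        object.__setattr__(self, "epsilon_true", np.asarray(self.epsilon_true, float))
        if self.epsilon_true.size != self.positions_kb.size - 1:
            raise InvalidConfigurationError("need one epsilon per inter-marker interval")
        if np.any(self.epsilon_true < 0):
            raise InvalidConfigurationError("epsilon_true must be >= 0")
        if np.any(np.diff(self.positions_kb) <= 0):
            raise InvalidConfigurationError("positions must be strictly increasing")

    @property
    def interval_start_kb(self) -> np.ndarray:
        return self.positions_kb[:-1]

    @property
    def interval_length_kb(self) -> np.ndarray:
        return np.diff(self.positions_kb)

    @property
    def cumulative_ldu(self) -> np.ndarray:
        """True cumulative map: 0 at the first marker, then sum eps*d."""
        return np.concatenate(
            ([0.0], np.cumsum(self.epsilon_true * self.interval_length_kb))
        )

    @property
    def total_ldu(self) -> float:
        return float(self.cumulative_ldu[-1])


@dataclass(frozen=True)
class HaplotypePanel:
    """Binary haplotype alleles (haplotype x SNP) with realised frequencies."""

    alleles: np.ndarray
    positions_kb: np.ndarray
    allele_freqs: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for the planted causal variant."""

    causal_index: int
    causal_kb: float
    beta_pheno: float = 0.0
    beta_expr: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate effect sizes for the phenotype models.

    Defaults follow the candidate-SNP biometric model: fasting-insulin-like
    traits gain 0.12 units per year of age and disease log-odds grow by
    ln(1.04) per year.  ``noise_sd`` is the residual SD of quantitative
    traits (trait units).
    """

    age_beta: float = 0.12
    age_log_or: float = float(np.log(1.04))
    sex_beta: float = 0.0
    year_effects: tuple[float, ...] = (0.0, 0.2, -0.1, 0.15, -0.05)
    batch_sd: float = 0.3
    noise_sd: float = 1.0
    age_mean: float = 55.0
    age_sd: float = 10.0
    n_batches: int = 4

    @classmethod
    def insulin_like(cls) -> "CovariateSpec":
        """Residual SD calibrated so age/sex/year explain R^2 ~= 0.18.

        With age SD 10 and slope 0.12/year the covariates contribute
        variance ~1.45; solving R^2 = v / (v + noise^2) = 0.18 gives
        noise_sd ~= 2.57.
        """
        v = 0.12**2 * 10.0**2 + np.var([0.0, 0.2, -0.1, 0.15, -0.05])
        noise = float(np.sqrt(v * (1 - 0.18) / 0.18))
        return cls(noise_sd=noise)


def simulate_recombination_profile(
    n_snps: int,
    region_kb: float,
    n_blocks: int,
    step_ldu_total: float,
    seed: int,
    start_kb: float = 184_743.0,
    background_fraction: float = 0.0,
) -> RecombinationProfile:
    """Lay down a block-step decay profile across a marker grid.

    Markers sit on a jittered even grid spanning ``region_kb``.  The
    ``n_blocks`` LD blocks are separated by ``n_blocks - 1`` hotspot
    intervals; the total map length ``sum eps_k d_k`` equals
    ``step_ldu_total`` exactly (e.g. 10 LDU for a European-like window,
    17 for an African-like one).  ``background_fraction`` of that total
    is spread uniformly per kb across the whole region, mimicking the
    low-rate LD breakdown real maps show between hotspots; the remainder
    is concentrated in the hotspot steps.
    """
    if n_snps < 3:
        raise InvalidConfigurationError("need at least 3 SNPs")
    if region_kb <= 0:
        raise InvalidConfigurationError("region_kb must be positive")
    if step_ldu_total < 0:
        raise InvalidConfigurationError("step_ldu_total must be >= 0")
    if n_blocks < 1 or n_blocks > n_snps - 1:
        raise InvalidConfigurationError(
            f"n_blocks must be in [1, n_snps-1]; got {n_blocks} for {n_snps} SNPs"
        )
    if n_blocks == 1 and step_ldu_total > 0:
        raise InvalidConfigurationError("a single block cannot carry any map length")

    rng = np.random.default_rng(seed)
    gap = region_kb / n_snps
    grid = start_kb + gap / 2.0 + gap * np.arange(n_snps)
    positions = grid + rng.uniform(-0.4 * gap, 0.4 * gap, size=n_snps)
    positions = np.sort(positions)
    # enforce strict increase at bp resolution
    positions = np.maximum.accumulate(positions + 1e-3 * np.arange(n_snps))

    if not (0 <= background_fraction <= 1):
        raise InvalidConfigurationError("background_fraction must be in [0, 1]")
    eps = np.zeros(n_snps - 1)
    if step_ldu_total > 0:
        d = np.diff(positions)
        span = positions[-1] - positions[0]
        eps += background_fraction * step_ldu_total / span
        steps = rng.choice(np.arange(1, n_snps - 2), size=n_blocks - 1, replace=False)
        step_total = (1.0 - background_fraction) * step_ldu_total
        intensities = rng.dirichlet(np.full(n_blocks - 1, 5.0)) * step_total
        eps[steps] += intensities / d[steps]
    return RecombinationProfile(positions_kb=positions, epsilon_true=eps)


def simulate_haplotypes(
    profile: RecombinationProfile,
    n_haplotypes: int,
    maf_min: float,
    seed: int,
    max_retries: int = 20,
) -> HaplotypePanel:
    """Draw haplotypes from the lineage-retention Markov process.

    Every SNP is guaranteed a realised MAF >= ``maf_min``: columns failing
    the filter have their target frequency redrawn closer to 0.5 and are
    re-thresholded from the same latent uniforms (which preserves the LD
    structure), up to ``max_retries`` times.
    """
    if n_haplotypes < 50:
        raise InvalidConfigurationError("need at least 50 haplotypes")
    if not (0 < maf_min < 0.5):
        raise InvalidConfigurationError("maf_min must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    m = profile.positions_kb.size
    d = profile.interval_length_kb
    retain = np.exp(-profile.epsilon_true * d)

    u = np.empty((n_haplotypes, m))
    u[:, 0] = rng.random(n_haplotypes)
    for k in range(m - 1):
        fresh = rng.random(n_haplotypes)
        keep = rng.random(n_haplotypes) < retain[k]
        u[:, k + 1] = np.where(keep, u[:, k], fresh)

    # sample target frequencies away from the floor so the realised filter
    # is satisfiable; margin shrinks nothing for the common maf_min = 0.05
    p = rng.uniform(maf_min + 0.02, 1.0 - maf_min - 0.02, size=m)
    alleles = (u < p[None, :]).astype(np.uint8)
    for _ in range(max_retries):
        freq = alleles.mean(axis=0)
        bad = np.minimum(freq, 1 - freq) < maf_min
        if not bad.any():
            break
        p_new = rng.uniform(min(2 * maf_min + 0.05, 0.4), 0.6, size=int(bad.sum()))
        p[bad] = p_new
        alleles[:, bad] = u[:, bad] < p[bad][None, :]
    else:
        raise GenerationFailureError("could not satisfy the MAF filter")
    return HaplotypePanel(
        alleles=alleles,
        positions_kb=profile.positions_kb.copy(),
        allele_freqs=alleles.mean(axis=0),
    )


def pair_haplotypes(
    panel: HaplotypePanel, n_individuals: int, seed: int
) -> GenotypeMatrix:
    """Random-union genotypes: sum two distinct haplotypes per individual."""
    if 2 * n_individuals > panel.n_haplotypes:
        raise InvalidConfigurationError(
            f"{panel.n_haplotypes} haplotypes cannot form {n_individuals} individuals"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(panel.n_haplotypes)
    a = panel.alleles[perm[:n_individuals]]
    b = panel.alleles[perm[n_individuals : 2 * n_individuals]]
    return GenotypeMatrix(
        genotypes=(a + b).astype(float), positions_kb=panel.positions_kb.copy()
    )


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Return a copy with calls set missing uniformly at random at ``rate``."""
    rng = np.random.default_rng(seed)
    g = genotypes.genotypes.copy()
    g[rng.random(g.shape) < rate] = np.nan
    out = GenotypeMatrix(
        genotypes=g,
        positions_kb=genotypes.positions_kb.copy(),
        snp_ids=list(genotypes.snp_ids),
        ref_allele=list(genotypes.ref_allele),
        alt_allele=list(genotypes.alt_allele),
        individual_ids=list(genotypes.individual_ids),
    )
    return out


def simulate_covariates(
    n: int, spec: CovariateSpec, seed: int, ids: list[str] | None = None
) -> pd.DataFrame:
    """Age / sex / year-of-visit / batch table; each individual its own cluster."""
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 90.0)
    sex = rng.integers(0, 2, n)
    year = rng.integers(0, len(spec.year_effects), n)
    batch = rng.integers(0, spec.n_batches, n)
    if ids is None:
        ids = [f"ind{k + 1:05d}" for k in range(n)]
    return pd.DataFrame(
        {
            "individual_id": ids,
            "age": age,
            "sex": sex,
            "year": year,
            "batch": batch,
            "cluster_id": ids,
        }
    )


def _covariate_linear_term(
    cov: pd.DataFrame, spec: CovariateSpec, age_coef: float, batch_effects=None
) -> np.ndarray:
    eta = age_coef * (cov["age"].to_numpy() - spec.age_mean)
    eta = eta + spec.sex_beta * cov["sex"].to_numpy()
    eta = eta + np.asarray(spec.year_effects)[cov["year"].to_numpy()]
    if batch_effects is not None:
        eta = eta + batch_effects[cov["batch"].to_numpy()]
    return eta


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    model: str,
    covariate_spec: CovariateSpec | None = None,
    prevalence: float | None = None,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    trait_name: str | None = None,
) -> pd.DataFrame:
    """Plant genotype effects into a phenotype or expression trait.

    model = "quantitative": trait = beta_pheno * g + covariates + noise.
    model = "binary": logistic on the same linear predictor (age on the
    log-odds scale), with the intercept solved so the expected prevalence
    matches ``prevalence``; the causal allele raises risk.
    model = "expression": beta_expr * g + batch effect + noise.
    """
    spec = covariate_spec or CovariateSpec()
    if not (0 <= truth.causal_index < genotypes.n_snps):
        raise InvalidConfigurationError("causal_index outside the genotype matrix")
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    if covariates is None:
        covariates = simulate_covariates(
            n, spec, seed=rng.integers(2**31 - 1), ids=list(genotypes.individual_ids)
        )
    g = np.nan_to_num(genotypes.genotypes[:, truth.causal_index])
    out = covariates.copy()

    if model == "quantitative":
        eta = truth.beta_pheno * g + _covariate_linear_term(
            covariates, spec, spec.age_beta
        )
        out[trait_name or "trait"] = eta + rng.normal(0.0, spec.noise_sd, n)
    elif model == "binary":
        if prevalence is None or not (0 < prevalence < 1):
            raise InvalidConfigurationError("binary model needs prevalence in (0,1)")
        eta = truth.beta_pheno * g + _covariate_linear_term(
            covariates, spec, spec.age_log_or
        )

        def mean_risk(c: float) -> float:
            return float(np.mean(expit(c + eta))) - prevalence

        c0 = brentq(mean_risk, -30.0, 30.0)
        status = (rng.random(n) < expit(c0 + eta)).astype(float)
        if status.sum() == 0 or status.sum() == n:
            raise GenerationFailureError("binary model produced a single class")
        out[trait_name or "status"] = status
    elif model == "expression":
        batch_effects = rng.normal(0.0, spec.batch_sd, spec.n_batches)
        expr = (
            truth.beta_expr * g
            + batch_effects[covariates["batch"].to_numpy()]
            + rng.normal(0.0, 1.0, n)
        )
        out[trait_name or "expression"] = expr
    else:
        raise InvalidConfigurationError(f"unknown phenotype model {model!r}")
    return out


def simulate_case_control(
    panel: HaplotypePanel,
    truth: TruthRecord,
    n_cases: int,
    n_controls: int,
    prevalence: float,
    covariate_spec: CovariateSpec | None = None,
    seed: int = 0,
    max_draws: int = 2_000_000,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Ascertained case-control sample under the logistic disease model.

    Individuals are formed by drawing haplotype pairs with replacement
    from the panel, assigned disease status at population ``prevalence``,
    and retained until the case/control quotas fill - mirroring how a
    case-control genotyping study oversamples affected individuals.
    """
    spec = covariate_spec or CovariateSpec()
    rng = np.random.default_rng(seed)
    m = panel.n_snps
    # population risk: solve intercept on an expected-genotype linear term
    p_c = panel.allele_freqs[truth.causal_index]
    probe = rng.integers(0, panel.n_haplotypes, size=(20000, 2))
    g_probe = (
        panel.alleles[probe[:, 0], truth.causal_index]
        + panel.alleles[probe[:, 1], truth.causal_index]
    )
    age_probe = np.clip(rng.normal(spec.age_mean, spec.age_sd, 20000), 18, 90)
    eta_probe = truth.beta_pheno * g_probe + spec.age_log_or * (age_probe - spec.age_mean)
    c0 = brentq(
        lambda c: float(np.mean(expit(c + eta_probe))) - prevalence, -30.0, 30.0
    )

    got_cases: list[np.ndarray] = []
    got_controls: list[np.ndarray] = []
    rows_cases: list[pd.DataFrame] = []
    rows_controls: list[pd.DataFrame] = []
    drawn = 0
    batch = max(4 * (n_cases + n_controls), 2000)
    while (
        sum(len(x) for x in got_cases) < n_cases
        or sum(len(x) for x in got_controls) < n_controls
    ):
        if drawn > max_draws:
            raise GenerationFailureError("case/control quotas not reached")
        idx = rng.integers(0, panel.n_haplotypes, size=(batch, 2))
        g = (panel.alleles[idx[:, 0]] + panel.alleles[idx[:, 1]]).astype(float)
        cov = simulate_covariates(batch, spec, seed=int(rng.integers(2**31 - 1)))
        eta = truth.beta_pheno * g[:, truth.causal_index] + _covariate_linear_term(
            cov, spec, spec.age_log_or
        )
        status = rng.random(batch) < expit(c0 + eta)
        got_cases.append(g[status])
        rows_cases.append(cov[status])
        got_controls.append(g[~status])
        rows_controls.append(cov[~status])
        drawn += batch

    g_cases = np.concatenate(got_cases)[:n_cases]
    g_controls = np.concatenate(got_controls)[:n_controls]
    cov_cases = pd.concat(rows_cases).iloc[:n_cases]
    cov_controls = pd.concat(rows_controls).iloc[:n_controls]
    g_all = np.concatenate([g_cases, g_controls])
    table = pd.concat([cov_cases, cov_controls], ignore_index=True)
    ids = [f"ind{k + 1:05d}" for k in range(len(table))]
    table["individual_id"] = ids
    table["cluster_id"] = ids
    table["status"] = np.concatenate(
        [np.ones(n_cases), np.zeros(n_controls)]
    )
    geno = GenotypeMatrix(
        genotypes=g_all, positions_kb=panel.positions_kb.copy(), individual_ids=ids
    )
    return geno, table.reset_index(drop=True)


def add_twin_structure(
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    trait: str,
    fraction: float,
    shared_sd: float,
    seed: int,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Duplicate a fraction of individuals into labelled twin clusters.

    Both members of a cluster share the genotype row and covariates and a
    common random intercept of SD ``shared_sd`` added to ``trait``; each
    member keeps an independent residual of the same magnitude so the
    within-cluster correlation is positive but below one.  No kinship
    matrix is modelled.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    pick = np.flatnonzero(rng.random(n) < fraction)
    dup = table.iloc[pick].copy()
    shared = rng.normal(0.0, shared_sd, len(pick))
    resid = rng.normal(0.0, shared_sd, len(pick))
    table = table.copy()
    table.loc[table.index[pick], trait] = (
        table.loc[table.index[pick], trait].to_numpy() + shared
    )
    dup[trait] = dup[trait].to_numpy() + shared + resid
    dup["individual_id"] = [f"{i}_tw" for i in dup["individual_id"]]
    # cluster label = original individual id for both members
    table.loc[table.index[pick], "cluster_id"] = [
        table["individual_id"].iloc[i] for i in pick
    ]
    dup["cluster_id"] = [table["individual_id"].iloc[i] for i in pick]
    out_table = pd.concat([table, dup], ignore_index=True)
    g = np.vstack([genotypes.genotypes, genotypes.genotypes[pick]])
    geno = GenotypeMatrix(
        genotypes=g,
        positions_kb=genotypes.positions_kb.copy(),
        snp_ids=list(genotypes.snp_ids),
        individual_ids=list(out_table["individual_id"]),
    )
    return geno, out_table


def simulate_cascade_dataset(
    n: int,
    beta_focal: float,
    r_bystander: float,
    binary: bool,
    seed: int,
    prevalence: float = 0.045,
    n_batches: int = 4,
    n_null_probes: int = 2,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression panel with a focal probe that drives the phenotype.

    The focal probe has standardised effect ``beta_focal`` on the
    phenotype (log-odds per SD when ``binary``); a bystander probe is
    correlated with the focal probe at ``r_bystander`` (e.g. -0.38, the
    co-expression seen between neighbouring-gene probes) but has no direct
    phenotype effect; ``n_null_probes`` further probes are pure noise.
    """
    rng = np.random.default_rng(seed)
    ids = [f"ind{k + 1:05d}" for k in range(n)]
    batch = rng.integers(0, n_batches, n)
    focal = rng.normal(0.0, 1.0, n)
    bystander = r_bystander * focal + np.sqrt(1 - r_bystander**2) * rng.normal(
        0.0, 1.0, n
    )
    probes = {"focal_probe": focal, "bystander_probe": bystander}
    for k in range(n_null_probes):
        probes[f"null_probe{k + 1}"] = rng.normal(0.0, 1.0, n)
    values = pd.DataFrame(probes, index=ids).T
    expr = ExpressionMatrix(
        values=values, batch=pd.Series(batch, index=ids, name="batch")
    )

    age = np.clip(rng.normal(55.0, 10.0, n), 18, 90)
    table = pd.DataFrame(
        {
            "individual_id": ids,
            "age": age,
            "sex": rng.integers(0, 2, n),
            "year": rng.integers(0, 5, n),
            "batch": batch,
            "cluster_id": ids,
        }
    )
    if binary:
        eta = beta_focal * focal + np.log(1.04) * (age - 55.0)
        c0 = brentq(lambda c: float(np.mean(expit(c + eta))) - prevalence, -30, 30)
        table["status"] = (rng.random(n) < expit(c0 + eta)).astype(float)
        if table["status"].sum() in (0, n):
            raise GenerationFailureError("cascade phenotype is single-class")
    else:
        table["trait"] = beta_focal * focal + 0.012 * (age - 55.0) + rng.normal(
            0.0, 1.0, n
        )
    return expr, table
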