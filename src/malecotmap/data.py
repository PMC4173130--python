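"""Core in-memory containers shared across the pipeline.

Genotypes live in a small dataclass wrapping a dense ``individual x SNP``
dosage matrix (0/1/2, NaN for missing).  Phenotype and expression tables
are plain :class:`pandas.DataFrame` objects with documented column
conventions, validated by the helpers below rather than wrapped in a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigurationError

#: Phenotype-table covariate columns the scan stage understands.
COVARIATE_COLUMNS = ("age", "sex", "year", "batch")


@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes coded as counted-allele dosage 0/1/2.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_snps)`` float array with entries in
        ``{0, 1, 2}`` and ``NaN`` for missing calls.
    positions_kb
        Strictly increasing marker positions in kilobases (1-based bp
        coordinates divided by 1000; bp resolution is three decimals).
    snp_ids
        Marker labels, unique.
    ref_allele, alt_allele
        Allele labels per SNP; the *alt* allele is the counted one, so a
        hom-ref call is dosage 0 (the rs3732581-style 0/1/2 coding applied
        uniformly).
    """

    genotypes: np.ndarray
    positions_kb: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    ref_allele: list[str] = field(default_factory=list)
    alt_allele: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)
    chrom: str = "3"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.positions_kb = np.asarray(self.positions_kb, dtype=float)
        if self.genotypes.ndim != 2:
            raise InvalidConfigurationError("genotypes must be a 2-D matrix")
        n, m = self.genotypes.shape
        if m != self.positions_kb.size:
            raise InvalidConfigurationError(
                f"{m} genotype columns but {self.positions_kb.size} positions"
            )
        if m < 2:
            raise InvalidConfigurationError("need at least 2 SNPs")
        if np.any(np.diff(self.positions_kb) <= 0):
            raise InvalidConfigurationError("positions_kb must be strictly increasing")
        ok = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise InvalidConfigurationError("genotype entries must be 0/1/2 or NaN")
        if not self.snp_ids:
            self.snp_ids = [f"snp{k + 1:04d}" for k in range(m)]
        if len(self.snp_ids) != m:
            raise InvalidConfigurationError("snp_ids length mismatch")
        if not self.ref_allele:
            self.ref_allele = ["A"] * m
        if not self.alt_allele:
            self.alt_allele = ["G"] * m
        if not self.individual_ids:
            self.individual_ids = [f"ind{k + 1:05d}" for k in range(n)]
        if len(self.individual_ids) != n:
            raise InvalidConfigurationError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - np.mean(np.isnan(self.genotypes), axis=0)

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-SNP counted-allele frequency (NaN-aware)."""
        return np.nanmean(self.genotypes, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freqs
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            positions_kb=self.positions_kb[idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            ref_allele=[self.ref_allele[i] for i in idx],
            alt_allele=[self.alt_allele[i] for i in idx],
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[idx, :],
            individual_ids=[self.individual_ids[i] for i in idx],
        )


def validate_phenotype_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table conventions used throughout the pipeline.

    Required: an ``individual_id`` column with unique entries.  Optional
    well-known columns: covariates (:data:`COVARIATE_COLUMNS`), a
    ``cluster_id`` family/twin label, a binary ``status`` in {0, 1, NaN},
    and any number of quantitative trait columns.
    """
    if "individual_id" not in table.columns:
        raise InvalidConfigurationError("phenotype table needs an individual_id column")
    if table["individual_id"].duplicated().any():
        raise InvalidConfigurationError("individual_id values must be unique")
    if "status" in table.columns:
        vals = table["status"].dropna().unique()
        if not np.isin(vals, (0, 1)).all():
            raise InvalidConfigurationError("status must be binary 0/1")
    for col in ("age",):
        if col in table.columns and not np.isfinite(table[col].to_numpy(float)).all():
            raise InvalidConfigurationError(f"covariate {col!r} has non-finite values")
    return table


@dataclass
class ExpressionMatrix:
    """Probe-by-individual expression abundances with batch labels."""

    values: pd.DataFrame  # probes x individuals
    batch: pd.Series  # indexed by individual id
    tissue: str = "adipose"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise InvalidConfigurationError("expression values must be finite")
        missing = [c for c in self.values.columns if c not in self.batch.index]
        if missing:
            raise InvalidConfigurationError(
                f"batch labels missing for {len(missing)} individuals"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.columns)

    def probe(self, probe_id: str) -> pd.Series:
        return self.values.loc[probe_id]
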