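"""End-to-end pipeline with stage artifacts and manifests.

Stages: ``simulate`` -> ``ldmap`` -> ``scan`` -> ``maplocus`` -> ``eqtl``
-> ``cascade`` -> ``meta``.  Each stage reads the artifacts of its
dependencies from the output directory, writes its own artifact plus a
manifest (input checksums, settings, seed, version), and reruns
byte-identically under the same configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .downstream import eqtl_probe_scan, fisher_combine, probe_phenotype_cascade
from .exceptions import DependencyError, InvalidConfigurationError
from .ldu import LDUMap, LDUMapModel
from .location import fit_location_model
from .pairwise import pairwise_ld_table
from .scan import single_snp_scan
from . import synthetic as syn

logger = logging.getLogger("malecotmap")

ALL_STAGES = ("simulate", "ldmap", "scan", "maplocus", "eqtl", "cascade", "meta")


@dataclass
class PipelineConfig:
    """Settings shared across stages; defaults mirror an 800 kb window."""

    out_dir: str = "malecotmap_out"
    seed: int = 1
    # simulate
    n_snps: int = 100
    region_kb: float = 800.0
    start_kb: float = 184_743.0
    n_blocks: int = 6
    step_ldu_total: float = 10.0
    n_haplotypes: int = 2000
    n_individuals: int = 800
    maf_min: float = 0.05
    beta_pheno: float = 0.3
    beta_expr: float = 0.5
    prevalence: float = 0.2
    # ldmap / maplocus
    max_pair_kb: float = 500.0
    L_mode: str = "fitted"
    grid_step_ldu: float = 0.05
    n_perm: int = 0
    window_kb: tuple[float, float] | None = None
    alpha_region: float = 1e-5
    alpha_cascade: float = 0.05

    def __post_init__(self) -> None:
        if self.window_kb is not None:
            lo, hi = self.window_kb
            if not lo < hi:
                raise InvalidConfigurationError("window start must precede end")
        for a in (self.alpha_region, self.alpha_cascade):
            if not (0 < a < 1):
                raise InvalidConfigurationError("alpha settings must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "window_kb" in raw and raw["window_kb"] is not None:
            raw["window_kb"] = tuple(raw["window_kb"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["window_kb"] is not None:
            d["window_kb"] = list(d["window_kb"])
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    artifacts: dict = field(default_factory=dict)


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {needed_by!r} needs the output of stage {stage!r} ({path.name})"
        )
    return path


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> PipelineResult:
    """Run the requested stages in canonical order, writing artifacts."""
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        raise InvalidConfigurationError(f"unknown stages: {bad}")
    stages = tuple(s for s in ALL_STAGES if s in stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arts: dict = {}
    cfg_settings = config.to_dict()

    vcf = out / "genotypes.vcf"
    pheno_p = out / "phenotypes.tsv"
    expr_p = out / "expression.tsv"
    truth_p = out / "truth.json"
    map_p = out / "ldu_map.tsv"
    pairs_p = out / "pair_ld.tsv"
    scan_p = out / "scan.tsv"
    loc_p = out / "location_fit.json"
    eqtl_p = out / "eqtl_fit.json"
    casc_a = out / "cascade_panel_a.tsv"
    casc_b = out / "cascade_panel_b.tsv"
    meta_p = out / "meta.json"

    if "simulate" in stages:
        profile = syn.simulate_recombination_profile(
            config.n_snps,
            config.region_kb,
            config.n_blocks,
            config.step_ldu_total,
            seed=config.seed,
            start_kb=config.start_kb,
        )
        panel = syn.simulate_haplotypes(
            profile, config.n_haplotypes, config.maf_min, seed=config.seed + 1
        )
        geno = syn.pair_haplotypes(panel, config.n_individuals, seed=config.seed + 2)
        causal = config.n_snps // 2
        truth = syn.TruthRecord(
            causal_index=causal,
            causal_kb=float(profile.positions_kb[causal]),
            beta_pheno=config.beta_pheno,
            beta_expr=config.beta_expr,
        )
        pheno = syn.simulate_phenotypes(
            geno, truth, "binary", prevalence=config.prevalence, seed=config.seed + 3
        )
        quant = syn.simulate_phenotypes(
            geno, truth, "quantitative", seed=config.seed + 4, covariates=pheno
        )
        pheno["trait"] = quant["trait"]
        expr_tab = syn.simulate_phenotypes(
            geno, truth, "expression", seed=config.seed + 5, covariates=pheno
        )
        values = pd.DataFrame(
            [expr_tab["expression"].to_numpy()],
            index=["probe_causal"],
            columns=list(pheno["individual_id"]),
        )
        from .data import ExpressionMatrix

        expr = ExpressionMatrix(
            values=values,
            batch=pd.Series(
                pheno["batch"].to_numpy(), index=list(pheno["individual_id"])
            ),
        )
        mio.write_vcf(geno, vcf)
        mio.write_plink_text(geno, out / "genotypes")
        mio.write_phenotypes(pheno, pheno_p)
        mio.write_expression(expr, expr_p)
        mio.write_truth(truth, truth_p)
        arts["simulate"] = [vcf, pheno_p, expr_p, truth_p]
        mio.write_manifest(out, "simulate", [], arts["simulate"], cfg_settings, config.seed)

    if "ldmap" in stages:
        geno = mio.read_genotypes(_require(vcf, "simulate", "ldmap"))
        pairs = pairwise_ld_table(geno, max_pair_kb=config.max_pair_kb)
        pairs.to_csv(pairs_p, sep="\t", index=False)
        res = LDUMapModel(
            pairs,
            geno.positions_kb,
            snp_ids=geno.snp_ids,
            L_mode=config.L_mode,
            max_pair_kb=config.max_pair_kb,
        ).fit(seed=config.seed)
        res.map.to_tsv(map_p)
        arts["ldmap"] = [pairs_p, map_p]
        mio.write_manifest(out, "ldmap", [vcf], arts["ldmap"], cfg_settings, config.seed)

    if "scan" in stages:
        geno = mio.read_genotypes(_require(vcf, "simulate", "scan"))
        pheno = mio.read_phenotypes(_require(pheno_p, "simulate", "scan"))
        scan = single_snp_scan(
            geno,
            pheno["status"].to_numpy(float),
            covariates=pheno[["age", "year"]],
        )
        scan.to_csv(scan_p, sep="\t", index=False)
        arts["scan"] = [scan_p]
        mio.write_manifest(
            out, "scan", [vcf, pheno_p], arts["scan"], cfg_settings, config.seed
        )

    if "maplocus" in stages:
        _require(map_p, "ldmap", "maplocus")
        _require(scan_p, "scan", "maplocus")
        ldu_map = LDUMap.from_tsv(map_p)
        scan = pd.read_csv(scan_p, sep="\t")
        fit = fit_location_model(
            scan, ldu_map, config.window_kb, grid_step_ldu=config.grid_step_ldu
        )
        fit.to_json(loc_p)
        arts["maplocus"] = [loc_p]
        mio.write_manifest(
            out, "maplocus", [map_p, scan_p], arts["maplocus"], cfg_settings, config.seed
        )

    if "eqtl" in stages:
        _require(map_p, "ldmap", "eqtl")
        geno = mio.read_genotypes(_require(vcf, "simulate", "eqtl"))
        expr = mio.read_expression(_require(expr_p, "simulate", "eqtl"))
        ldu_map = LDUMap.from_tsv(map_p)
        probe = expr.values.iloc[0]
        fit = eqtl_probe_scan(
            geno,
            probe.to_numpy(float),
            ldu_map,
            batch=expr.batch.to_numpy(),
            window_kb=config.window_kb,
            grid_step_ldu=config.grid_step_ldu,
        )
        fit.to_json(eqtl_p)
        arts["eqtl"] = [eqtl_p]
        mio.write_manifest(
            out, "eqtl", [vcf, expr_p, map_p], arts["eqtl"], cfg_settings, config.seed
        )

    if "cascade" in stages:
        pheno = mio.read_phenotypes(_require(pheno_p, "simulate", "cascade"))
        expr = mio.read_expression(_require(expr_p, "simulate", "cascade"))
        traits = [c for c in ("trait", "status") if c in pheno.columns]
        casc = probe_phenotype_cascade(
            expr,
            pheno,
            focal_probe=expr.probe_ids[0],
            phenotype_columns=traits,
            alpha=config.alpha_cascade,
        )
        casc.panel_a.to_csv(casc_a, sep="\t", index=False)
        casc.panel_b.to_csv(casc_b, sep="\t", index=False)
        arts["cascade"] = [casc_a, casc_b]
        mio.write_manifest(
            out, "cascade", [pheno_p, expr_p], arts["cascade"], cfg_settings, config.seed
        )

    if "meta" in stages:
        ps = []
        for p in (loc_p, eqtl_p):
            if p.exists():
                with open(p) as fh:
                    ps.append(json.load(fh)["p_value"])
        if len(ps) < 2:
            raise DependencyError("stage 'meta' needs at least two fitted p-values")
        meta = fisher_combine(ps)
        with open(meta_p, "w") as fh:
            json.dump(
                {
                    "chi2": meta.chi2,
                    "df": meta.df,
                    "p_combined": meta.p_combined,
                    "inputs": ps,
                    "alpha_region": config.alpha_region,
                },
                fh,
                indent=2,
            )
        arts["meta"] = [meta_p]
        mio.write_manifest(
            out, "meta", [loc_p, eqtl_p], arts["meta"], cfg_settings, config.seed
        )

    return PipelineResult(out_dir=out, artifacts=arts)
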