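"""Readers and writers for the standard formats the pipeline touches.

Genotypes: biallelic GT-only VCF (read through cyvcf2/htslib), a
PLINK-style transposed text pair (.tped/.tfam), and a simple dosage TSV.
Phenotype and expression tables are tab-separated with a header; the
truth record and fit reports are JSON.  All genomic coordinates are
written 1-based (VCF convention); kb positions are bp / 1000 at
three-decimal resolution.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GenotypeMatrix
from .exceptions import ParseError
from .synthetic import TruthRecord

logger = logging.getLogger("malecotmap")

__all__ = [
    "read_genotypes",
    "write_vcf",
    "write_plink_text",
    "write_genotype_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_expression",
    "read_expression",
    "write_truth",
    "read_truth",
    "write_manifest",
]


def _kb_to_bp(kb: float) -> int:
    return int(round(kb * 1000))


# ---------------------------------------------------------------------------
# VCF


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Biallelic GT-only VCF; dosage 0/1/2 becomes 0/0, 0/1, 1/1."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genotypes.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for k in range(genotypes.n_snps):
            calls = [
                gt_map.get(g, "./.") if not np.isnan(g) else "./."
                for g in genotypes.genotypes[:, k]
            ]
            fh.write(
                f"{genotypes.chrom}\t{_kb_to_bp(genotypes.positions_kb[k])}\t"
                f"{genotypes.snp_ids[k]}\t{genotypes.ref_allele[k]}\t"
                f"{genotypes.alt_allele[k]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    positions = []
    ids = []
    ref = []
    alt = []
    skipped = 0
    chrom = "3"
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        chrom = v.CHROM
        gts = np.array([a[0] + a[1] if a[0] >= 0 and a[1] >= 0 else np.nan
                        for a in ((g[0], g[1]) for g in v.genotypes)])
        rows.append(gts)
        positions.append(v.POS / 1000.0)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
    vcf.close()
    if skipped:
        logger.warning("skipped %d non-biallelic sites", skipped)
    if not rows:
        raise ParseError("no biallelic sites in VCF")
    return GenotypeMatrix(
        genotypes=np.column_stack(rows),
        positions_kb=np.array(positions),
        snp_ids=ids,
        ref_allele=ref,
        alt_allele=alt,
        individual_ids=samples,
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# PLINK-style transposed text


def write_plink_text(genotypes: GenotypeMatrix, prefix) -> None:
    """.tped/.tfam pair; two allele columns per individual, '0 0' missing."""
    prefix = str(prefix)
    with open(prefix + ".tfam", "w") as fh:
        for ind in genotypes.individual_ids:
            fh.write(f"{ind} {ind} 0 0 0 -9\n")
    with open(prefix + ".tped", "w") as fh:
        for k in range(genotypes.n_snps):
            ref, alt = genotypes.ref_allele[k], genotypes.alt_allele[k]
            allele_pairs = {0.0: f"{ref} {ref}", 1.0: f"{ref} {alt}", 2.0: f"{alt} {alt}"}
            calls = " ".join(
                allele_pairs.get(g, "0 0") if not np.isnan(g) else "0 0"
                for g in genotypes.genotypes[:, k]
            )
            fh.write(
                f"{genotypes.chrom} {genotypes.snp_ids[k]} 0 "
                f"{_kb_to_bp(genotypes.positions_kb[k])} {calls}\n"
            )


def _read_plink_text(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    if prefix.endswith(".tped"):
        prefix = prefix[: -len(".tped")]
    try:
        fam = pd.read_csv(prefix + ".tfam", sep=r"\s+", header=None)
    except FileNotFoundError as e:
        raise ParseError(f"missing .tfam for {prefix}") from e
    inds = list(fam[1].astype(str))
    rows = []
    positions = []
    ids = []
    refs = []
    alts = []
    chrom = "3"
    with open(prefix + ".tped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4 + 2 * len(inds):
                raise ParseError(
                    f"{prefix}.tped line {ln}: expected {4 + 2 * len(inds)} fields, "
                    f"got {len(parts)} (truncated file?)"
                )
            chrom, snp_id, _, bp = parts[:4]
            alleles = parts[4:]
            obs = sorted({a for a in alleles if a != "0"})
            if len(obs) > 2:
                logger.warning("skipping multi-allelic site %s", snp_id)
                continue
            ref = obs[0] if obs else "A"
            alt = obs[1] if len(obs) > 1 else ("G" if ref != "G" else "T")
            dose = []
            for a1, a2 in zip(alleles[::2], alleles[1::2]):
                if a1 == "0" or a2 == "0":
                    dose.append(np.nan)
                else:
                    dose.append(float((a1 == alt) + (a2 == alt)))
            rows.append(dose)
            positions.append(float(bp) / 1000.0)
            ids.append(snp_id)
            refs.append(ref)
            alts.append(alt)
    if not rows:
        raise ParseError("no sites in .tped")
    return GenotypeMatrix(
        genotypes=np.array(rows, float).T,
        positions_kb=np.array(positions),
        snp_ids=ids,
        ref_allele=refs,
        alt_allele=alts,
        individual_ids=inds,
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# dosage TSV


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.genotypes,
        index=pd.Index(genotypes.individual_ids, name="individual_id"),
        columns=genotypes.snp_ids,
    )
    with open(path, "w") as fh:
        fh.write(
            "# positions_kb="
            + ",".join(f"{p:.3f}" for p in genotypes.positions_kb)
            + f"\tchrom={genotypes.chrom}\n"
        )
        df.to_csv(fh, sep="\t")


def _read_genotype_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# positions_kb="):
            raise ParseError("dosage TSV missing positions header")
        meta = first[2:].strip().split("\t")
        positions = np.array([float(x) for x in meta[0].split("=", 1)[1].split(",")])
        chrom = meta[1].split("=", 1)[1] if len(meta) > 1 else "3"
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.shape[1] != positions.size:
        raise ParseError("dosage TSV column count does not match positions header")
    return GenotypeMatrix(
        genotypes=df.to_numpy(float),
        positions_kb=positions,
        snp_ids=list(df.columns),
        individual_ids=list(df.index.astype(str)),
        chrom=chrom,
    )


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF, PLINK-style text, or dosage TSV.

    ``fmt`` in {"vcf", "plink_text", "tsv"}; inferred from the extension
    when omitted.
    """
    p = str(path)
    if fmt is None:
        if p.endswith(".vcf") or p.endswith(".vcf.gz"):
            fmt = "vcf"
        elif p.endswith(".tped") or os.path.exists(p + ".tped"):
            fmt = "plink_text"
        elif p.endswith(".tsv"):
            fmt = "tsv"
        else:
            raise ParseError(f"cannot infer genotype format from {p!r}")
    if fmt == "vcf":
        return _read_vcf(p)
    if fmt == "plink_text":
        return _read_plink_text(p)
    if fmt == "tsv":
        return _read_genotype_tsv(p)
    raise ParseError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# tables, truth, manifests


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    from .data import validate_phenotype_table

    return validate_phenotype_table(pd.read_csv(path, sep="\t"))


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.index.name = "probe_id"
    with open(path, "w") as fh:
        fh.write(
            "# batch=" + ",".join(str(b) for b in expr.batch.loc[df.columns]) + "\n"
        )
        fh.write(f"# tissue={expr.tissue}\n")
        df.to_csv(fh, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        b_line = fh.readline()
        t_line = fh.readline()
        if not b_line.startswith("# batch="):
            raise ParseError("expression TSV missing batch header")
        batches = b_line.strip().split("=", 1)[1].split(",")
        tissue = t_line.strip().split("=", 1)[1] if t_line.startswith("# tissue=") else ""
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if len(batches) != df.shape[1]:
        raise ParseError("batch header length does not match expression columns")
    return ExpressionMatrix(
        values=df,
        batch=pd.Series(batches, index=df.columns, name="batch"),
        tissue=tissue,
    )


def write_truth(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


def read_truth(path) -> TruthRecord:
    with open(path) as fh:
        return TruthRecord(**json.load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir, stage: str, inputs: list, outputs: list, settings: dict, seed: int
) -> Path:
    """Record checksums, settings, seed and version for one pipeline stage."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "seed": seed,
        "settings": settings,
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs if os.path.exists(str(p))},
        "outputs": {str(p): _sha256(p) for p in outputs if os.path.exists(str(p))},
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
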