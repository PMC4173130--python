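# malecotmap

Candidate-region association mapping on the linkage-disequilibrium-unit
(LDU) scale: build a genetic map in which distance is measured by the
decay of allelic association, fit a multimarker model that estimates the
*location* of a functional variant directly (with a confidence interval
in kb), and follow the signal through meta-analysis and an
expression/phenotype regression cascade.

The package is aimed at statistical geneticists fine-mapping a gene-rich
region - the motivating setting is an ~800 kb window containing a
disease-associated transporter gene, typed with 100-200 common SNPs
(MAF >= 0.05) in case-control and population cohorts with expression
data - and at anyone who wants a fully synthetic, end-to-end testbed for
LDU-based association mapping.

## The model

Association between two loci declines with distance according to the
Malecot form

    rho(d) = (1 - L) * M * exp(-eps * d) + L

with amplitude `M`, residual association `L`, and decay rate `eps` per
kb.  Fitting one rate per inter-marker interval to the pairwise |D'|
matrix of a region yields the **LDU map**: the cumulative position of
marker *i* is `sum_k eps_k d_k` in LD units, one LDU being a "swept
radius" (the distance over which association falls by a factor e).
Plotted against kb the map shows a block-step structure - plateaus are
LD blocks, steps are recombination hotspots.

On that map the per-SNP association profile `z_i` (the absolute partial
phenotype-genotype correlation) is modelled as

    z_i = M * exp(-|LDU(S) - LDU_i|) + L_z

and weighted least squares over all markers simultaneously gives the
functional-variant location estimate `S_hat` with a standard error, a
kb confidence interval (bootstrap percentiles by default), and a
region-wide test whose null reference is simulated from the correlation
structure of the scan (a permutation version is also provided).

Downstream, per-sample region p-values are combined with Fisher's
method, expression probes are mapped with the same location machinery
after batch residualisation, probe-phenotype effects are screened
univariately and then conditionally, and multiplicity is handled with
Bonferroni and effective-number-of-tests corrections.

## Worked example

Simulate a European-like window (100 SNPs over 800 kb, 10 LDU of map
length in 12 blocks), plant a risk variant with odds ratio 1.5 per
allele, fit the LDU map from a separate reference panel, and locate the
variant from a 1000/1000 case-control cohort:

```python
import numpy as np
import malecotmap as mm

profile = mm.simulate_recombination_profile(
    n_snps=100, region_kb=800, n_blocks=12, step_ldu_total=10.0,
    background_fraction=0.15, seed=1,
)
panel = mm.simulate_haplotypes(profile, n_haplotypes=6000, maf_min=0.05, seed=2)
maf = np.minimum(panel.allele_freqs, 1 - panel.allele_freqs)
causal = int(np.argmin(np.abs(maf - 0.3)))
truth = mm.TruthRecord(causal, float(profile.positions_kb[causal]),
                       beta_pheno=float(np.log(1.5)))

reference = mm.pair_haplotypes(panel, 1000, seed=3)
pairs = mm.pairwise_ld_table(reference, max_pair_kb=500)
ldu_map = mm.fit_ldu_map(pairs, reference.positions_kb)

geno, pheno = mm.simulate_case_control(panel, truth, n_cases=1000,
                                       n_controls=1000, prevalence=0.1, seed=4)
status = pheno["status"].to_numpy()
scan = mm.single_snp_scan(geno, status, covariates=pheno[["age", "year"]])
fit = mm.fit_location_model(scan, ldu_map, genotypes=geno, phenotype=status,
                            covariates=pheno[["age", "year"]], n_boot=200, seed=5)
print(fit.summary())
```

prints

```
Malecot multimarker location fit
================================================
S_hat:        184,870.9 kb  (2.367 LDU)
SE(S):        1.916 LDU  (bootstrap)
95% CI (kb):  184,815.9 - 185,298.6
M_hat:        0.0648
L_hat:        0.0141
markers:      100
lambda:       126.038  (mvn reference)
P:            0.00807
boundary optimum: False
```

The planted variant sits at 184,908.6 kb: the point estimate lands
38 kb away and the 95% interval covers it.  `S_hat` is where the
association profile peaks on the *genetic* map; the kb interval is the
LDU interval pushed back through the map, so it widens across LD blocks
(every position in a block shares one map coordinate) and narrows at
hotspots.  `M_hat` is the profile amplitude, `L_hat` the baseline
association far from `S`, and `P` the region-wide test of `M = 0`
against the simulated null.  Combining several such samples is one
call: `mm.fisher_combine([p1, p2, p3])`.

A `malecotmap` command-line interface exposes the same pipeline as
subcommands (`simulate`, `ldmap`, `scan`, `maplocus`, `eqtl`,
`cascade`, `meta`), each writing its artifact plus a manifest with
checksums, settings and the seed.

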