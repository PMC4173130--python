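# Methods

This note documents the statistical machinery in `malecotmap`: the
models, the synthetic-data generator whose outputs the tests run on,
the numerical choices, and what the test results do and do not show
about real data.

## 1. Pairwise LD from unphased genotypes

For each marker pair within a distance cap (default 500 kb) the four
two-locus haplotype frequencies are estimated by EM on the 3x3 genotype
count table.  Only the double-heterozygote cell has ambiguous phase; the
E-step splits it by the posterior odds of the two phase configurations
and the M-step renormalises the expected haplotype counts.  The EM is
run from the linkage-equilibrium start and from one restart perturbed
toward maximal positive association (the two-locus likelihood can be
bimodal); the higher log-likelihood wins, and monotonicity of the
log-likelihood is asserted at every iteration.  Convergence is a
log-likelihood change below 1e-8, with a 1000-iteration cap.

From the fitted frequencies, `D = p_AB - p_A p_B` and `D' = D / D_max`
with the sign-appropriate normaliser.  The map is built from |D'|.

Each pair carries the information weight
`K_ij = n_ij p_i(1-p_i) p_j(1-p_j)` (pairwise-complete sample size times
both heterozygosities), rescaled to mean one.  This is this package's
explicit choice; it favours pairs that carry more information about the
decline curve and is fully reproducible from the genotypes alone.

## 2. The LDU map

The map is the weighted least-squares fit of

    |D'|_ij = (1 - L) * M * exp(-sum_{k=i..j-1} eps_k d_k) + L

with one decay rate `eps_k >= 0` per inter-marker interval,
`0 < M <= 1`, `0 <= L < 1`.  Optimisation alternates a closed-form
weighted update of `(M, L)` given the decay covariate (the model is
linear in `a = (1-L)M` and `L`) with bounded quasi-Newton (L-BFGS-B,
analytic gradient) steps on the rates; three starts (an adjacent-pair
moment start plus log-normal perturbations) are kept and the best
penalised objective wins.  The alternation is verified never to
increase the objective; convergence is a relative change below 1e-8 or
30 outer rounds.

Two identifiability guards matter in block-step LD:

* **Depth cap.** `eps_k d_k` is bounded by 8: association across a step
  deeper than ~8 swept radii is below any realistic |D'| noise floor,
  so deeper rates are not estimable.
* **Minimal-map ridge.** Pairs across a deep step sit at (or below) the
  fitted baseline `L`, leaving the RSS flat in the step depth; an
  unpenalised fit drifts along the flat direction and inflates the map.
  A ridge of `1e-4` of the null variation per LDU resolves flat
  directions toward the *shallowest* map consistent with the data
  (minimum-norm principle).  The coefficient is small enough that
  noiseless model-generated data are still recovered to better than
  1e-3 LDU (a unit-test oracle); the reported RSS excludes the penalty.

`L` is fitted freely by default; `L_mode="predicted"` instead fixes it
at the Monte-Carlo expectation of |D'| between independent loci at the
table's median sample size (the small-sample |D'| bias).  Both
behaviours appear in the LDU-map literature, so the choice is exposed
rather than asserted.

Fitted maps interpolate kb -> LDU piecewise-linearly with slope
`eps_k`.  The inverse returns a kb *interval*: on zero-rate plateaus
(LD blocks) every position shares one map coordinate, so a plateau
query widens to the block's kb span.  Point summaries use the interval
midpoint.

## 3. The multimarker location model

Given a per-SNP association profile `z_i` - the absolute partial
phenotype-genotype correlation, computed by OLS for quantitative traits
and from the logistic score statistic (`sqrt(chi2/n)`) for case-control
status, with cluster-robust sandwich standard errors over family/twin
clusters on request - the location model is

    z_i = M * exp(-|LDU(S) - LDU_i|) + L_z .

The decay rate on the LDU scale is fixed at one per LDU: that association
falls by a factor e per unit *is* the LDU calibration, so no separate
rate is fitted.  At any candidate `S` the pair `(M, L_z)` has a closed
form (clipped to `M >= 0`, `L_z >= 0`), so `S` is profiled on a grid of
step <= 0.05 LDU over the analytical window and refined by bounded 1-D
minimisation; a boundary optimum is flagged.  `S` is constrained to the
window (default: the full mapped span; the motivating analyses use an
800 kb window).

### Region-wide test

    lambda = (RSS_null - RSS_model) / (RSS_model / (m - 3)),

`RSS_null` being the flat `M = 0` fit.  Because the `z_i` of markers in
LD are strongly correlated, lambda is far from chi-square with 2 df
under the null (empirically its null median exceeds the chi2_2 median
roughly tenfold on LD-structured panels).  The default reference is
therefore simulated: null profiles are drawn as `|t|/sqrt(n_i)` with
`t ~ MVN(0, R)`, where `R` is the correlation of the per-SNP score
statistics (the residualised, variance-weighted dosages, carried over
from the scan), lambda is recomputed for each draw with the same grid
search, and the 400-draw distribution is smoothed by a moment-matched
gamma so small p-values extrapolate.  `null_calibration="chi2"` keeps
the 2-df convention for reference, and `permutation_pvalue` provides a
fully empirical check (add-one rule, within-cluster block permutation
when labels are given); on null simulations the default analytic p and
the permutation p agree with log-scale slope ~1 over the range the
empirical estimator can resolve.

### Confidence interval for S

The curvature of the profiled RSS at the optimum
(`Var(S) ~ 2 sigma^2 / Q''`) is valid only for a locally quadratic,
unimodal profile.  With block-step LD the argmin jumps between
competing blocks across sampling replicates, and curvature intervals
badly undercover (≈46% observed at nominal 95% on case-control
replicates).  When raw genotype and phenotype data are supplied, the CI
is therefore a case-resampling bootstrap: individuals are resampled
(stratified by case/control status; by whole clusters when labels are
given), the scan and grid argmin are recomputed per resample, and the
2.5/97.5 percentiles of the bootstrap `S` distribution are mapped to kb
through the map inverse with the plateau convention.  The reported
`se_S_ldu` is then the bootstrap SD.  Without raw data the curvature
interval is reported and labelled as such in the fit settings.

CIs in kb are asymmetric whenever the map is nonlinear around `S`; no
skew correction is applied on the LDU scale.

### Cross-sample concordance

`compare_locations` reports pairwise |dS| in kb, CI overlap, and an
inverse-variance pooled location on the LDU scale of a reference map.

## 4. Downstream statistics

* **Fisher's method**: `chi2 = -2 sum ln p` on `2k` df; inputs are
  assumed independent (they come from distinct cohorts).
* **eQTL mapping**: an expression probe is residualised on recorded
  experimental batch (skipped with a log note for a single level) and
  then passed through the scan and location model unchanged.
* **Probe-phenotype cascade**: Panel A regresses each phenotype on each
  probe with age and batch covariates (logistic for binary status);
  Panel B refits on the focal probe plus the nominally significant
  others and flags which survive conditioning.  Odds-ratio intervals
  are Wald, `exp(b +/- 1.96 SE)` - the formula is printed with the
  result because other interval constructions exist.  Conditional sets
  nearly collinear with the focal probe (|r| > 0.99) are rejected.
* **Effective number of tests**:
  `M_eff = 1 + (d-1)(1 - Var(lambda)/d)` over the eigenvalues of the
  trait-trait (or probe-probe) correlation matrix, floored to an
  integer; identity gives `d`, perfect correlation gives 1, and
  moderately correlated families reduce (6 probes at r = 0.6 -> 4;
  5 traits at r = 0.7 -> 3).  The estimator is a documented stand-in
  for the loosely specified "regression method" in the literature and
  is labelled in the output metadata.  Crossed families multiply their
  effective counts in the corrected alpha.
* **Quartile prevalence**: individuals are cut at expression quartile
  boundaries with ties assigned to the lower quartile (discrete scores
  tie at boundaries in samples of hundreds), and the 4x2 table is
  tested with a 3-df chi-square.
* **Quantile normalisation**: rank-based inverse-normal scores with the
  Blom offset `(rank - 3/8)/(n + 1/4)`; ties share averaged ranks.

## 5. The synthetic-data generator

The generator emulates the data a fine-mapping study of one gene-rich
window would see; every downstream stage is tested against it.

**Haplotypes.** A first-order "lineage retention" Markov chain: each
haplotype carries a latent uniform variate along the chromosome that
survives interval `k` with probability `exp(-eps_k d_k)` and is
redrawn otherwise; the allele at marker `j` is the indicator
`U_j < p_j`.  Under this coupling the expected signed D' between any
two markers is exactly `exp(-sum eps_k d_k)` - the Malecot decline with
`M = 1, L = 0` - so realised LD follows the model the map-fitting stage
assumes, by construction.  Every SNP is guaranteed a realised
MAF >= `maf_min` (default 0.05) by redrawing target frequencies from
the same latent uniforms, which preserves LD.

**Decay profiles.** Markers on a jittered even grid; `n_blocks` LD
blocks separated by Dirichlet-weighted hotspot steps whose depths sum,
with an optional uniformly spread background fraction, to a prescribed
total (10 LDU European-like, 17 LDU African-like for the same 800 kb
window).  The study conditions used in the tests are 100 SNPs, 12
blocks and background fraction 0.15 - a hotspot every ~60-70 kb with a
strictly increasing map, chosen for realism: all-or-nothing profiles
with a handful of mega-blocks create multi-LDU marker-free gaps that
real maps do not show and that make the location parameter degenerate
mid-step.

**Phenotypes.** Quantitative traits are linear in causal dosage with
age/sex/year-of-visit effects and Gaussian noise; the insulin-like
preset uses an age slope of 0.12 units/year with the residual SD solved
so the covariates explain R^2 = 0.18.  Disease status follows a
logistic model (age effect ln(1.04)/year on the log-odds) with the
intercept solved for a target prevalence; `simulate_case_control`
oversamples affected individuals by drawing haplotype pairs with
replacement until case/control quotas fill, mirroring ascertained
case-control designs.  Expression traits add batch effects; the
cascade generator plants a focal probe driving the phenotype and a
bystander probe correlated with it (default r = -0.38) but with no
direct effect.  Twin structure is emulated by duplicating a fraction of
individuals into labelled clusters with a shared random intercept - no
kinship matrix is modelled, which is exactly what the cluster-robust
standard errors assume.

**What passing tests show - and don't.** The generator realises the
Malecot decline exactly, has no genotyping error, no population
stratification, no ascertainment of markers by prior evidence, and
Gaussian covariate structure.  Passing coverage and calibration tests
therefore validate the estimators *under the model's own assumptions*;
on real data, map misspecification, stratification and differential
bias can add errors the tests do not measure.  The test suite's
replicate counts (e.g. 200 coverage replicates at odds ratio 1.3 with
1000 cases/1000 controls; 500 null draws for calibration; 200 map
replicates at 500 individuals) were sized to run on one CPU.

## 6. Known limitations

* The LDU map's total length retains a modest upward bias from the
  positivity constraint on rates (~+15-20% at 500 individuals), which
  largely cancels in cross-population length *ratios*; deep steps are
  reported at the shallowest depth the data support.
* The bootstrap CI is percentile-based and mildly conservative
  (measured coverage near the upper half of the 90-98% band); with
  weak effects the honest interval can span most of the window - a
  faithful statement of how poorly a weak signal localises.
* The gamma smoothing of the simulated null is a tail approximation;
  extreme p-values (< ~1e-6) are extrapolations.
* One tissue, one window, biallelic SNPs only; no imputation, no
  multi-variant models, no X-chromosome handling.
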