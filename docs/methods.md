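# Methods

This note documents the models and procedures `landgen` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Synthetic landscape generator

The generator builds the statistical structure the analysis chain assumes,
with a known answer key.

**Landscape.** A regular lon×lat grid (default 20×10 over 95–115°E,
30–40°N). Environmental variables are linear gradients, sinusoids, or
Gaussian random fields with exponential covariance
`sd² · exp(−d/ℓ)` on cell coordinates (correlation length ℓ in degrees).
Populations (default 17, matching a typical range-wide sampling design)
occupy distinct cells spread over the grid; their site environments are the
grid values at those cells.

**Allele frequencies.** Every locus draws an intercept `a = logit(p0)`,
`p0 ~ U(0.1, 0.9)`, and a drift deviate `g` from a Gaussian field over
population coordinates (sd 0.5, length 3° in the benchmark — weak,
spatially autocorrelated drift that produces IBD). Adaptive loci add a
selection term: `p = logistic(a + g + β·z)` with `z` the standardized
driver. Drift applies to adaptive loci too, not only neutral ones: with
β = 0 adaptive and neutral loci are then statistically exchangeable
(selection acts on top of drift rather than replacing it), which is the
correct null for power/calibration studies.

**Genotypes.** Each diploid draws two allele copies at its population's
true frequency (Hardy–Weinberg within populations, no LD within fragments
— SNPs sharing a fragment ID are independent draws, a simplification the
fragment-thinning step does not depend on). Missingness is completely at
random (default 5%). All randomness flows from one integer seed through a
fixed `SeedSequence` spawning order (landscape noise, intercepts, drift,
genotypes, missingness), so identical seeds give byte-identical VCFs.

**Scenarios.** Future climates are additive/multiplicative shifts of the
current grid (the benchmark uses E1 + 2.0 and E1 + 4.0, i.e. ~0.7 and ~1.4
within-population-range standard deviations of the driver — a moderate and
a doubled extreme scenario). A zero shift returns the grid unchanged.

**What the benchmark is not.** It has no coalescent/forward-time dynamics,
no LD, no selection history, no missingness mechanism beyond MCAR, and its
climate "grids" are not projections. Passing tests demonstrates that the
estimators and the inference chain recover planted structure at realistic
effect sizes and sample sizes — not that any particular real dataset would
behave the same way.

## QC filter chain

Order is fixed: biallelic → heterozygosity → missingness → MAF. The order
changes only per-rule attribution in the report, not the final SNP set,
because the criteria are independent; fixing it makes `FilterReport`
reproducible. Heterozygosity (homeolog screen, ≤ 0.70) is computed among
non-missing genotypes; MAF (≥ 0.05) on the pooled sample. Positions are
kept 1-based throughout (VCF convention). Thinning keeps the
lowest-position SNP per fragment, ties broken by SNP ID.

## Diversity and differentiation

π is computed at variant sites only (per-SNP average of unbiased expected
heterozygosity `(2n/(2n−1))·2p̂q̂` with n the genotyped individuals at the
site): VCF input carries no assembled-locus lengths, so per-bp values are
out of reach and per-site values are not comparable to per-bp figures from
assembly-aware pipelines. F_IS aggregates as a ratio of multi-locus
averages (mean Hobs over mean He), the common multi-locus convention;
monomorphic-only input leaves it undefined (NaN).

Weir–Cockerham θ uses the original a/b/c variance components per locus,
summed before the ratio; missing genotypes reduce per-locus n; loci where
any group lacks genotyped individuals (or n̄ ≤ 1) are skipped. Negative
pairwise estimates are legitimate estimator behavior and are clamped to 0
only inside the Rousset linearization x/(1−x).

## Mantel tests

r is the Pearson correlation of upper-triangle entries; the null permutes
rows/columns of the second matrix simultaneously; the test is one-sided
(positive association), matching directional IBD/IBE hypotheses, with
p = (hits+1)/(N+1). Geographic distance defaults to great-circle
(haversine, Earth radius 6371.0088 km) with a planar `euclidean-degrees`
option for compatibility with analyses that use raw coordinates.
Environmental distance standardizes variables to mean 0, sample sd 1
before Euclidean distance.

## Outlier scans

**PC scan.** Scaled genotypes regressed on the first K PC score vectors
give K z-scores per SNP; their robust Mahalanobis distance (minimum
covariance determinant, fixed seed) is rescaled by the genomic inflation
factor λ = median(D²)/median(χ²_K) and referred to χ²_K. q-values are
Benjamini–Hochberg (conservative relative to Storey-type estimators;
chosen for simplicity and stability at a few hundred SNPs); the default
threshold is q ≤ 0.01.

**Environmental scan.** The neutral population covariance is the empirical
covariance across SNPs of standardized frequency vectors
`(p_k − p̄)/√(p̄(1−p̄))`, ridge-regularized (ε = 1e−6, repeated until
positive definite). Frequencies and the standardized environment are both
centered and multiplied by the inverse Cholesky factor before Spearman
correlation, so shared drift cannot masquerade as environmental signal;
the decision variable is the top fraction (default 5%) of |ρ|, with an
optional permutation p. This is a deterministic analogue of MCMC
covariance/Bayes-factor machinery, keeping the same decision-variable
family. Note that standardization centers on the across-population mean,
so even independent populations show off-diagonal covariance −diag/(k−1);
the whitening accounts for this automatically.

## Gradient forest

Per SNP, a CART regression forest (variance-reduction splits,
mtry = ⌈p/3⌉, leaf size 5, bootstrap of populations, default 2000 trees)
is fitted to population allele frequencies; the in-package forest kernel
records out-of-bag predictions, out-of-bag permutation importances, and
every split's (predictor, threshold, impurity improvement) — the three
ingredients turnover construction needs — and is numba-compiled so
thousands of forests fit in seconds (sklearn's RandomForestRegressor
serves as an independent cross-check in the test suite).

Aggregation: SNPs with OOB R² ≤ 0 are discarded; each surviving SNP's
per-predictor importance share (permutation importances, negatives
clipped, normalized per SNP) is weighted by its R², giving I_{s,p}; the
overall importance I_p is the mean over surviving SNPs. Along each
predictor, split improvements are binned (201 equal-width bins over the
observed range), each SNP's bin mass normalized to its I_{s,p}, summed
over SNPs, divided by the histogram density of observed predictor values
(bins with splits but no observations get the mean density), cumulated,
and rescaled to end exactly at I_p. F_p is therefore monotone
non-decreasing with F_p(min) = 0 and F_p(max) = I_p, asserted on every
fit. Outside the fitted range F_p clamps flat — cumulative importance is
undefined where no splits were observed.

With 17 populations the OOB R² of individual SNPs is noisy; the
min-polymorphism filter (polymorphic in ≥ 5 populations) is enforced
before fitting, and only aggregate quantities (I_p, F_p) should be
interpreted.

RGB maps: centered PCA of the cells×predictors composition matrix; the
first three PCs are min–max scaled to [0, 255] (sign fixed by making the
largest-|loading| predictor positive; rank-deficient axes get mid-gray
128).

## Genetic offset

Offset is the Euclidean distance between current and future compositions
in the full transformed-predictor space — not a PCA reduction, which
would discard variance arbitrarily. It is symmetric in the epochs,
invariant to predictors with zero turnover, and zero wherever the shift
stays in a flat (clamped or split-free) region. It is a climate-only
mismatch measure: no migration, biotic interaction or demography.

## RDA and variance partitioning

MEM: Euclidean distances on coordinates, truncation t at the longest
minimum-spanning-tree edge, weights `1 − (d/(4t))²` within t (0 beyond),
doubly centered, eigendecomposed; positive-eigenvalue functions are
returned with Moran's I and a one-sided permutation p. The construction
reproduces `vegan::pcnm` eigenvectors exactly (frozen-oracle test). On a
regular transect the first eigenfunction is the broadest-scale sinusoid —
antisymmetric about the center with flattened ends, rank correlation
≈ 0.83 with the coordinate; this is a property of Moran-eigenvector bases
generally, worth knowing before interpreting "MEM1" as a simple gradient.
The default geographic set is the top three eigenfunctions with
significant positive spatial correlation (Moran p ≤ 0.05 and
I > −1/(n−1)), overridable.

RDA centers the response (population minor/alternate allele frequencies)
per SNP; R² = SS(fitted)/SS(total); adjusted R² by Ezekiel,
`1 − (1−R²)(n−1)/(n−p−1)`. Partial RDA residualizes response and
predictors on the conditioning set (rank-aware projection, so a fully
conditioned-away predictor contributes nothing) and reports fractions
relative to total response variance. Permutation tests permute response
rows (simple) or reduced-model residuals (partial); pseudo-F =
(R²/p)/((1−R²−R²_cond)/(n−p−q−1)). Forward selection adds the
best-gaining candidate if its marginal permutation p ≤ α, with the
standard double stop (α and the global model's adjusted R²). VIF
screening drops the highest-VIF column iteratively (later-listed dropped
on ties) until all ≤ 10.

Partition fractions are assembled by subtraction from the env-only,
geo-only, and combined models, so `env|geo + geo|env + confounded =
total explained` holds to machine precision; the confounded fraction is
not a testable hypothesis and carries no p-value.

## Problem sizes and numerical choices

The benchmark is 17 populations × 12 diploids × 500 SNPs (50 adaptive,
β = 2) on a 200-cell grid — large enough that the driver's rank-1 recovery
is stable across seeds, small enough for interactive use. Simulation-based
checks use the designs stated in the test suite (e.g. 500 replicates for
permutation-test calibration, 20 seeds for power/escalation ladders).
Tolerances: exact estimator identities are tested to 1e−12, eigenvector
contracts to 1e−10, cross-implementation agreement to printed or 1e−6
precision, stochastic rates to binomial-error bands. Ties are broken
deterministically everywhere (thinning by position then ID; VIF by column
order; PCA/MEM signs by largest-|loading| entry).
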