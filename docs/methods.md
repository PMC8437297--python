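# Methods

## The model

For one SNP and K traits, let **z** = (z_1, …, z_K) collect the per-trait
GWAS Z-scores.  Under the complete null, **z** ~ N(0, Σ_r), where Σ_r is the
residual Z-score covariance: for a trait pair measured in studies of sizes
n_1 and n_2 sharing n_s samples with phenotypic covariance ρ,

    σ_z = ρ · n_s / √(n_1 n_2).

With no overlap Σ_r is the identity; with complete overlap it equals the
phenotypic correlation matrix.  Under association, **z** gains a genetic
component whose cross-trait structure is summarized by the genetic
covariance Σ_g.

Two joint tests are built on this model:

* **omnibus** — the Wald statistic T = zᵗ Σ_r⁻ z, chi-square with K′ degrees
  of freedom where K′ is the rank retained by the pseudo-inverse.  It is
  invariant to orthonormal re-parameterizations of the trait space and
  decomposes exactly as the sum of sumZ statistics over the eigenvectors of
  Σ_r (`omnibus_eigen_identity` asserts this identity to 1e-8 relative).
* **sumZ** — T = (wᵗz)² / (wᵗ Σ_r w), chi-square with 1 df, for a weight
  vector w.  Supported weightings: all-ones (`unit`), first eigenvector of
  Σ_r (`pheno_pc1`), first eigenvector of Σ_g (`gene_pc1`), and an
  ICA-derived direction (`ica`): FastICA (deflation, seeded, at most K
  components) is run on the complete Z matrix and the component whose sumZ
  scan finds the most regions significant at 1e-8 that no univariate test
  finds is kept, ties broken by total significant regions then component
  index.

The omnibus is the better test when effects spread over many traits; a
well-chosen 1-df projection wins when the signal concentrates along one
direction (e.g. a single trait), which the power simulations reproduce.

## Estimating Σ_r and Σ_g

When the overlap parameters (ρ, n_s, n_1, n_2) are unknown, Σ_r is estimated
from genome-wide Z-scores:

* moment estimators — pairwise-complete covariance of the Z columns over all
  SNPs (`naive`), a random subset (`pruned`), or after removing SNPs
  significant in any trait at `trim_p` (default 5e-8, `trimmed`).  Causal
  SNPs with correlated effects bias the naive off-diagonals away from the
  truth; trimming shrinks that bias.
* LD-score regression — for each trait pair, z_j·z_k is regressed on the
  per-SNP LD score with weights 1/max(ℓ, 1): the intercept estimates
  (Σ_r)_jk free of polygenic contamination and the slope times M/√(n_j n_k)
  estimates (Σ_g)_jk; the per-trait diagonal uses z².  Standard errors come
  from a delete-one block jackknife over 200 contiguous blocks (configurable;
  tests use fewer blocks at reduced panel sizes).  The simple 1/ℓ weight
  keeps the intercept target at the panel sizes used here without modelling
  the full heteroskedasticity of the products.

Singular or near-singular Σ_r is inverted by an explicit policy:
`truncate` (default, eigenvalues > 1e-6 kept, df = retained rank), `floor`
(small eigenvalues raised to ε, df = K), or `ridge` ((Σ_r + εI)⁻¹, df = K).
Truncation keeps the omnibus calibrated on rank-deficient null panels, which
the tests verify at rank 50 of 100.

## Preprocessing

Per-trait tables go through: Z derivation from signed statistics and
p-values (z = sign(β)·Φ⁻¹(1−p/2); p = 0 floored at 1e-300, far beyond any
decision threshold); sample-size inference for rows missing N via
n̂ = 1/(se²·2f(1−f)), which targets N·var(residual) for linear models and is
proportional to N·p(1−p) for case/control logit models; allele
harmonization against a strand-unambiguous reference (swapped alleles flip
the sign of z, strand flips are complemented before matching, unmatched
orientations become missing); and masking of entries whose sample size is
below 70% of the trait's maximum (the per-trait reference is the 99.9th
percentile of n, resisting single-row typos).  The filter matters because a
single genome-wide Σ_r is wrong for SNPs measured on very different
subsamples: the heterogeneous-n simulation shows the omnibus median rising
with the spread of per-SNP sample sizes and returning to its nominal value
once the small-n entries are masked.

When both z and (β, se) are present but disagree by more than 0.1, the
p-derived value wins and the conflict is logged: the p-value is treated as
the canonical source.

## Imputation

Within an LD region, missing Z-scores are filled with the best linear
predictor given the observed ones, ẑ_t = Σ_{t,o}(Σ_{o,o} + λI)⁻¹ z_o, with
per-SNP quality q_t = Σ_{t,o}(Σ_{o,o} + λI)⁻¹ Σ_{o,t}.  Defaults: λ = 0.1,
quality threshold 0.6 (entries below it stay missing).  Observed entries are
never altered.  Because the conditional mean is a shrinkage predictor, the
joint statistics on imputed entries are slightly conservative, never
inflated; the paired null experiment (mask 20% of a complete panel,
re-impute, compare p-value distributions) keeps the Kolmogorov–Smirnov
distance under 0.02.  A post-imputation QC removes significant SNPs
(p < 1e-8) with no neighbouring SNP in LD (r² ≥ 0.2 by default) at
p < 1e-6 — isolated hits unsupported by their haplotype.

## Locus discovery

Signals are summarized per predefined LD block: the minimum joint p and the
minimum univariate p over the region classify it as `multitrait_only`
(new association), `univariate_only`, `both` or `neither` at the 1e-8
genome-wide threshold.  Lead SNPs come from greedy clumping in the PLINK
convention (smallest p first, absorb everything at r² ≥ 0.2; ties broken by
position then id; LD across regions treated as zero).  For clustering, SNPs
passing any of the three tracks (minimum univariate, ICA sumZ, omnibus) at
1e-8 are clumped and each clump is represented by its smallest-p member with
at least 60% of its trait profile observed.

## Mixture clustering with missing data

Selected SNP profiles are modelled as a k-component Gaussian mixture.  The
EM treats missing coordinates inside the model: the E-step evaluates each
component's likelihood on the observed sub-vector and the M-step completes
the sufficient statistics with the conditional mean and covariance of the
missing block, so no pre-imputation is needed.  Implementation choices:
k-means++ initialization on column-mean-completed data, 5 restarts by
default keeping the best log-likelihood; covariance eigenvalues floored at
1e-6; a collapsed component is re-seeded once, then the restart is declared
failed; components are re-ordered by the first coordinate of their means so
labels are reproducible.  The per-iteration log-likelihood is recorded and
is non-decreasing.

Assignment ambiguity is the posterior entropy −Σ_j p_j ln p_j (natural log;
the convention here is the standard signed entropy, with higher values
flagging ambiguous SNPs); SNPs above 0.75 are excluded from hard
assignments.  Note that for k = 2 the maximum attainable entropy, ln 2 ≈
0.693, is below that threshold, so the filter can only act for k ≥ 3.

The number of clusters is chosen by a compound rule on bootstrap curves:
for each k the model is refitted on random 80% subsamples, recording BIC and
the silhouette of hard assignments (Euclidean distance on data completed by
each SNP's conditional expectation under its assigned component).  The
silhouette tends to be conservative and BIC anticonservative, so if the BIC
optimum exceeds the silhouette optimum, k walks upward from the silhouette
optimum until a one-sided Welch test on the replicate silhouettes flags a
significant drop (α = 0.05) or the BIC optimum is reached.  Mirror clusters
induced by arbitrary allele coding (μ_a ≈ −μ_b) are a known phenomenon;
they are reported for inspection rather than auto-merged.

## Cluster profiles

With standardized effects β̂ = z/√N, the per-cluster genetic covariance of a
trait pair over M independent SNPs is the mean of the per-SNP contributions

    X_j = β̂_j1 β̂_j2 − n_s ρ_Y / (n_1 n_2),

whose correction term removes the bias that sample overlap and phenotypic
correlation add to the product of estimates; significance is a two-sided
one-sample t-test of mean(X) = 0.  The corresponding correlation divides by
per-trait variances corrected the same way, mean(β̂² − 1/n) (since
E[β̂²] = β² + 1/n); it is reported missing when a corrected variance is
non-positive.  A cluster's dominant direction is the first principal
component of its (column-centered) effect matrix, averaged over 20 random
re-codings of the coded allele with sign alignment to the first replicate —
centering makes the PCA sensitive to the arbitrary allele orientation, which
the shuffling averages out.  Profiles are aligned to that direction (sign
flip iff the dot product is negative), and concordance with an external
trait is assessed by an exact two-sided binomial sign test on the aligned
Z-scores (zeros excluded, at least 5 nonzero signs, SNPs thinned at the
stricter clump r² of 0.05).  Per-cluster variance-explained shares use
z²/n (the squared standardized effect) normalized per trait; shares under
0.1% are flagged as they are usually dropped from displays.

## Simulation engine

All generators are deterministic given a seed.

* Null panels: rows i.i.d. N(0, Σ_r), with Σ_r assembled from a random
  correlation matrix (eigenvalues from a flat Dirichlet scaled to sum K,
  randomly rotated) and an overlap fraction.
* Power scenarios (K = 10 by default): Z = Z_g + Z_res with Z_res ~ N(0, Σ_r)
  and Z_g per scenario — per-trait Uniform(−6, 6) (`random_eff`); correlated
  normal effects (`corG`); effects along one direction with isotropic noise
  of SD 1 (`wG`); independent strong effects, SD 4 (`highH`); strong effects
  on the first trait only (`hetH`).  The uniform bound ±6 is applied
  independently per trait; the SD-4 "high" scale and the wG geometry are
  free parameters of the design, chosen so that power at genome-wide
  thresholds is neither saturated nor negligible.  The residual correlation
  is either independent of the genetic one (`random`) or the 0.4/0.6 mixture
  of the genetic correlation with a random matrix, projected to the nearest
  correlation matrix (`aligned`).
* Individual-level data (≤ 10⁴ × 10⁴ by design): genotypes Binomial(2, f)
  with f ~ U(0.01, 0.99), standardized; phenotypes linear in a causal subset
  plus correlated normal noise, optionally quantile-transformed so thirds of
  the traits get uniform / Laplace / exponential margins.  Univariate
  Z-scores use the exact monotone t→z map; the per-SNP MANOVA p-value uses
  the single-predictor Wilks' lambda, Λ = 1 − ρ_c² with ρ_c the canonical
  correlation, and its exact F transform.
* LD-structured panels: AR(1) correlation r^|i−j| within blocks; Z drawn
  with covariance LD ⊗ Σ_r and mean LD·effects, so causal signal propagates
  to neighbours as in a real GWAS.
* Mixture panels: labels ~ Multinomial(π), rows component-normal, MCAR
  missingness (every row keeps at least one observed coordinate).  The
  three-component reference fixture separates means by 10 SDs along every
  coordinate so cluster identity stays identifiable when individual
  coordinates are missing.
* Heterogeneous-n panels: a random subset of (SNP, trait) entries comes from
  a nested 30% subsample, giving each SNP its own true Σ_r.

What the generators deliberately do not emulate: LD between blocks,
allele-frequency-dependent architectures, population stratification, and
non-MCAR missingness.  Passing tests therefore validate the statistical
machinery under its stated assumptions, not robustness to those further
features of real data.

## Problem sizes and numerical choices

Validation runs use 10⁵ SNPs for calibration checks, 2 000 SNPs × 5 000
individuals for the MANOVA comparison, 50 replicates × 500 causal SNPs for
power orderings, and 20 seeds × 2 000 SNPs for mixture recovery; bootstrap
model selection in tests uses 5 replicates per k with 3 EM restarts (the
library defaults are 100 and 5).  ICA calibration checks scale the panel
with the trait count (10⁴ SNPs per trait) because the component-selection
adaptivity vanishes at genome-wide panel sizes but is visible on very small
panels.  Tolerances: symmetric-matrix checks at 1e-10, the eigen identity at
1e-8 relative, imputation against its closed form at 1e-10, EM monotonicity
at 1e-8 per step.  Monte-Carlo assertions use 3 binomial/empirical standard
errors.

## Known limitations

* The LDSC weighting is the simple 1/ℓ scheme; in very high-heritability
  regimes a full heteroskedasticity model would be more efficient.
* Indels and multi-allelic records are rejected at parse time; strand
  ambiguous (A/T, C/G) SNPs must be excluded from the reference.
* Imputation is within-region only; SNPs in regions with no observed
  neighbour stay missing.
* The disease sign test treats SNPs as exchangeable after 0.05-r² thinning;
  residual LD inflates its effective sample size slightly.
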