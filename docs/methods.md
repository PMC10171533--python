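# Methods

## The model

`genomicpca` operates entirely on GWAS summary statistics. For trait *i*
and SNP *j* it consumes the signed statistic Z<sub>ij</sub>, the
per-variant sample size N<sub>ij</sub>, and reference LD scores
ℓ<sub>j</sub> with their SNP count M.

**LD score regression.** SNP-heritability and confounding are separated
by regressing association statistics on LD scores:

    E[χ²_ij] = intercept_i + (N_ij · h²_i / M) · ℓ_j
    E[Z_ij · Z_kj] = CTI_ik + (√(N_ij N_kj) · σ_g,ik / M) · ℓ_j

The slope of the cross-trait regression estimates genetic covariance
σ<sub>g,ik</sub>; the free intercept (CTI, cross-trait intercept)
absorbs the correlation between the two GWAS's sampling errors — under
full sample overlap it converges on the phenotypic correlation of the
two traits. Genetic correlation is r<sub>g,ik</sub> =
σ<sub>g,ik</sub>/√(h²<sub>i</sub>h²<sub>k</sub>), clamped into [−1, 1]
with a logged count.

Both regressions use two weighted passes. Pass 1 weights by
1/max(ℓ<sub>j</sub>, 1); pass 2 additionally divides by the squared
model-predicted statistic scale, (1 + N̄ĥ²ℓ<sub>j</sub>/M)² for the
univariate fit and the product of the two traits' terms for the
cross-trait fit, with ĥ² taken from pass 1 and clamped to [0, 1] for
weighting only. Standard errors come from a delete-a-block jackknife
over contiguous variant blocks (default 200 blocks); the rg standard
error deletes the same blocks jointly from the cross-trait and both
univariate regressions. Intercepts are never constrained — the PC-GWAS
synthesis consumes them.

**Genomic PCA.** The k×k genetic correlation matrix is eigendecomposed.
Standardised loadings are eigenvector × √eigenvalue, so squared loadings
sum to one per trait and the variance explained by component *c* is
λ<sub>c</sub>/k. Component signs are fixed so each component's mean
loading is nonnegative; eigenvalue ties fall back to the solver's
deterministic order, hence input trait order. Sampling noise can push
the assembled matrix slightly indefinite; it is then projected to the
nearest positive-semidefinite correlation matrix by Higham-style
alternating projections with Dykstra correction (fixed point for inputs
already PSD; tolerance 1e-10, at most 200 sweeps), and the smallest raw
eigenvalue is recorded.

**PC-GWAS synthesis.** With PC1 loading vector **w** and CTI matrix
**C** (unit diagonal by convention; a configuration switch places the
univariate intercepts on the diagonal instead),

    z_pc,j = Σ_i w_i Z_ij / √(wᵀCw)
    n_eff,j = (Σ_i w_i √N_ij)² / (wᵀCw)
    β_j = z_pc,j / √(n_eff,j · 2 p_j (1 − p_j)),   se_j = β_j / z_pc,j

with p<sub>j</sub> the effect-allele frequency of the reference frame.
The √(wᵀCw) denominator is the sample-overlap correction: it is exactly
the standard deviation of the weighted Z sum when the per-SNP nulls are
correlated as **C** describes, so the synthesized statistic keeps unit
null variance even when every input GWAS used the same individuals.
z_pc is invariant to positive rescaling of **w**; the variant frame is
the strict intersection of the inputs, so the weight vector is never
renormalised per variant. Combination happens in the Z domain (inputs
may be on arbitrary per-trait scales) and β/se are back-converted on the
standardised scale. Only PC1 gets a synthesized GWAS; later components'
loadings are reported but not combined.

**Chance baselines.** Parallel analysis draws symmetric unit-diagonal
null matrices whose (i, j) cell is Normal(0, se<sub>ij</sub>) using the
per-cell jackknife SEs, smooths each draw to PSD, and retains components
whose observed eigenvalue exceeds the per-rank null quantile (default
0.95). This cell-wise null is a deliberate simplification — it matches
the information the jackknife provides and ignores sampling dependence
between cells. The random-grouping null samples same-size trait subsets
uniformly and records PC1 r²; the empirical p-value uses the add-one
correction (1 + #{null ≥ observed})/(B + 1). Draws identical to the
observed member set are redrawn, since the null describes *alternative*
groupings; in the degenerate case group_size = k no alternative exists
and every draw equals the observed (p = 1).

**Phenotypic arm and comparisons.** Phenotypic PCA runs the identical
eigen path on a Pearson correlation matrix of (optionally
covariate-residualised) trait values, with pairwise-complete
observations. Loading and correlation-vector comparisons use OLS with
intercept; p-values use the t distribution with n−2 df and are
descriptive only, because stacked correlation-matrix cells are not
independent. Tucker congruence is Σa<sub>i</sub>b<sub>i</sub>/√(Σa²Σb²).
Age sensitivity is the per-trait pairwise-complete Pearson correlation
with age. Network-size adjustment divides per-network effects by member
counts.

**One-factor model.** The common-factor fit minimises the unweighted
least-squares discrepancy between observed off-diagonal correlations and
λλᵀ over λ ∈ [−1, 1]<sup>k</sup> (L-BFGS-B, analytic gradient, start at
the first-eigenvector loadings, objective tolerance 1e-14, iteration
budget 10,000). A full SEM treatment would weight by the sampling
covariance of the matrix cells; that matrix is out of scope here, so fit
quality is summarised by SRMR over off-diagonal residuals and no model
χ² is reported — a stated fidelity gap, not an oversight. The
factor-external extension jointly refits λ and ρ with the external
trait's indicator correlations modelled as ρλ<sub>i</sub>; |ρ| > 1
before clamping and negative residual variances are flagged as Heywood
cases and clamped. Degenerate input rule: when every off-diagonal is
numerically zero the canonical solution λ = 0 is returned directly
(the eigenvector start is itself a perfect-fit stationary point there,
but an arbitrary one).

## The synthetic-data generator

The generator emulates the target study design: tens of volumetric
traits measured on the same individuals, SNP-heritabilities of a few
tenths, a dominant shared genetic dimension, and full sample overlap.

*Genotypes.* SNPs come in LD blocks (default 10 SNPs). Per block, two
latent Gaussian haplotype vectors with exchangeable correlation ρ are
thresholded at each SNP's MAF (drawn from Uniform(0.05, 0.5)), giving
Hardy–Weinberg dosages. ρ is drawn per block from Uniform(0, 0.95) by
default — real genomes have strongly heterogeneous LD, and a constant ρ
makes every LD score nearly equal, leaving the LDSC slope poorly
identified; a scalar ρ remains available and is what the validation
experiment t1 uses. The analytic LD score is ℓ<sub>i</sub> = 1 +
Σ<sub>j≠i</sub>(r²<sub>ij</sub> + (1 − r²<sub>ij</sub>)/(n − 1)), where
r<sub>ij</sub> comes from bivariate-normal orthant probabilities
(96-node Gauss–Legendre quadrature) and the (1 − r²)/(n − 1) term is the
expected *in-sample* excess — what regression on in-sample GWAS
statistics actually responds to.

*Traits.* Per-SNP causal effects on the standardised-genotype scale are
λ<sub>t</sub>f<sub>j</sub> + √(1 − λ<sub>t</sub>²)u<sub>tj</sub> with f
and u i.i.d. standard normal; several correlated shared factors are
supported via a factor-assignment vector and factor correlation matrix.
Genetic values are rescaled so realised genetic variance equals
h²<sub>t</sub> exactly (fixed-effects architecture: effects are drawn
once per study). Environmental noise is drawn with correlation
proportional to the genetic correlations by default (the Cheverud
regime, which makes genetic/phenotypic congruence a recoverable
property) or independent via a switch. Defaults: k = 10 traits, λ = 0.63
and h² = 0.25 each, n = 10,000 individuals, 20,000 SNPs — giving a true
genetic-PC1 variance share of λ² + (1 − λ²)/k ≈ 0.43, i.e. a dominant
first dimension of roughly 40%.

*GWAS.* Per-SNP simple linear regression of the standardised phenotype
on centred dosage (covariates residualised from the phenotype first),
vectorised and chunked; monomorphic SNPs are dropped with a count. The
phenotypic-PC1 GWAS regresses scores built as standardised phenotypes ×
sample PC1 loadings. A study is bitwise-deterministic given its seed.

*What the generator does not emulate.* Realistic LD maps and MAF
spectra, annotation structure, relatedness, population stratification,
binary traits, trait-specific missingness. Passing tests therefore show
the estimators are correct under their own assumptions at desk scale,
not that real-data QC choices are optimal.

## Validation experiments and problem sizes

The package ships four canned experiments (`genomicpca.experiments`),
all deterministic given a seed; `scripts/acceptance.py` reruns the first
two and the test suite covers all four:

* **PC-GWAS validation** — k = 10, n = 10,000, 20,000 SNPs in blocks of
  10 with scalar ρ = 0.8, λ = 0.8, h² = 0.3, full overlap. The genetic
  correlation between the synthesized genetic-PC1 GWAS and the direct
  phenotypic-PC1 GWAS is ≈ 1 (observed ≥ 0.999).
* **Intercept agreement** — k = 20, n = 10,000, 50,000 SNPs, loadings
  spread so true phenotypic correlations cover ≈ [−0.21, 0.90];
  regressing the 190 estimated CTIs on true phenotypic correlations
  gives R² > 0.99 with slope ≈ 1.
* **Null calibration** — k = 5 all-noise traits (h² = 0) sharing
  correlated environment on n = 4,000, 10,000 SNPs: mean χ² of the
  synthesized statistics stays within a few percent of 1.
* **Factor–PC correlation** — 7 one-factor "cognitive" indicators plus
  8 "brain" traits on a second factor (n = 6,000, 12,000 SNPs), with the
  factor–factor correlation calibrated so the implied correlation
  between the cognitive factor and the brain-PC1 composite is 0.20
  (the attenuation λ_b/√(λ_b² + (1 − λ_b²)/k_b) is accounted for).

These sizes keep each experiment in the minutes range on one CPU while
leaving the estimators enough information to be identified; they are the
package's chosen desk-scale study conditions.

## Known limitations

* At desk scale, per-pair r_g errors are strongly correlated across the
  matrix (the shared factor is realised once per study), so aggregate
  matrix distances fluctuate more than per-cell jackknife SEs suggest;
  recovery guarantees are therefore stated per quantity (within 2
  jackknife SEs), not as matrix norms.
* CTI diagonals are fixed at 1 by convention (Z variance ≈ 1 after QC);
  traits with appreciable uncorrected confounding would violate this,
  which is why the univariate-intercept diagonal is exposed as a switch.
* The parallel-analysis null and the ULS factor fit both ignore sampling
  dependence between correlation-matrix cells.
* rg jackknife SEs treat blocks as exchangeable; with very few blocks or
  strongly heterogeneous information per block they are rough.
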