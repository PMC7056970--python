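# Methods

## Synthetic doubled-haploid populations

The generator emulates a connected biparental DH population. Parents are
independent fully homozygous haplotypes with allele frequency 0.5; family
*f* crosses parents (*f* mod *P*, *f*+1 mod *P*), a chain that uses every
parent and shares parents between consecutive crosses, keeping the panel
genetically connected. Each DH line is one recombinant gamete of the F1,
doubled — so genotypes are coded −1/+1 with no heterozygotes. Meiosis
uses the Haldane model (crossovers as a Poisson process on the genetic
map, no interference), which gives the closed-form recombination fraction
c = (1 − e^(−2d/100))/2 used as a test oracle. Markers are evenly spaced,
apportioned to chromosomes by genetic length; the default map is seven
chromosomes of 150 cM (≈1050 cM total, barley-like). The default design
mirrors a real malting-barley experiment: 145 lines in four families
(33/39/45/28) from five parents, eight traits, nine environments with two
blocks, eight replicated check lines per environment (augmented partially
replicated layout). All constants are overridable.

**Genetic covariance through marker effects.** Marker effects for the *t*
traits are drawn MVN with covariance Σ_g/m_eff (m_eff = Σ 2p(1−p)) and
breeding values are u = Wα with W the column-centered genotypes. On a
linked genome with ±1 coding the realized covariance of Wα overshoots the
target (per-marker variance is 4p(1−p), and LD between linked markers
adds further covariance), so the effect matrix is linearly recalibrated —
α ← αTᵀ with T = Σ_g^{1/2} C_raw^{−1/2} — making the realized
breeding-value covariance equal Σ_g exactly while preserving the additive
identity u = Wα. This exact standardization (as simulation toolkits in
this field commonly do) gives sharp, known truth for heritability and
genetic-correlation recovery.

**Phenotypes.** Per plot and trait: y = μ + E_env + B_block(env) + u +
GE_(line,env) + e, with environment, block and GEI effects independent
normal at configured variances, and residuals drawn with covariance Σ_e
across traits within a plot. GEI is unstructured white noise per
line×environment — adequate for variance-component work; it does not
emulate structured GEI (e.g. factor-analytic environment loadings).

**What the generator does not emulate:** real allele-frequency spectra
and map heterogeneity, dominance/epistasis (meaningless for fully inbred
DH material in an additive model), selection, structured GEI, or
non-Gaussian trait distributions. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
performance on real field data.

## BLUEs, variance components and Cullis H²

The trial model above is fitted by EM-REML on Henderson's mixed-model
equations with i.i.d. random effects (environment, block-in-environment,
GEI, and genotype when random). EM was chosen over average-information
REML because it is monotone in the restricted likelihood (asserted in
tests) and never produces negative components; convergence is a relative
log-likelihood change < 1e−8 or 500 iterations (fits flag
non-convergence rather than raising). A variance floor of 1e−10 × var(y)
prevents division blow-ups when a component collapses. For a
single-environment scope the E and GEI terms drop, matching how
per-environment BLUEs are conventionally computed. BLUEs are reported as
intercept + genotype effect (first genotype as reference) so they live on
the trait scale; standard errors come from the inverse coefficient
matrix.

Cullis heritability refits the same model with genotype random and reads
the genotype prediction-error-variance block from the inverse coefficient
matrix: H² = 1 − v̄_BLUP/(2σ²_g), clamped to [0, 1], with a degenerate
flag when σ²_g ≈ 0. On balanced designs this tracks the plug-in
line-mean formula σ²_g/(σ²_g + σ²_ge/e + σ²_e/(eb)) within ≈0.05
(tested), which is how the recovery targets 0.30 and 0.66 are
constructed (e = 3 environments, b = 2 blocks, fully replicated). The
heritability-recovery runs cap EM at 150 iterations: the component
estimates stabilize long before the strict likelihood tolerance, and the
cap keeps 40 replicate fits at desk scale.

Trait and environment correlations are pairwise-complete Pearson r with
two-sided t-based p-values (unadjusted, α = 0.05 convention); the PCA
used for correlation-driven trait sets is an eigendecomposition of the
trait correlation matrix on complete cases, with loadings sign-fixed so
each component's largest-magnitude loading is positive.

## Kinship

VanRaden method-1 on the −1/0/+1 scale: per-marker mean imputation of
missing codes, centering by 2(p − 0.5), K = WW′/(2Σp(1−p)). For fully
inbred DH lines the expected diagonal is 1 + f = 2 under this scaling
(tested as a Monte-Carlo property). QC removes markers with call rate
< 0.95, minor allele frequency < 0.05 (strict inequality — a marker at
exactly 0.05 is kept) or no chromosome assignment, then re-orients codes
so −1 is the minor allele in the retained line set; MAF counts alleles,
so a heterozygous call contributes one of two. A fixed jitter of 1e−6 is
added to the diagonal only when the smallest eigenvalue is negative
(duplicated inbred lines make K singular), recorded on the object,
because the samplers factorize K.

## Single-trait Bayesian GBLUP

y = 1μ + u + e with u ~ N(0, Kσ²_g) and e ~ N(0, Rσ²_e), R = I by
default or diag(1/w) with precision weights (e.g. 1/se² of the BLUEs).
This is the K-parameterized form of Bayesian ridge regression — the two
are the same model when K = WW′/c — implemented in the K form because
the multi-trait model needs it anyway. Priors: scaled-inverse-χ² with
df = 5 for both variances, scales set so the prior modes split the
phenotypic variance by prior_R2 = 0.5 (the genetic scale divided by
mean diag K to account for the inbred scaling); flat prior on μ. The
sampler rotates once into the eigenbasis of the observed-lines kinship
block (O(n³) once, O(n) per iteration); with heterogeneous weights the
rotation no longer diagonalizes jointly and a dense Cholesky per
iteration is used instead. Genetic values of unphenotyped lines are
drawn each iteration from their conditional normal given the observed
lines' values. Defaults: 3000 iterations, 1500 burn-in, no thinning, one
chain; a split-half correlation of the posterior-mean genetic values is
stored as a convergence guard.

## Multi-trait Bayesian GBLUP

vec(Y) = μ + u + e with u ~ MVN(0, Σ⊗K) and e ~ MVN(0, R⊗I); Σ
unstructured, R diagonal by construction — residual covariances between
traits are deliberately not estimated, so any CV2 gain is attributable
to the genetic covariance alone. Full conditionals per iteration:
(a) missing cells of Y from N(μ_j + u_ij, r_j) (data augmentation —
with diagonal R the missing entries are conditionally independent);
(b) genetic values jointly across traits in the eigenbasis of K — each
eigencomponent has a t×t Gaussian conditional with precision
R⁻¹ + Σ⁻¹/d_i, batched over components through one t×t
eigendecomposition per iteration; (c) Σ from an inverse-Wishart with
df = t + 2 + n and scale S₀ + V′D⁻¹V, prior scale S₀ = 0.5 × diag of
the observed phenotypic covariance (weakly informative, proper; jitter
and redraw on a numerically non-PD conditional, counted on the fit);
(d) each r_j from a scaled-inverse-χ² (df 5); (e) per-trait intercepts
from flat-prior normals. Initialization: μ = observed trait means,
U = 0, Σ = 0.5 × phenotypic diag, R = 0.5 × phenotypic variances.
Augmentation rather than marginalization makes CV1 and CV2 pure masking
patterns over one code path. A `diagonal_sigma` switch constrains Σ
diagonal, which provably reduces the fit to stacked single-trait fits
(tested at correlation > 0.99).

`conditional_mean_oracle` builds the exact joint covariance
Σ⊗K + R⊗I and returns conditional means of unobserved cells by a direct
solve — feasible to n·t ≈ 2000 — and is the independent cross-check for
the sampler's missing-value predictions (agreement within 2% of the
prediction SD at fixed parameters).

## Cross-validation and trait-set strategies

60/40 random line splits, reproducible per repeat from derived RNG
streams; 100 repeats by default (the conventional setting), 20-ish in
the acceptance runs to stay at desk scale. CV1 masks all model traits of
test lines; CV2 masks only the target — test lines' correlated-trait
phenotypes remain in the likelihood as observed data. `compare_schemes`
runs ST-CV1, MT-CV1 and MT-CV2 on shared partitions so scheme contrasts
are paired rather than confounded with partition noise. Predictive
ability is the Pearson correlation between predicted genetic values and
held-out BLUEs; degenerate (constant) predictions are recorded missing.
Strategies: AGRO = {YLD, TGW, GM2, PLM}; A+M adds {BGL, EXT, SNI, GPC};
COR1 = {BGL, PLM, SNI, GPC} (the protein-correlated set); COR2/COR3 =
top-4 |loading| traits on PC1/PC2 of the BLUE correlation matrix, with
the target appended when absent. Un-phenotyped-environment prediction
stacks each (trait × environment) BLUE as a separate variable of the
multi-trait model — the target variable is (target trait, target
environment) and CV2 keeps test lines' source-environment records — a
parameterization chosen over averaging environments because it needs no
extra machinery and exposes leave-one-location/year-out directly.

## Study conditions for the CV experiments

The CV2-gain experiments use 300 DH lines as 150 two-line families from
151 chained parents, 2000 markers on 7×150 cM, one phenotype record per
line, target trait h² = 0.3 with a helper trait at h² = 0.6 and genetic
correlation 0.8 (or 0 for the null check). The many-small-families
design is the realistic early-generation cohort for this question: with
few large full-sib families, long DH haplotype blocks make kinship-only
prediction so accurate (r_PA ≈ 0.45 at h² = 0.3) that a helper trait is
nearly redundant and CV2 gains shrink to a few percent — a property of
the closed-form conditional mean, not of the sampler. With many small
families, kinship-only r_PA sits in the realistic 0.1–0.3 range and the
helper phenotype carries genuinely new information; the relative CV2
gain is then 50–100%. Comparisons are pooled over three independent
populations (7 paired repeats each) because a single simulated genome
leaves substantial between-population variance in CV1 accuracy. CV-heavy
runs use shortened chains (600 burn-in / 1200 iterations); spot checks
against the default 1500/3000 chains showed differences in mean r_PA
well under the repeat-to-repeat spread.

## Numerical choices and limitations

- Eigenvalues of K clipped at 1e−12 in the samplers; null directions
  then carry prior-only information, which is the correct limit.
- Scaled-inverse-χ² draws use (df·s² + SS)/χ²_df; inverse-Wishart draws
  via scipy with the fit's own Generator, so fits are bit-reproducible
  from their seed.
- EM-REML is O(m³) per iteration in the mixed-model-equation dimension m
  (dense Cholesky + inverse); intended for desk-scale trials (m up to a
  few thousand), not national MET databases.
- The Gibbs samplers run a single chain; the split-half diagnostic is a
  guard, not a substitute for multi-chain convergence assessment.
- Posterior-mean genetic correlations shrink toward zero when a trait's
  heritability is weakly identified (small families, low h²); recovery
  tests therefore use designs where Σ is identifiable, and the same
  shrinkage should be expected on comparably weak real designs.
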