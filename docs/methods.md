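# Methods

## Model

For individual `j` in full-sib family `k` with phenotype `Y_kj` and
genotype codes `x_kjm` at `M` bi-allelic markers,

    Y_kj = α + Σ_m β_m x_kjm + u_k + ε_kj,   ε_kj ~ N(0, σ²).

Priors: `α ~ N(0, c)` with `c = 10⁶` by default (a fixed variance, not
scaled by σ²); each `β_m` follows the mixture-of-uniforms density

    p(β) = p0/(2b) · I(−b,b)(β) + (1−p0)/(2(l−b)) · [I[−l,−b](β) + I[b,l](β)];

`u_k ~ N(0, σ_u²)` i.i.d. (optional; families are treated as
conditionally independent, deliberately ignoring half-sib and
parent–offspring covariances); `σ²` and `σ_u²` carry inverse-gamma
priors with shape `s` and rate `r` (density ∝ x^−(s+1) e^(−r/x); mode
r/(s+1); the default s = r = 0.01 approaches the scale-invariant 1/σ²
prior and has no finite mean).  At the boundary points ±b the density
takes the slab height — the indicator notation places closed intervals
on the slabs — a measure-zero choice fixed for determinism.

The hyper-parameters are interpretable: `p0` is the prior probability
that a marker's effect is negligible (so the QTL count
`N_Q = Σ_m I(|β_m| ≥ b)` has prior mean `M(1−p0)`), `b` is the border
between negligible and real effects, and `l` bounds the effect size.
Integrating the density gives `Var(β) = (1/3)[b² + l(l+b)(1−p0)]`,
which connects a prior specification to an implied heritability:
`h² = 2 Var(β) Σ f_m(1−f_m) / V_P` for −1/0/1 codes under
Hardy–Weinberg and linkage equilibrium, and `h² = M Var(β)/V_P` when
genotype columns are standardized.  These values are intentionally not
clipped to (0, 1): extreme prior specifications imply impossible
heritabilities, and the package reports them as such.

## Fully conditional distributions

The conjugate-normal likelihood times the step prior gives, for each
marker with column `x_m`, partial residual `r` and
`μ̃ = x_m'r / x_m'x_m`, `τ² = σ² / x_m'x_m`, a three-component mixture
of truncated normals on (−b, b), [−l, −b] and [b, l]: component `j`
with prior height `h_j` has weight ∝ `h_j·[Φ((hi_j−μ̃)/τ) −
Φ((lo_j−μ̃)/τ)]` and truncated `N(μ̃, τ²)` shape.  The intercept and
family-effect conditionals are the usual conjugate normals
(`var = (N/σ² + 1/c)⁻¹` etc.), and both variance conditionals are
inverse-gamma with shape `s + N/2` (resp. `s_u + K/2`) and rate
`r + SSE/2` (resp. `r_u + Σu_k²/2`).  These forms are derived here
directly from the hierarchy above and are guarded by adaptive-
quadrature oracles in the test suite (conditional mean and
P(S_m = 1) to 1e−6 over randomized instances, and a dense-grid
two-marker posterior check against the full sampler).

## Gibbs sampler

Each iteration performs a fixed systematic sweep α → β_1..β_M →
u_1..u_K → σ_u² → σ², maintaining the residual vector incrementally so
a marker update costs O(N); the residual is recomputed and compared
every `residual_check_every` iterations (1e−8 tolerance) to bound
drift.  Defaults mirror a long production run (220 000 iterations,
20 000 burn-in, thinning 20); the tests use 20 000-iteration chains.
Initialization: α = ȳ, β = 0, u = 0, σ² = var(y)/2, σ_u² = var(y)/100
(overridable; chains are expected to be compared across seeds and
priors).  One seeded generator drives each chain; the chain id offsets
the seed so parallel chains are independently reproducible.

Numerical policy for the marker update: component weights are computed
in log space using complementary-CDF (erfcx-based) forms on the far
side, so they remain finite for conditional locations at least 10³ τ
from the support; if all three log weights underflow to −∞ the update
falls back to the component nearest μ̃.  Truncated-normal draws use
inverse CDF with uniforms clamped to [1e−15, 1−1e−15]; beyond eight
standard deviations into a tail the quantile starts from the
exponential-tail approximation and is polished with Newton steps on
the exact CDF.  The hot sweep is numba-compiled; the scaled
complementary error function and the normal quantile (Wichura's AS241)
are implemented in nopython form and unit-tested against scipy.

## Generalized EM

GEM iterates the same sweep but replaces each parameter by its fully
conditional *expectation*: β_m ← the mixture-weighted truncated-normal
mean (means, not modes — for this conditional they differ), α ← the
conditional normal mean, σ² ← rate/(shape−1) (finite since
shape = s + N/2 > 1 for N ≥ 2).  Family effects are excluded by
default and can be enabled.  Convergence is declared when the summed
absolute parameter change over one sweep falls below
`tol_per_param × n_params` with `tol_per_param = 1e−7` and
`n_params = M + 2` (plus K + 1 with the polygenic block); "sum of
deviations" is read as a sum of absolute values so the criterion is a
norm.  The iteration is RNG-free and bit-reproducible; it converges to
a possibly local MAP point, and multi-start from other initializations
is left to the caller.  On standardized problems of a few hundred
individuals and markers it converges in tens of sweeps.

## Inference

Posterior inclusion probabilities are the fraction of stored draws
with `b ≤ |β_m| ≤ l` (the boundary counts as included), clipped to
[1/(2T), 1−1/(2T)] for T stored draws so that Bayes factors stay
finite; the clip constant is configurable.  `2 ln BF` is classified
with the Kass–Raftery bounds (>10 very strong, (6,10] strong, (2,6]
positive, (0,2] bare mention).  Whole-model summaries:
`N_Q = Σ_m S_m` per draw, and `h_M² = 1 − (σ² + 2σ_u²)/var(Y)` — the
factor 2 because the additive genetic covariance between full sibs is
one half; the sample variance of Y stands in for the phenotypic
variance, ignoring relatedness.  Per-marker variance explained uses
`%PVE = 2·MAF(1−MAF)·E_post[β²]/var(Y)` with the posterior mean of β²;
summing %PVE over markers underestimates the joint contribution
because LD covariances between markers are not included.

Robustness across chains run under different priors: markers are
ranked by descending 2 ln BF within each chain (average ranks on
ties — a conventional choice), and the marker-specific mean rank
across chains is the consensus ordering; the across-chain mean, min
and max of 2 ln BF accompany it.  Pairwise Spearman correlations and
mean ratios of 2 ln BF over a chosen signal subset (all values must be
positive for the ratios) quantify agreement in ranking and in
magnitude separately; `mean_ratio[i, j]` averages chain i over chain j.

## Prediction and cross-validation

`GEBV_i = Σ_m β̂_m x_im` with β̂ the posterior mean (MCMC) or the GEM
point estimate; estimated family effects are never carried into
prediction (they are defined only for training families).  Metrics:
Pearson correlation with TBV (simulated data) or with phenotype
divided by √h² (cross-validation); Spearman rank correlation among the
⌈N/10⌉ individuals with the largest TBV (stable tie-breaking on the
index); and the slope of regressing the target on GEBV (1 = unbiased).

Both 10-fold CV layouts partition all individuals: scheme I keeps each
full-sib family inside one fold (45 whole families per fold in the
450-family design), scheme II assigns each family's sibs to distinct
folds and therefore requires family sizes ≤ the fold count (larger
families raise an error rather than wrapping silently).  Within each
fold, genotype columns and the phenotype are standardized on the
training folds only, markers monomorphic in the training folds are
dropped for that fold, and held-out GEBV are computed with training
scaling constants and translated back to the trait scale.  SIS
pre-selection (rank by absolute marginal correlation after a MAF
filter, default 0.05) runs inside each training fold by default; a
`leaky_sis` flag reproduces the shortcut of screening on all
individuals, which leaks validation information and measurably
inflates null accuracy — the test suite demonstrates the inflation.
Combined GEBV are unweighted means across prior specifications (equal
weight per specification).  Standardization for CV accuracy uses
training-fold statistics; a global-statistics variant is available by
transforming the inputs beforehand.

## Synthetic data

The simulator gene-drops a sire×dam pedigree: founders (15 sires + 150
dams at full scale) receive haplotypes drawn independently per marker
at allele frequencies uniform on (0.05, 0.5) (founder linkage
equilibrium; the range is configurable since the original data's
frequency spectrum is not documented), and offspring gametes follow
Haldane's no-interference model with recombination fraction
`r = (1−e^(−2d))/2` between adjacent markers at distance d Morgan.
Linkage disequilibrium therefore arises only through co-segregation in
the pedigree — which is the structure the sampler must cope with — and
founder LD, selection, and mutation are absent; passing tests speak to
pedigree-driven LD, not to arbitrary population histories.  Half-sib
structure is generated (sires mate several dams) even though the
analysis model only knows full-sib families, mirroring the deliberate
model simplification.  QTL are placed at random marker positions with
normal effects (or caller-fixed effects), true breeding values are
`TBV_i = Σ_q a_q x_iq` on centered codes, and the residual variance is
solved so that `var(TBV)/(var(TBV) + family_env_var + σ_e²)` equals
the target h² on the realized training sample; an optional
family-environment variance, distinct from the analysis model's u_k,
enables misspecification scenarios.  Validation generations carry
genotypes and TBV but their phenotypes are withheld.

Presets: the full-scale design (6 chromosomes × 1000 markers at
0.1 cM, 1500 offspring per generation, 3 + 3 generations, 50 QTL,
h² = 0.30) mirrors the published study; the desk-scale preset
(2 × 250 markers, 15 sires × 6 dams × 6 offspring = 540 training
individuals in 90 families, one validation generation, 10 QTL,
h² = 0.30) is the problem size used throughout the test suite and
keeps a four-chain Gibbs analysis under a minute.

## Numerical and design choices

* Standardization uses the population (1/N) variance so "variance 1"
  is exact on the training set; the convention is fixed, not estimated.
* MAF is computed as mean dosage / 2, so imputed non-integer dosages
  contribute fractionally; explicit missing values raise.  MAF
  filtering is computed on the analysis set.
* Prior specifications stated in phenotypic-standard-deviation units
  (l set to sd(Y)) map to the standardized analysis scale by dividing
  b and l by sd(Y) (`MUPriorSpec.scaled`); the same conversion is
  applied for GEM on standardized data.
* Update order is a fixed systematic sweep in marker index order, not
  a random permutation.
* The two-marker grid oracle fixes σ² and α during sampling (via
  `GibbsConfig.fixed_sigma2` / `fixed_alpha`) so the comparison
  targets exactly the marginal the grid integrates.
* In detection checks against simulated truth, a QTL counts as found
  when a top-ranked marker lies within 5 cM on the same chromosome:
  at 0.1 cM spacing the causal column and its immediate neighbours are
  statistically interchangeable within families.

## Known limitations

* Single trait, additive effects only; no dominance, epistasis or
  imprinting; bi-allelic markers only.
* The polygenic term is a full-sib family effect, not a kinship-matrix
  polygenic component.
* No hyper-priors on (p0, b, l): sensitivity is addressed by running
  several specifications and combining, not by adding a hierarchy
  layer.
* GEM finds one fixed point; no convergence diagnostics beyond the
  deviation trace, and no MCMC diagnostics beyond cross-chain
  comparisons.
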