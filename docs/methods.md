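# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic generator's assumptions, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Landmark morphometrics

**Superimposition.** Generalized Procrustes Analysis removes position, scale
and orientation: each configuration is translated to zero centroid, scaled to
unit centroid size, and rotated onto the iteratively re-estimated consensus.
Rotations are pure 2-D rotations (partial Procrustes, no reflection), found
in closed form from the cross-products of each shape with the consensus:
θ* = atan2(Σ x×y, Σ x·y). Iteration stops when the consensus changes by less
than `tol = 1e-8` (Frobenius norm), with a cap of 100 iterations; the summed
squared distance to the consensus is non-increasing across iterations (a
property test asserts this). Degenerate configurations (all landmarks
coincident, centroid size 0) are rejected by name.

**Landmark scheme and trait registry.** The default 14-landmark scheme
(snout, jaw, eye margins, fin origins/ends, caudal peduncle, opercle,
ventral head) and the ten default distance-ratio traits built on it are a
repository convention, not a fact about any particular dataset; both are
configuration-driven (`TraitDefinition(name, numerator_pair,
denominator_pair)`), and users digitizing their own scheme supply their own
registry. Whether "eye–head position" should be pre-eye length over head
length is a judgement call; the default says yes and the registry makes it
overridable.

**Why ratios are computed on raw coordinates.** Ratios of inter-landmark
distances are invariant under translation, rotation and uniform scaling, so
computing them before or after superimposition is equivalent; the
implementation uses raw coordinates and a property test verifies invariance
under random similarity transforms to 1e-10. GPA is still required for the
morphospace, which operates on full shape coordinates.

**Morphospace.** PCA of the flattened aligned coordinates (2k-vectors).
Morphological richness (MRic) is the convex-hull area of a group's scores on
the first two axes (axis count configurable); hulls of groups with fewer
than three or collinear points are recorded as 0 with a warning. Because PCA
is an orthogonal rotation of centered data, scores preserve total variance
and (with all axes) pairwise distances; both are asserted in tests.

## Trait disparity and its null model

The disparity of trait x across N groups is mtD = Σ_{i<j} |x̄_i − x̄_j| /
x̄_all with x̄_all the *unweighted* mean of group means — a group's sample
size affects the precision of its mean but not its weight. The double sum is
read over unordered pairs (i < j); the ordered-pair reading would exactly
double every value and cancel in all downstream correlational analyses, but
the convention is fixed, documented, and tested against both oracles. The
statistic is scale-invariant (numerator and denominator both scale linearly)
and zero iff all group means coincide.

The null model shuffles group labels among members, preserving group sizes
(intraspecific level: individuals among locations; interspecific level:
species among genera), with 999 permutations by default. SES uses the
sample (n−1) standard deviation of the null; p-values use the add-one
estimator p = (1 + #{null ≥ obs})/(1 + n_perm), which guarantees
p ≥ 1/(n_perm+1) and super-uniformity under exchangeability. Members with a
missing trait value are dropped from that trait only. When sd(null) = 0 the
SES is undefined and flagged rather than reported as significant.

**A calibration caveat.** mtD's permutation null is right-skewed (it is a sum
of absolute differences), so the Gaussian-style threshold SES > 1.96 is
mildly anti-conservative: at the default study geometry (4 groups of 20) its
null exceedance is close to 3% rather than the nominal one-sided 2.5%. The
permutation p-value is the exact quantity; the SES flag is kept because it
is the field's convention, and both one- and two-sided flags are reported.

## Hill-number diversity partition

Per locus, with np populations genotyped, n_k genotyped diploids in
population k and ñ their harmonic mean (Nei & Chesser's bias-corrected
estimators, the ones `hierfstat::basic.stats` implements):

    Ho  = mean_k(observed heterozygote fraction)
    Hs~ = mean_k(1 − Σ_a p_{k,a}²)
    Hs  = ñ/(ñ−1) · (Hs~ − Ho/(2ñ))
    Ht~ = 1 − Σ_a p̄_a²,  p̄ the unweighted mean of p_k
    Ht  = Ht~ + Hs/(ñ·np) − Ho/(2·ñ·np)

Populations are weighted equally throughout. Loci genotyped in fewer than
two populations, or with ñ ≤ 1 (correction undefined), are dropped per locus
(not list-wise). On tiny samples the corrected per-locus values can leave
[0, 1]; they are kept raw, and only the multi-locus means — H_S = mean(Hs),
H_T = mean(Ht) — enter the partition, where the domain is checked. The Hill
components J_S = 1/(1−H_S), H_ST = (H_T−H_S)/(1−H_S), J_ST = 1/(1−H_ST),
J_T = 1/(1−H_T) satisfy J_T = J_S·J_ST identically (simple algebra:
1−H_T = (1−H_S)(1−H_ST)); the identity is asserted at 1e-12 on every
computed partition.

**Sample-size standardization.** Each down-sampling replicate draws at most
`max_ind_per_pop = 10` individuals per population and a fixed number of SNPs
(the lowest common count across species, computed from the data rather than
hard-coded) without replacement; 99 replicates by default. Headline values
are the means of the per-replicate J's — the multiplicative identity holds
within each replicate, not for means of ratios, which is why the replicate
table is retained. The mean (not the median) over replicates is reported.

## Comparative statistics

**Co-inertia / RV.** Both tables are column-centered with uniform row
weights; the SVD of XᵀY gives the co-inertia axes, and RV =
tr((XᵀY)(YᵀX)) / √(tr((XᵀX)²)·tr((YᵀY)²)) ∈ [0, 1]. The permutation test
shuffles the rows of one table (99 permutations by default). Because the
interspecific table lives at family level, each species receives its
family's row (replication), aligning the two tables row-by-row. The "pcoa"
mode replaces each table by its principal-coordinate scores from Euclidean
distances (all positive-eigenvalue axes) — an orthogonal change of basis
that leaves RV unchanged, verified numerically; both modes are exposed
because either framing is defensible.

**PGLS.** The Brownian covariance C has C[i,j] = shared root-to-MRCA path
length on the tree pruned to the analysis species, and the GLS fit
(via statsmodels, through a Cholesky square root of C) gives coefficients,
t-tests on n−p df, and R². With identity covariance the fit reduces exactly
to OLS (asserted at 1e-10), and inference is invariant to rescaling C.
`pagel_lambda` shrinks off-diagonal covariance, V(λ) = λC + (1−λ)diag(C),
with `"ml"` profiling the Gaussian likelihood over λ ∈ {0, 0.01, …, 1}.
The pipeline's PGLS fits default to λ-ML rather than strict Brownian motion:
with residuals dominated by within-species sampling noise (no phylogenetic
signal), strict BM is anti-conservative — near-identical sister tips receive
enormous weight after whitening — and the λ-ML fit collapses to OLS-like
inference in exactly that case while remaining BM when the signal is real
(a test verifies λ̂ tracks the residual structure). The low-level
`pgls_fit` default remains strict BM (λ = 1), matching the common usage of
tree-covariance regressions.

**PERMANOVA.** Euclidean distances; the Gower-centered inner-product matrix
G = −½·J·D²·J decomposes total SS = tr(G). Terms enter sequentially
(Type I): SS_j = tr(H_{1..j}G) − tr(H_{1..j−1}G) with H the hat matrix of
the growing design (intercept first; categorical terms dummy-coded; df by
rank increments). Pseudo-F uses the full-model residual mean square;
p-values come from free permutation of response rows (no strata),
999 permutations by default. For univariate responses the pseudo-F equals
the classical one-way ANOVA F exactly (property-tested at 1e-10 against
`scipy.stats.f_oneway`). R² entries sum to one by construction.

**Dispersal axis.** Adult body size (cm) and pelagic larval duration (days)
are z-scored (no log transform by default) and PCA'd; axis-1 scores are
oriented so their correlation with body size is positive, and each trait's
correlation with the axis is reported.

**Path model.** A piecewise SEM: all variables z-scored, each structural
equation fit by OLS, standardized coefficients with df and p per path;
cyclic equation sets are rejected. With one predictor the coefficient equals
the Pearson correlation. The pipeline's default path set is
`j_t ~ dispersal`, `pcoa_intra ~ j_t`, `j_st ~ dispersal`, where
`pcoa_intra` is the first principal-coordinate axis of the species ×
trait intraspecific mtD matrix, sign-oriented to increase with mean
disparity (the axis choice is exposed). No global fit indices or
d-separation tests are computed — the model is a set of standardized
regressions, not a latent-variable SEM.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth; it is not a biological simulation.

* **Phylogeny**: pure-birth (Yule) tree grown to the target tip count, tips
  extended by the Exp(nλ) waiting time to the next unobserved speciation (so
  no terminal branch is zero), rescaled ultrametric to depth 1. Genera and
  families are contiguous blocks of the ladderized tip order, so close
  relatives share taxa.
* **Shapes**: species mean = a hard-coded fish-like 14-landmark template +
  Brownian deviation along the tree (σ_BM = 0.05 per unit depth per
  coordinate). The location effect displaces the fin/peduncle/caudal
  landmarks (indices 4–10) by a fixed per-(species, location) Gaussian draw
  of magnitude δ_s; head landmarks are untouched, so head-based ratios act
  as negative controls, and ground truth records which traits a displacement
  can reach. Individuals add isotropic noise σ = 0.02 and a random
  similarity transform (rotation, scale 0.7–1.4, translation), which is what
  makes the superimposition step non-trivial.
* **Genotypes**: an island model. Ancestral frequencies follow a symmetric
  Beta(a, a) spectrum whose concentration rises with a per-species diversity
  scale (U-shaped spectra → low heterozygosity); population frequencies are
  Beta-distributed around p0 with Var = F·p0(1−p0) for target
  differentiation F (drawn per species from 0.02–0.30); genotypes are
  Binomial(2, p_k). This gives closed-form control of expected
  differentiation and diversity and is fast; no linkage, selection or
  coalescent structure is modelled.
* **Coupling**: with κ > 0, δ_s = δ0·(1 + κ·z(J_s)) clipped at zero, where
  J_s = 1/(1−H_T) computed from the drawn population frequencies at infinite
  sample size — so "diversity drives disparity" is true by construction and
  its strength is known exactly. Dispersal traits are generated from a
  latent axis that rises with z(J_s) (strength 0.7) and falls with z(F_s),
  plus noise, mapped to body size (log-normal around 25 cm) and PLD (around
  32 days).
* **Scale defaults**: 17 species in 10 families (sizes 3,3,2,2,2,1,1,1,1,1),
  4 locations × 20 individuals, 500 loci × 4 populations × 20 genotyped
  individuals per species; the interspecific reference set has 3 genera × 3
  species per family, one individual per species. δ0 = 0.08 and σ = 0.02
  put per-location mean shifts at a few percent of a trait value — large
  enough to be detectable at n = 20 per location but far from saturating.

Every generator is a pure function of (config, seed); the whole-study
generator derives per-stage child seeds from the master seed by hashing
(stage, unit), so per-species outputs do not depend on processing order.

**What passing tests do and do not show.** The generator's traits are
ratio-of-Gaussian-noise quantities with location effects that are exactly
exchangeable under the null — real photographic data add digitization error,
allometry, sex and size structure, and non-exchangeable sampling artifacts
that the null model does not capture. Genotypes are unlinked, neutral and
Hardy–Weinberg within populations; real ddRAD SNPs violate all three to some
degree. Recovery results on synthetic studies therefore validate the
statistical machinery, not the biology of any particular dataset.

## Problem sizes used in validation

The recovery study runs 100 replicate synthetic studies per coupling value
(κ = 0.8 and κ = 0) at the default scale above, with 199 permutations per
species-trait SES and the plain (non-down-sampled) Hill partition per
species inside the loop; null-calibration checks use 500 independent
species-trait tests at 999 permutations, and the permutation-test
calibrations for PERMANOVA and co-inertia use 200 null draws each. These
sizes keep the full validation suite in the low minutes on one CPU while
leaving Monte-Carlo error well below the effect sizes being checked.

## Known limitations

* The SES > 1.96 convention is mildly anti-conservative for a right-skewed
  permutation null (see above); use the permutation p-value when calibration
  matters.
* PERMANOVA uses free permutation; designs needing strata/blocks are out of
  scope.
* The λ grid search profiles a single branch-length parameter; Ornstein–
  Uhlenbeck or rate-shift models are not implemented.
* The TPS reader supports the LM=/IMAGE=/ID=/SCALE= dialect only (curves and
  semilandmarks are not parsed); deformation grids and sliding semilandmarks
  are out of scope.
* `downsample_diversity` reports means of per-replicate Hill numbers; the
  multiplicative identity applies within replicates only.
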