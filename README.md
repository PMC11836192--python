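# reefdisparity

Cross-scale analysis of morphological disparity and genetic diversity in reef
fishes: from landmark photographs of individuals sampled at distant locations,
through a trait-ratio disparity statistic with permutation null models, to
Hill-number partitioning of SNP diversity and the comparative statistics that
link the two.

## Who this is for

Evolutionary ecologists asking whether the morphological variation that
accumulates *within* species — among geographically separated populations —
mirrors the variation seen *between* species at deeper phylogenetic levels
(genera within families), and whether both relate to a species' genetic
diversity and dispersal ability. The package provides the full pipeline as a
library plus a CLI, and a synthetic-study generator with known ground truth so
every stage can be validated without any field data.

## The statistics at its core

**Morphological trait disparity (mtD).** Each individual's body shape is
summarized by ratios of Euclidean distances between anatomical landmarks
(body elongation SL/BD, caudal-peduncle elongation PL/PH, jaw–head length
JL/HL, …). For a trait x with group means x̄₁…x̄_N (groups = sampling
locations within a species, or genera within a family):

    mtD = Σ_{i<j} |x̄_i − x̄_j| / x̄_all ,      x̄_all = (1/N) Σ_i x̄_i

The observed mtD is compared with a null distribution obtained by shuffling
group labels among members (999 permutations), summarized as a standardized
effect size SES = (obs − mean(null)) / sd(null), with |SES| > 1.96 flagging
groups more disparate than expected at random.

**Hill-number diversity partition.** From biallelic SNP genotypes with
population labels, per-locus gene diversities are computed with Nei's
small-sample corrections (the estimators behind `hierfstat::basic.stats`),
averaged over loci into H_S (within-population) and H_T (total), and
converted to effective-number ("Hill") components

    J_S = 1/(1−H_S),   H_ST = (H_T−H_S)/(1−H_S),   J_ST = 1/(1−H_ST),
    J_T = 1/(1−H_T) = J_S × J_ST   (exact identity).

Sample sizes are standardized by capping individuals per population (10) and
down-sampling SNPs to the lowest common count, 99 replicates.

**Cross-scale links.** Co-inertia analysis with the RV coefficient tests the
congruence between the species × trait intraspecific mtD table and the
family-level interspecific mtD table; per-trait regressions (OLS and PGLS
under a Brownian-motion tree covariance, with optional Pagel's-λ ML) relate
the two scales and relate disparity to J_T; a sequential-sums-of-squares
PERMANOVA tests the multivariate mtD matrix against (J_T, J_ST); a PCA of
adult body size and pelagic larval duration ranks species by dispersal
ability; and a piecewise standardized path model ties dispersal → J_T →
disparity together.

## Worked example

```python
import numpy as np
from reefdisparity import GenotypeMatrix, nei_locus_stats, hill_partition

# one SNP: pop1 = {AA, Aa}, pop2 = {aa, aa}, coded as alt-allele counts
geno = GenotypeMatrix(
    genotypes=np.array([[0], [1], [2], [2]], dtype=np.int8),
    populations=np.array(["pop1", "pop1", "pop2", "pop2"], dtype=object),
    samples=["i1", "i2", "i3", "i4"],
    locus_ids=["snp1"],
)
hd = hill_partition(nei_locus_stats(geno))
print(f"H_S = {hd.h_s:.3f}  H_T = {hd.h_t:.3f}  H_ST = {hd.h_st:.3f}")
print(f"J_S = {hd.j_s:.3f}  J_ST = {hd.j_st:.3f}  J_T = {hd.j_t:.3f}")
```

```
H_S = 0.250  H_T = 0.500  H_ST = 0.333
J_S = 1.333  J_ST = 1.500  J_T = 2.000
```

Half of the total diversity sits within populations and half between them:
the data behave like J_T = 2 effectively distinct gene pools, J_ST = 1.5 of
which is attributable to population differentiation.

Running the whole pipeline on a synthetic study (17 species, 10 families,
4 locations × 20 individuals, 500 SNPs per species, diversity→disparity
coupling κ = 0.8):

```python
from reefdisparity import SimulationConfig, simulate_study, AnalysisParams, analyze_study

study = simulate_study(SimulationConfig(master_seed=1, coupling=0.8))
results = analyze_study(study, AnalysisParams(master_seed=1))
print(f"co-inertia RV = {results.coinertia.rv:.2f} (permutation p = {results.coinertia.perm_p:.3g})")
print(results.permanova_table.round(3).to_string())
```

```
co-inertia RV = 0.57 (permutation p = 0.01)
          df       ss     r2  pseudo_f  p_value
term                                           
J_T        1  226.995  0.576    19.445    0.001
J_ST       1    3.591  0.009     0.308    0.787
Residual  14  163.435  0.415       NaN      NaN
Total     16  394.022  1.000       NaN      NaN
```

The RV coefficient says the intra- and interspecific disparity tables share
more structure than row-permuted tables do (p = 0.01), and the PERMANOVA
attributes 58% of the variance in the multivariate disparity matrix to total
genetic diversity J_T (entered first), with no additional contribution of
differentiation J_ST — exactly the causal structure the generator injected.

## CLI

```bash
reefdisparity simulate --seed 1 --coupling 0.8 --out study/        # write a bundle
reefdisparity run-all --bundle study/ --seed 1 --out results/      # full analysis
reefdisparity traits --tps study/landmarks.tps --metadata study/metadata.csv --out traits.csv
reefdisparity hill --vcf study/genotypes/sp01.vcf --popmap popmap.csv --out hill.csv
```

All outputs are tidy CSVs; every run writes a `run_manifest.txt` with the
config hash, seeds and per-stage counts before any result file.

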