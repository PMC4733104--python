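# morphokaryo

Landmark-based geometric morphometrics for comparing chromosomal races of
the Western European house mouse (*Mus musculus domesticus*), built around
the question: do mice fixed for different sets of Robertsonian fusions have
different mandible shapes once size, genetic relatedness and geography are
accounted for — and do the mandible's two developmental modules (the
alveolar region and the ascending ramus) respond differently?

The package implements the full analysis chain as a reusable library plus
numbered driver scripts, and ships a synthetic-data generator that emulates
the study design (84 specimens, 66 vs 18 across two races, six populations
along a geographic cline, 15 two-dimensional landmarks, microsatellite-style
genotypes), so every stage is testable without any data download.

## Methods at its core

- **Generalized Procrustes analysis (GPA).** Configurations are centred,
  scaled to unit centroid size CS = √Σᵢ‖xᵢ − x̄‖², and iteratively rotated
  (proper rotations only) onto the consensus; coordinates are projected
  orthogonally onto the tangent space at the consensus, where ordinary
  multivariate statistics apply.
- **Allometry.** Multivariate regression of shape on CS; the percentage of
  shape variance explained is 100·SS_model/SS_total with a permutation test,
  and the residuals are the allometry-corrected data used downstream.
- **Race/population tests.** Nested MANCOVA (population within race, CS as
  covariate) with Wilks' Λ = det(E)/det(E+H) and Rao's F approximation; a
  permutation test on the tangent Procrustes distance between race mean
  shapes; leave-one-out cross-validated linear discriminant classification;
  between-group PCA on population means.
- **Matrix association.** Individual-level Nei D_A and Cavalli-Sforza &
  Edwards chord distances from diploid genotypes (allele frequencies 0, ½,
  1); a binary karyotypic distance matrix; Mantel and partial Mantel
  permutation tests; principal coordinate analysis; and residual
  randomization (RRPP) comparing shape ~ race + genetic PCo against
  shape ~ genetic PCo.
- **Spatial analysis.** Geographic distance matrices, and bearing analysis:
  Mantel correlations against geographic distances weighted by
  cos²(α_ij − θ) over a 36-direction grid, locating clines in shape.
- **Modularity.** Escoufier's RV = tr(S₁₂S₂₁)/√(tr(S₁₁²)tr(S₂₂²)) between
  landmark blocks; the random-partition test (proportion of same-size
  partitions with RV ≤ observed); RV rarefied to a common sample size; and
  a permutation test for a difference in modularity strength between groups.

## Worked example

Generate a dataset and run the analysis sequence:

```sh
python analysis/01_simulate_dataset.py --seed 0
python analysis/02_superimposition_allometry.py --seed 0
python analysis/04_genetic_karyotype_association.py --seed 0
python analysis/06_modularity.py --seed 0
```

which prints (seed 0):

```
GPA converged in 4 iterations; tangent/full distance correlation 0.999999
allometry: 6.28% of shape variance explained by centroid size (p=0.0002)
Mantel morphometric ~ genetic: r=0.518 p=0.0001
partial Mantel karyotype ~ morphometric | genetic: r=0.434 p=0.0001
PCoA of genetic distances: 19 axes with >= 1% variance
RRPP race beyond genetic structure: F=3.6333 Z=6.062 p=0.0010
partition test (all specimens): RV=0.423 proportion=0.0016
rarefied RV at n=18: ACR=0.446, CD=0.223; difference p=0.023
```

Reading: size explains a small share of shape variance; karyotype remains
associated with shape after controlling for genetic relatedness (both by
partial Mantel and by RRPP model comparison); the alveolar/ramus partition
has a lower RV than almost all random partitions of the same sizes
(supporting modularity). Tables and figures land under `results/`.

The same pipeline runs from one config file:

```sh
morphokaryo simulate --out-dir data/ --seed 3
morphokaryo run --config analysis.yaml
```

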