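# Methods

## Shape model and superimposition

Landmark configurations (k = 15 points in 2-D) are treated under the
standard small-variation Procrustes model: each specimen is a similarity
transform of a mean form plus a small shape deviation. GPA centres each
configuration, scales it to unit centroid size (CS), and rotates it onto the
running consensus with the proper (det = +1) optimal rotation; reflections
are never applied, and a specimen that would fit better reflected raises a
warning, since that usually indicates a digitization side error. The
consensus is re-estimated until its root-mean-square change falls below
`tol = 1e-10` (at most `max_iter = 100` iterations; non-convergence is an
error carrying the last change). The final superimposition is rotated to a
canonical orientation — consensus principal axes on the coordinate axes,
180° ambiguity broken by the sign of the third moment along x — so aligned
output is deterministic and invariant (to ~1e-9) under arbitrary similarity
transforms of the input.

Aligned coordinates are projected orthogonally onto the tangent space at the
consensus before any statistics. The package reports the correlation between
tangent and full Procrustes pairwise distances; at the variance levels of
mandible-like data it exceeds 0.999, which is what licenses the linear
methods downstream. The shape space has dimension at most 2k − 4 = 26; all
determinant-based statistics therefore operate on PCA scores retaining
eigenvalues above 1e-12 of the total.

## Statistical procedures

**Allometry.** Shape is regressed jointly on CS (raw CS by default; log-CS
by flag). Significance is assessed by permuting the size vector against
shape rows (default 10,000 permutations). Residuals from this regression are
the allometry-corrected data used by all later stages. Homogeneity of slopes
is checked by RRPP in two variants: full factorial (cs + factor + cs:factor
vs cs + factor) and a size-only variant (cs + cs:factor vs cs). Both are
reported; note the size-only variant confounds the interaction with the
factor's main effect (its reduced model has no factor term), so it reads as
"any factor signal, level or slope" — the full-factorial variant is the
slope-homogeneity test proper.

**Nested MANCOVA.** Terms enter sequentially (CS, race, population within
race); each term's H matrix is the difference of residual cross-products
between adjacent models, E is the full-model residual cross-product, and
Wilks' Λ = det(E)/det(E+H) is converted to Rao's F. With k = 15 landmarks
and the 6-populations/2-races design the hypothesis df are 26 (race) and
26 × 4 = 104 (population within race).

**Permutation conventions.** All permutation p-values include the observed
statistic in the null set, p = (b + 1)/(m + 1), so p ≥ 1/(m + 1); the
permutation unit is always the whole specimen (simultaneous row/column
shuffling of distance matrices, never independent cells). Whenever the
number of distinct reassignments is at most the requested permutation count
(n! for Mantel at small n, C(n, n₁) for two-group label tests, distinct
same-size partitions for the RV test), the null is enumerated exhaustively
and the p-value is exact.

**Partial Mantel.** The statistic is the first-order partial correlation
r_AB·C from the three pairwise Mantel correlations. The default null model
permutes the matrix of residuals of A on C and correlates it with the
residuals of B on C (residual randomization). The variant that permutes raw
A and re-estimates the partial statistic is available via `scheme="raw"`,
but it is measurably liberal when C is strongly correlated with A — in
calibration runs with correlated genetic and karyotypic matrices it rejected
at ~8% nominal 5% — so the residual scheme is the default.

**RRPP model comparison.** Full and reduced multivariate linear models are
compared by the trace-based F on residual sums of squares; the null
randomizes reduced-model residuals, adds them to reduced-model fitted
values, and refits (default 1,000 permutations). Z is the position of the
observed F in the permuted distribution in SD units. Collinear designs are
rejected naming the aliased columns.

**Genetic distances.** Individual-level allele "frequencies" for a diploid
are 0, ½ or 1 per allele. Nei's D_A between individuals is
1 − (1/L) Σ_l Σ_a √(x_a y_a); the chord distance uses
cos θ_l = Σ_a √(x_a y_a) and d_l = (2/π)√(2(1 − cos θ_l)); both average over
loci typed in both members of a pair. Loci missing in more than half the
individuals can be dropped (`drop_sparse_loci`); a pair sharing no typed
locus is an error.

**Bearing analysis.** Geographic distances are weighted by
w_ij = d_ij · cos²(α_ij − θ), with α_ij the inter-point axis in degrees
clockwise from north reduced modulo 180°; cos² is used because it guarantees
the 180°-periodicity of axes (|cos| is available by flag). The Mantel
correlation of morphometric distances against the weighted matrix is scanned
over a 36-direction grid (10° steps; directions beyond 180° mirror their
twin and are reported for grid fidelity). Raw per-direction p-values are
reported; with 36 correlated tests they are screening values, not
family-wise-corrected ones.

**Modularity.** RV-based analyses use whole-configuration Procrustes
coordinates (no per-block re-superimposition); per-module mean-shape and
Mantel analyses instead re-superimpose each block by its own GPA and remove
allometry against the block's own CS. The partition test reports the
proportion of same-size partitions with RV ≤ the observed RV (small values
support the modular hypothesis); this follows the cited testing logic even
though it can be phrased in the opposite direction. Alternative partitions
are unconstrained by default (an optional landmark contiguity graph
restricts them to spatially connected blocks). Group comparisons rarefy both
groups to the smaller sample size (RV is upward-biased at small n) and
permute group labels, two-sided.

## Synthetic data generator

The generator emulates a two-race contact zone: a fixed 15-landmark
mandible-like template (7 alveolar + 8 ramus points); populations nested in
races and placed along a geographic axis at the cline bearing (100° by
default, i.e. NW–SE), with perpendicular site offsets centred within each
race so the inter-race axis lies exactly along the bearing; shape deviations
in the template's tangent space composed of an allometric term, a race mean
offset, a cline term proportional to position along the bearing, and
block-structured noise; genotypes drawn from race-specific allele
frequencies (Dirichlet perturbation of a shared base, Balding–Nichols
style); and export after random rotation, scaling and translation so GPA is
always exercised.

Key defaults and why:

| parameter | default | meaning |
|---|---|---|
| `n_per_race` | (66, 18) | study sample sizes |
| `k` | 15 | landmarks (template hard-coded; other k fall back to an ellipse) |
| `n_populations` | 6 | sites, nested 4 + 2 in the two races |
| `allometry_fraction` | 0.045 | share of shape variance from size; the allometric coefficient is solved per dataset so the realized fraction matches |
| `race_effect_size` | 0.04 | tangent Procrustes distance between race means, on the scale of reported module-wise race distances |
| `cline_strength` | 0.02 | SD of the cline shape contribution |
| `within_module_corr` / `between_module_corr` | 0.30 / 0.05 | variance shares of the per-module and shared noise factors |
| `noise_sd` | 0.006 | per-coordinate tangent noise SD (≈0.03 RMS specimen deviation) |
| `n_loci`, `n_alleles`, `race_fst_like` | 10, 8, 0.2 | microsatellite-style divergence giving genetic distances that track karyotype |

Two generator details matter and were chosen deliberately. Module noise
factors are random *non-rigid* deformations of each block (orthogonal to the
block's translations and rotation): uniform block loadings would be rigid
block motions, which the superimposition absorbs and redistributes,
destroying the modular covariance the parameter is supposed to create.
And `effect_seed` optionally fixes the design (effect directions and site
layout) across replicates, separating "replicates of one study" from
"replicates of the design-drawing process"; parameter-recovery checks use it
for estimator-consistency assessments.

What the generator does not emulate: anatomically realistic deformations
(noise is Gaussian in tangent space), digitization error structure,
linkage between loci, within-race population substructure beyond the cline,
and missing genotypes. Passing tests therefore demonstrate correctness of
the statistical machinery under the declared model, not robustness to every
property of real mandible data.

## Numerical choices

Distance matrices must be symmetric within 1e-8 and are stored fully with
labels; downstream operations align matrices by label intersection and
refuse fewer than 3 shared labels. Degenerate inputs are refused loudly:
zero CS configurations, zero-variance distance matrices, a constant-pattern
control matrix in partial Mantel, collinear designs. A control matrix equal
to B itself yields partial r = 0 with p = 1 by construction. LOO
discriminant ties (decision score exactly 0) count as misclassifications.
The ANCOVA size test zeroes a term whose sum of squares is below 1e-12 of
the total (exactly collinear covariates). PCoA retains positive-eigenvalue
axes with at least the configured fraction (default 1%) of the summed
positive eigenvalues; negative eigenvalues are reported, never retained.

## Problem sizes in the test suite

Type-I calibration uses 500 null replicates at n = 40 (26/14) with 99
permutations per test (at which p ≤ 0.05 has exactly 5% probability under
exchangeability); parameter recovery uses 100 replicates at the full n = 84
design; modularity power runs use 25 replicates (84 or 60+20 specimens) and
the null-size run 200 replicates. The driver scripts default to 9,999
permutations for Mantel and mean-shape tests and 999 for RRPP and the RV
comparison, mirroring the package defaults at report quality.

## Known limitations

Only 2-D landmarks are supported (3-D input is rejected); no sliding
semilandmarks or bilateral-symmetry decomposition; Mantel-type tests are
used as specified by the workflow even though their power and calibration
on distance data are debated; the estimated allometric direction at n = 84
with ~5% allometric variance carries an irreducible estimation error
(expected vector correlation with truth ≈ 0.90 — the error-to-signal ratio
of the multivariate slope is (1 − f)/(f·n) independent of the noise
structure), which is why direction recovery is assessed as consistency
across replicates rather than per dataset.
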