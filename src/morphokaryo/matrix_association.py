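"""Distance-matrix construction and association tests.

Karyotypic (0/1) and individual-level genetic distance matrices (Nei's D_A
and the Cavalli-Sforza & Edwards chord distance from diploid genotypes),
Mantel and partial Mantel permutation tests, principal coordinate analysis,
and the RRPP comparison of a race + genetic-structure model against a
genetic-structure-only model.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial, pi

import numpy as np

from .datatypes import (
    DistanceMatrix,
    GenotypeTable,
    MantelResult,
    ModelTestResult,
    PCoAResult,
    align_matrices,
)
from .linmodels import (
    DesignMatrix,
    design_continuous,
    design_factor,
    design_intercept,
    rrpp_compare,
)

__all__ = [
    "karyotype_distance_matrix",
    "nei_da_distance",
    "chord_distance",
    "mantel",
    "partial_mantel",
    "pcoa",
    "rrpp_model_compare",
    "race_vs_genetic_rrpp",
]


def karyotype_distance_matrix(labels, ids=None) -> DistanceMatrix:
    """Binary karyotypic distances: 0 for the same karyotype, 1 otherwise."""
    labels = np.asarray(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 individuals")
    if ids is None:
        ids = [f"specimen_{i + 1}" for i in range(len(labels))]
    if len(set(labels.tolist())) < 2:
        import warnings

        warnings.warn(
            "single karyotype class: distance matrix is all zero and "
            "downstream tests on it are degenerate",
            stacklevel=2,
        )
    d = (labels[:, None] != labels[None, :]).astype(float)
    return DistanceMatrix(ids, d)


def _locus_similarities(g: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus genetic similarity sum_a sqrt(x_a * y_a) between individuals.

    Individual-level allele frequencies for a diploid are 0, 0.5 or 1 per
    allele.  Returns (S, typed) with S of shape (L, n, n) and typed the
    (n, L) non-missing mask.
    """
    n, loci = g.n, g.n_loci
    typed = ~g.missing_mask
    max_allele = int(g.alleles.max(initial=1))
    s = np.zeros((loci, n, n))
    for l in range(loci):
        freq = np.zeros((n, max_allele + 1))
        for copy in (0, 1):
            a = g.alleles[:, l, copy]
            ok = a > 0
            freq[np.nonzero(ok)[0], a[ok]] += 0.5
        root = np.sqrt(freq)
        s[l] = root @ root.T
    return s, typed


def _pairwise_from_locus(g: GenotypeTable, per_locus) -> DistanceMatrix:
    s, typed = _locus_similarities(g)
    shared = typed.T[:, :, None] & typed.T[:, None, :]   # (L, n, n)
    d_l = per_locus(np.clip(s, 0.0, 1.0))
    n_shared = shared.sum(axis=0)
    if np.any(n_shared[~np.eye(g.n, dtype=bool)] == 0):
        bad = np.argwhere((n_shared == 0) & ~np.eye(g.n, dtype=bool))
        i, j = bad[0]
        raise ValueError(
            f"individuals {g.ids[i]!r} and {g.ids[j]!r} share no typed locus"
        )
    d = np.where(shared, d_l, 0.0).sum(axis=0) / n_shared
    d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(g.ids, d)


def nei_da_distance(g: GenotypeTable) -> DistanceMatrix:
    """Nei's D_A between individuals: 1 - mean_l sum_a sqrt(x_a * y_a).

    Averaged over the loci typed in both members of each pair.
    """
    return _pairwise_from_locus(g, lambda s: 1.0 - s)


def chord_distance(g: GenotypeTable) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance between individuals.

    Per locus, cos(theta) = sum_a sqrt(x_a * y_a) and the chord is
    (2/pi) * sqrt(2 * (1 - cos theta)); the per-locus chords are averaged
    over loci typed in both individuals.
    """
    return _pairwise_from_locus(g, lambda s: (2.0 / pi) * np.sqrt(2.0 * (1.0 - s)))


# ---------------------------------------------------------------------------
# Mantel machinery


def _standardized_condensed(dm: DistanceMatrix, what: str) -> np.ndarray:
    v = dm.condensed()
    sd = v.std()
    if sd == 0:
        raise ValueError(f"matrix {what} has zero variance in its off-diagonal entries")
    return (v - v.mean()) / sd


def _condensed_r(a_vals: np.ndarray, b_std: np.ndarray, iu) -> float:
    v = a_vals[iu]
    sd = v.std()
    if sd == 0:
        return np.nan
    return float(((v - v.mean()) / sd) @ b_std) / len(v)


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 10000,
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Mantel test of matrix association.

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs; the
    null is built by simultaneous row/column permutation of ``a``.  When n!
    <= ``n_perm`` all permutations are enumerated and the p-value is exact;
    otherwise p = (#{r* as extreme} + 1) / (n_perm + 1).
    """
    a, b = align_matrices(a, b)
    n = a.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 specimens")
    iu = np.triu_indices(n, k=1)
    b_std = _standardized_condensed(b, "B")
    a_std = _standardized_condensed(a, "A")  # raises on zero variance
    r_obs = float(a_std @ b_std) / len(a_std)

    def extreme(r_p: float) -> bool:
        if tail == "greater":
            return r_p >= r_obs - 1e-12
        if tail == "two_sided":
            return abs(r_p) >= abs(r_obs) - 1e-12
        raise ValueError(f"unknown tail {tail!r}")

    if factorial(n) <= n_perm:
        count, total = 0, 0
        for perm in permutations(range(n)):
            idx = np.array(perm)
            r_p = _condensed_r(a.values[np.ix_(idx, idx)], b_std, iu)
            count += extreme(r_p)
            total += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            r_p = _condensed_r(a.values[np.ix_(idx, idx)], b_std, iu)
            count += extreme(r_p)
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(r=r_obs, p=float(p), n_perm=n_used, tail=tail, n=n)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    denom = (1 - r_ac**2) * (1 - r_bc**2)
    if denom <= 1e-12:
        raise ValueError(
            "partial correlation undefined: a controlling correlation is +/-1"
        )
    return (r_ab - r_ac * r_bc) / np.sqrt(denom)


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 10000,
    tail: str = "greater",
    seed: int | None = None,
    controlled_label: str = "C",
    scheme: str = "residual",
) -> MantelResult:
    """Partial Mantel test: association of A and B controlling for C.

    The statistic is the first-order partial correlation computed from the
    three pairwise Mantel correlations.  The default null model permutes
    (rows and columns simultaneously, whole specimens) the matrix of
    residuals of A regressed on C and correlates it with the residuals of B
    on C; this residual randomization holds its nominal size even when the
    control matrix is strongly correlated with A.  ``scheme="raw"``
    permutes A itself and re-estimates the partial statistic per
    permutation (a liberal variant, kept for sensitivity analysis).
    """
    a, b, c = align_matrices(a, b, c)
    n = a.n
    if n < 4:
        raise ValueError("partial Mantel test needs at least 4 specimens")
    if np.array_equal(b.values, c.values):
        # controlling for B itself: the partial correlation is 0 by
        # construction for every permutation of A
        return MantelResult(r=0.0, p=1.0, n_perm=n_perm, tail=tail, n=n,
                            controlled=controlled_label)
    iu = np.triu_indices(n, k=1)
    b_std = _standardized_condensed(b, "B")
    c_std = _standardized_condensed(c, "C")
    a_std = _standardized_condensed(a, "A")
    m = len(a_std)
    r_bc = float(b_std @ c_std) / m
    r_ab = float(a_std @ b_std) / m
    r_ac = float(a_std @ c_std) / m
    r_obs = _partial_r(r_ab, r_ac, r_bc)

    if scheme == "residual":
        res_a = a_std - r_ac * c_std
        res_b = b_std - r_bc * c_std
        res_b = res_b / res_b.std()
        from scipy.spatial.distance import squareform

        res_a_matrix = squareform(res_a)

        def perm_stat(idx: np.ndarray) -> float:
            v = res_a_matrix[np.ix_(idx, idx)][iu]
            sd = v.std()
            return float(((v - v.mean()) / sd) @ res_b) / m
    elif scheme == "raw":
        def perm_stat(idx: np.ndarray) -> float:
            v = a.values[np.ix_(idx, idx)][iu]
            sd = v.std()
            vs = (v - v.mean()) / sd
            return _partial_r(float(vs @ b_std) / m, float(vs @ c_std) / m, r_bc)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    def extreme(r_p: float) -> bool:
        if tail == "greater":
            return r_p >= r_obs - 1e-12
        if tail == "two_sided":
            return abs(r_p) >= abs(r_obs) - 1e-12
        raise ValueError(f"unknown tail {tail!r}")

    if factorial(n) <= n_perm:
        count, total = 0, 0
        for perm in permutations(range(n)):
            count += extreme(perm_stat(np.array(perm)))
            total += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            count += extreme(perm_stat(rng.permutation(n)))
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(
        r=float(r_obs), p=float(p), n_perm=n_used, tail=tail, n=n,
        controlled=controlled_label,
    )


def pcoa(d: DistanceMatrix, min_variance_fraction: float = 0.01) -> PCoAResult:
    """Principal coordinate analysis (classical metric scaling).

    Double-centres -0.5 * D^2, eigen-decomposes it, and retains the axes
    whose (positive) eigenvalue accounts for at least
    ``min_variance_fraction`` of the summed positive eigenvalues.  Negative
    eigenvalues are reported but never retained.
    """
    if d.n < 3:
        raise ValueError("PCoA needs at least 3 specimens")
    vals = d.values
    if np.all(vals == 0):
        raise ValueError("all-zero distance matrix")
    n = d.n
    b = -0.5 * vals**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    b = 0.5 * (b + b.T)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12 * max(evals.max(), 1.0)
    total_pos = evals[pos].sum()
    percent = np.where(pos, 100.0 * evals / total_pos, 0.0)
    retained = int(np.sum(pos & (evals >= min_variance_fraction * total_pos)))
    coords = evecs[:, :retained] * np.sqrt(evals[:retained])
    return PCoAResult(
        coordinates=coords,
        eigenvalues=evals,
        percent_variance=percent,
        retained=retained,
        labels=list(d.labels),
    )


def rrpp_model_compare(
    y: np.ndarray,
    x_full: DesignMatrix,
    x_reduced: DesignMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    term: str = "extra terms",
) -> ModelTestResult:
    """Compare nested multivariate linear models by residual randomization.

    Reports the trace-based F for the terms the full model adds, the effect
    size Z (location of the observed F in the permuted distribution, in SD
    units) and the RRPP p-value.
    """
    f, z, p, df = rrpp_compare(np.asarray(y, float), x_full, x_reduced,
                               n_perm=n_perm, seed=seed)
    return ModelTestResult(
        statistic_name="F", statistic=f, p=p, method="rrpp",
        df=df, n_perm=n_perm, z=z, term=term,
    )


def race_vs_genetic_rrpp(
    residuals: np.ndarray,
    race,
    genetic_scores: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ModelTestResult:
    """Does karyotype race explain shape beyond genetic relatedness?

    Full model: shape ~ race + genetic principal coordinates; reduced:
    shape ~ genetic principal coordinates.
    """
    n = len(np.asarray(race))
    gen = np.asarray(genetic_scores, float)
    x_gen = DesignMatrix(gen, [f"pco{i + 1}" for i in range(gen.shape[1])])
    reduced = design_intercept(n).hstack(x_gen)
    full = reduced.hstack(design_factor(race, "race"))
    return rrpp_model_compare(
        residuals, full, reduced, n_perm=n_perm, seed=seed,
        term="race | genetic structure",
    )
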