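"""Escoufier RV coefficient and modularity tests.

The RV coefficient measures multivariate association between two blocks of
landmarks; a hypothesized modular partition is supported when its RV is low
relative to random partitions of the same block sizes.  Because RV is
upward-biased at small n, group comparisons first rarefy both groups to a
common sample size.

All RV-based analyses use whole-configuration Procrustes coordinates (no
per-block re-superimposition).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from .datatypes import ModuleDefinition, RarefiedRV, RVComparisonResult, ShapeData

__all__ = [
    "rv_coefficient",
    "rv_partition_test",
    "rarefied_rv",
    "rv_group_comparison",
]


def _coords_matrix(data) -> np.ndarray:
    """(n, k, 2) Procrustes coordinates from ShapeData or an array."""
    if isinstance(data, ShapeData):
        return data.aligned
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("expected ShapeData or an (n, k, 2) coordinate array")
    return arr


def _block_columns(block, k: int) -> np.ndarray:
    idx = np.asarray(block, dtype=int)
    return np.concatenate([2 * idx, 2 * idx + 1])


def _rv(y1: np.ndarray, y2: np.ndarray) -> float:
    y1 = y1 - y1.mean(axis=0)
    y2 = y2 - y2.mean(axis=0)
    s11 = y1.T @ y1
    s22 = y2.T @ y2
    s12 = y1.T @ y2
    denom = np.sqrt(np.sum(s11 * s11) * np.sum(s22 * s22))
    if denom == 0:
        raise ValueError("zero within-block variance; RV undefined")
    return float(np.sum(s12 * s12) / denom)


def rv_coefficient(data, partition: ModuleDefinition) -> float:
    """Escoufier's RV between the two landmark blocks of a partition.

    RV = tr(S12 S21) / sqrt(tr(S11^2) tr(S22^2)) on the mean-centred block
    cross-covariance matrices; lies in [0, 1], invariant to separate
    orthogonal rotations and scalings of each block.
    """
    coords = _coords_matrix(data)
    n, k = coords.shape[0], coords.shape[1]
    if n <= 3:
        raise ValueError("RV needs n > 3 specimens")
    partition.validate_against(k)
    flat = coords.reshape(n, -1)
    return _rv(flat[:, _block_columns(partition.block_a, k)],
               flat[:, _block_columns(partition.block_b, k)])


def _is_connected(nodes: set, graph: dict) -> bool:
    nodes = set(nodes)
    stack = [next(iter(nodes))]
    seen = set()
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        stack.extend(graph.get(v, ()) & nodes - seen)
    return seen == nodes


def _normalize_graph(contiguity_graph, k: int) -> dict:
    graph = {i: set() for i in range(k)}
    for a, b in contiguity_graph:
        graph[a].add(b)
        graph[b].add(a)
    return graph


def rv_partition_test(
    data,
    hypothesis: ModuleDefinition,
    n_partitions: int = 10000,
    contiguity_graph=None,
    seed: int | None = None,
) -> dict:
    """Test a modularity hypothesis against random same-size partitions.

    Computes RV for the hypothesized partition and for alternative
    partitions preserving its block sizes, and returns the proportion of
    partitions with RV <= the observed RV (interpreted like a p-value: a
    small proportion supports the hypothesized modules).  When the number
    of distinct partitions is at most ``n_partitions`` they are enumerated
    exhaustively (the hypothesis included); otherwise partitions are
    sampled uniformly with the observed partition counted in the numerator
    and denominator.

    ``contiguity_graph`` (iterable of landmark-index edges) optionally
    restricts alternatives to partitions whose blocks are spatially
    connected.
    """
    coords = _coords_matrix(data)
    n, k = coords.shape[0], coords.shape[1]
    hypothesis.validate_against(k)
    flat = coords.reshape(n, -1)
    size_a = len(hypothesis.block_a)
    graph = _normalize_graph(contiguity_graph, k) if contiguity_graph is not None else None

    def rv_of(block_a: tuple) -> float:
        block_b = tuple(sorted(set(range(k)) - set(block_a)))
        return _rv(flat[:, _block_columns(block_a, k)],
                   flat[:, _block_columns(block_b, k)])

    def admissible(block_a: tuple) -> bool:
        if graph is None:
            return True
        block_b = set(range(k)) - set(block_a)
        return _is_connected(set(block_a), graph) and _is_connected(block_b, graph)

    rv_obs = rv_of(tuple(sorted(hypothesis.block_a)))

    n_distinct = comb(k, size_a)
    if 2 * size_a == k:
        n_distinct //= 2
    if n_distinct <= n_partitions:
        rvs = []
        for block_a in combinations(range(k), size_a):
            if 2 * size_a == k and 0 not in block_a:
                continue  # unordered partition: fix landmark 0 in block a
            if admissible(block_a):
                rvs.append(rv_of(block_a))
        if not rvs:
            raise ValueError("contiguity graph admits no partition of the required sizes")
        rvs = np.asarray(rvs)
        proportion = float(np.mean(rvs <= rv_obs + 1e-12))
        n_eval = len(rvs)
        exact = True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        n_eval = 0
        attempts = 0
        max_attempts = 50 * n_partitions
        while n_eval < n_partitions:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "could not sample enough admissible partitions "
                    "(contiguity graph too restrictive)"
                )
            block_a = tuple(sorted(rng.permutation(k)[:size_a].tolist()))
            if not admissible(block_a):
                continue
            count += rv_of(block_a) <= rv_obs + 1e-12
            n_eval += 1
        proportion = (count + 1) / (n_eval + 1)
        exact = False
    return {
        "rv_observed": rv_obs,
        "proportion": float(proportion),
        "n_partitions": int(n_eval),
        "exact": exact,
    }


def rarefied_rv(
    data,
    partition: ModuleDefinition,
    target_n: int,
    n_iters: int = 1000,
    seed: int | None = None,
) -> RarefiedRV:
    """RV rarefied to ``target_n`` specimens (mean and sd over subsamples).

    RV is upward-biased at small n; rarefaction makes values comparable
    across groups of different size.  At target_n = n every subsample is
    the full dataset and the result equals the plain RV with sd 0.
    """
    coords = _coords_matrix(data)
    n = coords.shape[0]
    if target_n > n:
        raise ValueError(f"target_n={target_n} exceeds sample size {n}")
    if target_n < 4:
        raise ValueError("rarefaction target must be at least 4")
    if target_n == n:
        return RarefiedRV(mean=rv_coefficient(coords, partition), sd=0.0,
                          target_n=target_n, n_iters=n_iters)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_iters)
    for i in range(n_iters):
        idx = rng.permutation(n)[:target_n]
        vals[i] = rv_coefficient(coords[idx], partition)
    return RarefiedRV(mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
                      target_n=target_n, n_iters=n_iters)


def rv_group_comparison(
    data,
    partition: ModuleDefinition,
    groups,
    n_rarefaction_iters: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
) -> RVComparisonResult:
    """Permutation test of equal modularity strength between two groups.

    The observed statistic is the difference of the two groups' RV
    coefficients rarefied to the smaller group's size; the null permutes
    group labels (keeping group sizes) and recomputes the rarefied
    difference.  Two-sided p-value including the observed statistic.
    """
    coords = _coords_matrix(data)
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) != 2:
        raise ValueError("exactly 2 groups are required")
    if counts.min() < 5:
        raise ValueError("each group needs at least 5 specimens (RV unstable below)")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    idx1 = np.nonzero(groups == levels[0])[0]
    idx2 = np.nonzero(groups == levels[1])[0]

    def rarefied_diff(i1, i2, r) -> tuple[float, float]:
        rv1 = rarefied_rv(coords[i1], partition, target, n_rarefaction_iters,
                          seed=int(r.integers(2**31 - 1)))
        rv2 = rarefied_rv(coords[i2], partition, target, n_rarefaction_iters,
                          seed=int(r.integers(2**31 - 1)))
        return rv1.mean, rv2.mean

    rv1_obs, rv2_obs = rarefied_diff(idx1, idx2, rng)
    obs = rv1_obs - rv2_obs
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        p1, p2 = perm[: len(idx1)], perm[len(idx1):]
        r1, r2 = rarefied_diff(p1, p2, rng)
        if abs(r1 - r2) >= abs(obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return RVComparisonResult(
        rv_group1=rv1_obs,
        rv_group2=rv2_obs,
        group_names=(str(levels[0]), str(levels[1])),
        rarefaction_n=target,
        n_rarefaction_iters=n_rarefaction_iters,
        observed_difference=float(obs),
        p=float(p),
        n_perm=n_perm,
        seed=seed if seed is not None else -1,
    )
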