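"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: brute-force
optimization, exhaustive enumeration, and textbook formulas via plain
numpy/scipy.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from scipy.optimize import minimize_scalar


def rotate(coords: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return coords @ np.array([[c, s], [-s, c]])


def full_procrustes_distance_grid(a: np.ndarray, b: np.ndarray,
                                  resolution: float = 1e-4) -> float:
    """Full Procrustes distance by brute-force search over rotation angle.

    Both configurations are centred and scaled to unit centroid size; for
    each angle on a grid of the given resolution (radians) the optimal
    scale is applied analytically and the best distance kept.
    """
    def unit(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)

    a, b = unit(a), unit(b)
    best = np.inf
    for theta in np.arange(0.0, 2 * np.pi, resolution):
        bt = rotate(b, theta)
        s = max(0.0, float(np.sum(a * bt)))
        d = np.linalg.norm(a - s * bt)
        best = min(best, d)
    return best


def gpa_alternating_oracle(coords: np.ndarray, n_restarts: int = 5,
                           n_sweeps: int = 200, seed: int = 0) -> np.ndarray:
    """Consensus by brute-force alternating optimization with restarts.

    Each configuration is centred and unit-scaled; rotations are found by
    1-D numerical minimization of the residual over the rotation angle
    (never the closed form), alternating with consensus re-estimation.
    The restart with the smallest total residual wins.
    """
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    x0 = coords - coords.mean(axis=1, keepdims=True)
    x0 = x0 / np.linalg.norm(x0, axis=(1, 2), keepdims=True)

    best_obj, best_consensus = np.inf, None
    for restart in range(n_restarts):
        x = np.array([rotate(c, rng.uniform(0, 2 * np.pi)) for c in x0])
        ref = x[rng.integers(n)].copy()
        consensus = ref / np.linalg.norm(ref)
        prev_obj = np.inf
        for _ in range(n_sweeps):
            for i in range(n):
                def resid(theta, xi=x[i]):
                    return float(np.sum((rotate(xi, theta) - consensus) ** 2))
                res = min(
                    (minimize_scalar(resid, bracket=(g - 0.5, g + 0.5))
                     for g in np.linspace(0, 2 * np.pi, 8, endpoint=False)),
                    key=lambda r: r.fun,
                )
                x[i] = rotate(x[i], float(res.x))
            consensus = x.mean(axis=0)
            consensus -= consensus.mean(axis=0)
            consensus /= np.linalg.norm(consensus)
            obj = float(np.sum((x - consensus) ** 2))
            if prev_obj - obj < 1e-14:
                break
            prev_obj = obj
        if obj < best_obj:
            best_obj, best_consensus = obj, consensus.copy()
    return best_consensus


def condensed(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_enumeration(a: np.ndarray, b: np.ndarray, tail: str = "greater"):
    """Exact Mantel p by enumerating every simultaneous row/col permutation."""
    n = a.shape[0]
    vb = condensed(b)
    r_obs = np.corrcoef(condensed(a), vb)[0, 1]
    rs = []
    for perm in permutations(range(n)):
        idx = np.array(perm)
        rs.append(np.corrcoef(condensed(a[np.ix_(idx, idx)]), vb)[0, 1])
    rs = np.asarray(rs)
    if tail == "greater":
        p = np.mean(rs >= r_obs - 1e-12)
    else:
        p = np.mean(np.abs(rs) >= abs(r_obs) - 1e-12)
    return float(r_obs), float(p)


def mean_shape_enumeration(y: np.ndarray, labels: np.ndarray):
    """Exact two-group mean-difference permutation p by label enumeration."""
    levels = sorted(set(labels.tolist()))
    n1 = int(np.sum(labels == levels[0]))
    n = len(labels)

    def stat(idx1):
        m1 = y[list(idx1)].mean(axis=0)
        rest = [i for i in range(n) if i not in set(idx1)]
        return float(np.linalg.norm(m1 - y[rest].mean(axis=0)))

    obs = stat(tuple(np.nonzero(labels == levels[0])[0]))
    vals = [stat(c) for c in combinations(range(n), n1)]
    p = float(np.mean(np.asarray(vals) >= obs - 1e-15))
    return obs, p


def rv_oracle(y1: np.ndarray, y2: np.ndarray) -> float:
    """Escoufier RV from the full covariance matrix via np.cov."""
    d1 = y1.shape[1]
    full = np.cov(np.hstack([y1, y2]).T)
    s11, s22 = full[:d1, :d1], full[d1:, d1:]
    s12 = full[:d1, d1:]
    return float(np.trace(s12 @ s12.T)
                 / np.sqrt(np.trace(s11 @ s11) * np.trace(s22 @ s22)))


def wilks_oracle(y: np.ndarray, labels: np.ndarray) -> float:
    """One-way MANOVA Wilks' Lambda from the definitional scatter matrices."""
    grand = y.mean(axis=0)
    e = np.zeros((y.shape[1], y.shape[1]))
    h = np.zeros_like(e)
    for g in sorted(set(labels.tolist())):
        block = y[labels == g]
        mg = block.mean(axis=0)
        dev = block - mg
        e += dev.T @ dev
        dm = (mg - grand)[:, None]
        h += len(block) * (dm @ dm.T)
    return float(np.linalg.det(e) / np.linalg.det(e + h))
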