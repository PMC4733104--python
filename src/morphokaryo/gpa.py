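"""Generalized Procrustes analysis and Procrustes distances.

The geometric core of the pipeline: iterative superimposition removing
translation, scale and rotation (proper rotations only — reflections are
never applied), centroid size, orthogonal tangent-space projection at the
consensus, pairwise shape distances, and landmark subsetting for module-wise
analyses.

Conventions follow the classic formulation: every configuration is scaled
to unit centroid size, and the consensus is re-estimated until its
root-mean-square change falls below ``tol``.  The final superimposition is
rotated to a canonical orientation (consensus principal axes on the
coordinate axes, with a deterministic 180-degree tie-break), so the output
is reproducible and invariant to arbitrary similarity transforms of the
input configurations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import DistanceMatrix, LandmarkDataset, ModuleDefinition, ShapeData

__all__ = [
    "centroid_size",
    "gpa_align",
    "procrustes_distance",
    "pairwise_shape_distances",
    "subset_landmarks",
    "tangent_vs_full_correlation",
]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark-to-centroid distances.

    Invariant to translation and rotation; scales linearly under isotropic
    scaling.  A value of 0 means all landmarks coincide (degenerate).
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 2:
        raise ValueError("a configuration needs at least 2 landmarks")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    centred = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, bool]:
    """Proper 2-D rotation R minimizing ||source @ R - target||_F.

    Returns (R, reflection_preferred): the second element is True when an
    improper (reflected) fit would be strictly better, which for digitized
    landmarks usually indicates a flipped specimen.
    """
    h = source.T @ target
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    r = u @ np.diag([1.0, d]) @ vt
    return r, d < 0


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation putting the consensus principal axes on x/y.

    The 180-degree ambiguity is broken by requiring a nonnegative third
    moment along x (falling back to y when x is symmetric).
    """
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    # major axis last from eigh; order descending and keep det = +1
    v = evecs[:, ::-1].copy()
    if np.linalg.det(v) < 0:
        v[:, 1] = -v[:, 1]
    rot = v  # consensus @ v has major axis along x
    test = consensus @ rot
    m3x = np.sum(test[:, 0] ** 3)
    m3 = m3x if abs(m3x) > 1e-12 else np.sum(test[:, 1] ** 3)
    if m3 < 0:
        rot = rot @ np.array([[-1.0, 0.0], [0.0, -1.0]])  # rotate by 180 deg
    return rot


def gpa_align(
    dataset: LandmarkDataset,
    max_iter: int = 100,
    tol: float = 1e-10,
    project_tangent: bool = True,
    canonical: bool = True,
) -> ShapeData:
    """Generalized Procrustes superimposition of a landmark dataset.

    Each configuration is centred, scaled to unit centroid size, and rotated
    (proper rotation) onto the running consensus; the consensus is then
    re-estimated and the cycle repeats until its RMS change drops below
    ``tol``.  With ``project_tangent`` the aligned coordinates are finally
    projected orthogonally onto the tangent space at the consensus.

    Raises on fewer than 2 configurations, a degenerate (zero centroid size)
    configuration, or non-convergence within ``max_iter`` iterations.
    """
    if len(dataset) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    coords = dataset.coords
    cs = np.array([centroid_size(c) for c in coords])
    if np.any(cs <= 0):
        bad = [dataset.ids[i] for i in np.nonzero(cs <= 0)[0]]
        raise ValueError(f"degenerate (zero centroid size) configurations: {bad}")
    x = coords - coords.mean(axis=1, keepdims=True)
    x = x / cs[:, None, None]

    consensus = x[0].copy()
    consensus /= np.linalg.norm(consensus)
    n_reflected = 0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rotated = np.empty_like(x)
        n_reflected = 0
        for i in range(len(x)):
            r, refl = _optimal_rotation(x[i], consensus)
            rotated[i] = x[i] @ r
            n_reflected += bool(refl)
        new_consensus = rotated.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.linalg.norm(new_consensus)
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        x = rotated
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus RMS change {change:.3e})"
        )
    if n_reflected:
        warnings.warn(
            f"{n_reflected} configuration(s) fit the consensus better reflected; "
            "check for digitization side errors",
            stacklevel=2,
        )
    if canonical:
        rot = _canonical_rotation(consensus)
        consensus = consensus @ rot
        x = x @ rot

    if project_tangent:
        c = consensus.ravel()
        c = c / np.linalg.norm(c)
        flat = x.reshape(len(x), -1)
        flat = flat - np.outer(flat @ c - 1.0, c)  # keep the consensus component at 1
        x = flat.reshape(x.shape)

    return ShapeData(
        ids=list(dataset.ids),
        aligned=x,
        centroid_sizes=cs,
        consensus=consensus,
        tangent_projected=project_tangent,
        iterations=iterations,
    )


def _as_complex(shape: np.ndarray) -> np.ndarray:
    shape = np.asarray(shape, dtype=float)
    z = shape[:, 0] + 1j * shape[:, 1]
    z = z - z.mean()
    norm = np.linalg.norm(z)
    if norm == 0:
        raise ValueError("degenerate configuration (zero centroid size)")
    return z / norm


def procrustes_distance(a: np.ndarray, b: np.ndarray, mode: str = "full") -> float:
    """Distance between two landmark configurations.

    ``full``: full Procrustes distance after optimal translation, scaling
    and proper rotation, d = sqrt(1 - |<a, b>|^2) on the unit pre-shapes
    (complex representation; rotation only, never reflection).

    ``tangent``: plain Euclidean distance between the flattened coordinates;
    the inputs are assumed already superimposed (and tangent-projected).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    if mode == "tangent":
        return float(np.linalg.norm(a - b))
    if mode != "full":
        raise ValueError(f"unknown mode {mode!r}")
    za, zb = _as_complex(a), _as_complex(b)
    h = np.abs(np.vdot(zb, za))
    return float(np.sqrt(max(0.0, 1.0 - min(h, 1.0) ** 2)))


def pairwise_shape_distances(shapes: ShapeData, mode: str = "tangent") -> DistanceMatrix:
    """All pairwise shape distances as a labelled matrix.

    Tangent mode (default) is the Euclidean distance between aligned
    (tangent) coordinates; full mode re-superimposes every pair.
    """
    if shapes.n < 3:
        raise ValueError("need at least 3 specimens for a distance matrix")
    if mode == "tangent":
        d = squareform(pdist(shapes.flat))
    elif mode == "full":
        d = np.zeros((shapes.n, shapes.n))
        for i in range(shapes.n):
            for j in range(i + 1, shapes.n):
                d[i, j] = d[j, i] = procrustes_distance(
                    shapes.aligned[i], shapes.aligned[j], mode="full"
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceMatrix(shapes.ids, d)


def residual_shape_distances(ids, residuals: np.ndarray) -> DistanceMatrix:
    """Euclidean distances between rows of an allometry-corrected shape matrix."""
    return DistanceMatrix(list(ids), squareform(pdist(np.asarray(residuals, float))))


def tangent_vs_full_correlation(shapes: ShapeData) -> float:
    """Correlation between tangent and full Procrustes pairwise distances.

    On low-variance (biological) data this should exceed 0.99, justifying
    the tangent-space linearization used by every downstream analysis.
    """
    dt = pairwise_shape_distances(shapes, mode="tangent").condensed()
    df = pairwise_shape_distances(shapes, mode="full").condensed()
    return float(np.corrcoef(dt, df)[0, 1])


def subset_landmarks(
    data,
    module_def: ModuleDefinition,
    which: str,
    realign: bool = False,
    **gpa_kwargs,
):
    """Extract one module's landmarks from a dataset or aligned shapes.

    With ``realign=True`` the landmark subset is re-superimposed by its own
    GPA (its own centroid sizes), as used for per-module mean shapes and
    Mantel analyses; the block must then hold >= 3 landmarks.  With
    ``realign=False`` the function returns the block's columns of the
    whole-configuration Procrustes coordinates unchanged (an (n, m, 2)
    array), the convention assumed by RV-based modularity tests.
    """
    idx = list(module_def.block(which))
    if isinstance(data, LandmarkDataset):
        module_def.validate_against(data.k)
        sub = LandmarkDataset(data.ids, data.coords[:, idx, :])
        if not realign:
            return sub
        if len(idx) < 3:
            raise ValueError("per-module GPA needs >= 3 landmarks in the block")
        return gpa_align(sub, **gpa_kwargs)
    if isinstance(data, ShapeData):
        module_def.validate_against(data.k)
        block = data.aligned[:, idx, :]
        if not realign:
            return block
        if len(idx) < 3:
            raise ValueError("per-module GPA needs >= 3 landmarks in the block")
        return gpa_align(LandmarkDataset(data.ids, block), **gpa_kwargs)
    raise TypeError("data must be a LandmarkDataset or ShapeData")
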