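"""Spatially explicit association tests.

Geographic distance matrices (planar or great-circle), pairwise inter-point
bearings, direction-weighted distances, and the bearing analysis that scans
Mantel correlations over a grid of directions to detect clines in shape.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import BearingProfile, DistanceMatrix, align_matrices
from .matrix_association import mantel

__all__ = [
    "geographic_distances",
    "pairwise_bearings",
    "bearing_weighted_distances",
    "bearing_analysis",
]

EARTH_RADIUS_KM = 6371.0


def geographic_distances(geo: np.ndarray, ids=None, crs: str = "planar") -> DistanceMatrix:
    """Pairwise geographic distances.

    ``planar``: Euclidean distance on (x, y).  ``lonlat``: great-circle
    (haversine) distance in km on (lon, lat) degrees, sphere radius 6371 km.
    """
    geo = np.asarray(geo, dtype=float)
    if geo.ndim != 2 or geo.shape[1] != 2:
        raise ValueError("geo must be an (n, 2) array")
    if not np.all(np.isfinite(geo)):
        raise ValueError("non-finite coordinates")
    if ids is None:
        ids = [f"specimen_{i + 1}" for i in range(len(geo))]
    if crs == "planar":
        d = squareform(pdist(geo))
    elif crs == "lonlat":
        lon, lat = np.radians(geo[:, 0]), np.radians(geo[:, 1])
        if np.any(np.abs(geo[:, 0]) > 180) or np.any(np.abs(geo[:, 1]) > 90):
            raise ValueError("lon/lat out of range")
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    else:
        raise ValueError(f"unknown crs {crs!r}")
    if np.all(d == 0):
        warnings.warn(
            "all points coincide: geographic distance matrix has zero variance",
            stacklevel=2,
        )
    return DistanceMatrix(ids, d)


def pairwise_bearings(geo: np.ndarray) -> np.ndarray:
    """Axis directions between points, degrees clockwise from north, mod 180.

    With planar (east, north) coordinates the bearing of the segment i->j is
    atan2(dx, dy); axes are undirected so the result is reduced modulo 180
    degrees and the matrix is symmetric.  Coincident pairs get NaN (their
    weight is forced to 0 downstream).
    """
    geo = np.asarray(geo, dtype=float)
    if len(geo) < 3:
        raise ValueError("need at least 3 points")
    dx = geo[None, :, 0] - geo[:, None, 0]
    dy = geo[None, :, 1] - geo[:, None, 1]
    with np.errstate(invalid="ignore"):
        alpha = np.degrees(np.arctan2(dx, dy)) % 180.0
    coincident = (dx == 0) & (dy == 0)
    if np.any(coincident & ~np.eye(len(geo), dtype=bool)):
        warnings.warn("coincident point pairs: bearing undefined, weight set to 0",
                      stacklevel=2)
    alpha[coincident] = np.nan
    # axis of j->i equals axis of i->j; enforce symmetry exactly
    iu = np.triu_indices(len(geo), k=1)
    alpha[(iu[1], iu[0])] = alpha[iu]
    return alpha


def bearing_weighted_distances(
    geo_d: DistanceMatrix, bearings: np.ndarray, theta: float
) -> DistanceMatrix:
    """Geographic distances weighted toward direction theta.

    w_ij = d_ij * cos^2(alpha_ij - theta): pairs aligned with the bearing
    keep their full distance, perpendicular pairs drop to zero, and the
    profile is periodic with period 180 degrees.  Undefined bearings
    (coincident points) get weight 0.
    """
    w = np.cos(np.radians(bearings - theta)) ** 2
    w = np.where(np.isfinite(w), w, 0.0)
    np.fill_diagonal(w, 0.0)
    return DistanceMatrix(geo_d.labels, geo_d.values * w)


DEFAULT_DIRECTIONS = np.arange(0.0, 360.0, 10.0)


def bearing_analysis(
    morph_d: DistanceMatrix,
    geo: np.ndarray,
    ids=None,
    directions=None,
    n_perm: int = 999,
    seed: int | None = None,
    crs: str = "planar",
) -> BearingProfile:
    """Scan Mantel correlations over a grid of geographic directions.

    For each direction theta, the morphometric distances are correlated
    (Mantel, one-tailed) with the geographic distances weighted by
    cos^2(alpha - theta).  A significant correlation at theta indicates a
    cline along that axis.  Directions beyond 180 degrees duplicate their
    modulo-180 twin and are reported for fidelity to a full-circle grid.
    A direction whose weighted matrix is degenerate (zero variance) is
    reported as NaN rather than aborting the scan.
    """
    if directions is None:
        directions = DEFAULT_DIRECTIONS
    directions = np.asarray(directions, dtype=float)
    geo_d = geographic_distances(geo, ids=ids, crs=crs)
    morph_d, geo_d = align_matrices(morph_d, geo_d)
    order = {s: i for i, s in enumerate(ids or geo_d.labels)}
    geo_aligned = np.asarray(geo, float)[[order[s] for s in geo_d.labels]]
    bearings = pairwise_bearings(geo_aligned)

    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(directions))
    r = np.full(len(directions), np.nan)
    p = np.full(len(directions), np.nan)
    cache: dict[float, tuple[float, float]] = {}
    for i, theta in enumerate(directions):
        key = float(theta % 180.0)
        if key in cache:
            r[i], p[i] = cache[key]
            continue
        weighted = bearing_weighted_distances(geo_d, bearings, theta)
        try:
            res = mantel(morph_d, weighted, n_perm=n_perm, tail="greater",
                         seed=int(seeds[i]))
        except ValueError:
            cache[key] = (np.nan, np.nan)
            continue
        cache[key] = (res.r, res.p)
        r[i], p[i] = res.r, res.p
    return BearingProfile(directions=directions, r=r, p=p, n_perm=n_perm)
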