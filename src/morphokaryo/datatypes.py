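"""Core containers shared across the pipeline.

Landmark configurations, Procrustes-aligned shape data, labelled distance
matrices, diploid genotype tables, module partitions and the result records
returned by the statistical routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkDataset",
    "ShapeData",
    "DistanceMatrix",
    "GenotypeTable",
    "ModuleDefinition",
    "AllometryModel",
    "ModelTestResult",
    "MantelResult",
    "PCoAResult",
    "BearingProfile",
    "RarefiedRV",
    "RVComparisonResult",
    "align_matrices",
]

MISSING_ALLELE = -1


class LandmarkDataset:
    """A set of 2-D landmark configurations with one id per specimen.

    Parameters
    ----------
    ids : sequence of str
        Unique specimen identifiers.
    coords : array, shape (n, k, 2)
        Raw landmark coordinates; ``k`` must be constant and >= 3.
    """

    def __init__(self, ids: Sequence[str], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        ids = [str(i) for i in ids]
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise ValueError(
                f"coords must have shape (n, k, 2); got {coords.shape} "
                "(3-D landmarks are not supported)"
            )
        if coords.shape[0] != len(ids):
            raise ValueError("number of ids does not match number of configurations")
        if coords.shape[1] < 3:
            raise ValueError("at least 3 landmarks per configuration are required")
        if len(set(ids)) != len(ids):
            raise ValueError("specimen ids must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")
        self.ids = list(ids)
        self.coords = coords

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n

    def subset(self, ids: Sequence[str]) -> "LandmarkDataset":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown specimen ids: {missing}")
        rows = [index[s] for s in ids]
        return LandmarkDataset(list(ids), self.coords[rows])


@dataclass
class ShapeData:
    """Procrustes-aligned coordinates plus centroid sizes and consensus.

    ``aligned`` has shape (n, k, 2) with every configuration centred at the
    origin and (before tangent projection) unit centroid size.  ``flat``
    exposes the same data as an (n, 2k) matrix for multivariate statistics.
    """

    ids: list
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    tangent_projected: bool = False
    iterations: int = 0

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.aligned.reshape(self.n, -1)

    def subset(self, ids: Sequence[str]) -> "ShapeData":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return ShapeData(
            ids=list(ids),
            aligned=self.aligned[rows],
            centroid_sizes=self.centroid_sizes[rows],
            consensus=self.consensus,
            tangent_projected=self.tangent_projected,
            iterations=self.iterations,
        )


class DistanceMatrix:
    """Labelled symmetric distance matrix with a zero diagonal."""

    #: tolerance beyond which asymmetry is rejected
    SYMMETRY_TOL = 1e-8

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix entries must be finite")
        if np.any(values < 0):
            raise ValueError("distance matrix entries must be nonnegative")
        if np.max(np.abs(values - values.T), initial=0.0) > self.SYMMETRY_TOL:
            raise ValueError("distance matrix is not symmetric within 1e-8")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        self.labels = list(labels)
        self.values = values

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Off-diagonal entries as a condensed (upper-triangle) vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.labels)}
        rows = [index[str(s)] for s in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(rows, rows)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def align_matrices(*matrices: DistanceMatrix) -> list[DistanceMatrix]:
    """Restrict matrices to their shared labels, in the first matrix's order.

    Raises if fewer than 3 labels are shared, which would make every
    downstream matrix statistic degenerate.
    """
    shared = set(matrices[0].labels)
    for m in matrices[1:]:
        shared &= set(m.labels)
    order = [s for s in matrices[0].labels if s in shared]
    if len(order) < 3:
        raise ValueError(f"only {len(order)} shared labels between matrices; need >= 3")
    return [m.submatrix(order) for m in matrices]


class GenotypeTable:
    """Diploid multilocus genotypes for a set of individuals.

    ``alleles`` has shape (n, L, 2) with positive integer allele labels and
    :data:`MISSING_ALLELE` marking missing calls (both alleles of a missing
    genotype are marked).
    """

    def __init__(self, ids: Sequence[str], loci: Sequence[str], alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=int)
        ids = [str(i) for i in ids]
        loci = [str(l) for l in loci]
        if alleles.shape != (len(ids), len(loci), 2):
            raise ValueError(
                f"alleles shape {alleles.shape} does not match "
                f"({len(ids)}, {len(loci)}, 2)"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        alleles = np.where(alleles == 0, MISSING_ALLELE, alleles)  # 0 marks missing
        if np.any((alleles <= 0) & (alleles != MISSING_ALLELE)):
            raise ValueError("allele labels must be positive integers (or missing)")
        # a genotype is missing as a whole: normalize half-missing calls
        half = (alleles == MISSING_ALLELE).sum(axis=2) == 1
        if np.any(half):
            alleles = alleles.copy()
            alleles[half] = MISSING_ALLELE
        self.ids = list(ids)
        self.loci = list(loci)
        self.alleles = alleles

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype is missing."""
        return self.alleles[:, :, 0] == MISSING_ALLELE

    def drop_sparse_loci(self, max_missing_fraction: float = 0.5):
        """Return (filtered table, dropped locus names).

        Loci missing in more than ``max_missing_fraction`` of individuals are
        excluded; pairwise distances downstream then use shared typed loci.
        """
        frac = self.missing_mask.mean(axis=0)
        keep = frac <= max_missing_fraction
        dropped = [l for l, k in zip(self.loci, keep) if not k]
        if not dropped:
            return self, []
        table = GenotypeTable(
            self.ids,
            [l for l, k in zip(self.loci, keep) if k],
            self.alleles[:, keep, :],
        )
        return table, dropped


@dataclass(frozen=True)
class ModuleDefinition:
    """Two-way partition of landmark indices (0-based).

    ``block_a`` is conventionally the alveolar (anterior, tooth-bearing)
    region and ``block_b`` the ascending ramus.
    """

    block_a: tuple
    block_b: tuple

    def __post_init__(self):
        a, b = tuple(self.block_a), tuple(self.block_b)
        object.__setattr__(self, "block_a", a)
        object.__setattr__(self, "block_b", b)
        if set(a) & set(b):
            raise ValueError("module blocks must be disjoint")
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("duplicate landmark index within a block")
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each module block needs at least 2 landmarks")

    def validate_against(self, k: int) -> None:
        if set(self.block_a) | set(self.block_b) != set(range(k)):
            raise ValueError(f"blocks must partition landmark indices 0..{k - 1}")

    def block(self, which: str) -> tuple:
        if which in ("a", "alveolar", "anterior"):
            return self.block_a
        if which in ("b", "ramus", "posterior"):
            return self.block_b
        raise ValueError(f"unknown block {which!r}")


# ---------------------------------------------------------------------------
# result records


@dataclass
class AllometryModel:
    coefficients: np.ndarray          # (p, d) rows = predictors incl. intercept
    predictor_name: str
    percent_variance: float           # 100 * SS_size / SS_total
    residuals: np.ndarray             # (n, d) allometry-corrected shape
    fitted: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    @property
    def allometric_vector(self) -> np.ndarray:
        """Direction of shape change per unit size (the size slope row)."""
        return self.coefficients[1]


@dataclass
class ModelTestResult:
    statistic_name: str               # WilksLambda | F | ProcrustesDistance | Z
    statistic: float
    p: float
    method: str                       # parametric | permutation | rrpp
    df: tuple = ()
    n_perm: int = 0
    z: float = float("nan")
    term: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    n: int
    controlled: str | None = None


@dataclass
class PCoAResult:
    coordinates: np.ndarray           # (n, m) scores on retained axes
    eigenvalues: np.ndarray           # all eigenvalues, descending
    percent_variance: np.ndarray      # share of positive-eigenvalue total
    retained: int
    labels: list


@dataclass
class BearingProfile:
    directions: np.ndarray            # degrees
    r: np.ndarray
    p: np.ndarray
    n_perm: int

    @property
    def argmax_direction(self) -> float:
        ok = np.isfinite(self.r)
        return float(self.directions[ok][np.argmax(self.r[ok])])

    @property
    def max_r(self) -> float:
        return float(np.nanmax(self.r))


@dataclass
class RarefiedRV:
    mean: float
    sd: float
    target_n: int
    n_iters: int


@dataclass
class RVComparisonResult:
    rv_group1: float
    rv_group2: float
    group_names: tuple
    rarefaction_n: int
    n_rarefaction_iters: int
    observed_difference: float
    p: float
    n_perm: int
    seed: int
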