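"""Synthetic data with the statistical structure of a two-race contact zone.

Generates landmark configurations, specimen metadata, microsatellite-style
genotypes and planar coordinates for a study design with two chromosomal
races sampled from populations arranged along a geographic axis: a weak
allometric signal, a race-specific mean-shape offset, a shape cline aligned
with the inter-race axis, block-structured (modular) shape noise, and
genotypes drawn from race-specific allele frequencies.  Every generating
quantity is returned in a ground-truth record so parameter recovery can be
tested end to end.

Shape deviations live in the tangent space of a fixed mandible-like
template (the standard small-variation assumption), orthogonal to the
similarity-transform directions, and configurations are exported after
random rotation, translation and scaling so the superimposition step is
always exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable, LandmarkDataset, ModuleDefinition

__all__ = [
    "MANDIBLE_TEMPLATE",
    "DEFAULT_PARTITION",
    "SimulationParams",
    "simulate_dataset",
    "simulate_modular_shapes",
]

# 15-landmark outline of a left mouse mandible in lingual view: landmarks
# 0-6 trace the alveolar (anterior, tooth-bearing) region, 7-14 the
# ascending ramus (coronoid, condylar and angular processes).
MANDIBLE_TEMPLATE = np.array(
    [
        [0.00, 0.45],   # incisor alveolus, dorsal
        [0.35, 0.55],   # diastema
        [0.90, 0.60],   # anterior molar alveolus
        [1.50, 0.62],   # posterior molar alveolus
        [0.20, 0.10],   # anterior ventral border
        [0.70, 0.00],   # mid ventral border
        [1.30, -0.05],  # posterior ventral border of the body
        [2.10, 0.90],   # coronoid process tip
        [2.50, 0.55],   # sigmoid notch
        [2.90, 0.65],   # condylar process, anterior
        [3.00, 0.35],   # condyle, posterior
        [2.80, -0.10],  # angular notch
        [2.95, -0.45],  # angular process
        [2.30, -0.50],  # ventral ascending ramus
        [1.80, -0.25],  # body-ramus junction
    ]
)

DEFAULT_PARTITION = ModuleDefinition(block_a=tuple(range(7)), block_b=tuple(range(7, 15)))


def _unit_template(k: int) -> np.ndarray:
    if k == MANDIBLE_TEMPLATE.shape[0]:
        t = MANDIBLE_TEMPLATE.copy()
    else:
        # fall back to an irregular ellipse for non-default landmark counts
        ang = np.linspace(0, 2 * np.pi, k, endpoint=False)
        t = np.column_stack([np.cos(ang) * 1.4, np.sin(ang) * (0.8 + 0.1 * np.cos(3 * ang))])
    t = t - t.mean(axis=0)
    return t / np.linalg.norm(t)


def _tangent_projector(template: np.ndarray) -> np.ndarray:
    """Projector removing translation, rotation and scaling directions."""
    k = template.shape[0]
    t = template.ravel()
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-template[:, 1], template[:, 0]]).ravel()
    basis = np.column_stack([tx, ty, t, rot])
    q, _ = np.linalg.qr(basis)
    return np.eye(2 * k) - q @ q.T


@dataclass
class SimulationParams:
    """Generating conditions for the synthetic contact-zone dataset."""

    n_per_race: tuple = (66, 18)
    k: int = 15
    n_populations: int = 6
    allometry_fraction: float = 0.045   # share of shape variance from size
    race_effect_size: float = 0.04      # Procrustes distance between race means
    cline_bearing: float = 100.0        # degrees clockwise from north
    cline_strength: float = 0.02        # sd of the cline shape contribution
    module_partition: ModuleDefinition = field(default_factory=lambda: DEFAULT_PARTITION)
    within_module_corr: float = 0.30    # equicorrelation of coords in a block
    between_module_corr: float = 0.05   # equicorrelation across blocks
    noise_sd: float = 0.006             # per-coordinate tangent noise sd
    n_loci: int = 10
    n_alleles: int = 8
    race_fst_like: float = 0.2          # allele-frequency divergence of races
    race_names: tuple = ("ACR", "CD")
    pop_spacing_km: float = 4.0
    seed: int = 0
    effect_seed: int | None = None  # fixes the generating effect directions
    # across replicates (replicate seeds then vary only sampling noise)

    def __post_init__(self):
        if not (0 <= self.allometry_fraction < 1):
            raise ValueError("allometry_fraction must be in [0, 1)")
        if not (0 <= self.between_module_corr <= self.within_module_corr < 1):
            raise ValueError(
                "infeasible covariance: need 0 <= between_module_corr <= "
                "within_module_corr < 1 "
                f"(got between={self.between_module_corr}, within={self.within_module_corr})"
            )
        if min(self.n_per_race) < 1 or self.n_populations < 2:
            raise ValueError("positive sample sizes and >= 2 populations required")
        if not (0 <= self.cline_bearing < 360):
            raise ValueError("cline_bearing must be in [0, 360)")
        if not (0 <= self.race_fst_like < 1):
            raise ValueError("race_fst_like must be in [0, 1)")


def _block_cols(block) -> np.ndarray:
    idx = np.asarray(block, dtype=int)
    return np.sort(np.concatenate([2 * idx, 2 * idx + 1]))


def _nonrigid_block_loading(rng, template: np.ndarray, block) -> np.ndarray:
    """Random unit deformation of one landmark block, orthogonal to its
    rigid motions (block translations and rotation about its centroid).

    A factor must deform the module, not move it rigidly: rigid block
    motions are largely absorbed by the superimposition and would leak
    integration into the other block.
    """
    k = template.shape[0]
    idx = np.asarray(block, dtype=int)
    m = len(idx)
    sub = template[idx] - template[idx].mean(axis=0)
    tx = np.tile([1.0, 0.0], m)
    ty = np.tile([0.0, 1.0], m)
    rot = np.column_stack([-sub[:, 1], sub[:, 0]]).ravel()
    q, _ = np.linalg.qr(np.column_stack([tx, ty, rot]))
    w = rng.standard_normal(2 * m)
    w = w - q @ (q.T @ w)
    w = w / np.linalg.norm(w)
    full = np.zeros(2 * k)
    full[_block_cols(idx)] = w
    return full


def _modular_noise(rng, n: int, k: int, partition: ModuleDefinition,
                   c_within: float, c_between: float, sd: float,
                   template: np.ndarray) -> np.ndarray:
    """Block-structured shape noise in the (n, 2k) coordinate space.

    One non-rigid deformation factor per module carries a fraction
    ``c_within - c_between`` of each block's variance, a shared global
    factor carries ``c_between``, and independent residuals carry the rest;
    per-coordinate variance averages sd^2.
    """
    d = 2 * k
    eps = np.sqrt(1.0 - c_within) * rng.standard_normal((n, d))
    shared_loading = rng.standard_normal(d)
    shared_loading /= np.linalg.norm(shared_loading)
    eps += np.sqrt(c_between * d) * rng.standard_normal((n, 1)) * shared_loading
    for block in (partition.block_a, partition.block_b):
        loading = _nonrigid_block_loading(rng, template, block)
        amp = np.sqrt((c_within - c_between) * 2 * len(block))
        eps += amp * rng.standard_normal((n, 1)) * loading
    return sd * eps


def simulate_dataset(params: SimulationParams | None = None, seed: int | None = None):
    """Generate one synthetic dataset under the study design.

    Returns a dict with ``landmarks`` (:class:`LandmarkDataset`, raw
    coordinates after random similarity transforms), ``metadata``
    (DataFrame), ``genotypes`` (:class:`GenotypeTable`) and ``truth`` (every
    generating vector and per-specimen latent quantity).
    """
    if params is None:
        params = SimulationParams()
    if seed is not None:
        params = SimulationParams(**{**params.__dict__, "seed": seed})
    rng = np.random.default_rng(params.seed)
    n1, n2 = params.n_per_race
    n = n1 + n2
    k = params.k
    template = _unit_template(k)
    proj = _tangent_projector(template)

    # populations nested in races, arranged along the cline axis
    n_pops1 = min(max(1, int(np.floor(params.n_populations * n1 / n))),
                  params.n_populations - 1)
    n_pops2 = params.n_populations - n_pops1
    pop_names = [f"P{i + 1}" for i in range(params.n_populations)]
    pop_race = [params.race_names[0]] * n_pops1 + [params.race_names[1]] * n_pops2

    def _split(total, parts):
        base = total // parts
        sizes = [base + (1 if i < total % parts else 0) for i in range(parts)]
        return sizes

    pop_sizes = _split(n1, n_pops1) + _split(n2, n_pops2)
    population = np.repeat(pop_names, pop_sizes)
    race = np.repeat(pop_race, pop_sizes)

    # geography: population centres spaced along the bearing axis, with
    # perpendicular offsets and individual jitter (planar km, x=east, y=north).
    # Sampling sites are study design: with effect_seed set they are fixed
    # across replicates, like the effect directions.
    rng_eff = (np.random.default_rng(params.effect_seed)
               if params.effect_seed is not None else rng)
    theta = np.radians(params.cline_bearing)
    u = np.array([np.sin(theta), np.cos(theta)])      # along-cline unit vector
    v = np.array([np.cos(theta), -np.sin(theta)])     # perpendicular
    centre_pos = np.linspace(-1.0, 1.0, params.n_populations) * (
        params.pop_spacing_km * (params.n_populations - 1) / 2
    )
    perp = rng_eff.normal(0, 0.2 * params.pop_spacing_km, params.n_populations)
    # centre the perpendicular offsets within each race's sites so the
    # inter-race axis lies exactly along the cline bearing
    perp[:n_pops1] -= perp[:n_pops1].mean()
    perp[n_pops1:] -= perp[n_pops1:].mean()
    centres = centre_pos[:, None] * u + perp[:, None] * v
    pop_index = {name: i for i, name in enumerate(pop_names)}
    geo = np.array([centres[pop_index[p]] for p in population])
    geo = geo + rng.normal(0, 0.35 * params.pop_spacing_km, size=(n, 2))

    # centroid sizes and body weights
    cs = np.exp(rng.normal(np.log(120.0), 0.06, n))
    weight = 18.0 * (cs / cs.mean()) ** 1.5 * np.exp(rng.normal(0, 0.08, n))

    # shape effects (all projected into the tangent space of the template)
    def unit_vec():
        w = proj @ rng_eff.standard_normal(2 * k)
        return w / np.linalg.norm(w)

    beta_dir = unit_vec()
    delta = unit_vec() * params.race_effect_size
    gamma_dir = unit_vec()

    cs_std = (cs - cs.mean()) / cs.std()
    s_along = geo @ u
    s_std = (s_along - s_along.mean()) / s_along.std()
    is_race2 = (race == params.race_names[1]).astype(float)

    noise = _modular_noise(rng, n, k, params.module_partition,
                           params.within_module_corr, params.between_module_corr,
                           params.noise_sd, template) @ proj.T
    dev_rest = (np.outer(is_race2, delta)
                + params.cline_strength * np.outer(s_std, gamma_dir)
                + noise)
    dev_rest -= dev_rest.mean(axis=0)
    ss_rest = float(np.sum(dev_rest**2))
    f = params.allometry_fraction
    if f > 0:
        b = np.sqrt(f / (1 - f) * ss_rest / float(cs_std @ cs_std))
    else:
        b = 0.0
    dev = np.outer(is_race2, delta) + params.cline_strength * np.outer(s_std, gamma_dir) \
        + noise + b * np.outer(cs_std, beta_dir)

    shapes = template[None] + dev.reshape(n, k, 2)

    # export after random similarity transforms
    ang = rng.uniform(0, 2 * np.pi, n)
    coords = np.empty((n, k, 2))
    for i in range(n):
        c, s = np.cos(ang[i]), np.sin(ang[i])
        rot = np.array([[c, -s], [s, c]])
        coords[i] = shapes[i] @ rot.T * cs[i] + rng.uniform(-50, 50, 2)

    ids = [f"M{i + 1:03d}" for i in range(n)]
    landmarks = LandmarkDataset(ids, coords)
    metadata = pd.DataFrame(
        {
            "specimen_id": ids,
            "race": race,
            "population": population,
            "locality": population,
            "weight": weight,
            "geo_x": geo[:, 0],
            "geo_y": geo[:, 1],
            "karyotype": race,
        }
    ).set_index("specimen_id", drop=False)

    genotypes = _simulate_genotypes(rng, ids, race, params)

    truth = {
        "template": template,
        "allometric_direction": beta_dir,
        "allometric_coefficient": b,
        "race_offset": delta,
        "cline_direction": gamma_dir,
        "cline_bearing": params.cline_bearing,
        "cline_scores": s_std,
        "centroid_sizes": cs,
        "params": params,
        "partition": params.module_partition,
    }
    return {
        "landmarks": landmarks,
        "metadata": metadata,
        "genotypes": genotypes,
        "truth": truth,
    }


def _simulate_genotypes(rng, ids, race, params: SimulationParams) -> GenotypeTable:
    """Race-specific allele frequencies via a Dirichlet perturbation.

    Each locus has a base frequency vector; each race draws its own vector
    from Dirichlet(base * (1 - F) / F) so larger ``race_fst_like`` F means
    stronger divergence (F = 0 gives identical frequencies).
    """
    races = sorted(set(race.tolist()))
    n, loci, a = len(ids), params.n_loci, params.n_alleles
    calls = np.empty((n, loci, 2), dtype=int)
    f = params.race_fst_like
    for l in range(loci):
        base = rng.dirichlet(np.ones(a))
        freqs = {}
        for r in races:
            if f > 0:
                conc = np.maximum(base * (1 - f) / f, 1e-3)
                freqs[r] = rng.dirichlet(conc)
            else:
                freqs[r] = base
        for r in races:
            rows = np.nonzero(np.asarray(race) == r)[0]
            draws = rng.choice(a, size=(len(rows), 2), p=freqs[r]) + 1
            calls[rows, l, :] = draws
    return GenotypeTable(ids, [f"L{l + 1}" for l in range(loci)], calls)


def simulate_modular_shapes(
    params: SimulationParams | None = None,
    n: int | None = None,
    shared_loading: float | None = None,
    seed: int | None = None,
):
    """Landmark data from an explicit two-module factor model.

    Shape deviations are one factor per module (within-module integration)
    plus an optional shared factor whose loading controls between-module
    integration: the expected RV between the blocks increases monotonically
    with ``shared_loading`` and approaches 1 when the shared factor
    dominates.  Used for modularity power and type-I studies.
    """
    if params is None:
        params = SimulationParams()
    if seed is None:
        seed = params.seed
    if n is None:
        n = sum(params.n_per_race)
    if shared_loading is None:
        shared_loading = params.between_module_corr
    if not (0 <= shared_loading <= 1):
        raise ValueError("shared_loading must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = params.k
    template = _unit_template(k)
    proj = _tangent_projector(template)
    part = params.module_partition
    part.validate_against(k)
    d = 2 * k
    within = max(params.within_module_corr, 1e-6)
    resid_share = max(1.0 - within - shared_loading**2, 0.0)
    eps = np.sqrt(resid_share) * rng.standard_normal((n, d))
    shared_dir = rng.standard_normal(d)
    shared_dir /= np.linalg.norm(shared_dir)
    eps += shared_loading * np.sqrt(d) * rng.standard_normal((n, 1)) * shared_dir
    for block in (part.block_a, part.block_b):
        loading = _nonrigid_block_loading(rng, template, block)
        eps += np.sqrt(within * 2 * len(block)) * rng.standard_normal((n, 1)) * loading
    dev = (params.noise_sd * eps) @ proj.T
    shapes = template[None] + dev.reshape(n, k, 2)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    truth = {
        "template": template,
        "partition": part,
        "shared_loading": shared_loading,
        "within_loading": within,
    }
    return LandmarkDataset(ids, shapes), truth
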