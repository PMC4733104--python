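"""End-to-end orchestration of the analysis stages.

Runs, in order: GPA, size tests, allometry regression and interaction
checks, race/population shape tests (nested MANCOVA, mean-shape permutation
test, LOO discriminant rate, between-group PCA), the genetic/karyotypic
Mantel suite, PCoA plus the RRPP model comparison, geographic Mantel tests
and the bearing profile, modularity (partition test and rarefied-RV race
comparison), and the per-module re-analysis.  Every statistic is reported
with its seed, permutation count and configuration snapshot; a failing
stage is recorded and later independent stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gpa, io_formats, matrix_association as ma, modularity, shape_models, spatial
from .datatypes import DistanceMatrix, ModuleDefinition

__all__ = ["PipelineConfig", "run_pipeline", "load_inputs", "report_to_markdown"]


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`."""

    tps_path: str | None = None
    metadata_path: str | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "genepop"
    genetic_distance_path: str | None = None

    module_partition: tuple | None = None   # (block_a, block_b), 0-based

    n_perm_mantel: int = 10000
    n_perm_mean_shape: int = 10000
    n_perm_rrpp: int = 1000
    n_perm_rv: int = 1000
    n_rarefaction_iters: int = 100
    n_partitions: int = 10000
    n_perm_bearing: int = 999
    bearing_step: float = 10.0
    min_axis_variance: float = 0.01
    allometry_predictor: str = "cs"
    crs: str = "planar"
    seed: int = 0
    stages: tuple = (
        "gpa", "size", "allometry", "race_shape", "genetic", "rrpp",
        "spatial", "modularity", "per_module",
    )
    out_dir: str | None = None

    def __post_init__(self):
        for name in ("n_perm_mantel", "n_perm_mean_shape", "n_perm_rrpp",
                     "n_perm_rv", "n_perm_bearing"):
            if getattr(self, name) < 99:
                raise ValueError(f"{name} must be at least 99")


def load_inputs(config: PipelineConfig):
    """Load landmark, metadata and genetic inputs named in the config."""
    landmarks = io_formats.read_tps(config.tps_path)
    metadata = io_formats.read_metadata(config.metadata_path)
    metadata = io_formats.join_metadata(landmarks, metadata)
    genotypes = None
    genetic_d = None
    if config.genotypes_path:
        genotypes = io_formats.read_genotypes(config.genotypes_path,
                                              format=config.genotypes_format)
    elif config.genetic_distance_path:
        genetic_d = io_formats.read_distance_matrix(config.genetic_distance_path)
    return landmarks, metadata, genotypes, genetic_d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(
    config: PipelineConfig,
    landmarks=None,
    metadata=None,
    genotypes=None,
    genetic_d: DistanceMatrix | None = None,
) -> dict:
    """Run the configured stages and return a JSON-serializable report.

    Inputs may be passed in memory (as from the synthetic generator) or
    loaded from the paths in the config.  Genetic stages are skipped with an
    explicit notice when neither genotypes nor a genetic distance matrix is
    available.
    """
    if landmarks is None:
        landmarks, metadata, genotypes, genetic_d = load_inputs(config)
    metadata = io_formats.join_metadata(landmarks, metadata)
    rng = np.random.default_rng(config.seed)
    stage_seed = {name: int(s) for name, s in zip(
        config.stages, rng.integers(0, 2**31 - 1, size=len(config.stages))
    )}
    report: dict = {
        "config": _jsonable({k: v for k, v in dataclasses.asdict(config).items()}),
        "n_specimens": len(landmarks),
        "stages": {},
        "failed_stages": [],
        "skipped_stages": [],
    }

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            report["stages"][name] = _jsonable(fn())
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report["failed_stages"].append(name)
            report["stages"][name] = {
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }

    race = metadata["race"].to_numpy()
    population = metadata["population"].to_numpy()
    karyotype = metadata["karyotype"].to_numpy() if "karyotype" in metadata else race
    geo = (metadata[["geo_x", "geo_y"]].to_numpy(float)
           if {"geo_x", "geo_y"} <= set(metadata.columns) else None)
    weight = metadata["weight"].to_numpy(float) if "weight" in metadata else None

    partition = None
    if config.module_partition is not None:
        partition = ModuleDefinition(*config.module_partition)

    state: dict = {}

    def stage_gpa():
        shapes = gpa.gpa_align(landmarks)
        state["shapes"] = shapes
        return {
            "iterations": shapes.iterations,
            "consensus": shapes.consensus,
            "mean_centroid_size": float(shapes.centroid_sizes.mean()),
            "tangent_full_correlation": gpa.tangent_vs_full_correlation(shapes),
        }

    def stage_size():
        shapes = state["shapes"]
        out = {"anova": shape_models.size_comparison(shapes.centroid_sizes, race)}
        if weight is not None and np.isfinite(weight).any():
            out["ancova_with_weight"] = shape_models.size_comparison(
                shapes.centroid_sizes, race, weight=weight
            )
        return out

    def stage_allometry():
        shapes = state["shapes"]
        model = shape_models.regress_shape_on_size(
            shapes, predictor=config.allometry_predictor,
            n_perm=config.n_perm_mean_shape, seed=stage_seed["allometry"],
        )
        state["allometry"] = model
        out = {
            "percent_variance": model.percent_variance,
            "p_value": model.p_value,
            "n_perm": model.n_perm,
            "seed": stage_seed["allometry"],
            "interactions": {},
        }
        for fac_name, fac in (("race", race), ("population", population)):
            for variant in ("full_factorial", "size_only"):
                res = shape_models.homogeneity_of_slopes_test(
                    shapes, shapes.centroid_sizes, fac,
                    n_perm=max(config.n_perm_rrpp, 99),
                    seed=stage_seed["allometry"], variant=variant,
                )
                out["interactions"][f"{fac_name}:{variant}"] = res
        return out

    def stage_race_shape():
        shapes = state["shapes"]
        resid = state["allometry"].residuals
        state["residuals"] = resid
        mancova = shape_models.nested_mancova(
            shapes.flat, race, population, shapes.centroid_sizes
        )
        perm = shape_models.mean_shape_permutation_test(
            resid, race, n_perm=config.n_perm_mean_shape,
            seed=stage_seed["race_shape"],
        )
        loo = shape_models.lda_crossval(resid, race)
        bg = shape_models.bg_pca(resid, population)
        return {
            "nested_mancova": mancova,
            "mean_shape_permutation": perm,
            "loo_classification_rate": loo,
            "bg_pca_percent_variance": bg["percent_total_variance"][:2],
            "seed": stage_seed["race_shape"],
        }

    def stage_genetic():
        if genotypes is None and genetic_d is None:
            report["skipped_stages"].append(
                {"stage": "genetic",
                 "reason": "no genotypes or genetic distance matrix provided"}
            )
            return {"skipped": True}
        resid = state["residuals"]
        morph_d = gpa.residual_shape_distances(landmarks.ids, resid)
        state["morph_d"] = morph_d
        if genetic_d is not None:
            gen_d = genetic_d
        else:
            gen_d = ma.nei_da_distance(genotypes)
        state["genetic_d"] = gen_d
        karyo_d = ma.karyotype_distance_matrix(karyotype, ids=landmarks.ids)
        state["karyo_d"] = karyo_d
        return {
            "mantel_morph_genetic": ma.mantel(
                morph_d, gen_d, n_perm=config.n_perm_mantel,
                seed=stage_seed["genetic"],
            ),
            "partial_mantel_karyo_morph_given_genetic": ma.partial_mantel(
                karyo_d, morph_d, gen_d, n_perm=config.n_perm_mantel,
                seed=stage_seed["genetic"], controlled_label="genetic",
            ),
            "seed": stage_seed["genetic"],
        }

    def stage_rrpp():
        if "genetic_d" not in state:
            report["skipped_stages"].append(
                {"stage": "rrpp", "reason": "genetic distances unavailable"}
            )
            return {"skipped": True}
        pco = ma.pcoa(state["genetic_d"], min_variance_fraction=config.min_axis_variance)
        res = ma.race_vs_genetic_rrpp(
            state["residuals"], race, pco.coordinates,
            n_perm=config.n_perm_rrpp, seed=stage_seed["rrpp"],
        )
        return {
            "pcoa_retained_axes": pco.retained,
            "model_comparison": res,
            "seed": stage_seed["rrpp"],
        }

    def stage_spatial():
        if geo is None:
            report["skipped_stages"].append(
                {"stage": "spatial", "reason": "no geographic coordinates in metadata"}
            )
            return {"skipped": True}
        resid = state["residuals"]
        morph_d = state.get("morph_d") or gpa.residual_shape_distances(landmarks.ids, resid)
        geo_d = spatial.geographic_distances(geo, ids=landmarks.ids, crs=config.crs)
        out = {
            "mantel_morph_geo": ma.mantel(
                morph_d, geo_d, n_perm=config.n_perm_mantel, seed=stage_seed["spatial"]
            ),
            "seed": stage_seed["spatial"],
        }
        if "genetic_d" in state:
            out["partial_mantel_morph_geo_given_genetic"] = ma.partial_mantel(
                morph_d, geo_d, state["genetic_d"], n_perm=config.n_perm_mantel,
                seed=stage_seed["spatial"], controlled_label="genetic",
            )
            out["partial_mantel_morph_geo_given_karyo"] = ma.partial_mantel(
                morph_d, geo_d, state["karyo_d"], n_perm=config.n_perm_mantel,
                seed=stage_seed["spatial"], controlled_label="karyotypic",
            )
            out["partial_mantel_karyo_morph_given_geo"] = ma.partial_mantel(
                state["karyo_d"], morph_d, geo_d, n_perm=config.n_perm_mantel,
                seed=stage_seed["spatial"], controlled_label="geographic",
            )
        directions = np.arange(0.0, 360.0, config.bearing_step)
        profile = spatial.bearing_analysis(
            morph_d, geo, ids=landmarks.ids, directions=directions,
            n_perm=config.n_perm_bearing, seed=stage_seed["spatial"],
            crs=config.crs,
        )
        out["bearing"] = {
            "directions": profile.directions,
            "r": profile.r,
            "p": profile.p,
            "argmax_direction": profile.argmax_direction,
            "max_r": profile.max_r,
        }
        return out

    def stage_modularity():
        if partition is None:
            report["skipped_stages"].append(
                {"stage": "modularity", "reason": "no module partition configured"}
            )
            return {"skipped": True}
        resid = state["residuals"]
        coords = resid.reshape(len(landmarks), landmarks.k, 2) + state["shapes"].consensus
        out = {
            "partition_test_full": modularity.rv_partition_test(
                coords, partition, n_partitions=config.n_partitions,
                seed=stage_seed["modularity"],
            ),
            "seed": stage_seed["modularity"],
        }
        for r in sorted(set(race.tolist())):
            out[f"partition_test_{r}"] = modularity.rv_partition_test(
                coords[race == r], partition, n_partitions=config.n_partitions,
                seed=stage_seed["modularity"],
            )
        out["rv_race_comparison"] = modularity.rv_group_comparison(
            coords, partition, race,
            n_rarefaction_iters=config.n_rarefaction_iters,
            n_perm=config.n_perm_rv, seed=stage_seed["modularity"],
        )
        return out

    def stage_per_module():
        if partition is None:
            report["skipped_stages"].append(
                {"stage": "per_module", "reason": "no module partition configured"}
            )
            return {"skipped": True}
        out = {}
        gen_chord = ma.chord_distance(genotypes) if genotypes is not None else None
        karyo_d = state.get("karyo_d") or ma.karyotype_distance_matrix(
            karyotype, ids=landmarks.ids
        )
        geo_d = (spatial.geographic_distances(geo, ids=landmarks.ids, crs=config.crs)
                 if geo is not None else None)
        for which, label in (("alveolar", "alveolar"), ("ramus", "ramus")):
            sub = gpa.subset_landmarks(landmarks, partition, which, realign=True)
            model = shape_models.regress_shape_on_size(
                sub, predictor=config.allometry_predictor,
                n_perm=config.n_perm_mean_shape, seed=stage_seed["per_module"],
            )
            block_out = {
                "allometry_percent_variance": model.percent_variance,
                "mean_shape_permutation": shape_models.mean_shape_permutation_test(
                    model.residuals, race, n_perm=config.n_perm_mean_shape,
                    seed=stage_seed["per_module"],
                ),
            }
            morph_d = gpa.residual_shape_distances(landmarks.ids, model.residuals)
            if gen_chord is not None:
                block_out["mantel_morph_genetic"] = ma.mantel(
                    morph_d, gen_chord, n_perm=config.n_perm_mantel,
                    seed=stage_seed["per_module"],
                )
                block_out["partial_mantel_karyo_morph_given_genetic"] = ma.partial_mantel(
                    karyo_d, morph_d, gen_chord, n_perm=config.n_perm_mantel,
                    seed=stage_seed["per_module"], controlled_label="genetic (chord)",
                )
            if geo_d is not None:
                block_out["mantel_morph_geo"] = ma.mantel(
                    morph_d, geo_d, n_perm=config.n_perm_mantel,
                    seed=stage_seed["per_module"],
                )
            out[label] = block_out
        out["seed"] = stage_seed["per_module"]
        return out

    run_stage("gpa", stage_gpa)
    if "shapes" in state:
        run_stage("size", stage_size)
        run_stage("allometry", stage_allometry)
        if "allometry" in state:
            run_stage("race_shape", stage_race_shape)
            if "residuals" in state:
                run_stage("genetic", stage_genetic)
                run_stage("rrpp", stage_rrpp)
                run_stage("spatial", stage_spatial)
                run_stage("modularity", stage_modularity)
                run_stage("per_module", stage_per_module)

    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
        )
        (out_dir / "report.md").write_text(report_to_markdown(report), encoding="utf-8")
    return report


STAGE_DESCRIPTIONS = {
    "gpa": "Generalized Procrustes superimposition; tangent-space adequacy",
    "size": "Centroid-size comparison between races (with/without weight covariate)",
    "allometry": "Multivariate regression of shape on size; slope-homogeneity checks",
    "race_shape": "Nested MANCOVA, mean-shape permutation test, LOO discriminant, bgPCA",
    "genetic": "Mantel: morphometric vs genetic; partial Mantel: karyotype | genetic",
    "rrpp": "PCoA of genetic distances; RRPP: race + genetic PCo vs genetic PCo",
    "spatial": "Geographic Mantel suite and directional (bearing) profile",
    "modularity": "RV partition test; rarefied RV comparison between races",
    "per_module": "Per-module GPA, allometry removal, mean-shape and Mantel tests",
}


def _fmt(v, nd=4):
    if isinstance(v, float):
        return f"{v:.{nd}g}"
    return str(v)


def report_to_markdown(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["# morphokaryo pipeline report", ""]
    lines.append(f"Specimens: {report.get('n_specimens')}")
    lines.append(f"Seed: {report['config'].get('seed')}")
    lines.append("")
    lines.append("| stage | analysis | status |")
    lines.append("|---|---|---|")
    for name, desc in STAGE_DESCRIPTIONS.items():
        if name not in report["stages"]:
            status = "not run"
        elif name in report["failed_stages"]:
            status = "FAILED"
        elif report["stages"][name].get("skipped"):
            status = "skipped"
        else:
            status = "ok"
        lines.append(f"| {name} | {desc} | {status} |")
    lines.append("")
    for name, stage in report["stages"].items():
        lines.append(f"## {name}")
        lines.append("```json")
        lines.append(json.dumps(stage, indent=2, sort_keys=True, default=str)[:4000])
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
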