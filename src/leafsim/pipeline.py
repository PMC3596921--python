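"""The batch pipeline: contour -> mesh -> deform -> season.

Each stage's failure is wrapped in :class:`StageError` carrying the stage
name.  A run manifest (all parameters, seed, package version) and a CSV
population history make any run reproducible from its output directory.
"""
from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .contour import fit_closed_bspline, sample_curve
from .deformation import SimConfig, constant_force, simulate
from .errors import LeafSimError, StageError
from .io import read_key_points, read_mask, write_mask, write_mesh
from .meshing import optimize, triangulate
from .seasons import Environment, LeafPopulation, SenescenceSpec, evolve_population
from .synthetic import MaskRecipe, OutlineRecipe, make_default_spec, make_mask, make_outline

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except (LeafSimError, OSError, ValueError, KeyError) as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("contour")
def _contour_stage(config: PipelineConfig) -> np.ndarray:
    if config.outline.file is not None:
        pts = read_key_points(config.outline.file)
    else:
        recipe = dict(config.outline.recipe or {})
        recipe.setdefault("seed", config.seed)
        pts = make_outline(OutlineRecipe(**recipe)).points
    curve = fit_closed_bspline(pts)
    return sample_curve(curve, config.meshing.n_boundary)


@_stage("meshing")
def _meshing_stage(config: PipelineConfig, boundary: np.ndarray):
    mesh = triangulate(boundary)
    return optimize(
        mesh,
        iterations=config.meshing.iterations,
        target_edge=config.meshing.target_edge,
    )


@_stage("mask")
def _mask_stage(config: PipelineConfig, boundary: np.ndarray):
    if config.mask.file is not None:
        return read_mask(config.mask.file)
    return make_mask(MaskRecipe(**(config.mask.recipe or {})), boundary)


@_stage("deformation")
def _deformation_stage(config: PipelineConfig, mesh, mask):
    block = config.deformation
    sim_config = SimConfig(
        dt=block.dt,
        tau_c=block.tau_c,
        stiffness=block.stiffness,
        damping=block.damping,
        external_force=(
            constant_force([0.0, 0.0, -block.gravity]) if block.gravity > 0 else None
        ),
        n_constraint_passes=block.n_constraint_passes,
    )
    return simulate(
        mesh,
        mask,
        sim_config,
        n_steps=block.n_steps,
        snapshot_every=block.snapshot_every,
        petiole=block.petiole,
        anchor_radius=block.anchor_radius,
    )


@_stage("seasons")
def _seasons_stage(config: PipelineConfig) -> LeafPopulation:
    block = config.seasons
    if block.spec_file is not None:
        spec = SenescenceSpec.from_json(str(block.spec_file))
    else:
        spec = make_default_spec(block.n_states, seed=config.seed)
    schedule = [
        (Environment(e.temperature, e.humidness), e.duration)
        for e in block.schedule
    ]
    pop = LeafPopulation.uniform(block.population, rng_seed=config.seed)
    return evolve_population(pop, schedule, spec)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts to the output directory.

    Outputs: mesh.obj, snapshot_%04d.obj, mask.png, population_history.csv,
    and manifest.json.  Identical config and seed produce identical
    manifest and history.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    boundary = _contour_stage(config)
    logger.info("contour: %d boundary samples", len(boundary))
    mesh = _meshing_stage(config, boundary)
    logger.info("meshing: %d vertices, %d triangles",
                len(mesh.vertices), len(mesh.triangles))
    mask = _mask_stage(config, boundary)
    snapshots = _deformation_stage(config, mesh, mask)
    logger.info("deformation: %d snapshots", len(snapshots))
    population = _seasons_stage(config)

    try:
        write_mesh(mesh, out / "mesh.obj")
        write_mask(mask, out / "mask.png")
        for i, snap in enumerate(snapshots):
            write_mesh(snap, out / f"snapshot_{i:04d}.obj")
        with open(out / "population_history.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "state", "count"])
            writer.writerows(population.history_rows())
        manifest = {
            "artifact_version": __version__,
            "seed": config.seed,
            "config": json.loads(config.model_dump_json()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise StageError("output", str(exc)) from exc
    return out
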