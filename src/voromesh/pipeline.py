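"""The umbrella workflow: synth -> mesh -> digitize -> analyze -> simulate.

A run config (YAML mapping, one key per stage) drives the full digitize /
represent / analyze / model chain; every stage is optional and later stages
consume the artifacts of earlier ones (or paths given explicitly).  Each
run writes its outputs plus a machine-readable manifest (package version,
seed, parameters, produced files) into ``out_dir`` so results are
regenerable from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, analyze, digitize, io, mesh as mesh_mod, simulate, synth

__all__ = ["PipelineError", "PipelineResult", "load_run_config", "load_model_config", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    mesh: mesh_mod.PolygonalMesh | None = None
    stats: dict = field(default_factory=dict)


def load_run_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg


def load_model_config(path) -> dict:
    """Model parameters from TOML or YAML (keys alpha, beta, gamma, ...)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        return tomllib.loads(path.read_text())
    return yaml.safe_load(path.read_text())


_DEFAULT_ROLE_MAP = {
    "cytoplasm": simulate.ROLE_CYTOPLASM,
    "shmoo_tip": simulate.ROLE_TIP,
    "cell_membrane": simulate.ROLE_BLOCKED,
    "nuclear_membrane": simulate.ROLE_BLOCKED,
    "nucleus": simulate.ROLE_BLOCKED,
    "outside": simulate.ROLE_OUTSIDE,
}


def run_pipeline(config: dict, out_dir=None) -> PipelineResult:
    """Execute the configured stages; raise :class:`PipelineError` on failure.

    Partial artifacts written before a failure are retained and the failing
    stage is named in the error.
    """
    out_dir = Path(out_dir or config.get("out_dir", "voromesh_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    outputs: list[str] = []
    manifest = {"version": __version__, "seed": seed, "config": config, "outputs": outputs}
    result = PipelineResult(out_dir, manifest)

    scene = None
    masks: dict[str, digitize.BinaryMask] = {}
    signal_image: digitize.IntensityImage | None = None
    the_mesh: mesh_mod.PolygonalMesh | None = None

    def emit(name: str) -> Path:
        outputs.append(name)
        return out_dir / name

    # -- synth ---------------------------------------------------------
    if "synth" in config:
        stage = config["synth"] or {}
        try:
            scene = synth.make_scene(stage.get("preset", "minimal"), stage.get("seed", seed))
            masks = synth.make_masks(scene)
            signal_image = synth.make_signal_image(scene, stage.get("species", "Fus3PP"))
            for name, m in masks.items():
                io.write_mask(m, emit(f"mask_{name}.png"))
            io.write_image(signal_image, emit(f"signal_{signal_image.species}.png"))
            scene_doc = {k: getattr(scene, k) for k in scene.__dataclass_fields__}
            emit("scene.json").write_text(json.dumps(scene_doc, default=list))
            log.info("synth: scene %s, tip pixel %s", stage.get("preset", "minimal"), scene.tip_pixel)
        except Exception as exc:
            raise PipelineError("synth", str(exc)) from exc

    # -- mesh ----------------------------------------------------------
    if "mesh" in config:
        stage = config["mesh"] or {}
        try:
            if "bbox" in stage:
                bbox = tuple(stage["bbox"])
            elif scene is not None:
                h, w = scene.shape
                bbox = (0, 0, w, h)
            else:
                raise ValueError("mesh stage needs 'bbox' or a synth stage")
            spacing = float(stage.get("spacing", 4.0))
            rules = []
            for rule in stage.get("regions", []):
                mname = rule["mask"]
                m = masks.get(mname) or io.read_mask(mname)
                rules.append((m, float(rule["spacing"])))
            if rules:
                seeds = mesh_mod.generate_region_seeds(bbox, spacing, rules)
            else:
                seeds = mesh_mod.generate_hex_seeds(bbox, spacing)
            the_mesh = mesh_mod.compute_adjacency(mesh_mod.build_voronoi_mesh(seeds))
            log.info("mesh: %d seeds -> %d subcompartments, %d contacts",
                     len(seeds), len(the_mesh), len(the_mesh.adjacency))
            io.write_mesh(the_mesh, emit("mesh.json"))
        except Exception as exc:
            raise PipelineError("mesh", str(exc)) from exc

    # -- digitize ------------------------------------------------------
    labels = None
    if "digitize" in config:
        stage = config["digitize"] or {}
        try:
            if the_mesh is None:
                the_mesh = io.read_mesh(stage["mesh"])
            ordered = []
            for item in stage.get("masks", list(masks)):
                if item in masks:
                    ordered.append(masks[item])
                else:
                    path, _, label = str(item).partition(":")
                    if not Path(path).exists():
                        raise FileNotFoundError(f"mask file not found: {path}")
                    ordered.append(io.read_mask(path, label or None))
            labels = digitize.label_grid(the_mesh)
            digitize.assign_types(the_mesh, ordered, stage.get("default", "outside"), labels=labels)
            digitize.apply_point_masks(the_mesh, ordered, labels)
            sig = stage.get("signal")
            if sig is not None or signal_image is not None:
                if signal_image is None or (sig and ":" in str(sig)):
                    path, _, species = str(sig).partition(":")
                    signal_image = io.read_image(path, species or None)
                digitize.acquire_signal(the_mesh, signal_image, labels=labels)
            counts: dict[str, int] = {}
            for s in the_mesh:
                counts[s.type] = counts.get(s.type, 0) + 1
            log.info("digitize: types %s", counts)
            io.write_mesh(the_mesh, emit("mesh_digitized.json"))
        except Exception as exc:
            raise PipelineError("digitize", str(exc)) from exc

    # -- analyze -------------------------------------------------------
    if "analyze" in config:
        stage = config["analyze"] or {}
        try:
            if the_mesh is None:
                the_mesh = io.read_mesh(stage["mesh"])
            species = stage.get("species", "Fus3PP")
            rows = []
            for types in stage.get("means", []):
                value = analyze.compartment_mean(the_mesh, types, species)
                rows.append(("mean", types, species, value))
                result.stats[f"mean:{types}"] = value
            if "ratio" in stage:
                num, den = stage["ratio"]
                value = analyze.compartment_ratio(the_mesh, num, den, species)
                rows.append(("ratio", f"{num}/{den}", species, value))
                result.stats[f"ratio:{num}/{den}"] = value
            if rows:
                io.write_stats_csv(rows, emit("stats.csv"))
            if "profile_x" in stage:
                p = stage["profile_x"]
                points = analyze.profile_along_axis(
                    the_mesh, species, p.get("types"), tuple(p["band"]))
                io.write_profile_csv(points, the_mesh, emit("profile_x.csv"))
            if "profile_angle" in stage:
                p = stage["profile_angle"]
                if p == "auto" and scene is not None:
                    r, c = scene.tip_pixel
                    center = scene.nucleus_center
                    refdir = (c + 0.5 - center[0], r + 0.5 - center[1])
                    ptypes = None
                else:
                    center = tuple(p["center"])
                    refdir = tuple(p["reference"])
                    ptypes = p.get("types")
                points = analyze.profile_around_point(the_mesh, species, ptypes, center, refdir)
                io.write_profile_csv(points, the_mesh, emit("profile_angle.csv"))
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc

    # -- simulate ------------------------------------------------------
    if "simulate" in config:
        stage = config["simulate"] or {}
        try:
            if the_mesh is None:
                the_mesh = io.read_mesh(stage["mesh"])
            if "model" in stage:
                stage = {**load_model_config(stage["model"]), **stage}
            role_map = dict(_DEFAULT_ROLE_MAP)
            role_map.update(stage.get("role_map", {}))
            for t in {s.type for s in the_mesh}:
                role_map.setdefault(t, simulate.ROLE_OUTSIDE)
            model = simulate.KineticModel(
                alpha=float(stage.get("alpha", 0.1)),
                beta=float(stage.get("beta", 0.1)),
                gamma=float(stage.get("gamma", 50.0)),
                role_map=role_map,
                flux_mode=stage.get("flux_mode", "paper_literal"),
            )
            species = stage.get("species", "Fus3PP")
            rhs = simulate.build_rhs(the_mesh, model)
            if stage.get("initial", "zero") == "digitized":
                y0 = np.array([
                    the_mesh[sid].properties.get(species, 0.0) for sid in rhs.ids
                ])
                y0 = np.nan_to_num(y0, nan=0.0)
            else:
                y0 = np.zeros(len(the_mesh))
            if stage.get("steady_state", False):
                state = simulate.steady_state(rhs, y0, tol=float(stage.get("tol", 1e-8)))
                for sid, v in zip(rhs.ids, state):
                    the_mesh[sid].properties[f"{species}_sim"] = float(v)
                io.write_mesh(the_mesh, emit("mesh_simulated.json"))
                has_obs = any(
                    not np.isnan(s.properties.get(species, np.nan)) for s in the_mesh
                )
                if has_obs:
                    emap = simulate.compare_to_image(state, the_mesh, model, species)
                    for s in the_mesh:
                        if s.id in emap.error:
                            s.properties["E"] = emap.error[s.id]
                            s.properties["E_norm"] = emap.normalized[s.id]
                    result.stats["error_summary"] = emap.summary
                    io.write_mesh(the_mesh, emit("error_map.json"))
            else:
                traj = simulate.integrate(
                    rhs, y0, float(stage.get("t_end", 100.0)),
                    output_times=stage.get("output_times"),
                    rtol=float(stage.get("rtol", 1e-8)),
                    atol=float(stage.get("atol", 1e-10)),
                    species=species,
                )
                io.write_trajectory_csv(traj, emit("trajectory.csv"))
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc

    result.mesh = the_mesh
    if result.stats:
        emit("analysis_summary.json").write_text(json.dumps(result.stats, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    outputs.append("manifest.json")
    return result
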