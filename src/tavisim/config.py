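"""Run configuration: one structured file describing a whole case.

A run config has sections ``anatomy``, ``device``, ``materials``,
``protocol``, ``solver`` and ``metrics`` plus ``seed`` and ``output_dir``.
Everything is optional; missing values fall back to the package defaults
(including the default material table).  ``run_case`` executes the full
pipeline — anatomy, device, optional valvuloplasty, crimp, positioning,
deployment, outcome metrics — writes VTK snapshots, a structured result
record and a provenance block, and is bit-reproducible for a fixed config
and seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .anatomy import AnatomyParams, build_anatomy
from .devices import DeviceSpec, build_balloon_expandable, build_self_expandable
from .fileio import write_anatomy, write_stent_vtk, write_vtk_polydata
from .materials import SuperelasticCard, default_materials, load_material_table
from .metrics import ProjectionSpec
from .protocols import Procedure, ProtocolParams
from .solver import SolverSettings

__all__ = ["RunConfig", "ConfigError", "load_config", "run_case"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    anatomy: AnatomyParams
    device: DeviceSpec
    materials: dict
    protocol: ProtocolParams
    solver: SolverSettings
    metrics: dict = field(default_factory=dict)
    output_dir: str = "tavisim_out"
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()


def _build(cls, section: dict, name: str):
    try:
        return cls(**(section or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name} section: {exc}") from exc


def load_config(source) -> RunConfig:
    """Load and validate a run config from a YAML path or a dict."""
    if isinstance(source, dict):
        raw = source
    else:
        try:
            with open(source) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {source}: {exc}") from exc
    anat_sec = dict(raw.get("anatomy") or {})
    if "ostia_heights" in anat_sec:
        anat_sec["ostia_heights"] = tuple(anat_sec["ostia_heights"])
    if "calcium_leaflets" in anat_sec:
        anat_sec["calcium_leaflets"] = tuple(anat_sec["calcium_leaflets"])
    anatomy = _build(AnatomyParams, anat_sec, "anatomy")
    dev_sec = dict(raw.get("device") or {})
    dev_sec.setdefault("family", "self_expandable")
    dev_sec.setdefault("nominal_size", 26.0)
    device = _build(DeviceSpec, dev_sec, "device")
    mat_sec = raw.get("materials")
    if mat_sec is None:
        materials = default_materials()
    elif isinstance(mat_sec, str):
        materials = load_material_table(mat_sec)
    else:
        materials = default_materials()
        materials.update(load_material_table(mat_sec))
    protocol = _build(ProtocolParams, raw.get("protocol") or {}, "protocol")
    solver_sec = dict(raw.get("solver") or {})
    solver_sec.setdefault("mass_scaling_factor", 1.0e6)
    solver_sec.setdefault("damping", 10.0)
    solver = _build(SolverSettings, solver_sec, "solver")

    # cross-reference checks, surfaced before any solver work
    mat_id = device.default_material
    if mat_id not in materials:
        raise ConfigError(f"device material {mat_id!r} not in the material table")
    if device.family == "self_expandable" and not isinstance(
        materials[mat_id], SuperelasticCard
    ):
        raise ConfigError(
            f"self-expandable frame needs a superelastic card, got {mat_id!r}"
        )
    return RunConfig(
        anatomy=anatomy,
        device=device,
        materials=materials,
        protocol=protocol,
        solver=solver,
        metrics=dict(raw.get("metrics") or {}),
        output_dir=str(raw.get("output_dir", "tavisim_out")),
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def _build_device(cfg: RunConfig):
    if cfg.device.family == "balloon_expandable":
        return build_balloon_expandable(cfg.device.nominal_size, spec=cfg.device)
    return build_self_expandable(cfg.device.nominal_size, spec=cfg.device)


def run_case(cfg: RunConfig, write_outputs: bool = True) -> dict:
    """Execute one end-to-end case and return its structured record."""
    from dataclasses import replace

    anat_params = replace(cfg.anatomy, seed=cfg.anatomy.seed or cfg.seed)
    anatomy = build_anatomy(anat_params)
    stent = _build_device(cfg)

    proc = Procedure(
        stent,
        anatomy=anatomy,
        params=cfg.protocol,
        settings=cfg.solver,
        materials=cfg.materials,
        seed=cfg.seed,
    )
    if cfg.protocol.run_bav and proc.with_balloon:
        proc.simulate_bav()
    proc.crimp()
    depth = proc.position_stent()
    if stent.spec.family == "balloon_expandable":
        proc.expand_balloon_stent()
    else:
        proc.release_sheath()
    result = proc.result()

    msec = cfg.metrics
    view = msec.get("view_direction", (1.0, 0.0, 0.0))
    proj = ProjectionSpec(view_direction=tuple(view))
    diameter = result.projected_diameter(proj)
    gm = result.gap_map(
        stations_per_mm=msec.get("stations_per_mm", 2.0),
        bins=msec.get("bins", 72),
        threshold=msec.get("threshold", 0.1),
    )
    from .metrics import detect_pvl

    pvl = detect_pvl(gm, stent.spec.family, anatomy)
    strain = result.strain_report()

    record = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "device": {"family": stent.spec.family, "size_mm": stent.spec.nominal_size},
        "implantation_depth_mm": depth,
        "valid": result.valid,
        "stages": [
            {
                "name": log.name,
                "ke_ie_ratio": log.ke_ie_ratio,
                "passed_gate": log.passed_gate,
                "steps": log.steps,
                "max_penetration_mm": log.max_penetration,
            }
            for log in result.stage_log
        ],
        "projected_diameter_mm": diameter,
        "valve_ring_mean_diameter_mm": result.ring_diameter(),
        "pvl": {
            "present": bool(pvl.present),
            "sinuses": sorted(pvl.sinuses()),
            "rule": pvl.device_rule_applied,
            "n_channels": len(pvl.channels),
        },
        "strain_pct": {
            "average_below_ostia": strain.average_below_ostia,
            "absolute_max": strain.absolute_max,
            "max_ncc_rcc": strain.max_ncc_rcc,
        },
    }

    if write_outputs:
        out = cfg.output_dir
        os.makedirs(out, exist_ok=True)
        with open(os.path.join(out, "record.json"), "w") as fh:
            json.dump(record, fh, indent=2)
        with open(os.path.join(out, "provenance.json"), "w") as fh:
            json.dump(
                {
                    "seed": cfg.seed,
                    "config_hash": cfg.config_hash(),
                    "config": cfg.raw,
                    "package": "tavisim",
                },
                fh,
                indent=2,
                default=str,
            )
        write_anatomy(anatomy, os.path.join(out, "anatomy_reference.vtk"))
        write_vtk_polydata(
            os.path.join(out, "wall_deformed.vtk"),
            result.wall_positions,
            faces=anatomy.wall_faces,
            cell_data={
                "region": anatomy.wall_regions,
                "max_principal_strain_pct": strain.field,
            },
        )
        write_stent_vtk(stent, os.path.join(out, "stent_deployed.vtk"),
                        positions=result.stent_positions)
        with open(os.path.join(out, "energy_log.txt"), "w") as fh:
            fh.write("stage\tsteps\tke_ie_ratio\tpassed_gate\tmax_penetration_mm\n")
            for log in result.stage_log:
                fh.write(
                    f"{log.name}\t{log.steps}\t{log.ke_ie_ratio:.6g}"
                    f"\t{log.passed_gate}\t{log.max_penetration:.4g}\n"
                )
    return record
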