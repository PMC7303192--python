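"""Scripted deployment procedures over the explicit solver.

A :class:`Procedure` assembles one coupled system — synthetic anatomy
(wall + leaflets + calcium), stent frame, and optionally a balloon — and
runs the staged protocol the clinical procedure follows:

* ``crimp``: a rigid coaxial cylinder shrinks radially until the frame is at
  the delivery-catheter diameter; inelastic state (plastic set, martensite)
  is retained for the subsequent stages;
* ``simulate_bav``: balloon aortic valvuloplasty — the balloon membrane is
  inflated inside the native valve to the valvuloplasty pressure (default
  5 atm) and deflated again, leaving the leaflets pushed open;
* ``position_stent``: rigid placement per family rule — the
  balloon-expandable frame sits with one third of its height below the
  annulus plane, the self-expandable frame at a configurable implantation
  depth that must not exceed 6 mm below the annulus;
* ``expand_balloon_stent``: balloon inflation to the deployment pressure
  with frame and tissue in contact, then deflation (plastic set retains the
  expansion, minus elastic recoil);
* ``release_sheath``: the confining cylindrical sheath is pulled back
  axially (default 80 mm) so the superelastic frame expands progressively
  from the released end.

Every stage is ramped smoothly and must end with kinetic/internal energy
below the quasi-static gate, else the result is marked invalid.

The balloon is modelled as a non-compliant membrane whose reference
configuration is the inflated shape; deflation-folding is approximated by a
radial shrink map (tension-field behaviour, no folding mechanics), so the
deflated balloon is slack and unfolds under pressure.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .anatomy import AnatomyModel
from .devices import StentModel
from .materials import MaterialCard, default_materials
from .metrics import (
    GapMap,
    ProjectionSpec,
    PVLReport,
    StrainReport,
    compute_gap_map,
    detect_pvl,
    projected_diameter,
    strain_report,
)
from .solver import (
    AnalyticCylinder,
    BeamGroup,
    ContactPair,
    MembraneGroup,
    SimState,
    SolverSettings,
    StageLog,
    SurfaceTarget,
    System,
    run_stage,
)

__all__ = [
    "ProtocolParams",
    "DeploymentResult",
    "Procedure",
    "crimp",
    "release_sheath",
    "expand_balloon_stent",
    "deploy",
]

_ATM = 0.101325  # MPa per atmosphere


@dataclass
class ProtocolParams:
    """Procedure parameters (defaults follow the clinical protocol)."""

    bav_pressure_atm: float = 5.0
    deploy_pressure_atm: float = 5.0
    sheath_pullback: float = 80.0  # mm
    corevalve_depth: float = 4.0  # mm below annulus, must be <= 6
    sapien_position_rule: float = 1.0 / 3.0  # fraction of frame below annulus
    crimp_diameter: float = 6.0  # mm
    balloon_diameter_ratio: float = 0.88  # inflated-reference dia / device nominal
    balloon_length_ratio: float = 1.6  # balloon body length / frame height
    run_bav: bool = True
    stage_durations: dict = field(default_factory=dict)  # name -> s

    def __post_init__(self) -> None:
        if self.bav_pressure_atm < 0:
            raise ValueError("bav_pressure must be >= 0")
        if self.corevalve_depth > 6.0:
            raise ValueError(
                f"self-expandable implantation depth {self.corevalve_depth} mm "
                "exceeds the 6 mm guideline limit below the annulus"
            )
        if not (0.0 < self.sapien_position_rule < 1.0):
            raise ValueError("sapien_position_rule must lie in (0, 1)")

    def duration(self, stage: str, default: float) -> float:
        return float(self.stage_durations.get(stage, default))


@dataclass
class DeploymentResult:
    """End state of a deployment with everything the metrics need."""

    stent: StentModel
    final_positions: np.ndarray  # all system nodes
    stent_ids: np.ndarray
    stage_log: list
    valid: bool
    anatomy: AnatomyModel | None = None
    wall_ids: np.ndarray | None = None
    leaflet_global: list | None = None  # per leaflet: global ids of its nodes
    provenance: dict = field(default_factory=dict)

    # -- geometry accessors -------------------------------------------------
    @property
    def stent_positions(self) -> np.ndarray:
        return self.final_positions[self.stent_ids]

    @property
    def wall_positions(self) -> np.ndarray:
        if self.wall_ids is None:
            raise ValueError("no anatomy in this deployment")
        return self.final_positions[self.wall_ids]

    def ring_positions(self, ring: int) -> np.ndarray:
        return self.stent_positions[self.stent.rings[ring]]

    def ring_diameter(self, ring: int | None = None) -> float:
        ring = self.stent.valve_ring if ring is None else ring
        pts = self.ring_positions(ring)
        c = pts.mean(axis=0)
        return float(2.0 * np.linalg.norm(pts[:, :2] - c[None, :2], axis=1).mean())

    def frame_samples(self, per_beam: int = 5) -> np.ndarray:
        """Points sampled along every beam of the deployed frame."""
        pos = self.stent_positions
        a = pos[self.stent.beams[:, 0]]
        b = pos[self.stent.beams[:, 1]]
        t = np.linspace(0.0, 1.0, per_beam)
        return (a[:, None, :] * (1 - t)[None, :, None] + b[:, None, :] * t[None, :, None]).reshape(-1, 3)

    def deployed_stent_surface(self, per_beam: int = 5):
        return self.frame_samples(per_beam)

    # -- outcome metrics ----------------------------------------------------
    def projected_diameter(self, proj: ProjectionSpec | None = None) -> float:
        proj = proj or ProjectionSpec()
        return projected_diameter(self.ring_positions(self.stent.valve_ring), proj)

    def tissue_meshes(self):
        if self.anatomy is None:
            raise ValueError("no anatomy in this deployment")
        meshes = [
            trimesh.Trimesh(
                vertices=self.wall_positions, faces=self.anatomy.wall_faces, process=False
            )
        ]
        for k in range(3):
            verts = self.final_positions[self.leaflet_global[k]]
            meshes.append(
                trimesh.Trimesh(
                    vertices=verts, faces=self.anatomy.leaflet_faces[k], process=False
                )
            )
        return meshes

    def gap_map(self, stations_per_mm=2.0, bins=72, threshold=0.1) -> GapMap:
        stent = self.stent
        anatomy = self.anatomy
        pos = self.stent_positions
        z0 = float(pos[:, 2].min())
        if stent.spec.family == "self_expandable":
            z1 = z0 + stent.spec.skirt_length
        else:
            z1 = float(pos[:, 2].max())
        strut_r = 0.5 * stent.spec.strut_thickness
        meshes = self.tissue_meshes()  # [wall, leaflet0..2]
        t_leaf = 0.5
        blockers = [(m, t_leaf / 2.0, t_leaf / 2.0) for m in meshes[1:]]
        for body in anatomy.calcium_bodies:
            verts = self.final_positions[self.leaflet_global[body.leaflet]]
            faces = anatomy.leaflet_faces[body.leaflet][body.element_ids]
            patch = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
            # deposits sit on the aortic (outer) face of the leaflet
            blockers.append((patch, t_leaf / 2.0, body.thickness))
        wall_half = 0.95  # artery half-thickness, mm
        return compute_gap_map(
            self.frame_samples(),
            meshes[0],
            (z0 + 0.3, z1 - 0.3),
            stations_per_mm=stations_per_mm,
            bins=bins,
            threshold=threshold,
            strut_radius=strut_r,
            wall_offset=wall_half,
            blockers=blockers,
        )

    def pvl_report(self, **kw) -> PVLReport:
        return detect_pvl(self.gap_map(**kw), self.stent.spec.family, self.anatomy)

    def strain_report(self) -> StrainReport:
        z_prox = float(self.stent_positions[:, 2].min())
        return strain_report(self.anatomy, self.wall_positions, frame_proximal_z=z_prox)


# ---------------------------------------------------------------------------
# balloon geometry


def _balloon_mesh(radius: float, length: float, shoulder: float = 4.0, cath_r: float = 1.0,
                  n_theta: int = 24, n_axial: int = 16, z_center: float = 0.0):
    """Revolution membrane: cylindrical body with conical shoulders down to
    the catheter radius; end rings ride on the catheter (fully fixed)."""
    total = length + 2.0 * shoulder
    z = np.linspace(-total / 2.0, total / 2.0, n_axial) + z_center
    zl = z - z_center
    r = np.where(
        np.abs(zl) <= length / 2.0,
        radius,
        cath_r + (radius - cath_r) * np.clip((total / 2.0 - np.abs(zl)) / shoulder, 0.0, 1.0),
    )
    th = 2.0 * np.pi * np.arange(n_theta) / n_theta
    Z, T = np.meshgrid(z, th, indexing="ij")
    R = np.repeat(r[:, None], n_theta, axis=1)
    verts = np.column_stack([(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()])
    faces = []
    for j in range(n_axial - 1):
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            a = j * n_theta + i
            b = j * n_theta + i2
            c = (j + 1) * n_theta + i2
            d = (j + 1) * n_theta + i
            faces.append((a, b, c))
            faces.append((a, c, d))
    end_rings = np.concatenate([np.arange(n_theta), np.arange((n_axial - 1) * n_theta, n_axial * n_theta)])
    return verts, np.asarray(faces, dtype=np.int64), end_rings


def _radial_shrink(verts: np.ndarray, target_r: float) -> np.ndarray:
    """Map points radially so the maximum radius becomes ``target_r``
    (deflation-folding approximation)."""
    out = verts.copy()
    r = np.linalg.norm(verts[:, :2], axis=1)
    rmax = r.max()
    if rmax <= target_r:
        return out
    scale = np.minimum(1.0, target_r / np.maximum(r, 1e-9))
    out[:, 0] *= scale
    out[:, 1] *= scale
    return out


# ---------------------------------------------------------------------------
# procedure


class Procedure:
    """One assembled deployment case.

    Build with an anatomy (or ``None`` for free-space bench runs), a stent,
    and optionally a rigid test tube; then call the stage methods in
    protocol order.  The same system and state are carried through all
    stages, so energies and inelastic state are continuous.
    """

    def __init__(
        self,
        stent: StentModel,
        anatomy: AnatomyModel | None = None,
        params: ProtocolParams | None = None,
        settings: SolverSettings | None = None,
        materials: dict | None = None,
        rigid_tube_diameter: float | None = None,
        with_balloon: bool | None = None,
        seed: int = 0,
    ):
        self.stent = stent
        self.anatomy = anatomy
        self.params = params or ProtocolParams()
        self.materials = materials or default_materials()
        self.settings = settings or SolverSettings(
            mass_scaling_factor=1.0e6, damping=60.0
        )
        self.seed = seed
        self.stage_logs: list[StageLog] = []
        self.valid = True
        if with_balloon is None:
            with_balloon = (
                stent.spec.family == "balloon_expandable"
                or (anatomy is not None and self.params.run_bav)
            )
        self.with_balloon = with_balloon
        self.rigid_tube_diameter = rigid_tube_diameter
        self._assemble()

    # -- assembly -----------------------------------------------------------
    def _assemble(self) -> None:
        stent, anatomy = self.stent, self.anatomy
        blocks = [stent.nodes]
        self.stent_ids = np.arange(stent.n_nodes)
        offset = stent.n_nodes

        self.wall_ids = None
        self.leaflet_global = None
        leaf_targets = []
        if anatomy is not None:
            nw = anatomy.wall_vertices.shape[0]
            self.wall_ids = np.arange(offset, offset + nw)
            blocks.append(anatomy.wall_vertices)
            offset += nw
            self.leaflet_global = []
            for k in range(3):
                lv = anatomy.leaflet_vertices[k]
                att = anatomy.leaflet_attachment[k]
                gids = np.empty(lv.shape[0], dtype=np.int64)
                merged = dict(zip(att[:, 0].tolist(), att[:, 1].tolist()))
                new_local = [i for i in range(lv.shape[0]) if i not in merged]
                blocks.append(lv[new_local])
                for pos_idx, i in enumerate(new_local):
                    gids[i] = offset + pos_idx
                for l_id, w_id in merged.items():
                    gids[l_id] = self.wall_ids[w_id]
                offset += len(new_local)
                self.leaflet_global.append(gids)

        self.balloon_ids = None
        if self.with_balloon:
            size = stent.spec.nominal_size
            rb = 0.5 * size * self.params.balloon_diameter_ratio
            if stent.spec.family == "balloon_expandable":
                lb = stent.spec.height * self.params.balloon_length_ratio
            else:
                # balloon used for valvuloplasty only: size it to the root,
                # not to the (much taller) self-expandable frame
                lb = 24.0 if anatomy is None else 1.2 * anatomy.params.sinus_height
            bv, bf, bends = _balloon_mesh(rb, lb, z_center=stent.spec.height / 2.0)
            self.balloon_faces = bf
            self.balloon_end_local = bends
            self.balloon_ids = np.arange(offset, offset + bv.shape[0])
            self._balloon_ref = bv
            blocks.append(_radial_shrink(bv, 1.2))
            offset += bv.shape[0]

        x0 = np.vstack(blocks)
        sysm = System(x0)
        self.x_ref = x0.copy()

        # frame beams
        mat = self.materials[stent.material_id]
        self.beam_group = BeamGroup(
            stent.beams,
            np.vstack([stent.nodes] + [np.zeros((0, 3))]),
            mat,
            stent.spec.strut_width,
            stent.spec.strut_thickness,
            name="frame",
        )
        # reference geometry for beams is the expanded frame
        sysm.add_beams(self.beam_group)

        self._wall_group = None
        self._leaf_group = None
        if anatomy is not None:
            wall_tris_g = self.wall_ids[anatomy.wall_faces]
            self._wall_group = MembraneGroup(
                wall_tris_g, x0, self.materials["artery"], name="wall"
            )
            sysm.add_membrane(self._wall_group)
            leaf_tris_g = np.vstack(
                [self.leaflet_global[k][anatomy.leaflet_faces[k]] for k in range(3)]
            )
            self._leaf_group = MembraneGroup(
                leaf_tris_g, x0, self.materials["leaflet"], name="leaflets"
            )
            sysm.add_membrane(self._leaf_group)
            if anatomy.calcium_bodies:
                calc_tris = np.vstack(
                    [
                        self.leaflet_global[b.leaflet][
                            anatomy.leaflet_faces[b.leaflet][b.element_ids]
                        ]
                        for b in anatomy.calcium_bodies
                    ]
                )
                th = anatomy.calcium_bodies[0].thickness
                sysm.add_membrane(
                    MembraneGroup(
                        calc_tris, x0, self.materials["calcium"],
                        name="calcium", thickness=th,
                    )
                )
            # fix the wall end rims
            nr, nt = anatomy.wall_grid_shape
            rims = np.concatenate([self.wall_ids[:nt], self.wall_ids[-nt:]])
            sysm.fix(rims)

        self._balloon_group = None
        self._balloon_pressure = None
        if self.with_balloon:
            tris_g = self.balloon_ids[self.balloon_faces]
            # reference configuration of the balloon is its inflated shape
            xref = x0.copy()
            xref[self.balloon_ids] = self._balloon_ref
            self._balloon_group = MembraneGroup(
                tris_g, xref, self.materials["pet"], name="balloon"
            )
            self._balloon_group.tension_only = True
            # selective mass scaling: the slender shoulder triangles would
            # otherwise govern the global stable step
            self._balloon_group.mass_boost = 4.0
            sysm.add_membrane(self._balloon_group)
            self._balloon_pressure = sysm.add_pressure(self._balloon_group, 0.0)
            sysm.fix(self.balloon_ids[self.balloon_end_local])

        # ---- contact pairs (activated per stage) ----
        self.pairs: dict[str, ContactPair] = {}
        strut_r = 0.5 * stent.spec.strut_thickness
        if anatomy is not None:
            wall_t = SurfaceTarget(wall_tris_g, side=-1.0)
            off_w = strut_r + 0.5 * self.materials["artery"].thickness
            self.pairs["stent_wall"] = ContactPair(
                self.stent_ids, wall_t, penalty_stiffness=15.0, gap_offset=off_w, name="stent_wall"
            )
            # leaflet faces are generated with normals toward the axis, so
            # followers approaching from the lumen are on the +normal side
            lt = SurfaceTarget(leaf_tris_g, side=1.0)
            off_l = strut_r + 0.5 * self.materials["leaflet"].thickness
            self.pairs["stent_leaf"] = ContactPair(
                self.stent_ids, lt, penalty_stiffness=15.0, gap_offset=off_l,
                capture_band=0.2, name="stent_leaf",
            )
            # leaflets rest on the wall when pressed outward
            leaf_node_ids = np.unique(np.concatenate(self.leaflet_global))
            leaf_node_ids = leaf_node_ids[~np.isin(leaf_node_ids, self.wall_ids)]
            off_lw = 0.5 * (self.materials["leaflet"].thickness
                            + self.materials["artery"].thickness)
            self.pairs["leaf_wall"] = ContactPair(
                leaf_node_ids, SurfaceTarget(wall_tris_g, side=-1.0),
                penalty_stiffness=10.0, gap_offset=off_lw, capture_band=1.0,
                name="leaf_wall",
            )
            if self.with_balloon:
                # tissue nodes follow the balloon surface: the balloon is a
                # closed convex target, so the contact side is unambiguous
                balloon_t = SurfaceTarget(self.balloon_ids[self.balloon_faces], side=1.0)
                leaf_ids = np.unique(np.concatenate(self.leaflet_global))
                self.pairs["leaf_balloon"] = ContactPair(
                    leaf_ids, balloon_t, penalty_stiffness=40.0,
                    gap_offset=0.03 + 0.25, capture_band=4.0, name="leaf_balloon",
                )
                self.pairs["wall_balloon"] = ContactPair(
                    self.wall_ids, balloon_t, penalty_stiffness=40.0,
                    gap_offset=0.03 + 0.95, capture_band=4.0, name="wall_balloon",
                )
        if self.with_balloon:
            self.pairs["stent_balloon"] = ContactPair(
                self.stent_ids,
                SurfaceTarget(self.balloon_ids[self.balloon_faces], side=1.0),
                penalty_stiffness=40.0,
                gap_offset=strut_r + 0.03,
                name="stent_balloon",
            )
        if self.rigid_tube_diameter is not None:
            self.pairs["tube"] = ContactPair(
                self.stent_ids,
                AnalyticCylinder(0.5 * self.rigid_tube_diameter, contain=True),
                penalty_stiffness=25.0,
                gap_offset=strut_r,
                name="tube",
            )

        self.system = sysm
        self.state = SimState.for_nodes(x0)
        self._active: set = set()
        if self.rigid_tube_diameter is not None:
            self._activate("tube")

    def _activate(self, *names):
        self.system.contact_pairs = []
        self._active.update(names)
        for n in self._active:
            self.system.contact_pairs.append(self.pairs[n])
        self.system._mass = None  # contact stiffness may change the stable step

    def _deactivate(self, *names):
        for n in names:
            self._active.discard(n)
        self.system.contact_pairs = [self.pairs[n] for n in self._active]

    def _run(self, name, duration, on_fraction=None, settle_time=None, damping=None):
        settings = self.settings
        if damping is not None:
            settings = SolverSettings(
                time_step_safety=settings.time_step_safety,
                mass_scaling_factor=settings.mass_scaling_factor,
                damping=damping,
                quasi_static_ke_ratio_max=settings.quasi_static_ke_ratio_max,
                max_steps=settings.max_steps,
                contact_search_every=settings.contact_search_every,
            )
        log = run_stage(
            self.system, self.state, name, duration, settings,
            on_fraction=on_fraction, settle_time=settle_time,
        )
        self.stage_logs.append(log)
        if not log.passed_gate:
            self.valid = False
        return log

    # -- stages -------------------------------------------------------------
    def crimp(self, target_diameter: float | None = None, duration: float | None = None) -> StageLog:
        """Radial crimp by a shrinking rigid coaxial cylinder."""
        target = target_diameter or self.params.crimp_diameter
        spec = self.stent.spec
        if target >= spec.nominal_size:
            raise ValueError("crimp target must be below the nominal diameter")
        strut_r = 0.5 * spec.strut_thickness
        pos = self.state.positions[self.stent_ids]
        r0 = np.linalg.norm(pos[:, :2], axis=1).max() + strut_r + 0.5
        crimper = AnalyticCylinder(r0, contain=True)
        self.pairs["crimper"] = ContactPair(
            self.stent_ids, crimper, penalty_stiffness=30.0,
            gap_offset=strut_r, name="crimper",
        )
        self._activate("crimper")
        # hold the inflow ring axially: crimp elongation goes distally and
        # release foreshortening pulls the outflow down, preserving the
        # implantation depth at the inflow (as the operator does)
        inflow = self.stent.rings[0]
        self.system.fix(self.stent_ids[inflow], dofs=[2])
        r1 = 0.5 * target

        def ramp(s):
            crimper.radius = r0 + (r1 + strut_r - r0) * s

        dur = duration or self.params.duration("crimp", 1.0)
        return self._run("crimp", dur, on_fraction=ramp)

    def release_crimper(self, duration: float | None = None) -> StageLog:
        """Expand the crimper cylinder back out (free-recovery bench test)."""
        crimper = self.pairs["crimper"].target
        r1 = crimper.radius
        r2 = 0.6 * self.stent.spec.nominal_size + 2.0

        def ramp(s):
            crimper.radius = r1 + (r2 - r1) * s

        dur = duration or self.params.duration("release_crimper", 1.5)
        return self._run("release_crimper", dur, on_fraction=ramp,
                         settle_time=4.0 * dur, damping=6.0)

    def simulate_bav(self, duration: float | None = None) -> StageLog:
        """Balloon valvuloplasty: inflate to the BAV pressure, deflate."""
        if not self.with_balloon or self.anatomy is None:
            raise ValueError("BAV needs a balloon and an anatomy")
        # balloon straddling the native valve leaflets
        self._position_balloon(z_center=0.45 * self.anatomy.params.sinus_height)
        names = ["wall_balloon", "leaf_balloon", "leaf_wall"]
        self._activate(*names)
        p_max = self.params.bav_pressure_atm * _ATM
        load = self._balloon_pressure

        def inflate(s):
            load.pressure = p_max * s

        dur = duration or self.params.duration("bav_inflate", 0.8)
        log = self._run("bav_inflate", dur, on_fraction=inflate)
        self._deflate_balloon()
        self._deactivate(*names)
        return log

    def _balloon_body_length(self) -> float:
        return self.stent.spec.height * self.params.balloon_length_ratio

    def _position_balloon(self, z_center: float) -> None:
        ids = self.balloon_ids
        cur = self.state.positions[ids]
        shift = z_center - 0.5 * (cur[:, 2].min() + cur[:, 2].max())
        self.state.positions[ids, 2] += shift
        self._balloon_ref[:, 2] += shift
        self.x_ref[ids, 2] += shift
        # rebuild reference metric at the shifted inflated shape
        self._rebuild_balloon_reference()

    def _rebuild_balloon_reference(self) -> None:
        xref = self.x_ref.copy()
        xref[self.balloon_ids] = self._balloon_ref
        grp = self._balloon_group
        new = MembraneGroup(grp.tris, xref, grp.card, name=grp.name)
        new.tension_only = True
        grp.Dm_inv = new.Dm_inv
        grp.A0 = new.A0

    def _deflate_balloon(self, duration: float | None = None) -> StageLog:
        """Pressure off, then prescribe a radial shrink of the balloon."""
        load = self._balloon_pressure
        p0 = load.pressure
        start = self.state.positions[self.balloon_ids].copy()
        target = _radial_shrink(start, 1.2)
        ids = self.balloon_ids
        t0 = [None]

        def ramp(s):
            load.pressure = p0 * max(0.0, 1.0 - 2.0 * s)
            if s > 0.5:
                u = (s - 0.5) * 2.0
                self.state.positions[ids] = start * (1 - u) + target * u
                self.state.velocities[ids] = 0.0

        dur = duration or self.params.duration("deflate", 0.8)
        return self._run("deflate", dur, on_fraction=ramp)

    def position_stent(self) -> float:
        """Rigid axial placement of the crimped frame per family rule.

        Returns the achieved implantation depth (mm below the annulus).
        """
        spec = self.stent.spec
        if spec.family == "balloon_expandable":
            depth = self.params.sapien_position_rule * spec.height
        else:
            depth = self.params.corevalve_depth
            if depth > 6.0:
                raise ValueError("self-expandable depth beyond 6 mm below annulus")
        pos = self.state.positions[self.stent_ids]
        z_prox = pos[:, 2].min()
        shift = -depth - z_prox
        self.state.positions[self.stent_ids, 2] += shift
        self.state.velocities[self.stent_ids] = 0.0
        if self.with_balloon and spec.family == "balloon_expandable":
            self._position_balloon(
                z_center=0.5 * (pos[:, 2].min() + pos[:, 2].max()) + shift
            )
        self.achieved_depth = depth
        return depth

    def expand_balloon_stent(self, duration: float | None = None) -> StageLog:
        """Balloon-expansion deployment (same phases as valvuloplasty)."""
        names = ["stent_balloon"]
        if self.anatomy is not None:
            names += ["stent_wall", "wall_balloon", "leaf_balloon", "stent_leaf", "leaf_wall"]
        if self.rigid_tube_diameter is not None:
            names.append("tube")
        if "crimper" in self.pairs:
            self.pairs["crimper"].target.radius = 1e6  # crimper withdrawn
        self._activate(*names)
        p_max = self.params.deploy_pressure_atm * _ATM
        load = self._balloon_pressure

        def inflate(s):
            load.pressure = p_max * s

        dur = duration or self.params.duration("expand", 1.2)
        log = self._run("expand", dur, on_fraction=inflate)
        self._deflate_balloon()
        return log

    def release_sheath(self, duration: float | None = None) -> StageLog:
        """Pull back the confining sheath; the frame expands from the
        released (inflow) end upward."""
        spec = self.stent.spec
        strut_r = 0.5 * spec.strut_thickness
        pos = self.state.positions[self.stent_ids]
        zb, zt = pos[:, 2].min(), pos[:, 2].max()
        margin = 3.0
        sheath = AnalyticCylinder(
            0.5 * self.params.crimp_diameter + strut_r,
            contain=True,
            z_min=zb - margin,
            z_max=zt + margin,
        )
        self.pairs["sheath"] = ContactPair(
            self.stent_ids, sheath, penalty_stiffness=30.0,
            gap_offset=strut_r, name="sheath",
        )
        names = ["sheath"]
        if self.anatomy is not None:
            names += ["stent_wall", "stent_leaf", "leaf_wall"]
        if self.rigid_tube_diameter is not None:
            names.append("tube")
        if "crimper" in self.pairs:
            self.pairs["crimper"].target.radius = 1e6
        self._activate(*names)
        z0, z1 = sheath.z_min, sheath.z_max
        pull = self.params.sheath_pullback

        def ramp(s):
            sheath.z_min = z0 + pull * s
            sheath.z_max = z1 + pull * s

        dur = duration or self.params.duration("release", 2.0)
        return self._run("release", dur, on_fraction=ramp,
                         settle_time=2.5 * dur, damping=15.0)

    # -- result -------------------------------------------------------------
    def result(self) -> DeploymentResult:
        prov = {
            "seed": self.seed,
            "config_hash": self.config_hash(),
            "stages": [log.name for log in self.stage_logs],
        }
        return DeploymentResult(
            stent=self.stent,
            final_positions=self.state.positions.copy(),
            stent_ids=self.stent_ids,
            stage_log=list(self.stage_logs),
            valid=self.valid,
            anatomy=self.anatomy,
            wall_ids=self.wall_ids,
            leaflet_global=self.leaflet_global,
            provenance=prov,
        )

    def config_hash(self) -> str:
        payload = repr(
            (
                self.stent.spec,
                self.anatomy.params if self.anatomy else None,
                self.params,
                self.settings,
                self.seed,
            )
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# module-level convenience operations (spec surface)


def crimp(stent: StentModel, target_diameter: float, settings=None, **kw) -> Procedure:
    """Crimp a frame in free space; returns the procedure for inspection."""
    proc = Procedure(stent, anatomy=None, settings=settings, with_balloon=False, **kw)
    proc.crimp(target_diameter)
    return proc


def release_sheath(stent: StentModel, anatomy=None, params=None, settings=None, **kw) -> DeploymentResult:
    proc = Procedure(stent, anatomy=anatomy, params=params, settings=settings, **kw)
    proc.crimp()
    if anatomy is not None:
        proc.position_stent()
    proc.release_sheath()
    return proc.result()


def expand_balloon_stent(stent: StentModel, anatomy=None, params=None, settings=None, **kw) -> DeploymentResult:
    proc = Procedure(stent, anatomy=anatomy, params=params, settings=settings,
                     with_balloon=True, **kw)
    proc.crimp()
    if anatomy is not None:
        proc.position_stent()
    proc.expand_balloon_stent()
    return proc.result()


def deploy(
    stent: StentModel,
    anatomy: AnatomyModel | None,
    params: ProtocolParams | None = None,
    settings: SolverSettings | None = None,
    seed: int = 0,
) -> DeploymentResult:
    """End-to-end procedure: (BAV) -> crimp -> position -> deploy -> settle."""
    params = params or ProtocolParams()
    proc = Procedure(stent, anatomy=anatomy, params=params, settings=settings, seed=seed)
    if anatomy is not None and params.run_bav and proc.with_balloon:
        proc.simulate_bav()
    proc.crimp()
    if anatomy is not None:
        proc.position_stent()
    if stent.spec.family == "balloon_expandable":
        proc.expand_balloon_stent()
    else:
        proc.release_sheath()
    return proc.result()
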