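"""Parametric synthetic implantation-site anatomy.

Builds a triangulated aortic root — left-ventricular outflow segment,
annulus, the three sinuses of Valsalva, sinotubular junction and ascending
aorta — together with three native leaflet membranes and optional calcific
deposits bound to the leaflet bellies.  The wall is a surface of revolution
of a profile curve modulated by a three-lobed sinus bulge; this is the
simplest shape that carries every landmark the outcome metrics need
(annulus plane, coronary ostia, sinus sectors).

Coordinate convention, shared by the whole package: the annulus plane is
z = 0, the root axis is +z toward the aorta, angles are measured
counter-clockwise viewed from the aorta, and the non-coronary sinus (NCC)
sector is centered at angle 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "AnatomyParams",
    "AnatomyModel",
    "CalciumBody",
    "build_anatomy",
    "sector_of",
    "mesh_volume",
    "SECTOR_ORDER",
]

SECTOR_ORDER = ("NCC", "RCC", "LCC")  # centers at 0, 120, 240 degrees

# wall region labels (cell data on the wall mesh)
REGIONS = {
    "lvot": 0,
    "annulus": 1,
    "sinus_NCC": 2,
    "sinus_RCC": 3,
    "sinus_LCC": 4,
    "sinotubular": 5,
    "ascending": 6,
}


@dataclass(frozen=True)
class AnatomyParams:
    """Geometric and composition parameters of a synthetic implantation site.

    Lengths in mm, volumes in mm^3.  ``calcium_volume`` defaults to the
    cohort-average leaflet calcium load; ``sinus_bulge`` is the ratio of
    mid-sinus radius to annulus radius (>= 1).
    """

    annulus_diameter: float = 24.0
    root_height: float = 50.0
    lvot_depth: float = 10.0
    sinus_bulge: float = 1.35
    sinus_height: float = 20.0
    ascending_aorta_diameter: float = 30.0
    ostia_heights: tuple[float, float] = (14.0, 13.0)  # (left, right) mm above annulus
    leaflet_free_edge_radius: float = 0.0  # 0 -> annulus_radius * 0.35
    leaflet_coaptation_height: float = 5.0
    calcium_volume: float = 726.0
    calcium_pattern: str = "nodular"  # none | nodular | arc
    calcium_leaflets: tuple = (0, 1, 2)  # cusps carrying deposits
    n_theta: int = 48
    axial_spacing: float = 1.25  # target wall ring spacing, mm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "annulus_diameter",
            "root_height",
            "lvot_depth",
            "sinus_height",
            "ascending_aorta_diameter",
            "leaflet_coaptation_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.calcium_volume < 0:
            raise ValueError("calcium_volume must be >= 0")
        if self.sinus_bulge < 1.0:
            raise ValueError("sinus_bulge must be >= 1")
        if self.calcium_pattern not in ("none", "nodular", "arc"):
            raise ValueError("calcium_pattern must be none | nodular | arc")
        if min(self.ostia_heights) <= 0:
            raise ValueError(
                "coronary ostia must lie above the annulus plane "
                f"(got heights {self.ostia_heights})"
            )
        if min(self.ostia_heights) >= self.root_height:
            raise ValueError("ostia above the top of the root")


@dataclass
class CalciumBody:
    """One calcific deposit: leaflet elements it stiffens plus a closed
    surface used for volume book-keeping."""

    leaflet: int  # cusp index 0=NCC 1=RCC 2=LCC
    element_ids: np.ndarray  # indices into that leaflet's triangles
    surface: trimesh.Trimesh  # closed nodule surface
    volume: float  # mm^3, divergence-theorem volume of `surface`
    thickness: float  # equivalent membrane thickness, mm


@dataclass
class AnatomyModel:
    """Labelled implantation-site geometry with landmarks."""

    params: AnatomyParams
    wall_vertices: np.ndarray  # (n, 3)
    wall_faces: np.ndarray  # (m, 3)
    wall_regions: np.ndarray  # (m,) int, see REGIONS
    wall_grid_shape: tuple[int, int]  # (n_rings, n_theta) of the structured grid
    leaflet_vertices: list  # three (ni, 3) arrays
    leaflet_faces: list  # three (mi, 3) arrays
    leaflet_attachment: list  # per leaflet: (k, 2) [leaflet node id, wall node id]
    leaflet_free_edge: list  # per leaflet: node ids along the free edge
    calcium_bodies: list = field(default_factory=list)  # list[CalciumBody]
    annulus_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    annulus_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    ostia: np.ndarray = field(default_factory=lambda: np.zeros((2, 3)))  # left, right

    @property
    def wall_mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.wall_vertices, faces=self.wall_faces, process=False
        )

    def leaflet_mesh(self, k: int) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.leaflet_vertices[k], faces=self.leaflet_faces[k], process=False
        )

    @property
    def total_calcium_volume(self) -> float:
        return float(sum(b.volume for b in self.calcium_bodies))


# ---------------------------------------------------------------------------
# sector convention


def sector_of(angle: float, model: AnatomyModel | None = None) -> str:
    """Cusp sector containing ``angle`` (degrees in [0, 360)).

    Sectors are fixed 120-degree half-open intervals: NCC is centered at 0
    (i.e. [300, 360) + [0, 60)), RCC is [60, 180), LCC is [180, 300).
    """
    a = float(angle) % 360.0
    if a < 60.0 or a >= 300.0:
        return "NCC"
    if a < 180.0:
        return "RCC"
    return "LCC"


def sector_center(label: str) -> float:
    return {"NCC": 0.0, "RCC": 120.0, "LCC": 240.0}[label]


# ---------------------------------------------------------------------------
# volume


def mesh_volume(mesh) -> float:
    """Signed divergence-theorem volume of a closed triangulated surface.

    Positive for outward orientation.  Raises ``ValueError`` naming the
    boundary edges if the surface is open.
    """
    if isinstance(mesh, (tuple, list)):
        mesh = trimesh.Trimesh(vertices=mesh[0], faces=mesh[1], process=False)
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) > 0:
        shown = boundary[:10].tolist()
        raise ValueError(
            f"surface is not closed: {len(boundary)} boundary edges, e.g. {shown}"
        )
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


# ---------------------------------------------------------------------------
# wall construction


def _wall_radius(params: AnatomyParams, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Radius of the wall surface at axial position z and angle theta (rad)."""
    r_ann = params.annulus_diameter / 2.0
    r_asc = params.ascending_aorta_diameter / 2.0
    h_sin = params.sinus_height
    taper = 6.0  # mm, sinotubular-to-ascending blend length

    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    # base profile: annulus radius below the sinotubular junction, smooth
    # blend to the ascending radius above it
    t = np.clip((z - h_sin) / taper, 0.0, 1.0)
    smooth = t * t * (3.0 - 2.0 * t)
    base = r_ann + (r_asc - r_ann) * smooth
    # three-lobed Valsalva bulge, peaked mid-sinus, vanishing at the annulus
    # and the sinotubular junction
    zb = np.clip(z / h_sin, 0.0, 1.0)
    axial_bump = np.sin(np.pi * zb) ** 2
    lobes = 0.5 * (1.0 + np.cos(3.0 * theta))
    bulge = 1.0 + (params.sinus_bulge - 1.0) * axial_bump * lobes
    return base * bulge


def _build_wall(params: AnatomyParams):
    """Structured-grid wall surface from -lvot_depth to root_height."""
    z0, z1 = -params.lvot_depth, params.root_height
    n_rings = max(int(round((z1 - z0) / params.axial_spacing)) + 1, 8)
    zs = np.linspace(z0, z1, n_rings)
    nt = params.n_theta
    thetas = 2.0 * np.pi * np.arange(nt) / nt

    Z, T = np.meshgrid(zs, thetas, indexing="ij")
    R = _wall_radius(params, Z, T)
    R[Z < 0.0] = params.annulus_diameter / 2.0  # cylindrical outflow tract
    verts = np.column_stack(
        [(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()]
    )

    faces = []
    regions = []
    h_sin = params.sinus_height
    for j in range(n_rings - 1):
        zmid = 0.5 * (zs[j] + zs[j + 1])
        for i in range(nt):
            i2 = (i + 1) % nt
            a = j * nt + i
            b = j * nt + i2
            c = (j + 1) * nt + i2
            d = (j + 1) * nt + i
            # outward orientation: counter-clockwise seen from outside
            faces.append((a, b, c))
            faces.append((a, c, d))
            ang = np.degrees(thetas[i] + np.pi / nt) % 360.0
            if zmid < -1.0:
                reg = REGIONS["lvot"]
            elif zmid < 1.5:
                reg = REGIONS["annulus"]
            elif zmid < h_sin - 1.0:
                reg = REGIONS[f"sinus_{sector_of(ang)}"]
            elif zmid < h_sin + 5.0:
                reg = REGIONS["sinotubular"]
            else:
                reg = REGIONS["ascending"]
            regions.append(reg)
            regions.append(reg)
    return (
        verts,
        np.asarray(faces, dtype=np.int64),
        np.asarray(regions, dtype=np.int32),
        (n_rings, nt),
        zs,
        thetas,
    )


# ---------------------------------------------------------------------------
# leaflets


def _build_leaflet(params: AnatomyParams, cusp: int, zs, thetas, wall_shape):
    """One native leaflet as a structured membrane patch.

    The attachment edge follows a U-shaped curve on the wall (commissures at
    the sinotubular level, dipping to the annulus at the sector center); the
    free edge runs from commissure to commissure through a central coaptation
    point.  Interior nodes blend linearly between the two curves with a small
    diastolic belly sag.
    """
    n_rings, nt = wall_shape
    center = np.radians(sector_center(SECTOR_ORDER[cusp]))
    half = np.pi / 3.0  # 60 degrees to each commissure
    n_s = 13  # nodes across the sector (attachment samples)
    n_t = 7  # nodes from attachment to free edge
    r_ann = params.annulus_diameter / 2.0
    r_free = params.leaflet_free_edge_radius or 0.35 * r_ann
    h_com = min(0.65 * params.sinus_height, params.sinus_height - 1.0)
    h_coapt = params.leaflet_coaptation_height

    s = np.linspace(-1.0, 1.0, n_s)  # -1..1 across the sector
    ang = center + s * half
    # attachment curve: parabolic dip from commissure height to the annulus
    z_att = h_com * s**2
    # snap attachment points onto wall grid vertices
    att_wall_ids = []
    for a_k, z_k in zip(ang, z_att):
        it = int(round((a_k % (2 * np.pi)) / (2 * np.pi) * nt)) % nt
        jz = int(np.argmin(np.abs(zs - z_k)))
        att_wall_ids.append(jz * nt + it)
    att_wall_ids = np.asarray(att_wall_ids, dtype=np.int64)

    # free edge: from commissures through the coaptation point near the axis
    z_free = h_coapt + (h_com - h_coapt) * s**2
    r_edge = r_free + (r_ann * 0.98 - r_free) * s**2
    free_pts = np.column_stack(
        [r_edge * np.cos(ang), r_edge * np.sin(ang), z_free]
    )

    belly = 0.18 * r_ann  # belly sag amplitude toward the axis / downward
    return {
        "n_s": n_s,
        "n_t": n_t,
        "att_wall_ids": att_wall_ids,
        "free_pts": free_pts,
        "s": s,
        "belly": belly,
    }


def _leaflet_mesh_from_plan(plan, wall_verts):
    n_s, n_t = plan["n_s"], plan["n_t"]
    att = wall_verts[plan["att_wall_ids"]]
    free_pts = plan["free_pts"]
    s = plan["s"]
    belly = plan["belly"]
    t = np.linspace(0.0, 1.0, n_t)
    verts = np.zeros((n_t * n_s, 3))
    for j, tv in enumerate(t):
        row = att * (1.0 - tv) + free_pts * tv
        sag = belly * np.sin(np.pi * tv) * (1.0 - s**2)
        # the belly droops mostly downward: slack in the meridional
        # direction lets the leaflet open to the wall without stretching
        radial = row[:, :2]
        rr = np.linalg.norm(radial, axis=1, keepdims=True)
        rr = np.maximum(rr, 1e-9)
        row = row.copy()
        row[:, :2] -= radial / rr * (0.2 * sag)[:, None]
        row[:, 2] -= 0.8 * sag
        verts[j * n_s : (j + 1) * n_s] = row
    faces = []
    for j in range(n_t - 1):
        for i in range(n_s - 1):
            a = j * n_s + i
            b = j * n_s + i + 1
            c = (j + 1) * n_s + i + 1
            d = (j + 1) * n_s + i
            faces.append((a, b, c))
            faces.append((a, c, d))
    faces = np.asarray(faces, dtype=np.int64)
    # orient all leaflet normals toward the root axis (ventricular side),
    # so contact sides are uniform across the three cusps
    tri = verts[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    cent = tri.mean(axis=1)
    radial = cent.copy()
    radial[:, 2] = 0.0
    if float(np.einsum("ni,ni->n", n, radial).mean()) > 0.0:
        faces = faces[:, ::-1].copy()
    attachment = np.column_stack(
        [np.arange(n_s, dtype=np.int64), plan["att_wall_ids"]]
    )
    free_edge = np.arange((n_t - 1) * n_s, n_t * n_s, dtype=np.int64)
    return verts, faces, attachment, free_edge


# ---------------------------------------------------------------------------
# calcium


def _nodule_surface(leaf_verts, leaf_faces, elem_ids, thickness):
    """Closed prism surface over a leaflet patch: offset top, original base,
    side walls along the patch rim; volume by the divergence theorem."""
    tris = leaf_faces[elem_ids]
    used = np.unique(tris)
    remap = -np.ones(leaf_verts.shape[0], dtype=np.int64)
    remap[used] = np.arange(len(used))
    base_v = leaf_verts[used]
    base_f = remap[tris]

    patch = trimesh.Trimesh(vertices=base_v, faces=base_f, process=False)
    vn = patch.vertex_normals
    top_v = base_v + vn * thickness

    nv = len(base_v)
    verts = np.vstack([base_v, top_v])
    faces = [base_f[:, ::-1], base_f + nv]  # base flipped (outward down), top up
    # rim side walls
    edges = patch.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    rim = uniq[counts == 1]
    side = []
    # orient side quads using the boundary edge direction from face winding
    edge_set = {tuple(e) for e in rim}
    for f in base_f:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if tuple(sorted((a, b))) in edge_set:
                side.append((a, b, b + nv))
                side.append((a, b + nv, a + nv))
    faces.append(np.asarray(side, dtype=np.int64))
    surf = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    vol = mesh_volume(surf)
    return surf, abs(vol)


def _place_calcium(params: AnatomyParams, leaflets, rng):
    """Distribute the requested calcium volume over leaflet-belly patches.

    nodular: one roughly round patch per cusp with seeded jitter;
    arc: an elongated patch along the attachment line of each cusp.
    The membrane-equivalent thickness is solved so the summed closed-surface
    volumes match ``calcium_volume``.
    """
    if params.calcium_pattern == "none" or params.calcium_volume <= 0:
        return []
    bodies = []
    patches = []
    cusps = [k for k in params.calcium_leaflets if 0 <= k <= 2]
    vol_per = params.calcium_volume / max(len(cusps), 1)
    for k in cusps:
        lv, lf = leaflets[k]
        centroids = lv[lf].mean(axis=1)
        if params.calcium_pattern == "nodular":
            # patch around a jittered point on the belly, sized so the
            # nodule thickness stays anatomically plausible
            tgt = centroids[
                np.argsort(np.abs(centroids[:, 2] - np.median(centroids[:, 2])))[
                    len(centroids) // 3
                ]
            ]
            jitter = rng.normal(scale=0.8, size=3)
            center = tgt + jitter
            d = np.linalg.norm(centroids - center, axis=1)
            radius = float(np.clip(1.2 * vol_per ** (1.0 / 3.0), 2.5, 8.0))
            ids = np.where(d < radius)[0]
            if len(ids) < 4:
                ids = np.argsort(d)[:6]
        else:  # arc along the attachment (first structured rows)
            n_s = 13
            row_elems = np.arange(lf.shape[0])
            # first two element rows adjacent to the attachment edge
            ids = row_elems[: 2 * 2 * (n_s - 1)]
        patches.append((k, np.asarray(ids, dtype=np.int64)))

    # total patch area -> first-guess thickness, then one secant refinement
    def total_volume(th):
        vols = []
        for k, ids in patches:
            lv, lf = leaflets[k]
            _, vol = _nodule_surface(lv, lf, ids, th)
            vols.append(vol)
        return vols

    area = 0.0
    for k, ids in patches:
        lv, lf = leaflets[k]
        tr = lv[lf[ids]]
        area += 0.5 * np.linalg.norm(
            np.cross(tr[:, 1] - tr[:, 0], tr[:, 2] - tr[:, 0]), axis=1
        ).sum()
    th = params.calcium_volume / max(area, 1e-9)
    vols = total_volume(th)
    # iterate: prism volume is nonlinear in thickness for bulky nodules
    for _ in range(8):
        err = sum(vols) / params.calcium_volume
        if abs(err - 1.0) < 0.01:
            break
        th /= err
        vols = total_volume(th)

    for (k, ids), vol in zip(patches, vols):
        lv, lf = leaflets[k]
        surf, v = _nodule_surface(lv, lf, ids, th)
        bodies.append(
            CalciumBody(leaflet=k, element_ids=ids, surface=surf, volume=v, thickness=th)
        )
    return bodies


# ---------------------------------------------------------------------------
# top level


def build_anatomy(params: AnatomyParams) -> AnatomyModel:
    """Build a synthetic implantation site from its parameters.

    Deterministic for a fixed seed; raises ``ValueError`` with an explanatory
    message for degenerate geometry (checked in ``AnatomyParams``).
    """
    wall_v, wall_f, wall_r, shape, zs, thetas = _build_wall(params)

    leaf_plans = [
        _build_leaflet(params, k, zs, thetas, shape) for k in range(3)
    ]
    leaflet_vertices, leaflet_faces, attachments, free_edges = [], [], [], []
    for plan in leaf_plans:
        lv, lf, att, fe = _leaflet_mesh_from_plan(plan, wall_v)
        leaflet_vertices.append(lv)
        leaflet_faces.append(lf)
        attachments.append(att)
        free_edges.append(fe)

    rng = np.random.default_rng(params.seed)
    bodies = _place_calcium(
        params, list(zip(leaflet_vertices, leaflet_faces)), rng
    )

    # ostia: left coronary in the LCC sector, right coronary in the RCC sector
    zl, zr = params.ostia_heights
    al = np.radians(sector_center("LCC"))
    ar = np.radians(sector_center("RCC"))
    rl = _wall_radius(params, np.array([zl]), np.array([al]))[0]
    rr_ = _wall_radius(params, np.array([zr]), np.array([ar]))[0]
    ostia = np.array(
        [
            [rl * np.cos(al), rl * np.sin(al), zl],
            [rr_ * np.cos(ar), rr_ * np.sin(ar), zr],
        ]
    )

    return AnatomyModel(
        params=params,
        wall_vertices=wall_v,
        wall_faces=wall_f,
        wall_regions=wall_r,
        wall_grid_shape=shape,
        leaflet_vertices=leaflet_vertices,
        leaflet_faces=leaflet_faces,
        leaflet_attachment=attachments,
        leaflet_free_edge=free_edges,
        calcium_bodies=bodies,
        ostia=ostia,
    )
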