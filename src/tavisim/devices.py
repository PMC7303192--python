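"""Beam-lattice stent frames in their expanded reference configurations.

Two families are provided, mirroring the devices implanted in the study
cohort: a balloon-expandable cylindrical frame (cobalt-chromium alloy,
elastoplastic) in sizes 23/26/29 mm, and a self-expandable hourglass frame
(superelastic Nitinol) in sizes 26/29 mm with a 12 mm skirt at the inflow
(proximal) end.  Frames are diamond-cell lattices of two-node beam elements;
the exact strut dimensions and cell counts of the commercial devices are not
public, so the defaults here are representative and fully configurable.

The frame axis is +z; the proximal (inflow, annulus-side) end is at z = 0 in
the reference configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DeviceSpec", "StentModel", "build_balloon_expandable", "build_self_expandable"]

_BALLOON_SIZES = (23.0, 26.0, 29.0)
_SELF_SIZES = (26.0, 29.0)

# frame heights, mm (desk-scale choices; commercial values are not printed
# in any source this package relies on)
_BE_HEIGHT = {23.0: 14.5, 26.0: 17.2, 29.0: 19.1}
_SE_HEIGHT = {26.0: 48.0, 29.0: 50.0}


@dataclass(frozen=True)
class DeviceSpec:
    """Parametric description of a stent frame."""

    family: str  # balloon_expandable | self_expandable
    nominal_size: float  # mm
    frame_height: float | None = None
    cells_circumferential: int = 8
    cells_axial: int | None = None
    strut_width: float = 0.4
    strut_thickness: float = 0.35
    elements_per_strut: int = 2
    skirt_length: float = 12.0  # self_expandable only
    valve_level: float | None = None  # axial fraction; None -> family default
    crimped_diameter: float = 6.0
    material_id: str | None = None  # None -> family default card

    def __post_init__(self) -> None:
        if self.family == "balloon_expandable":
            allowed = _BALLOON_SIZES
        elif self.family == "self_expandable":
            allowed = _SELF_SIZES
        else:
            raise ValueError(f"unknown device family {self.family!r}")
        if float(self.nominal_size) not in allowed:
            raise ValueError(
                f"{self.family} size {self.nominal_size} unsupported; "
                f"supported sizes: {sorted(allowed)}"
            )
        if self.crimped_diameter >= self.nominal_size:
            raise ValueError("crimped_diameter must be smaller than nominal_size")

    @property
    def height(self) -> float:
        if self.frame_height is not None:
            return self.frame_height
        table = _BE_HEIGHT if self.family == "balloon_expandable" else _SE_HEIGHT
        return table[float(self.nominal_size)]

    @property
    def default_material(self) -> str:
        if self.material_id:
            return self.material_id
        return "mp35n" if self.family == "balloon_expandable" else "nitinol"


@dataclass
class StentModel:
    """A beam-lattice frame.

    ``rings`` groups node ids by axial level (ordered proximal to distal);
    ``radial_profile`` is the nominal radius of each ring; ``valve_ring`` is
    the ring where the bioprosthetic valve sits and where the projected
    diameter is measured; ``skirt_rings`` are the rings within the skirt
    length of the proximal end (self-expandable only).
    """

    spec: DeviceSpec
    nodes: np.ndarray  # (n, 3)
    beams: np.ndarray  # (m, 2)
    material_id: str
    rings: list  # list of np.ndarray node ids
    ring_z: np.ndarray  # (n_rings,)
    radial_profile: np.ndarray  # (n_rings,)
    valve_ring: int
    skirt_rings: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def ring_diameter(self, ring: int, positions: np.ndarray | None = None) -> float:
        """Mean diameter of a ring in the given (default reference) config."""
        pts = (self.nodes if positions is None else positions)[self.rings[ring]]
        center = pts.mean(axis=0)
        r = np.linalg.norm(pts[:, :2] - center[:2], axis=1)
        return float(2.0 * r.mean())

    def connected(self) -> bool:
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        n = self.n_nodes
        g = sp.coo_matrix(
            (np.ones(len(self.beams)), (self.beams[:, 0], self.beams[:, 1])),
            shape=(n, n),
        )
        ncomp, _ = connected_components(g, directed=False)
        return ncomp == 1


def _diamond_lattice(spec: DeviceSpec, radius_of_z, height: float, cells_axial: int):
    """Diamond (rhombus) lattice on a surface of revolution.

    Vertex rows j = 0..cells_axial at z_j, each with ``cells_circumferential``
    junction nodes, alternate rows rotated by half a cell; each junction
    connects to two junctions of the next row, and every strut is subdivided
    into ``elements_per_strut`` beam elements.
    """
    nc = spec.cells_circumferential
    nrows = cells_axial + 1
    zs = np.linspace(0.0, height, nrows)
    nodes = []
    row_ids = []
    for j in range(nrows):
        off = 0.5 * (j % 2)
        ang = 2.0 * np.pi * (np.arange(nc) + off) / nc
        r = radius_of_z(zs[j])
        start = len(nodes)
        for a in ang:
            nodes.append((r * np.cos(a), r * np.sin(a), zs[j]))
        row_ids.append(np.arange(start, start + nc))
    nodes = np.asarray(nodes, dtype=float)

    struts = []
    for j in range(nrows - 1):
        lo, hi = row_ids[j], row_ids[j + 1]
        for i in range(nc):
            if j % 2 == 0:
                struts.append((lo[i], hi[i]))
                struts.append((lo[(i + 1) % nc], hi[i]))
            else:
                struts.append((lo[i], hi[i]))
                struts.append((lo[i], hi[(i + 1) % nc]))

    # subdivide struts, interpolating on straight chords
    nsub = max(int(spec.elements_per_strut), 1)
    all_nodes = [nodes]
    beams = []
    next_id = len(nodes)
    for a, b in struts:
        prev = a
        for k in range(1, nsub):
            t = k / nsub
            p = nodes[a] * (1 - t) + nodes[b] * t
            all_nodes.append(p[None, :])
            beams.append((prev, next_id))
            prev = next_id
            next_id += 1
        beams.append((prev, b))
    nodes_full = np.vstack(all_nodes)
    beams = np.asarray(beams, dtype=np.int64)

    # rings: group all nodes (junction + midside) by axial coordinate
    z_all = nodes_full[:, 2]
    z_lvls = np.unique(np.round(z_all, 6))
    rings = [np.where(np.abs(z_all - z) < 1e-5)[0] for z in z_lvls]
    return nodes_full, beams, rings, z_lvls


def build_balloon_expandable(size: float, spec: DeviceSpec | None = None) -> StentModel:
    """Cylindrical diamond-cell frame of nominal diameter = size."""
    if spec is None:
        spec = DeviceSpec(family="balloon_expandable", nominal_size=float(size))
    height = spec.height
    cells_axial = spec.cells_axial or 3
    radius = spec.nominal_size / 2.0
    nodes, beams, rings, z_lvls = _diamond_lattice(
        spec, lambda z: radius, height, cells_axial
    )
    profile = np.full(len(rings), radius)
    vl = spec.valve_level if spec.valve_level is not None else 0.5
    valve_ring = int(np.argmin(np.abs(z_lvls - vl * height)))
    return StentModel(
        spec=spec,
        nodes=nodes,
        beams=beams,
        material_id=spec.default_material,
        rings=rings,
        ring_z=z_lvls,
        radial_profile=profile,
        valve_ring=valve_ring,
    )


def _hourglass_radius(spec: DeviceSpec, height: float):
    """Inflow at nominal radius, constrained waist, flared outflow."""
    r_in = spec.nominal_size / 2.0
    r_waist = 0.78 * r_in
    r_out = 1.10 * r_in
    z_waist = 0.45 * height

    def radius(z):
        t = z / height
        tw = z_waist / height
        if t <= tw:
            u = t / tw
            s = 0.5 - 0.5 * np.cos(np.pi * u)
            return r_in + (r_waist - r_in) * s
        u = (t - tw) / (1.0 - tw)
        s = 0.5 - 0.5 * np.cos(np.pi * u)
        return r_waist + (r_out - r_waist) * s

    return radius


def build_self_expandable(size: float, spec: DeviceSpec | None = None) -> StentModel:
    """Hourglass diamond-cell frame: flared inflow at nominal diameter,
    waist, flared outflow; skirt rings cover the proximal 12 mm."""
    if spec is None:
        spec = DeviceSpec(
            family="self_expandable",
            nominal_size=float(size),
            strut_width=0.5,
            strut_thickness=0.4,
        )
    height = spec.height
    cells_axial = spec.cells_axial or 8
    radius = _hourglass_radius(spec, height)
    nodes, beams, rings, z_lvls = _diamond_lattice(spec, radius, height, cells_axial)
    profile = np.array([radius(z) for z in z_lvls])
    if spec.valve_level is not None:
        valve_ring = int(np.argmin(np.abs(z_lvls - spec.valve_level * height)))
    else:
        valve_ring = int(np.argmin(profile))  # at the waist
    skirt = np.where(z_lvls <= spec.skirt_length + 0.5)[0]
    return StentModel(
        spec=spec,
        nodes=nodes,
        beams=beams,
        material_id=spec.default_material,
        rings=rings,
        ring_z=z_lvls,
        radial_profile=profile,
        valve_ring=valve_ring,
        skirt_rings=skirt,
    )
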