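"""Clinical outcome metrics computed from a deployed configuration.

Three predictors are extracted from the end-of-deployment state:

* **projected stent diameter** — the frame ring at the valve level is
  projected onto the plane normal to an x-ray viewing direction (deployed
  frames are not circular, so the projection matters) and the maximal
  point-pair distance of the projected ring is reported;
* **paravalvular-leak (PVL) channels** — a cylindrical clearance map between
  the frame's outer envelope and the surrounding tissue (wall, leaflets and
  calcific deposits all count as tissue) is thresholded into an occupancy
  grid; connected gap regions (8-neighbourhood with angular wraparound, so
  helical paths count) that are continuous along the full device rule range
  — the entire frame for the balloon-expandable device, the proximal 12 mm
  skirt for the self-expandable device — are reported as leak channels,
  labelled with the sinus sectors their angular span crosses;
* **regional maximum principal strain** — the largest principal
  Green-Lagrange strain of each wall element, in percent, summarised as the
  average over the region below the coronary ostia, the absolute maximum
  over the whole implantation site, and the maximum in the NCC-RCC sector
  (left-bundle-branch territory, the conduction-risk proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import AnatomyModel, sector_of

__all__ = [
    "ProjectionSpec",
    "GapMap",
    "PVLChannel",
    "PVLReport",
    "StrainReport",
    "projected_diameter",
    "compute_gap_map",
    "detect_pvl",
    "detect_pvl_bruteforce",
    "strain_report",
    "green_lagrange_max_principal",
]


# ---------------------------------------------------------------------------
# projected diameter


@dataclass(frozen=True)
class ProjectionSpec:
    """An x-ray viewing direction and the axial level of the measurement."""

    view_direction: tuple = (1.0, 0.0, 0.0)
    measurement_level: float | int | None = None  # ring id or axial mm

    def unit_view(self) -> np.ndarray:
        v = np.asarray(self.view_direction, dtype=float)
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ValueError("view_direction must be a nonzero vector")
        return v / n


def projected_diameter(ring_points: np.ndarray, proj: ProjectionSpec) -> float:
    """Maximal point-pair distance of the ring projected along the view.

    ``ring_points`` are the 3-D coordinates of the measurement-level ring
    nodes in the deployed configuration.
    """
    pts = np.asarray(ring_points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("empty measurement ring")
    v = proj.unit_view()
    p = pts - np.outer(pts @ v, v)  # project onto plane normal to the view
    d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=2)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# gap map


@dataclass
class GapMap:
    """Cylindrical clearance field between frame envelope and tissue."""

    axial_stations: np.ndarray  # (ns,) mm along the frame axis
    angular_bins: np.ndarray  # (nb,) degrees, bin centers
    clearance: np.ndarray  # (ns, nb) mm, >= 0
    occupied: np.ndarray  # (ns, nb) bool, clearance > threshold
    threshold: float
    excluded_stations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ns, nb = self.clearance.shape
        assert len(self.axial_stations) == ns and len(self.angular_bins) == nb


def _ray_hits(meshes, z, theta_deg, first_only=True):
    """Radial ray casting from the axis: for each (station, bin) ray return
    the first hit distance (``first_only``) or the list of all hit
    distances.  Moeller-Trumbore, vectorised over triangles per ray batch."""
    nb = len(theta_deg)
    ns = len(z)
    th = np.radians(theta_deg)
    dirs = np.zeros((nb, 3))
    dirs[:, 0] = np.cos(th)
    dirs[:, 1] = np.sin(th)

    tris_all = []
    for mesh in meshes:
        v = np.asarray(mesh.vertices)
        f = np.asarray(mesh.faces)
        if len(f):
            tris_all.append(v[f])
    first = np.full((ns, nb), np.nan)
    all_hits = [[[] for _ in range(nb)] for _ in range(ns)]
    if not tris_all:
        return (first if first_only else all_hits)
    tri = np.vstack(tris_all)  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    zmin = tri[:, :, 2].min(axis=1)
    zmax = tri[:, :, 2].max(axis=1)

    for si, zi in enumerate(z):
        origin = np.array([0.0, 0.0, zi])
        m = (zmin <= zi + 1.0) & (zmax >= zi - 1.0)
        if not np.any(m):
            continue
        E1, E2, V0 = e1[m], e2[m], v0[m]
        s = origin - V0
        q = np.cross(s, E1)
        for bi in range(nb):
            d = dirs[bi]
            h = np.cross(d, E2)
            a = np.einsum("mi,mi->m", E1, h)
            ok = np.abs(a) > 1e-12
            f_ = np.where(ok, 1.0 / np.where(a == 0, 1.0, a), 0.0)
            u = f_ * np.einsum("mi,mi->m", s, h)
            vv = f_ * (q @ d)
            t = f_ * np.einsum("mi,mi->m", q, E2)
            hit = ok & (u >= -1e-9) & (vv >= -1e-9) & (u + vv <= 1.0 + 1e-9) & (t > 1e-6)
            if np.any(hit):
                ts = t[hit]
                first[si, bi] = ts.min()
                if not first_only:
                    all_hits[si][bi] = np.sort(ts).tolist()
    return first if first_only else all_hits


def _envelope_radii(samples, z_stations, theta_deg, station_halfwidth):
    """Outer-envelope radius of the frame per (station, bin): the maximum
    sample radius in each cell, filled by periodic linear interpolation in
    angle where a station has empty bins."""
    ns, nb = len(z_stations), len(theta_deg)
    r = np.sqrt(samples[:, 0] ** 2 + samples[:, 1] ** 2)
    ang = np.degrees(np.arctan2(samples[:, 1], samples[:, 0])) % 360.0
    bin_w = 360.0 / nb
    bi = np.clip((ang / bin_w).astype(int), 0, nb - 1)
    env = np.full((ns, nb), np.nan)
    for si, zc in enumerate(z_stations):
        m = np.abs(samples[:, 2] - zc) <= station_halfwidth
        if not np.any(m):
            continue
        row = np.full(nb, -np.inf)
        np.maximum.at(row, bi[m], r[m])
        row[np.isinf(row)] = np.nan
        env[si] = row
    # periodic angular interpolation of empty bins
    for si in range(ns):
        row = env[si]
        good = ~np.isnan(row)
        if not np.any(good):
            continue
        if np.all(good):
            continue
        xp = np.where(good)[0]
        fp = row[xp]
        x = np.arange(nb)
        env[si] = np.interp(x, xp, fp, period=nb)
    return env


def compute_gap_map(
    frame_samples: np.ndarray,
    tissue_meshes,
    z_range: tuple,
    stations_per_mm: float = 2.0,
    bins: int = 72,
    threshold: float = 0.1,
    strut_radius: float = 0.0,
    wall_offset: float = 0.0,
    blockers=None,
) -> GapMap:
    """Clearance between the frame's outer envelope and the containing wall.

    ``frame_samples`` are points sampled densely along the deployed frame
    beams; ``tissue_meshes`` is the containing surface (artery wall; a list
    is accepted and merged).  A paravalvular channel hugs the device, so
    the leak clearance of a cell is the radial distance from the frame
    envelope (plus ``strut_radius``) to the *first* tissue surface along
    the bin's ray: the wall inner surface (midsurface hit minus
    ``wall_offset``) or any interposed structure given in ``blockers`` —
    ``(mesh, inner_offset)`` tuples for the native leaflets and calcific
    deposits, whose inner faces seal against the frame when pressed onto
    it regardless of the open sinus pocket behind them.  A cell is an open
    gap (occupied) when the clearance exceeds ``threshold``; stations whose
    rays miss the wall everywhere are excluded and logged.
    """
    z0, z1 = z_range
    ns = max(int(round((z1 - z0) * stations_per_mm)) + 1, 2)
    z = np.linspace(z0, z1, ns)
    theta = (np.arange(bins) + 0.5) * 360.0 / bins

    halfwidth = 0.5 * (z[1] - z[0]) if ns > 1 else 1.0
    env = _envelope_radii(frame_samples, z, theta, max(halfwidth, 1.0))
    if not isinstance(tissue_meshes, (list, tuple)):
        tissue_meshes = [tissue_meshes]
    wall_r = _ray_hits(tissue_meshes, z, theta, first_only=True)

    block_hits = []
    for blocker in blockers or []:
        mesh, off_in = blocker[0], blocker[1]
        block_hits.append((_ray_hits([mesh], z, theta, first_only=False), off_in))

    clearance = np.zeros((ns, nb := bins))
    for si in range(ns):
        for bi in range(nb):
            rd = env[si, bi] + strut_radius
            rw = wall_r[si, bi] - wall_offset
            if not np.isfinite(rw):
                clearance[si, bi] = np.nan
                continue
            first = rw
            for hits, off_in in block_hits:
                for t in hits[si][bi]:
                    inner = t - off_in
                    # surfaces already inside the envelope are in contact
                    if inner < first:
                        first = inner
            clearance[si, bi] = max(first - rd, 0.0)

    excluded = [int(i) for i in range(ns) if np.all(np.isnan(clearance[i]))]
    cl = np.nan_to_num(np.maximum(clearance, 0.0), nan=0.0)
    occupied = cl > threshold
    return GapMap(
        axial_stations=z,
        angular_bins=theta,
        clearance=cl,
        occupied=occupied,
        threshold=threshold,
        excluded_stations=excluded,
    )


# ---------------------------------------------------------------------------
# PVL detection


@dataclass
class PVLChannel:
    """One continuous leak channel through the gap map."""

    cells: np.ndarray  # (k, 2) (station, bin) indices
    angular_span: tuple  # (start_deg, end_deg) of the bins crossed
    axial_extent: float  # mm
    sinuses: tuple  # cusp labels crossed


@dataclass
class PVLReport:
    present: bool
    channels: list
    device_rule_applied: str  # full_length | proximal_12mm

    def sinuses(self) -> set:
        out: set = set()
        for ch in self.channels:
            out.update(ch.sinuses)
        return out


def _periodic_label(occupied: np.ndarray):
    """Connected components (8-neighbourhood) on a grid periodic in the
    second axis."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(occupied, structure=structure)
    if n == 0 or occupied.shape[1] < 2:
        return labels, n
    # merge components across the angular seam
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    first, last = labels[:, 0], labels[:, -1]
    ns = occupied.shape[0]
    for i in range(ns):
        if last[i]:
            for di in (-1, 0, 1):
                j = i + di
                if 0 <= j < ns and first[j]:
                    union(last[i], first[j])
    out = labels.copy()
    for lab in range(1, n + 1):
        out[labels == lab] = find(lab)
    return out, n


def detect_pvl(gapmap: GapMap, family: str, anatomy: AnatomyModel | None = None) -> PVLReport:
    """Leak channels: connected gap components spanning the full axial rule
    range of the device family."""
    rule = "full_length" if family == "balloon_expandable" else "proximal_12mm"
    occ = gapmap.occupied
    ns = occ.shape[0]
    labels, n = _periodic_label(occ)
    channels = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        cells = np.argwhere(labels == lab)
        smin, smax = cells[:, 0].min(), cells[:, 0].max()
        if smin > 0 or smax < ns - 1:
            continue  # not continuous along the whole rule range
        bins = np.unique(cells[:, 1])
        angs = gapmap.angular_bins[bins]
        sinuses = tuple(sorted({sector_of(a) for a in angs}))
        channels.append(
            PVLChannel(
                cells=cells,
                angular_span=(float(angs.min()), float(angs.max())),
                axial_extent=float(
                    gapmap.axial_stations[smax] - gapmap.axial_stations[smin]
                ),
                sinuses=sinuses,
            )
        )
    return PVLReport(present=len(channels) > 0, channels=channels, device_rule_applied=rule)


def detect_pvl_bruteforce(occupied: np.ndarray) -> list:
    """Exhaustive path-search oracle: breadth-first search from every
    occupied cell of the first station, 8-neighbourhood with angular
    wraparound; returns the sets of cells of every spanning component.

    Independent of the labelling implementation; used to pin the channel
    semantics.
    """
    ns, nb = occupied.shape
    seen = np.zeros_like(occupied, dtype=bool)
    comps = []
    for s0 in range(ns):
        for b0 in range(nb):
            if not occupied[s0, b0] or seen[s0, b0]:
                continue
            stack = [(s0, b0)]
            seen[s0, b0] = True
            comp = []
            while stack:
                s, b = stack.pop()
                comp.append((s, b))
                for ds in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        if ds == 0 and db == 0:
                            continue
                        s2, b2 = s + ds, (b + db) % nb
                        if 0 <= s2 < ns and occupied[s2, b2] and not seen[s2, b2]:
                            seen[s2, b2] = True
                            stack.append((s2, b2))
            rows = {c[0] for c in comp}
            if 0 in rows and ns - 1 in rows:
                comps.append(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# strain report


def green_lagrange_max_principal(verts_ref, faces, verts_def):
    """Largest principal in-plane Green-Lagrange strain per triangle."""
    a0, b0, c0 = (verts_ref[faces[:, k]] for k in range(3))
    a1, b1, c1 = (verts_def[faces[:, k]] for k in range(3))
    d10, d20 = b0 - a0, c0 - a0
    d11, d21 = b1 - a1, c1 - a1
    # metric tensors of reference and deformed configurations
    g0 = np.empty((len(faces), 2, 2))
    g0[:, 0, 0] = np.einsum("ni,ni->n", d10, d10)
    g0[:, 0, 1] = g0[:, 1, 0] = np.einsum("ni,ni->n", d10, d20)
    g0[:, 1, 1] = np.einsum("ni,ni->n", d20, d20)
    g1 = np.empty_like(g0)
    g1[:, 0, 0] = np.einsum("ni,ni->n", d11, d11)
    g1[:, 0, 1] = g1[:, 1, 0] = np.einsum("ni,ni->n", d11, d21)
    g1[:, 1, 1] = np.einsum("ni,ni->n", d21, d21)
    # E in the covariant basis: solve generalised eigenproblem of C = g0^-1 g1
    det = g0[:, 0, 0] * g0[:, 1, 1] - g0[:, 0, 1] ** 2
    inv = np.empty_like(g0)
    inv[:, 0, 0] = g0[:, 1, 1] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -g0[:, 0, 1] / det
    inv[:, 1, 1] = g0[:, 0, 0] / det
    C = np.einsum("nij,njk->nik", inv, g1)
    tr = C[:, 0, 0] + C[:, 1, 1]
    dt = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - dt, 0.0))
    lam_max = tr / 2.0 + disc  # largest stretch^2
    return 0.5 * (lam_max - 1.0)


@dataclass
class StrainReport:
    """Regional maximum-principal-strain statistics of the wall, percent."""

    average_below_ostia: float
    absolute_max: float
    max_ncc_rcc: float
    field: np.ndarray  # per wall element, percent


def strain_report(
    anatomy: AnatomyModel,
    deformed_wall_vertices: np.ndarray,
    frame_proximal_z: float | None = None,
    nccrcc_range: tuple = (0.0, 120.0),
) -> StrainReport:
    """Regional strain statistics from reference vs deformed wall geometry.

    ``average_below_ostia`` averages over elements whose centroid lies below
    the lower coronary ostium (and above the proximal frame end when given);
    ``max_ncc_rcc`` restricts to the angular span between the NCC and RCC
    midlines, where the left bundle branch runs.
    """
    if deformed_wall_vertices.shape != anatomy.wall_vertices.shape:
        raise ValueError("deformed wall must match the reference mesh")
    faces = anatomy.wall_faces
    strains = (
        green_lagrange_max_principal(
            anatomy.wall_vertices, faces, deformed_wall_vertices
        )
        * 100.0
    )
    cent = anatomy.wall_vertices[faces].mean(axis=1)
    z = cent[:, 2]
    ang = np.degrees(np.arctan2(cent[:, 1], cent[:, 0])) % 360.0

    z_ostia = float(anatomy.ostia[:, 2].min())
    below = z < z_ostia
    if frame_proximal_z is not None:
        below &= z > frame_proximal_z
    a0, a1 = nccrcc_range
    in_nccrcc = ((ang - a0) % 360.0) <= ((a1 - a0) % 360.0)

    avg = float(strains[below].mean()) if np.any(below) else 0.0
    absmax = float(strains.max()) if len(strains) else 0.0
    sel = below & in_nccrcc
    max_nr = float(strains[sel].max()) if np.any(sel) else 0.0
    return StrainReport(
        average_below_ostia=avg,
        absolute_max=absmax,
        max_ncc_rcc=max_nr,
        field=strains,
    )
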