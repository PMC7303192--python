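"""Outcome-metric oracles: projected diameter, gap maps, leak-channel
detection, regional principal strains."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from tavisim.anatomy import AnatomyParams, build_anatomy
from tavisim.metrics import (
    GapMap,
    ProjectionSpec,
    compute_gap_map,
    detect_pvl,
    detect_pvl_bruteforce,
    green_lagrange_max_principal,
    projected_diameter,
    strain_report,
)


def _ring(n=72, a=13.0, b=13.0):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(th), b * np.sin(th), np.zeros(n)])


def _tube(radius, z0=-5.0, z1=5.0, n_theta=96, n_z=21):
    th = 2 * np.pi * np.arange(n_theta) / n_theta
    zs = np.linspace(z0, z1, n_z)
    verts = np.array([[radius * np.cos(a), radius * np.sin(a), z] for z in zs for a in th])
    faces = []
    for j in range(n_z - 1):
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            faces.append((j * n_theta + i, j * n_theta + i2, (j + 1) * n_theta + i2))
            faces.append((j * n_theta + i, (j + 1) * n_theta + i2, (j + 1) * n_theta + i))
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def _frame_samples(radius, z0=-4.0, z1=4.0, n=4000, offset=0.0, seed=0):
    rng = np.random.default_rng(seed)
    th = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(z0, z1, n)
    return np.column_stack([radius * np.cos(th) + offset, radius * np.sin(th), z])


# ---------------------------------------------------------------------------
# projected diameter


def test_circle_projects_to_its_diameter_for_any_perpendicular_view():
    ring = _ring(a=13.0, b=13.0)
    for v in ([1, 0, 0], [0, 1, 0], [0.6, 0.8, 0]):
        assert projected_diameter(ring, ProjectionSpec(tuple(v))) == pytest.approx(26.0, rel=1e-3)


def test_ellipse_views_along_principal_axes():
    ring = _ring(a=12.0, b=14.0)
    # viewing along the minor (x) axis leaves the major diameter visible
    assert projected_diameter(ring, ProjectionSpec((1, 0, 0))) == pytest.approx(28.0, rel=1e-3)
    assert projected_diameter(ring, ProjectionSpec((0, 1, 0))) == pytest.approx(24.0, rel=1e-3)


def test_view_along_axis_gives_true_max_in_plane_diameter():
    ring = _ring(a=12.0, b=14.0)
    assert projected_diameter(ring, ProjectionSpec((0, 0, 1))) == pytest.approx(28.0, rel=1e-3)


def test_projection_invariant_under_joint_scene_rotation():
    ring = _ring(a=12.0, b=14.0)
    Q = Rotation.from_rotvec([0.3, 0.5, -0.2]).as_matrix()
    v = np.array([1.0, 0.0, 0.0])
    d1 = projected_diameter(ring, ProjectionSpec(tuple(v)))
    d2 = projected_diameter(ring @ Q.T, ProjectionSpec(tuple(Q @ v)))
    assert d1 == pytest.approx(d2, rel=1e-9)


def test_empty_ring_rejected():
    with pytest.raises(ValueError, match="empty"):
        projected_diameter(np.zeros((0, 3)), ProjectionSpec())


# ---------------------------------------------------------------------------
# gap map


def test_concentric_frame_in_tube_clearance_is_annulus_width():
    gm = compute_gap_map(
        _frame_samples(10.0), _tube(12.0), (-3.5, 3.5),
        stations_per_mm=1.0, bins=36, threshold=0.1,
    )
    body = gm.clearance
    assert np.nanmax(np.abs(body - 2.0)) < 0.1
    assert gm.occupied.all()


def test_full_contact_leaves_no_occupied_cells():
    gm = compute_gap_map(
        _frame_samples(10.0), _tube(10.05), (-3.5, 3.5),
        stations_per_mm=1.0, bins=36, threshold=0.1,
    )
    assert not gm.occupied.any()


def test_eccentric_annulus_clearance_matches_closed_form():
    """Frame radius 10 offset by 1 inside a tube of radius 11: clearance
    along each ray equals d cos(t) + sqrt(R^2 - d^2 sin^2 t) - r."""
    d, R, r = 1.0, 11.0, 10.0
    gm = compute_gap_map(
        _frame_samples(r, offset=d, n=20000), _tube(R), (-3.0, 3.0),
        stations_per_mm=1.0, bins=72, threshold=0.1,
    )
    th = np.radians(gm.angular_bins)
    # rays emanate from the tube axis; frame surface along the ray:
    frame_r = d * np.cos(th) + np.sqrt(r**2 - d**2 * np.sin(th) ** 2)
    expected = np.clip(R - frame_r, 0.0, None)
    measured = gm.clearance.mean(axis=0)
    wide = expected > 0.3
    np.testing.assert_allclose(measured[wide], expected[wide], rtol=0.05, atol=0.05)
    # occupied arc only on the wide side
    assert gm.occupied[:, np.argmax(expected)].all()
    assert not gm.occupied[:, np.argmin(expected)].any()


def test_blockers_fill_the_gap():
    """A second surface interposed between frame and wall removes the free
    interval its thickness covers."""
    gm_open = compute_gap_map(
        _frame_samples(10.0), _tube(13.0), (-3.0, 3.0),
        stations_per_mm=1.0, bins=18, threshold=0.1,
    )
    blocker = _tube(11.5)
    gm_block = compute_gap_map(
        _frame_samples(10.0), _tube(13.0), (-3.0, 3.0),
        stations_per_mm=1.0, bins=18, threshold=0.1,
        blockers=[(blocker, 0.75, 0.75)],
    )
    assert np.nanmean(gm_open.clearance) == pytest.approx(3.0, abs=0.1)
    # blocker band [10.75, 12.25] splits the gap into two 0.75 mm slits
    assert np.nanmean(gm_block.clearance) == pytest.approx(0.75, abs=0.1)


# ---------------------------------------------------------------------------
# leak channel detection


def _report_sets(occ):
    gm = GapMap(
        axial_stations=np.arange(occ.shape[0], dtype=float),
        angular_bins=(np.arange(occ.shape[1]) + 0.5) * 360.0 / occ.shape[1],
        clearance=occ.astype(float),
        occupied=occ,
        threshold=0.5,
    )
    rep = detect_pvl(gm, "balloon_expandable")
    return {frozenset(map(tuple, ch.cells)) for ch in rep.channels}, rep


def test_fully_occupied_map_is_one_channel_spanning_all_sinuses():
    occ = np.ones((6, 12), dtype=bool)
    sets, rep = _report_sets(occ)
    assert rep.present and len(rep.channels) == 1
    assert rep.sinuses() == {"NCC", "RCC", "LCC"}


def test_single_column_at_ncc_midline():
    occ = np.zeros((8, 72), dtype=bool)
    occ[:, 0] = True  # bin centered at 2.5 degrees -> NCC
    sets, rep = _report_sets(occ)
    assert rep.present and len(rep.channels) == 1
    assert rep.channels[0].sinuses == ("NCC",)


def test_helical_path_counts_via_diagonal_connectivity():
    occ = np.zeros((5, 10), dtype=bool)
    for s in range(5):
        occ[s, (2 * s) % 10] = True
        occ[s, (2 * s + 1) % 10] = True
    sets, rep = _report_sets(occ)
    assert rep.present


def test_non_spanning_component_is_not_a_channel():
    occ = np.zeros((6, 12), dtype=bool)
    occ[1:5, 3] = True  # does not reach either end station
    sets, rep = _report_sets(occ)
    assert not rep.present and rep.channels == []


def test_detection_equals_bruteforce_oracle_exhaustive_small_maps():
    """All 4096 occupancy maps on a 3 x 4 periodic grid, exhaustively."""
    for code in range(4096):
        occ = np.array([(code >> k) & 1 for k in range(12)], dtype=bool).reshape(3, 4)
        sets, rep = _report_sets(occ)
        oracle = {frozenset(c) for c in detect_pvl_bruteforce(occ)}
        assert sets == oracle, f"mismatch at code {code}"


def test_detection_equals_bruteforce_oracle_random_large_maps():
    rng = np.random.default_rng(42)
    for _ in range(200):
        ns = rng.integers(4, 12)
        nb = rng.integers(6, 24)
        occ = rng.random((ns, nb)) < rng.uniform(0.2, 0.7)
        sets, rep = _report_sets(occ)
        oracle = {frozenset(c) for c in detect_pvl_bruteforce(occ)}
        assert sets == oracle


# ---------------------------------------------------------------------------
# strain report


@pytest.fixture(scope="module")
def root():
    return build_anatomy(AnatomyParams(calcium_volume=0.0, seed=4))


def test_undeformed_anatomy_reports_zero_strains(root):
    rep = strain_report(root, root.wall_vertices.copy())
    assert rep.average_below_ostia == pytest.approx(0.0, abs=1e-6)
    assert rep.absolute_max == pytest.approx(0.0, abs=1e-5)
    assert rep.max_ncc_rcc == pytest.approx(0.0, abs=1e-5)


def test_uniform_radial_inflation_gives_green_lagrange_strain(root):
    """Stretch 1.1 in-plane: max principal Green-Lagrange strain is
    (lambda^2 - 1)/2 = 10.5% on every element."""
    lam = 1.1
    deformed = root.wall_vertices * [lam, lam, 1.0]
    strains = green_lagrange_max_principal(
        root.wall_vertices, root.wall_faces, deformed
    )
    # hoop stretch is exactly lam everywhere on a surface of revolution
    assert strains.max() == pytest.approx(0.105, rel=1e-6)
    assert np.all(strains > 0.5 * 0.105)
    rep = strain_report(root, deformed)
    assert rep.absolute_max == pytest.approx(10.5, rel=1e-6)


def test_localized_bump_is_caught_by_the_conduction_risk_sector(root):
    def bump(center_deg, width=18.0, amp=1.2):
        v = root.wall_vertices.copy()
        ang = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 360
        dist = np.minimum(np.abs(ang - center_deg), 360 - np.abs(ang - center_deg))
        zsel = np.exp(-((v[:, 2] - 4.0) ** 2) / 18.0)
        w = amp * np.exp(-(dist / width) ** 2) * zsel
        r = np.linalg.norm(v[:, :2], axis=1)
        v[:, 0] += w * v[:, 0] / r
        v[:, 1] += w * v[:, 1] / r
        return v

    rep_nr = strain_report(root, bump(60.0))  # NCC-RCC commissure
    assert rep_nr.max_ncc_rcc == pytest.approx(rep_nr.absolute_max, rel=0.05)
    rep_lcc = strain_report(root, bump(240.0))  # LCC midline
    assert rep_lcc.max_ncc_rcc < 0.5 * rep_lcc.absolute_max


def test_strain_report_invariant_under_rigid_motion(root):
    lam = 1.05
    deformed = root.wall_vertices * [lam, lam, 1.0]
    Q = Rotation.from_rotvec([0.2, -0.1, 0.4]).as_matrix()
    moved = deformed @ Q.T + np.array([3.0, -2.0, 5.0])
    a = green_lagrange_max_principal(root.wall_vertices, root.wall_faces, deformed)
    b = green_lagrange_max_principal(root.wall_vertices, root.wall_faces, moved)
    np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)


def test_mismatched_reference_rejected(root):
    with pytest.raises(ValueError):
        strain_report(root, root.wall_vertices[:-1])
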