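"""Structural-solver oracles: beam bending, membrane stress states,
penalty contact, and the explicit integrator."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tavisim.materials import MaterialCard
from tavisim.solver import (
    AnalyticCylinder,
    AnalyticPlane,
    BeamGroup,
    ContactPair,
    MembraneGroup,
    SimState,
    SolverSettings,
    SurfaceTarget,
    System,
    advance,
    contact_forces,
    stable_time_step,
)

STEEL = MaterialCard("steel", "linear_elastic", 200000.0, 0.3, density=8000.0)
ARTERY = MaterialCard("artery", "linear_elastic", 7.78, 0.45, density=1250.0, thickness=1.9)


def _cantilever(ne=10, L=20.0, w=1.0, t=0.5):
    x0 = np.zeros((ne + 1, 3))
    x0[:, 0] = np.linspace(0, L, ne + 1)
    sysm = System(x0)
    g = BeamGroup(
        np.column_stack([np.arange(ne), np.arange(1, ne + 1)]), x0, STEEL, w, t
    )
    sysm.add_beams(g)
    sysm.fix([0])
    return sysm, g, x0


# ---------------------------------------------------------------------------
# beams


def test_undeformed_frame_has_zero_forces():
    sysm, g, x0 = _cantilever()
    st = SimState.for_nodes(x0)
    _, _, Fi, Fj, Mi, Mj = g.internal_forces(st)
    assert np.abs(Fi).max() < 1e-12
    assert np.abs(Mi).max() < 1e-12


def test_cantilever_tip_deflection_matches_euler_bernoulli():
    """Tip-loaded cantilever vs PL^3 / 3EI at 10-element refinement."""
    ne, L, w, t = 10, 20.0, 1.0, 0.5
    sysm, g, x0 = _cantilever(ne, L, w, t)
    I = w * t**3 / 12.0
    P = 0.5
    sysm.external_forces[ne, 2] = P
    expected = P * L**3 / (3.0 * STEEL.young_modulus * I)
    st = SimState.for_nodes(x0)
    advance(sysm, st, 3.0, SolverSettings(mass_scaling_factor=1e6, damping=12.0))
    assert st.positions[ne, 2] == pytest.approx(expected, rel=0.02)


def test_rigid_rotation_produces_no_internal_forces():
    sysm, g, x0 = _cantilever()
    Q = Rotation.from_rotvec([0.4, -0.7, 1.1]).as_matrix()
    st = SimState.for_nodes(x0 @ Q.T)
    st.rotations[:] = Q
    _, _, Fi, Fj, Mi, Mj = g.internal_forces(st)
    char = STEEL.young_modulus * g.area  # characteristic force scale
    assert np.abs(Fi).max() < 1e-8 * char
    assert np.abs(Mi).max() < 1e-8 * char


def test_beam_forces_are_equal_and_opposite_with_zero_net_moment():
    sysm, g, x0 = _cantilever(ne=6)
    rng = np.random.default_rng(0)
    st = SimState.for_nodes(x0 + rng.normal(scale=0.05, size=x0.shape))
    st.rotations = Rotation.from_rotvec(rng.normal(scale=0.02, size=(7, 3))).as_matrix()
    i, j, Fi, Fj, Mi, Mj = g.internal_forces(st)
    np.testing.assert_allclose(Fi + Fj, 0.0, atol=1e-12)
    # zero net moment about node i, element by element
    r = st.positions[j] - st.positions[i]
    net = np.cross(r, Fj) + Mi + Mj
    assert np.abs(net).max() < 1e-9


def test_zero_length_beam_rejected_at_assembly():
    x0 = np.zeros((2, 3))
    with pytest.raises(ValueError, match="zero-length"):
        BeamGroup(np.array([[0, 1]]), x0, STEEL, 1.0, 1.0)


# ---------------------------------------------------------------------------
# membranes


def _flat_patch(n=4, size=10.0):
    xs = np.linspace(0, size, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            c = (i + 1) * n + j + 1
            d = i * n + j + 1
            faces.append((a, b, c))
            faces.append((a, c, d))
    return verts, np.asarray(faces)


def test_membrane_identity_deformation_zero_force():
    verts, faces = _flat_patch()
    g = MembraneGroup(faces, verts, ARTERY)
    st = SimState.for_nodes(verts)
    _, f1, f2, f3 = g.internal_forces(st)
    assert max(np.abs(f1).max(), np.abs(f2).max(), np.abs(f3).max()) < 1e-12


def test_equibiaxial_stretch_matches_plane_stress_resultant():
    """Equibiaxial Green-Lagrange strain E under plane stress gives
    S = E_mod * E / (1 - nu); boundary nodal forces must integrate to the
    corresponding edge traction."""
    verts, faces = _flat_patch(n=5, size=10.0)
    card = ARTERY
    g = MembraneGroup(faces, verts, card)
    lam = 1.02
    st = SimState.for_nodes(verts * [lam, lam, 1.0])
    E2, _ = g.strain_tensors(st.positions)
    E_gl = 0.5 * (lam**2 - 1.0)
    np.testing.assert_allclose(E2[:, 0, 0], E_gl, rtol=1e-9)
    np.testing.assert_allclose(E2[:, 1, 1], E_gl, rtol=1e-9)
    S_expected = card.young_modulus * E_gl / (1.0 - card.poisson_ratio)
    # edge force per unit reference length = lam * S * t (first Piola)
    _, f1, f2, f3 = g.internal_forces(st)
    forces = np.zeros_like(verts)
    np.add.at(forces, faces[:, 0], f1)
    np.add.at(forces, faces[:, 1], f2)
    np.add.at(forces, faces[:, 2], f3)
    edge = np.where(np.isclose(verts[:, 0], 10.0))[0]
    total = -forces[edge, 0].sum()  # reaction pulling the edge inward
    expected = lam * S_expected * card.thickness * 10.0
    assert total == pytest.approx(expected, rel=0.01)


def test_pressurized_tube_converges_to_laplace_hoop_stress():
    """Internal pressure p on a thin tube: hoop stress -> p r / t with
    refinement."""
    errs = []
    for n_theta, n_z in [(16, 5), (32, 9)]:
        r0, length, t, p = 10.0, 20.0, 0.5, 0.004
        card = MaterialCard("soft", "linear_elastic", 7.78, 0.45,
                            density=1250.0, thickness=t)
        th = 2 * np.pi * np.arange(n_theta) / n_theta
        zs = np.linspace(0, length, n_z)
        verts = np.array([[r0 * np.cos(a), r0 * np.sin(a), z] for z in zs for a in th])
        faces = []
        for j in range(n_z - 1):
            for i in range(n_theta):
                i2 = (i + 1) % n_theta
                a = j * n_theta + i
                b = j * n_theta + i2
                c = (j + 1) * n_theta + i2
                d = (j + 1) * n_theta + i
                faces.append((a, b, c))
                faces.append((a, c, d))
        faces = np.asarray(faces)
        sysm = System(verts)
        g = MembraneGroup(faces, verts, card)
        sysm.add_membrane(g)
        sysm.add_pressure(g, p)
        ends = np.concatenate([np.arange(n_theta), np.arange((n_z - 1) * n_theta, n_z * n_theta)])
        sysm.fix(ends, dofs=[2])
        st = SimState.for_nodes(verts)
        advance(sysm, st, 2.5, SolverSettings(mass_scaling_factor=1e6, damping=10.0))
        mid = np.abs(st.positions[:, 2] - length / 2) < length / (n_z - 1)
        r = np.linalg.norm(st.positions[mid, :2], axis=1).mean()
        # measured hoop stress from the strain state at mid-tube
        E2, _ = g.strain_tensors(st.positions)
        S = g._stress(E2)
        hoop = S[:, 0, 0].max()
        expected = p * r / t
        errs.append(abs(hoop - expected) / expected)
    assert errs[1] < errs[0]
    assert errs[1] < 0.05


def test_degenerate_membrane_triangle_flagged():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
    with pytest.raises(ValueError, match="degenerate"):
        MembraneGroup(np.array([[0, 1, 2]]), verts, ARTERY)


# ---------------------------------------------------------------------------
# contact


def test_separated_follower_feels_no_force():
    x0 = np.array([[5.0, 0.0, 0.0]])
    st = SimState.for_nodes(x0)
    pair = ContactPair(np.array([0]), AnalyticCylinder(8.0, contain=True),
                       penalty_stiffness=10.0, gap_offset=0.5)
    f = np.zeros((1, 3))
    pen = contact_forces(st, pair, f)
    assert pen == 0.0
    assert np.all(f == 0.0)


def test_cylinder_penetration_force_is_linear_in_depth():
    delta = 0.3
    x0 = np.array([[8.0 - 0.5 + delta, 0.0, 0.0]])  # past offset by delta
    st = SimState.for_nodes(x0)
    pair = ContactPair(np.array([0]), AnalyticCylinder(8.0, contain=True),
                       penalty_stiffness=10.0, gap_offset=0.5)
    f = np.zeros((1, 3))
    pen = contact_forces(st, pair, f)
    assert pen == pytest.approx(delta)
    np.testing.assert_allclose(f[0], [-10.0 * delta, 0.0, 0.0])


def test_loaded_node_on_plane_settles_at_load_over_stiffness():
    x0 = np.array([[0.0, 0.0, 0.05], [3.0, 0.0, 0.05]])
    sysm = System(x0)
    g = BeamGroup(np.array([[0, 1]]), x0, STEEL, 1.0, 1.0)
    sysm.add_beams(g)
    k = 50.0
    sysm.add_contact(ContactPair(np.array([0, 1]),
                                 AnalyticPlane(np.zeros(3), np.array([0.0, 0, 1.0])),
                                 penalty_stiffness=k))
    P = 2.0
    sysm.external_forces[:, 2] = -P
    st = SimState.for_nodes(x0)
    advance(sysm, st, 1.5, SolverSettings(mass_scaling_factor=1e5, damping=20.0))
    assert st.positions[0, 2] == pytest.approx(-P / k, rel=0.01)


def test_deformable_target_reactions_obey_newtons_third_law():
    verts, faces = _flat_patch(n=4, size=6.0)
    extra = np.array([[3.0, 3.0, 0.2]])  # follower above the sheet
    x0 = np.vstack([verts, extra])
    st = SimState.for_nodes(x0)
    st.positions[-1, 2] = -0.1  # push through the surface
    tgt = SurfaceTarget(faces, side=1.0)
    pair = ContactPair(np.array([len(verts)]), tgt,
                       penalty_stiffness=30.0, gap_offset=0.05)
    f = np.zeros_like(x0)
    pen = contact_forces(st, pair, f)
    assert pen > 0
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)


def test_friction_force_capped_by_coulomb_limit():
    delta = 0.2
    x0 = np.array([[0.0, 0.0, -delta]])
    st = SimState.for_nodes(x0)
    st.velocities[0] = [50.0, 0.0, 0.0]  # fast tangential sliding
    mu, k = 0.3, 10.0
    pair = ContactPair(np.array([0]), AnalyticPlane(np.zeros(3), np.array([0.0, 0, 1.0])),
                       penalty_stiffness=k, friction_coefficient=mu)
    f = np.zeros((1, 3))
    contact_forces(st, pair, f)
    fn = k * delta
    assert f[0, 2] == pytest.approx(fn)
    assert abs(f[0, 0]) == pytest.approx(mu * fn, rel=1e-9)


# ---------------------------------------------------------------------------
# time stepping


def test_stable_step_scales_with_sqrt_of_mass_scaling():
    sysm, g, x0 = _cantilever()
    s1 = SolverSettings(mass_scaling_factor=1.0)
    s2 = SolverSettings(mass_scaling_factor=2.0)
    assert stable_time_step(sysm, s2) == pytest.approx(
        np.sqrt(2.0) * stable_time_step(sysm, s1)
    )


def test_stable_step_tracks_element_length_over_wave_speed():
    sysm, g, x0 = _cantilever(ne=10, L=20.0)
    settings = SolverSettings(time_step_safety=0.8, mass_scaling_factor=1.0)
    c = np.sqrt(STEEL.young_modulus / (STEEL.density * 1e-12))
    expected = 0.8 * 0.5 * (2.0 / c)  # element length 2 mm, halved margin
    assert stable_time_step(sysm, settings) == pytest.approx(expected)
    # refining (halving element lengths) halves the step
    sysm2, _, _ = _cantilever(ne=20, L=20.0)
    assert stable_time_step(sysm2, settings) == pytest.approx(expected / 2.0)


def test_empty_model_rejected():
    with pytest.raises(ValueError, match="empty"):
        stable_time_step(System(np.zeros((3, 3))), SolverSettings())


def test_zero_forces_zero_velocities_state_unchanged():
    sysm, g, x0 = _cantilever()
    st = SimState.for_nodes(x0)
    advance(sysm, st, 0.01, SolverSettings(mass_scaling_factor=1e4, damping=5.0))
    np.testing.assert_allclose(st.positions, x0, atol=1e-12)


def test_damped_oscillator_matches_analytic_solution():
    """A single axial spring-mass with mass-proportional damping vs the
    closed-form damped cosine over ten periods."""
    L, A = 10.0, 1.0
    card = MaterialCard("bar", "linear_elastic", 1000.0, 0.0, density=8000.0)
    x0 = np.array([[0.0, 0, 0], [L, 0, 0]])
    sysm = System(x0)
    g = BeamGroup(np.array([[0, 1]]), x0, card, 1.0, 1.0)
    sysm.add_beams(g)
    sysm.fix([0])
    sysm.fix([1], dofs=[1, 2])
    settings = SolverSettings(mass_scaling_factor=1.0, damping=0.0)
    sysm.compute_masses(settings)
    k = card.young_modulus * A / L
    m = sysm._mass[1]
    om = np.sqrt(k / m)
    c = 0.05 * om  # light mass-proportional damping
    settings = SolverSettings(mass_scaling_factor=1.0, damping=c)
    u0 = 0.01
    st = SimState.for_nodes(x0)
    st.positions[1, 0] += u0
    T = 10 * 2 * np.pi / om
    dt = stable_time_step(sysm, settings) * 0.2
    advance(sysm, st, T, settings, dt=dt)
    om_d = om * np.sqrt(1.0 - (c / (2 * om)) ** 2)
    expected = u0 * np.exp(-0.5 * c * T) * (
        np.cos(om_d * T) + 0.5 * c / om_d * np.sin(om_d * T)
    )
    u = st.positions[1, 0] - L
    assert u == pytest.approx(expected, abs=0.01 * u0)
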