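"""Explicit quasi-static structural solver.

Central-difference time integration with mass scaling and mass-proportional
damping, advanced slowly enough that inertial effects are negligible; the
quasi-static hypothesis is checked by requiring the kinetic-to-internal
energy ratio to fall below a configurable gate (default 5%) at the end of
every protocol stage.

Element technology:

* two-node corotational beams (frames): axial stretch and Hermite bending
  curvatures are evaluated in an element-attached frame, fiber strains over a
  cross-section integration grid feed the 1-D constitutive updates
  (elastic / elastoplastic / superelastic), and the integrated axial force and
  end moments are pushed back to the nodes with equal-and-opposite forces and
  zero net moment; torsion is linear elastic;
* constant-strain-triangle membranes (wall, leaflets, balloon, calcium
  patches): plane-stress St. Venant-Kirchhoff from the surface deformation
  gradient, with an optional von Mises radial-return plastic correction for
  calcific deposits;
* penalty contact of follower nodes against deformable triangulated surfaces
  or rigid analytic surfaces (cylinder, plane), with a clearance offset
  absorbing strut radius and shell half-thickness, and optional Coulomb-capped
  tangential friction.

Units: mm / N / MPa / s; nodal masses in tonnes (densities on the cards are
kg/m^3 and are converted here, 1 kg/m^3 = 1e-12 t/mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .materials import (
    FiberState,
    MaterialCard,
    SuperelasticCard,
    superelastic_update,
)

__all__ = [
    "SolverSettings",
    "SimState",
    "BeamGroup",
    "MembraneGroup",
    "ContactPair",
    "AnalyticCylinder",
    "AnalyticPlane",
    "SurfaceTarget",
    "System",
    "stable_time_step",
    "advance",
    "run_stage",
    "EnergyBlowupError",
]

_DENS = 1.0e-12  # kg/m^3 -> t/mm^3
_GAUSS = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])


class EnergyBlowupError(RuntimeError):
    """Raised when the kinetic energy grows without bound (unstable run)."""


@dataclass
class SolverSettings:
    """Numerical controls of the explicit scheme.

    ``mass_scaling_factor`` multiplies all nodal masses (the stable step
    grows with its square root); ``damping`` is the mass-proportional
    damping coefficient in 1/s; ``quasi_static_ke_ratio_max`` is the
    kinetic/internal energy gate every stage must pass.
    """

    time_step_safety: float = 0.8
    mass_scaling_factor: float = 1.0
    damping: float = 2000.0
    quasi_static_ke_ratio_max: float = 0.05
    max_steps: int = 2_000_000
    contact_search_every: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.time_step_safety <= 1.0):
            raise ValueError("time_step_safety must lie in (0, 1]")
        if self.mass_scaling_factor < 1.0:
            raise ValueError("mass_scaling_factor must be >= 1")
        if self.damping < 0.0 or self.max_steps <= 0:
            raise ValueError("damping and max_steps must be positive")
        if not (0.0 < self.quasi_static_ke_ratio_max < 1.0):
            raise ValueError("quasi_static_ke_ratio_max must lie in (0, 1)")


@dataclass
class SimState:
    """Nodal kinematics + accumulated energies of an assembled system."""

    positions: np.ndarray  # (n, 3)
    velocities: np.ndarray  # (n, 3)
    rotations: np.ndarray  # (n, 3, 3) — identity for membrane-only nodes
    angular_velocities: np.ndarray  # (n, 3)
    time: float = 0.0
    internal_energy: float = 0.0
    kinetic_energy: float = 0.0

    @classmethod
    def for_nodes(cls, x0: np.ndarray) -> "SimState":
        n = x0.shape[0]
        rot = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        return cls(x0.copy(), np.zeros((n, 3)), rot, np.zeros((n, 3)))

    @property
    def ke_ie_ratio(self) -> float:
        return self.kinetic_energy / max(self.internal_energy, 1e-12)

    def copy(self) -> "SimState":
        s = SimState(
            self.positions.copy(),
            self.velocities.copy(),
            self.rotations.copy(),
            self.angular_velocities.copy(),
            self.time,
            self.internal_energy,
            self.kinetic_energy,
        )
        return s


# ---------------------------------------------------------------------------
# rotation helpers (vectorised)


def _rodrigues(w: np.ndarray) -> np.ndarray:
    """exp of skew(w) for an (n,3) array of rotation vectors."""
    theta = np.linalg.norm(w, axis=1, keepdims=True)
    small = theta[:, 0] < 1e-12
    axis = np.where(theta > 1e-12, w / np.maximum(theta, 1e-30), 0.0)
    c = np.cos(theta)[:, :, None]
    s = np.sin(theta)[:, :, None]
    K = np.zeros((w.shape[0], 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    eye = np.broadcast_to(np.eye(3), K.shape)
    R = eye * c + s * K + (1.0 - c) * np.einsum("nij,njk->nik", K, K + eye * 0)
    R[:, 0, 0] += 0.0
    aa = np.einsum("ni,nj->nij", axis, axis)
    R = eye * c + s * K + (1.0 - c) * aa
    R[small] = np.eye(3)
    return R


def _small_rotvec(R: np.ndarray) -> np.ndarray:
    """Rotation vector of near-identity rotations (arcsin-corrected)."""
    w = 0.5 * np.stack(
        [R[:, 2, 1] - R[:, 1, 2], R[:, 0, 2] - R[:, 2, 0], R[:, 1, 0] - R[:, 0, 1]],
        axis=1,
    )
    s = np.linalg.norm(w, axis=1)
    scale = np.ones_like(s)
    m = (s > 1e-9) & (s < 1.0)
    scale[m] = np.arcsin(s[m]) / s[m]
    return w * scale[:, None]


# ---------------------------------------------------------------------------
# beam group


def _fiber_grid(width: float, thickness: float, n: int = 2):
    """Gauss integration grid over a rectangular w x t cross-section."""
    gp, gw = np.polynomial.legendre.leggauss(n)
    y = 0.5 * width * gp
    z = 0.5 * thickness * gp
    Y, Z = np.meshgrid(y, z, indexing="ij")
    WY, WZ = np.meshgrid(gw * width / 2.0, gw * thickness / 2.0, indexing="ij")
    return Y.ravel(), Z.ravel(), (WY * WZ).ravel()


class BeamGroup:
    """A set of beam elements sharing one material card and cross-section."""

    def __init__(
        self,
        conn: np.ndarray,
        x0: np.ndarray,
        material,
        width: float,
        thickness: float,
        fiber_order: int = 2,
        name: str = "beams",
    ):
        self.name = name
        self.conn = np.asarray(conn, dtype=np.int64)
        self.material = material
        self.width = float(width)
        self.thickness = float(thickness)
        xi = x0[self.conn[:, 0]]
        xj = x0[self.conn[:, 1]]
        d = xj - xi
        self.L0 = np.linalg.norm(d, axis=1)
        if np.any(self.L0 < 1e-9):
            bad = np.where(self.L0 < 1e-9)[0]
            raise ValueError(f"zero-length beam elements at indices {bad.tolist()}")
        t0 = d / self.L0[:, None]
        # reference normal: any vector not parallel to the axis
        ref = np.where(np.abs(t0[:, 2:3]) < 0.9, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        n0 = np.cross(ref, t0)
        n0 /= np.linalg.norm(n0, axis=1, keepdims=True)
        b0 = np.cross(t0, n0)
        self.E0 = np.stack([t0, n0, b0], axis=2)  # columns = local axes

        self.fy, self.fz, self.fw = _fiber_grid(width, thickness, fiber_order)
        m, nf = len(self.conn), len(self.fy)
        self.state = FiberState(m * 2 * nf)
        self._shape = (m, 2, nf)

        self.area = self.width * self.thickness
        # torsion constant of a rectangle (approximate closed form)
        a, b = max(width, thickness) / 2.0, min(width, thickness) / 2.0
        self.J = a * b**3 * (16.0 / 3.0 - 3.36 * b / a * (1.0 - b**4 / (12.0 * a**4)))
        self.I_y = width * thickness**3 / 12.0
        self.I_z = thickness * width**3 / 12.0

    @property
    def young(self) -> float:
        if isinstance(self.material, SuperelasticCard):
            return self.material.austenite_modulus
        return self.material.young_modulus

    @property
    def density(self) -> float:
        return self.material.density * _DENS

    @property
    def shear(self) -> float:
        return self.material.shear_modulus

    def internal_forces(self, state: SimState):
        """Forces and moments the elements exert on the nodes."""
        pos, R = state.positions, state.rotations
        i, j = self.conn[:, 0], self.conn[:, 1]
        d = pos[j] - pos[i]
        L = np.linalg.norm(d, axis=1)
        e1 = d / L[:, None]

        Ri, Rj = R[i], R[j]
        n_ref = self.E0[:, :, 1]
        ni = np.einsum("nij,nj->ni", Ri, n_ref)
        nj = np.einsum("nij,nj->ni", Rj, n_ref)
        navg = ni + nj
        navg -= np.einsum("ni,ni->n", navg, e1)[:, None] * e1
        nrm = np.linalg.norm(navg, axis=1, keepdims=True)
        # fall back to any perpendicular if degenerate
        bad = nrm[:, 0] < 1e-8
        if np.any(bad):
            alt = np.cross(e1[bad], np.array([0.0, 0.0, 1.0]))
            alt_n = np.linalg.norm(alt, axis=1, keepdims=True)
            alt2 = np.cross(e1[bad], np.array([1.0, 0.0, 0.0]))
            alt = np.where(alt_n > 1e-8, alt, alt2)
            navg[bad] = alt
            nrm = np.linalg.norm(navg, axis=1, keepdims=True)
        e2 = navg / nrm
        e3 = np.cross(e1, e2)
        T = np.stack([e1, e2, e3], axis=2)

        # local nodal rotations relative to the element frame
        Rl_i = np.einsum("nji,njk,nkl->nil", T, Ri, self.E0)
        Rl_j = np.einsum("nji,njk,nkl->nil", T, Rj, self.E0)
        th_i = _small_rotvec(Rl_i)
        th_j = _small_rotvec(Rl_j)

        eps0 = (L - self.L0) / self.L0

        m, _, nf = self._shape
        # curvatures at the two Gauss points
        g = _GAUSS
        c1 = 6.0 * g - 4.0
        c2 = 6.0 * g - 2.0
        vpp = (th_i[:, 2:3] * c1[None, :] + th_j[:, 2:3] * c2[None, :]) / self.L0[:, None]
        wpp = (-th_i[:, 1:2] * c1[None, :] - th_j[:, 1:2] * c2[None, :]) / self.L0[:, None]

        eps = (
            eps0[:, None, None]
            - self.fy[None, None, :] * vpp[:, :, None]
            - self.fz[None, None, :] * wpp[:, :, None]
        ).reshape(-1)

        mat = self.material
        if isinstance(mat, SuperelasticCard):
            sig, _ = superelastic_update(eps, self.state, mat)
        elif mat.model == "elastoplastic":
            d_eps = eps - self.state.strain
            sig, _ = elastoplastic_vec(d_eps, self.state, mat)
        else:
            sig = mat.young_modulus * eps
            self.state.stress = sig
            self.state.strain = eps

        sig3 = sig.reshape(self._shape)
        N_g = np.einsum("mgf,f->mg", sig3, self.fw)
        Mz_g = np.einsum("mgf,f->mg", sig3, -self.fw * self.fy)
        My_g = np.einsum("mgf,f->mg", sig3, -self.fw * self.fz)

        f_u = 0.5 * (N_g[:, 0] + N_g[:, 1])
        m_th = np.zeros((m, 2, 3))  # dU/dtheta at node i (index 0) and j (1)
        m_th[:, 0, 2] = 0.5 * (Mz_g[:, 0] * c1[0] + Mz_g[:, 1] * c1[1])
        m_th[:, 1, 2] = 0.5 * (Mz_g[:, 0] * c2[0] + Mz_g[:, 1] * c2[1])
        m_th[:, 0, 1] = -0.5 * (My_g[:, 0] * c1[0] + My_g[:, 1] * c1[1])
        m_th[:, 1, 1] = -0.5 * (My_g[:, 0] * c2[0] + My_g[:, 1] * c2[1])
        phi = th_j[:, 0] - th_i[:, 0]
        GJ_L = self.shear * self.J / self.L0
        m_th[:, 0, 0] = -GJ_L * phi
        m_th[:, 1, 0] = GJ_L * phi

        # nodal moments exerted by the element (local, then global)
        mu_i = -m_th[:, 0, :]
        mu_j = -m_th[:, 1, :]
        M_i = np.einsum("nij,nj->ni", T, mu_i)
        M_j = np.einsum("nij,nj->ni", T, mu_j)

        # forces: axial pull plus shear equilibrating the end moments
        F_j = -f_u[:, None] * e1 + np.cross(e1, M_i + M_j) / L[:, None]
        F_i = -F_j
        return i, j, F_i, F_j, M_i, M_j

    def max_fiber_strain(self) -> float:
        return float(np.max(np.abs(self.state.strain))) if self.state.strain.size else 0.0

    def strain_energy(self) -> float:
        """Recoverable (elastic) strain energy estimate, mJ."""
        sig = self.state.stress.reshape(self._shape)
        E = self.young
        per_fiber = sig**2 / (2.0 * E)  # energy density per fiber
        per_gauss = np.einsum("mgf,f->mg", per_fiber, self.fw)
        return float(np.einsum("mg,m->", per_gauss, self.L0 / 2.0))


def elastoplastic_vec(d_eps, state: FiberState, card: MaterialCard):
    """In-place vectorised radial-return (module-level for reuse)."""
    from .materials import elastoplastic_update

    return elastoplastic_update(d_eps, state, card)


# ---------------------------------------------------------------------------
# membrane group


class MembraneGroup:
    """Constant-strain-triangle plane-stress membranes."""

    def __init__(self, tris: np.ndarray, x0: np.ndarray, card: MaterialCard, name="membrane", thickness: float | None = None):
        self.name = name
        self.tris = np.asarray(tris, dtype=np.int64)
        self.card = card
        self.thickness = float(thickness if thickness is not None else (card.thickness or 1.0))
        a = x0[self.tris[:, 0]]
        b = x0[self.tris[:, 1]]
        c = x0[self.tris[:, 2]]
        d1, d2 = b - a, c - a
        n = np.cross(d1, d2)
        A2 = np.linalg.norm(n, axis=1)
        if np.any(A2 < 1e-12):
            bad = np.where(A2 < 1e-12)[0]
            raise ValueError(f"degenerate membrane triangles at {bad.tolist()}")
        self.A0 = 0.5 * A2
        emax = np.maximum(
            np.linalg.norm(d1, axis=1),
            np.maximum(np.linalg.norm(d2, axis=1), np.linalg.norm(d2 - d1, axis=1)),
        )
        self.min_altitude = 2.0 * self.A0 / emax  # shortest triangle height
        # local 2-D reference basis per triangle
        t1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
        nz = n / A2[:, None]
        t2 = np.cross(nz, t1)
        # reference edge matrix and inverse
        Dm = np.zeros((len(self.tris), 2, 2))
        Dm[:, 0, 0] = np.einsum("ni,ni->n", d1, t1)
        Dm[:, 1, 0] = np.einsum("ni,ni->n", d1, t2)
        Dm[:, 0, 1] = np.einsum("ni,ni->n", d2, t1)
        Dm[:, 1, 1] = np.einsum("ni,ni->n", d2, t2)
        det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
        inv = np.empty_like(Dm)
        inv[:, 0, 0] = Dm[:, 1, 1] / det
        inv[:, 0, 1] = -Dm[:, 0, 1] / det
        inv[:, 1, 0] = -Dm[:, 1, 0] / det
        inv[:, 1, 1] = Dm[:, 0, 0] / det
        self.Dm_inv = inv
        self.plastic = card.model == "elastoplastic"
        self.Ep = np.zeros((len(self.tris), 2, 2)) if self.plastic else None
        # tension-field (wrinkling) approximation: negative principal
        # stresses are dropped; used for the slack/deflated balloon
        self.tension_only = False
        # selective extra mass scaling for this group (stable-step control)
        self.mass_boost = 1.0

    @property
    def density(self) -> float:
        return self.card.density * _DENS

    def _stress(self, E2):
        """Plane-stress St. Venant-Kirchhoff 2nd Piola stress, with optional
        von Mises radial-return correction for elastoplastic cards."""
        E, nu = self.card.young_modulus, self.card.poisson_ratio
        fac = E / (1.0 - nu * nu)
        Ee = E2 - self.Ep if self.plastic else E2
        tr = Ee[:, 0, 0] + Ee[:, 1, 1]
        S = fac * ((1.0 - nu) * Ee + nu * tr[:, None, None] * np.broadcast_to(np.eye(2), Ee.shape))
        if self.tension_only:
            # principal decomposition of S (coaxial with Ee for isotropy)
            s11, s22, s12 = S[:, 0, 0], S[:, 1, 1], S[:, 0, 1]
            mean = 0.5 * (s11 + s22)
            rad = np.sqrt(np.maximum(0.25 * (s11 - s22) ** 2 + s12**2, 0.0))
            p1, p2 = mean + rad, mean - rad
            phi = 0.5 * np.arctan2(2.0 * s12, np.where(s11 == s22, 1e-30, s11 - s22))
            cp, sp = np.cos(phi), np.sin(phi)
            # wrinkled (one negative) -> uniaxial tension along the major axis
            one_neg = (p2 < 0.0) & (p1 > 0.0)
            # taut uniaxial stress from the major principal strain alone
            e11, e22, e12 = Ee[:, 0, 0], Ee[:, 1, 1], Ee[:, 0, 1]
            em = 0.5 * (e11 + e22)
            er = np.sqrt(np.maximum(0.25 * (e11 - e22) ** 2 + e12**2, 0.0))
            p1u = E * (em + er)
            p1_eff = np.where(one_neg, np.maximum(p1u, 0.0), p1)
            p2_eff = np.where(one_neg, 0.0, p2)
            slack = p1 <= 0.0
            p1_eff = np.where(slack, 0.0, p1_eff)
            p2_eff = np.where(slack, 0.0, p2_eff)
            S = np.empty_like(S)
            S[:, 0, 0] = p1_eff * cp * cp + p2_eff * sp * sp
            S[:, 1, 1] = p1_eff * sp * sp + p2_eff * cp * cp
            S[:, 0, 1] = S[:, 1, 0] = (p1_eff - p2_eff) * cp * sp
            return S
        if self.plastic:
            sy = self.card.yield_stress
            s11, s22, s12 = S[:, 0, 0], S[:, 1, 1], S[:, 0, 1]
            svm = np.sqrt(np.maximum(s11**2 + s22**2 - s11 * s22 + 3.0 * s12**2, 1e-30))
            over = svm > sy
            if np.any(over):
                scale = np.where(over, sy / svm, 1.0)
                # plastic strain increment from the stress brought back
                dS = S * (1.0 - scale[:, None, None])
                # approximate associated flow: dEp = C^-1 : dS (elastic compliance)
                dEp = np.empty_like(dS)
                dEp[:, 0, 0] = (dS[:, 0, 0] - nu * dS[:, 1, 1]) / E
                dEp[:, 1, 1] = (dS[:, 1, 1] - nu * dS[:, 0, 0]) / E
                dEp[:, 0, 1] = dS[:, 0, 1] * (1.0 + nu) / E
                dEp[:, 1, 0] = dEp[:, 0, 1]
                self.Ep = self.Ep + dEp
                S = S * scale[:, None, None]
        return S

    def strain_tensors(self, positions: np.ndarray):
        """In-plane Green-Lagrange strain tensor per triangle."""
        a = positions[self.tris[:, 0]]
        b = positions[self.tris[:, 1]]
        c = positions[self.tris[:, 2]]
        D = np.stack([b - a, c - a], axis=2)  # (m, 3, 2)
        F = np.einsum("nik,nkj->nij", D, self.Dm_inv)  # (m, 3, 2)
        C = np.einsum("nki,nkj->nij", F, F)
        E2 = 0.5 * (C - np.eye(2))
        return E2, F

    def internal_forces(self, state: SimState):
        E2, F = self.strain_tensors(state.positions)
        S = self._stress(E2)
        P = np.einsum("nik,nkj->nij", F, S)  # (m, 3, 2) first Piola
        tA = self.thickness * self.A0
        # shape gradients: rows of Dm_inv
        g2 = self.Dm_inv[:, 0, :]  # dN2/dX (2,)
        g3 = self.Dm_inv[:, 1, :]
        f2 = -tA[:, None] * np.einsum("nij,nj->ni", P, g2)
        f3 = -tA[:, None] * np.einsum("nij,nj->ni", P, g3)
        f1 = -(f2 + f3)
        return self.tris, f1, f2, f3

    def strain_energy(self, positions: np.ndarray) -> float:
        """Recoverable strain energy, mJ (no state side effects)."""
        E2, _ = self.strain_tensors(positions)
        E, nu = self.card.young_modulus, self.card.poisson_ratio
        fac = E / (1.0 - nu * nu)
        if self.tension_only:
            S = self._stress(E2)  # no mutation on the tension-only path
            dens = 0.5 * np.einsum("nij,nij->n", S, E2)
            dens = np.maximum(dens, 0.0)
        else:
            Ee = E2 - self.Ep if self.plastic else E2
            tr = Ee[:, 0, 0] + Ee[:, 1, 1]
            S = fac * ((1.0 - nu) * Ee + nu * tr[:, None, None] * np.broadcast_to(np.eye(2), Ee.shape))
            if self.plastic:
                sy = self.card.yield_stress
                s11, s22, s12 = S[:, 0, 0], S[:, 1, 1], S[:, 0, 1]
                svm = np.sqrt(np.maximum(s11**2 + s22**2 - s11 * s22 + 3 * s12**2, 1e-30))
                S = S * np.minimum(1.0, sy / svm)[:, None, None]
            dens = 0.5 * np.einsum("nij,nij->n", S, Ee)
        return float(np.sum(dens * self.thickness * self.A0))

    def normals_areas(self, positions: np.ndarray):
        a = positions[self.tris[:, 0]]
        b = positions[self.tris[:, 1]]
        c = positions[self.tris[:, 2]]
        n = np.cross(b - a, c - a)
        A2 = np.linalg.norm(n, axis=1)
        return n / np.maximum(A2[:, None], 1e-30), 0.5 * A2


# ---------------------------------------------------------------------------
# contact


@dataclass
class AnalyticCylinder:
    """Rigid cylinder, axis along z through (cx, cy).  ``contain=True``
    keeps followers inside (crimper / sheath / rigid test tube); otherwise it
    keeps them outside (expanding mandrel)."""

    radius: float
    contain: bool = True
    center: tuple = (0.0, 0.0)
    z_min: float = -np.inf
    z_max: float = np.inf

    def gaps(self, x):
        dx = x[:, 0] - self.center[0]
        dy = x[:, 1] - self.center[1]
        r = np.sqrt(dx * dx + dy * dy)
        inside_z = (x[:, 2] >= self.z_min) & (x[:, 2] <= self.z_max)
        nr = np.zeros_like(x)
        rr = np.maximum(r, 1e-12)
        nr[:, 0] = dx / rr
        nr[:, 1] = dy / rr
        if self.contain:
            g = self.radius - r  # positive when clear
            normal = -nr  # pushes follower inward
        else:
            g = r - self.radius
            normal = nr
        g = np.where(inside_z, g, np.inf)
        return g, normal


@dataclass
class AnalyticPlane:
    """Rigid half-space: followers are kept on the ``normal`` side of
    ``point``."""

    point: np.ndarray
    normal: np.ndarray

    def gaps(self, x):
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        g = (x - np.asarray(self.point)) @ n
        return g, np.broadcast_to(n, x.shape)


class SurfaceTarget:
    """Deformable triangulated contact target whose vertices are system
    nodes; reaction forces are distributed back to the triangle nodes."""

    def __init__(self, tris: np.ndarray, side: float = 1.0):
        self.tris = np.asarray(tris, dtype=np.int64)
        self.side = float(side)  # followers stay on side*normal side
        self._tree = None
        self._cand = None  # cached candidate triangles between searches

    def build_tree(self, positions):
        pts = positions[self.tris]
        cent = pts.mean(axis=1)
        self._tree = cKDTree(cent)
        self.tri_radius = float(np.linalg.norm(pts - cent[:, None, :], axis=2).max())
        self._cand = None

    def closest(self, x, positions, k=8):
        if self._tree is None:
            self.build_tree(positions)
        k = min(k, len(self.tris))
        if self._cand is None or self._cand.shape[0] != len(x):
            _, idx = self._tree.query(x, k=k)
            if k == 1:
                idx = idx[:, None]
            self._cand = idx
        idx = self._cand
        tri_pts = positions[self.tris[idx]]  # (nf, k, 3, 3)
        p, bary = _closest_point_triangles(x[:, None, :], tri_pts)
        d = np.linalg.norm(p - x[:, None, :], axis=2)
        best = np.argmin(d, axis=1)
        rows = np.arange(len(x))
        return idx[rows, best], p[rows, best], bary[rows, best]


def _closest_point_triangles(q, tri):
    """Closest point on each triangle to each query point.

    q: (n, 1, 3) broadcastable; tri: (n, k, 3, 3).  Returns points (n, k, 3)
    and barycentric coordinates (n, k, 3).  Vectorised version of the
    standard region-classification algorithm.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = q - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = q - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = q - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom = np.where(np.abs(vb + vc + va) > 0, va + vb + vc, 1.0)
    v = vb / np.where(denom == 0, 1.0, denom)
    w = vc / np.where(denom == 0, 1.0, denom)

    # start from interior solution, then overwrite edge/vertex regions
    v_in = np.clip(v, 0.0, 1.0)
    w_in = np.clip(w, 0.0, 1.0)
    u_in = 1.0 - v_in - w_in
    bary = np.stack([u_in, v_in, w_in], axis=-1)

    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    # edge AB
    t_ab = np.where(np.abs(d1 - d3) > 1e-30, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    # edge AC
    t_ac = np.where(np.abs(d2 - d6) > 1e-30, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    # edge BC
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    t_bc = np.where(np.abs(den) > 1e-30, num / np.where(den == 0, 1.0, den), 0.0)
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    bary = np.where(
        m_bc[..., None],
        np.stack([np.zeros_like(t_bc), 1.0 - t_bc, t_bc], axis=-1),
        bary,
    )
    bary = np.where(
        m_ac[..., None],
        np.stack([1.0 - t_ac, np.zeros_like(t_ac), t_ac], axis=-1),
        bary,
    )
    bary = np.where(
        m_ab[..., None],
        np.stack([1.0 - t_ab, t_ab, np.zeros_like(t_ab)], axis=-1),
        bary,
    )
    one = np.ones_like(d1)
    zero = np.zeros_like(d1)
    bary = np.where(m_c[..., None], np.stack([zero, zero, one], axis=-1), bary)
    bary = np.where(m_b[..., None], np.stack([zero, one, zero], axis=-1), bary)
    bary = np.where(m_a[..., None], np.stack([one, zero, zero], axis=-1), bary)
    bary = np.clip(bary, 0.0, 1.0)
    bary = bary / np.maximum(bary.sum(axis=-1, keepdims=True), 1e-30)
    p = (
        bary[..., 0:1] * a + bary[..., 1:2] * b + bary[..., 2:3] * c
    )
    return p, bary


@dataclass
class ContactPair:
    """Penalty contact between a follower node set and a target surface."""

    followers: np.ndarray
    target: object  # AnalyticCylinder | AnalyticPlane | SurfaceTarget
    penalty_stiffness: float = 20.0  # N/mm per follower node
    friction_coefficient: float = 0.0
    gap_offset: float = 0.0  # mm; strut radius + shell half-thickness
    capture_band: float = 1.5  # mm; deeper apparent penetration = far side
    name: str = "contact"

    def __post_init__(self) -> None:
        self.followers = np.asarray(self.followers, dtype=np.int64)
        if self.penalty_stiffness <= 0:
            raise ValueError("penalty_stiffness must be positive")
        if self.friction_coefficient < 0:
            raise ValueError("friction_coefficient must be >= 0")


def contact_forces(state: SimState, pair: ContactPair, forces: np.ndarray, search=True):
    """Accumulate penalty forces of one pair into ``forces``.

    Returns the maximum penetration depth (0 when fully separated).
    """
    tgt = pair.target
    if isinstance(tgt, SurfaceTarget):
        if search or tgt._tree is None or not hasattr(pair, "_active"):
            tgt.build_tree(state.positions)
            d1, _ = tgt._tree.query(state.positions[pair.followers], k=1)
            r_act = pair.gap_offset + pair.capture_band + tgt.tri_radius + 2.0
            pair._active = np.where(d1 < r_act)[0]
        act = pair._active
        if len(act) == 0:
            return 0.0
        followers = pair.followers[act]
        x = state.positions[followers]
        tri_idx, p, bary = tgt.closest(x, state.positions)
        tris = tgt.tris[tri_idx]
        a = state.positions[tris[:, 0]]
        b = state.positions[tris[:, 1]]
        c = state.positions[tris[:, 2]]
        nrm = np.cross(b - a, c - a)
        nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-30)
        nrm *= tgt.side
        dvec = x - p
        dist = np.linalg.norm(dvec, axis=1)
        sgn = np.sign(np.einsum("ni,ni->n", dvec, nrm))
        sgn[sgn == 0] = 1.0
        g = sgn * dist - pair.gap_offset
        pen = np.maximum(-g, 0.0)
        # a node "penetrating" deeper than the capture band is on the far
        # side of the (open) target sheet, not in contact with it; the force
        # tapers smoothly to zero toward the band edge to avoid impulsive
        # engagement/release
        band = pair.gap_offset + pair.capture_band
        taper = np.clip((band - pen) / (0.3 * band), 0.0, 1.0)
        fmag = pair.penalty_stiffness * pen * taper
        f = fmag[:, None] * nrm
        np.add.at(forces, followers, f)
        # reaction on the triangle nodes
        for k in range(3):
            np.add.at(forces, tris[:, k], -f * bary[:, k][:, None])
        if pair.friction_coefficient > 0.0:
            _friction(state, followers, pair, pen, nrm, fmag, forces, tris, bary)
        engaged = pen * (taper > 0.0)
        return float(engaged.max()) if len(engaged) else 0.0

    x = state.positions[pair.followers]
    g, normal = tgt.gaps(x)
    g = g - pair.gap_offset
    pen = np.maximum(-g, 0.0)
    pen[~np.isfinite(pen)] = 0.0
    f = (pair.penalty_stiffness * pen)[:, None] * normal
    np.add.at(forces, pair.followers, f)
    if pair.friction_coefficient > 0.0:
        fn = pair.penalty_stiffness * pen
        v = state.velocities[pair.followers]
        vt = v - np.einsum("ni,ni->n", v, normal)[:, None] * normal
        vt_n = np.linalg.norm(vt, axis=1)
        visc = 10.0 * pair.penalty_stiffness  # viscous regularisation, N s/mm
        fmag_t = np.minimum(visc * vt_n, pair.friction_coefficient * fn)
        with np.errstate(invalid="ignore"):
            dir_t = np.where(vt_n[:, None] > 1e-12, vt / np.maximum(vt_n[:, None], 1e-30), 0.0)
        np.add.at(forces, pair.followers, -fmag_t[:, None] * dir_t)
    return float(pen.max()) if len(pen) else 0.0


def _friction(state, followers, pair, pen, nrm, fn, forces, tris, bary):
    v = state.velocities[followers]
    vt = v - np.einsum("ni,ni->n", v, nrm)[:, None] * nrm
    vt_n = np.linalg.norm(vt, axis=1)
    visc = 10.0 * pair.penalty_stiffness
    fmag_t = np.minimum(visc * vt_n, pair.friction_coefficient * fn)
    dir_t = np.where(vt_n[:, None] > 1e-12, vt / np.maximum(vt_n[:, None], 1e-30), 0.0)
    ft = -fmag_t[:, None] * dir_t
    np.add.at(forces, followers, ft)
    for k in range(3):
        np.add.at(forces, tris[:, k], -ft * bary[:, k][:, None])


# ---------------------------------------------------------------------------
# assembled system


@dataclass
class PressureLoad:
    """Follower pressure on a membrane group (positive along its normals)."""

    group: MembraneGroup
    pressure: float = 0.0  # MPa


class System:
    """An assembled stent--tissue--tool system."""

    def __init__(self, x0: np.ndarray):
        self.x0 = np.asarray(x0, dtype=float)
        self.n = self.x0.shape[0]
        self.beam_groups: list[BeamGroup] = []
        self.membrane_groups: list[MembraneGroup] = []
        self.contact_pairs: list[ContactPair] = []
        self.pressure_loads: list[PressureLoad] = []
        self.fixed: np.ndarray = np.zeros(self.n, dtype=bool)
        self.fixed_dof: np.ndarray = np.zeros((self.n, 3), dtype=bool)
        self.prescribed: list = []  # (node_ids, fn(t) -> positions)
        self.external_forces = np.zeros((self.n, 3))
        self._mass = None
        self._inertia = None
        self.rot_ids = np.zeros(0, dtype=np.int64)  # nodes with rotational DOFs

    # -- assembly -----------------------------------------------------------
    def add_beams(self, group: BeamGroup):
        self.beam_groups.append(group)
        self.rot_ids = np.unique(np.concatenate([self.rot_ids, group.conn.ravel()]))

    def add_membrane(self, group: MembraneGroup):
        self.membrane_groups.append(group)

    def add_contact(self, pair: ContactPair):
        self.contact_pairs.append(pair)

    def add_pressure(self, group: MembraneGroup, pressure: float = 0.0) -> PressureLoad:
        load = PressureLoad(group, pressure)
        self.pressure_loads.append(load)
        return load

    def fix(self, node_ids, dofs=None):
        node_ids = np.asarray(node_ids, dtype=np.int64)
        if dofs is None:
            self.fixed[node_ids] = True
            self.fixed_dof[node_ids] = True
        else:
            for d in dofs:
                self.fixed_dof[node_ids, d] = True

    def prescribe(self, node_ids, trajectory):
        """``trajectory(t)`` returns (len(node_ids), 3) positions."""
        self.prescribed.append((np.asarray(node_ids, dtype=np.int64), trajectory))

    # -- masses -------------------------------------------------------------
    def compute_masses(self, settings: SolverSettings):
        m = np.zeros(self.n)
        I = np.zeros(self.n)
        for g in self.beam_groups:
            mel = g.density * g.area * g.L0
            np.add.at(m, g.conn[:, 0], 0.5 * mel)
            np.add.at(m, g.conn[:, 1], 0.5 * mel)
            # boosted rotary inertia (quasi-static: only stability matters)
            iel = 0.5 * mel * (g.L0**2 + g.width**2 + g.thickness**2) / 12.0 * 10.0
            np.add.at(I, g.conn[:, 0], iel)
            np.add.at(I, g.conn[:, 1], iel)
        for g in self.membrane_groups:
            mel = g.mass_boost * g.density * g.thickness * g.A0 / 3.0
            for k in range(3):
                np.add.at(m, g.tris[:, k], mel)
        m = np.maximum(m, 1e-15)
        I = np.maximum(I, 1e-18)
        self._mass = m * settings.mass_scaling_factor
        self._inertia = I * settings.mass_scaling_factor
        return self._mass

    def strain_energy(self, state: SimState) -> float:
        """Current recoverable strain energy of all elements, mJ."""
        e = 0.0
        for g in self.beam_groups:
            e += g.strain_energy()
        for g in self.membrane_groups:
            e += g.strain_energy(state.positions)
        return e

    # -- forces -------------------------------------------------------------
    def internal_and_contact_forces(self, state: SimState, search=True):
        f_mat = np.zeros((self.n, 3))
        mom = np.zeros((self.n, 3))
        for g in self.beam_groups:
            i, j, F_i, F_j, M_i, M_j = g.internal_forces(state)
            np.add.at(f_mat, i, F_i)
            np.add.at(f_mat, j, F_j)
            np.add.at(mom, i, M_i)
            np.add.at(mom, j, M_j)
        for g in self.membrane_groups:
            tris, f1, f2, f3 = g.internal_forces(state)
            np.add.at(f_mat, tris[:, 0], f1)
            np.add.at(f_mat, tris[:, 1], f2)
            np.add.at(f_mat, tris[:, 2], f3)
        f_ext = self.external_forces.copy()
        for load in self.pressure_loads:
            if load.pressure != 0.0:
                nrm, A = load.group.normals_areas(state.positions)
                fp = (load.pressure * A)[:, None] * nrm / 3.0
                for k in range(3):
                    np.add.at(f_ext, load.group.tris[:, k], fp)
        max_pen = 0.0
        f_con = np.zeros((self.n, 3))
        for pair in self.contact_pairs:
            max_pen = max(max_pen, contact_forces(state, pair, f_con, search=search))
        return f_mat, mom, f_ext, f_con, max_pen


# ---------------------------------------------------------------------------
# time stepping


def stable_time_step(system: System, settings: SolverSettings) -> float:
    """Conservative stable step: element length over wave speed (with mass
    scaling), bounded by contact-spring and rotary limits."""
    if not system.beam_groups and not system.membrane_groups:
        raise ValueError("empty model: no elements assembled")
    scale = np.sqrt(settings.mass_scaling_factor)
    dts = []
    for g in system.beam_groups:
        c = np.sqrt(g.young / g.density)
        dts.append(np.min(g.L0) / c)
    for g in system.membrane_groups:
        E, nu = g.card.young_modulus, g.card.poisson_ratio
        c = np.sqrt(E / (g.mass_boost * g.density * (1.0 - nu * nu)))
        dts.append(np.min(g.min_altitude) / c)
    dt = min(dts) * scale
    if system.contact_pairs:
        if system._mass is None:
            system.compute_masses(settings)
        kmax = max(p.penalty_stiffness for p in system.contact_pairs)
        dt = min(dt, np.sqrt(2.0 * np.min(system._mass) / kmax))
    return settings.time_step_safety * 0.5 * dt


def advance(
    system: System,
    state: SimState,
    duration: float,
    settings: SolverSettings,
    on_time=None,
    dt: float | None = None,
    record=None,
):
    """Advance the system for ``duration`` seconds of simulation time.

    ``on_time(t_abs)`` is called every step to update loads, tool surfaces
    and prescribed-motion targets.  Returns the final KE/IE ratio.
    Raises :class:`EnergyBlowupError` on a sustained kinetic-energy blow-up.
    """
    if system._mass is None:
        system.compute_masses(settings)
    m = system._mass[:, None]
    I = system._inertia[:, None]
    if dt is None:
        dt = stable_time_step(system, settings)
    nsteps = max(int(np.ceil(duration / dt)), 1)
    dt = duration / nsteps
    c = settings.damping
    fac1 = 1.0 - 0.5 * c * dt
    fac2 = 1.0 / (1.0 + 0.5 * c * dt)

    for step in range(nsteps):
        t = state.time
        if on_time is not None:
            on_time(t)
        search = step % settings.contact_search_every == 0
        f_mat, mom, f_ext, f_con, max_pen = system.internal_and_contact_forces(
            state, search=search
        )
        f_tot = f_mat + f_ext + f_con
        f_tot[system.fixed_dof] = 0.0

        state.velocities = (state.velocities * fac1 + dt * f_tot / m) * fac2
        state.velocities[system.fixed_dof] = 0.0
        rid = system.rot_ids
        state.angular_velocities[rid] = (
            state.angular_velocities[rid] * fac1 + dt * mom[rid] / I[rid]
        ) * fac2
        state.angular_velocities[system.fixed] = 0.0

        dx = dt * state.velocities
        for ids, traj in system.prescribed:
            target = traj(t + dt)
            dx[ids] = target - state.positions[ids]
            state.velocities[ids] = dx[ids] / dt
        state.positions += dx
        if len(rid):
            dR = _rodrigues(state.angular_velocities[rid] * dt)
            state.rotations[rid] = np.einsum("nij,njk->nik", dR, state.rotations[rid])
        state.time += dt

        # energies
        state.internal_energy += float(np.einsum("ni,ni->", -f_mat, dx))
        ke = 0.5 * float(
            np.einsum("ni,ni->", m * state.velocities, state.velocities)
            + np.einsum(
                "ni,ni->",
                I[rid] * state.angular_velocities[rid],
                state.angular_velocities[rid],
            )
        )
        state.kinetic_energy = ke
        # instability signature: non-finite energy, or nodes jumping by more
        # than a mesh-scale distance in a single increment
        if not np.isfinite(ke) or float(np.abs(dx).max()) > 5.0:
            raise EnergyBlowupError(
                f"kinetic energy blow-up at t={state.time:.4g}s (KE={ke:.3g} mJ)"
            )
        if record is not None:
            record(step, state, max_pen)
    return state.ke_ie_ratio


@dataclass
class StageLog:
    """Outcome of one protocol stage."""

    name: str
    duration: float
    steps: int
    ke_ie_ratio: float
    passed_gate: bool
    max_penetration: float = 0.0


def run_stage(
    system: System,
    state: SimState,
    name: str,
    duration: float,
    settings: SolverSettings,
    on_fraction=None,
    settle_time: float | None = None,
) -> StageLog:
    """Run one ramped loading stage then let the system settle.

    ``on_fraction(s)`` receives a smooth-step ramp fraction in [0, 1] and
    applies the stage's loading (tool motion, pressure, prescribed targets).
    After the ramp the loading is held at 1 and the system relaxes until the
    quasi-static gate passes or the settle budget is exhausted.
    """
    dt = stable_time_step(system, settings)
    t0 = state.time

    def smooth(t):
        s = np.clip((t - t0) / duration, 0.0, 1.0)
        return s * s * (3.0 - 2.0 * s)

    def on_time(t):
        if on_fraction is not None:
            on_fraction(smooth(t))

    pen_track = [0.0]

    def record(step, st, max_pen):
        pen_track[0] = max(pen_track[0], max_pen)

    advance(system, state, duration, settings, on_time=on_time, dt=dt, record=record)
    steps = int(round(duration / dt))

    def gate_ratio():
        return state.kinetic_energy / max(system.strain_energy(state), 1e-9)

    # settle with loading held until the quasi-static gate passes and the
    # configuration stops moving; superelastic recovery in particular
    # creeps slowly through its hysteresis, so settling is judged on both
    # the energy ratio and the largest nodal displacement per chunk
    if settle_time is None:
        settle_time = duration
    settle_chunks = 32
    chunk = settle_time / 8.0
    ratio = gate_ratio()
    moved = np.inf  # largest nodal displacement over the last chunk
    for _ in range(settle_chunks):
        if ratio < settings.quasi_static_ke_ratio_max and moved < 0.05:
            break
        before = state.positions.copy()
        advance(system, state, chunk, settings, on_time=on_time, dt=dt, record=record)
        moved = float(np.abs(state.positions - before).max())
        ratio = gate_ratio()
        steps += int(round(chunk / dt))
    passed = ratio < settings.quasi_static_ke_ratio_max
    return StageLog(name, state.time - t0, steps, ratio, passed, pen_track[0])
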