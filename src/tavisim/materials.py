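"""Constitutive laws for the stent--tissue system.

Three behaviours are supported, matching the material table shipped with the
package (``data/materials.yaml``):

* ``linear_elastic`` -- arterial wall, native leaflets and the balloon fabric,
  used as plane-stress membranes with a nominal thickness;
* ``elastoplastic`` -- von Mises / 1-D radial-return plasticity with optional
  linear isotropic hardening, used for the cobalt-chromium frame alloy and for
  calcific deposits;
* ``superelastic`` -- a one-dimensional flag-shaped hysteresis model of
  Nitinol at body temperature: an austenite elastic branch, a stress plateau
  where the martensite fraction grows from 0 to 1 carrying the transformation
  strain, a lower unloading plateau, and full strain recovery on unloading to
  zero stress.  Tension and compression are treated symmetrically via a signed
  martensite fraction.

All updates are vectorised over arrays of fibers so that a beam cross-section
integration grid can be advanced in one call.

Unit system: mm / N / MPa / s; densities are stated in kg/m^3 on the cards and
converted where masses are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "MaterialCard",
    "SuperelasticCard",
    "FiberState",
    "default_materials",
    "load_material_table",
    "elastic_stress",
    "elastoplastic_update",
    "superelastic_update",
]


@dataclass(frozen=True)
class MaterialCard:
    """A single row of the material table.

    ``thickness`` is only meaningful for surface (membrane) materials;
    ``yield_stress`` only for the elastoplastic model.  ``hardening_modulus``
    defaults to perfect plasticity.
    """

    name: str
    model: str  # linear_elastic | elastoplastic | superelastic
    young_modulus: float
    poisson_ratio: float
    density: float = 1000.0  # kg/m^3
    yield_stress: float | None = None
    hardening_modulus: float = 0.0
    thickness: float | None = None  # mm

    def __post_init__(self) -> None:
        if self.model not in ("linear_elastic", "elastoplastic", "superelastic"):
            raise ValueError(f"unknown material model {self.model!r}")
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.model == "elastoplastic":
            if self.yield_stress is None or self.yield_stress <= 0:
                raise ValueError("elastoplastic card needs a positive yield_stress")

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))


@dataclass(frozen=True)
class SuperelasticCard:
    """Parameters of the flag-shaped superelastic hysteresis.

    The loading plateau runs from ``transformation_start_stress_loading`` at
    zero martensite to ``transformation_finish_stress_loading`` at full
    martensite; the unloading plateau is mirrored at lower stresses.  During
    transformation the stress is computed with the austenite modulus, so that
    the dissipated energy of a full cycle equals the area between the plateau
    lines exactly; the martensite modulus governs the fully transformed branch.
    """

    name: str = "nitinol"
    austenite_modulus: float = 45000.0
    martensite_modulus: float = 32000.0
    transformation_start_stress_loading: float = 440.0
    transformation_finish_stress_loading: float = 540.0
    transformation_start_stress_unloading: float = 250.0
    transformation_finish_stress_unloading: float = 140.0
    transformation_strain: float = 0.045
    poisson_ratio: float = 0.33
    density: float = 6450.0
    max_strain: float = 0.15

    def __post_init__(self) -> None:
        sLs = self.transformation_start_stress_loading
        sLf = self.transformation_finish_stress_loading
        sUs = self.transformation_start_stress_unloading
        sUf = self.transformation_finish_stress_unloading
        if not (sLf >= sLs > 0):
            raise ValueError("loading plateau must satisfy finish >= start > 0")
        if not (sUs >= sUf > 0):
            raise ValueError("unloading plateau must satisfy start >= finish > 0")
        if not (min(sLs, sLf) > max(sUs, sUf)):
            raise ValueError("loading plateau must lie above unloading plateau")
        if self.transformation_strain <= 0:
            raise ValueError("transformation_strain must be positive")

    @property
    def shear_modulus(self) -> float:
        return self.austenite_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def elastic_limit_strain(self) -> float:
        """Strain at the onset of the loading plateau."""
        return self.transformation_start_stress_loading / self.austenite_modulus


@dataclass
class FiberState:
    """Internal state of a bundle of 1-D fibers.

    ``plastic_strain`` is the accumulated plastic strain of the elastoplastic
    law; ``martensite_fraction`` is the *signed* martensite fraction of the
    superelastic law (its magnitude lies in [0, 1], the sign is the loading
    direction); ``strain`` and ``stress`` are the converged values of the last
    update.
    """

    n: int
    stress: np.ndarray = field(default=None)  # type: ignore[assignment]
    strain: np.ndarray = field(default=None)  # type: ignore[assignment]
    plastic_strain: np.ndarray = field(default=None)  # type: ignore[assignment]
    martensite_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("stress", "strain", "plastic_strain", "martensite_fraction"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.n))

    def copy(self) -> "FiberState":
        return FiberState(
            self.n,
            self.stress.copy(),
            self.strain.copy(),
            self.plastic_strain.copy(),
            self.martensite_fraction.copy(),
        )


# ----------------------------------------------------------------------------
# material table loading


def _card_from_dict(name: str, d: dict) -> MaterialCard | SuperelasticCard:
    d = dict(d)
    model = d.pop("model")
    if model == "superelastic":
        return SuperelasticCard(name=name, **d)
    return MaterialCard(name=name, model=model, **d)


def load_material_table(source) -> dict:
    """Load a material table from a YAML mapping (path or dict)."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    return {name: _card_from_dict(name, d) for name, d in raw.items()}


def default_materials() -> dict:
    """The package's default material table."""
    text = resources.files("tavisim.data").joinpath("materials.yaml").read_text()
    return load_material_table(yaml.safe_load(text))


# ----------------------------------------------------------------------------
# constitutive updates


def elastic_stress(strain, card: MaterialCard):
    """Uniaxial linear-elastic stress, sigma = E * eps."""
    if card.model != "linear_elastic":
        raise ValueError(f"card {card.name!r} is not linear_elastic")
    return card.young_modulus * np.asarray(strain, dtype=float)


def elastoplastic_update(strain_increment, state: FiberState, card: MaterialCard):
    """Radial-return update of 1-D elastoplasticity with linear hardening.

    Returns the new stress array and mutates ``state`` in place (stress,
    accumulated plastic strain, total strain).
    """
    if card.model != "elastoplastic":
        raise ValueError(f"card {card.name!r} is not elastoplastic")
    d_eps = np.asarray(strain_increment, dtype=float)
    E = card.young_modulus
    H = card.hardening_modulus
    sy = card.yield_stress

    trial = state.stress + E * d_eps
    flow = np.abs(trial) - (sy + H * state.plastic_strain)
    dgamma = np.where(flow > 0.0, flow / (E + H), 0.0)
    stress = trial - np.sign(trial) * E * dgamma
    state.stress = stress
    state.plastic_strain = state.plastic_strain + dgamma
    state.strain = state.strain + d_eps
    return stress, state


def _superelastic_stress(eps, z, card: SuperelasticCard):
    """Stress for given total strain and signed martensite fraction.

    Austenite modulus everywhere except on the fully-martensitic branch,
    which continues from the plateau corner with the martensite modulus.
    """
    EA = card.austenite_modulus
    EM = card.martensite_modulus
    epsL = card.transformation_strain
    sLf = card.transformation_finish_stress_loading
    sig = EA * (eps - z * epsL)
    full = np.abs(z) >= 1.0 - 1e-12
    if np.any(full):
        m = np.sign(z)
        x = m * eps  # strain magnitude on the transformed side
        corner = epsL + sLf / EA
        beyond = full & (x > corner)
        sig = np.where(beyond, m * (sLf + EM * (x - corner)), sig)
    return sig


def superelastic_update(strain, state: FiberState, card: SuperelasticCard):
    """Strain-driven update of the flag-shaped superelastic law.

    Transformation evolves so the stress follows the loading plateau line
    (martensite fraction growing) or the unloading plateau line (shrinking);
    between the plateaus the response is elastic at the austenite modulus.
    Tension and compression are symmetric via the signed fraction.  Raises
    ``ValueError`` if any strain magnitude exceeds ``card.max_strain``.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(np.abs(eps) > card.max_strain):
        raise ValueError(
            f"superelastic strain beyond modelled range |eps| <= {card.max_strain}"
        )
    EA = card.austenite_modulus
    epsL = card.transformation_strain
    sLs = card.transformation_start_stress_loading
    dsL = card.transformation_finish_stress_loading - sLs
    sUf = card.transformation_finish_stress_unloading
    dsU = card.transformation_start_stress_unloading - sUf

    z = np.asarray(state.martensite_fraction, dtype=float)
    # work in the frame of the currently transformed side
    side = np.where(z != 0.0, np.sign(z), np.where(eps >= 0.0, 1.0, -1.0))
    e = side * eps
    zz = side * z  # in [0, 1]

    sig = EA * (e - zz * epsL)
    # forward transformation: stress reaches the loading plateau line
    z_fwd = (EA * e - sLs) / (EA * epsL + dsL)
    fwd = (sig > sLs + zz * dsL) & (zz < 1.0)
    zz_new = np.where(fwd, np.minimum(np.maximum(z_fwd, zz), 1.0), zz)
    # reverse transformation: stress falls to the unloading plateau line
    z_rev = (EA * e - sUf) / (EA * epsL + dsU)
    rev = (sig < sUf + zz * dsU) & (zz > 0.0)
    zz_new = np.where(rev, np.clip(z_rev, 0.0, zz), zz_new)
    # crossing to the opposite side once fully untransformed
    e_op = -e
    z_op = (EA * e_op - sLs) / (EA * epsL + dsL)
    cross = (zz_new <= 0.0) & (EA * e_op > sLs)
    zz_new = np.where(cross, -np.clip(z_op, 0.0, 1.0), zz_new)

    z_signed = side * zz_new
    stress = _superelastic_stress(eps, z_signed, card)
    state.martensite_fraction = z_signed
    state.stress = stress
    state.strain = eps.copy() if eps.shape else np.asarray(eps)
    return stress, state
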