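"""Shared fixtures.

The deployment fixtures are expensive (minutes each), so they are
session-scoped and shared between the deployment suite and the acceptance
suite; every simulation input here is generated programmatically.
"""

import numpy as np
import pytest

from tavisim.anatomy import AnatomyParams, build_anatomy
from tavisim.devices import build_balloon_expandable, build_self_expandable
from tavisim.protocols import Procedure, ProtocolParams
from tavisim.solver import SolverSettings

SEED = 2


def quasi_static_settings() -> SolverSettings:
    return SolverSettings(mass_scaling_factor=1.0e6, damping=10.0)


def calcified_root(annulus: float):
    """Synthetic root with one bulky calcific nodule on the RCC leaflet."""
    return build_anatomy(
        AnatomyParams(
            annulus_diameter=annulus,
            n_theta=28,
            axial_spacing=2.2,
            calcium_leaflets=(1,),
            calcium_volume=726.0,
            seed=SEED,
        )
    )


def release_in_root(anatomy, size: int):
    params = ProtocolParams(
        run_bav=False, stage_durations={"crimp": 0.5, "release": 1.2}
    )
    proc = Procedure(
        build_self_expandable(size),
        anatomy=anatomy,
        params=params,
        with_balloon=False,
        settings=quasi_static_settings(),
        seed=SEED,
    )
    proc.crimp()
    proc.position_stent()
    proc.release_sheath()
    return proc


@pytest.fixture(scope="session")
def free_recovery():
    """Self-expandable frame crimped to the catheter diameter and released
    in free space (superelastic recovery benchmark)."""
    stent = build_self_expandable(26)
    proc = Procedure(
        stent, anatomy=None, with_balloon=False, settings=quasi_static_settings()
    )
    proc.crimp(6.0, duration=0.5)
    crimped = proc.state.positions[proc.stent_ids].copy()
    proc.release_crimper(duration=1.5)
    return {
        "stent": stent,
        "proc": proc,
        "crimped_positions": crimped,
        "final_positions": proc.state.positions[proc.stent_ids].copy(),
    }


@pytest.fixture(scope="session")
def undersized_deployment():
    """26 mm frame released in a 24.5 mm-annulus calcified root: an
    undersized deployment expected to leak."""
    proc = release_in_root(calcified_root(24.5), 26)
    return proc.result()


@pytest.fixture(scope="session")
def oversized_deployment():
    """26 mm frame released in a 23.5 mm-annulus root built with the same
    seed and nodule: the oversized counterpart expected to seal."""
    proc = release_in_root(calcified_root(23.5), 26)
    return proc.result()


@pytest.fixture(scope="session")
def large_device_deployment():
    """29 mm frame in the same 23.5 mm root, for the strain ordering."""
    proc = release_in_root(calcified_root(23.5), 29)
    return proc.result()


@pytest.fixture(scope="session")
def crimped_balloon_expandable():
    """Balloon-expandable frame crimped to 6 mm and released in free space
    (plastic set benchmark)."""
    stent = build_balloon_expandable(26)
    proc = Procedure(
        stent, anatomy=None, with_balloon=False, settings=quasi_static_settings()
    )
    proc.crimp(6.0, duration=0.8)
    crimped = proc.state.positions[proc.stent_ids].copy()
    plastic = proc.beam_group.state.plastic_strain.copy()
    proc.release_crimper(duration=1.0)
    return {
        "stent": stent,
        "proc": proc,
        "crimped_positions": crimped,
        "plastic_strain_at_crimp": plastic,
        "final_positions": proc.state.positions[proc.stent_ids].copy(),
    }
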