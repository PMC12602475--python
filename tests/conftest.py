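import logging

import numpy as np
import pytest

from tibfem.jcs import LandmarkSet

logging.getLogger("tibfem").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def simple_landmarks() -> LandmarkSet:
    """Hand-constructible right-knee landmark set with axis-aligned frames."""
    pts = {
        "Ofem": [0, 0, 0], "Chip": [0, 0, 400],
        "Mppc": [-30, -20, 5], "Lppc": [30, -20, 5],
        "Mepi": [-41, -8, 12], "Lepi": [41, -8, 12],
        "Otib": [0, 0, 0], "Cank": [0, 0, -380],
        "Mctc": [-25, 0, -3], "Lctc": [25, 0, -3],
    }
    return LandmarkSet(points={k: np.asarray(v, float) for k, v in pts.items()},
                       side="right")


@pytest.fixture(scope="session")
def coarse_knee():
    """Fast synthetic knee fixture (coarse meshes) plus flexion cycles."""
    from tibfem.synthetic import generate_synthetic_knee
    return generate_synthetic_knee("coarse", seed=3)


@pytest.fixture(scope="session")
def coarse_settings():
    """Solver tolerance matched to the coarse fixture's mesh faceting.

    The generalized-force residual floor scales with facet size; the coarse
    test meshes need a looser tolerance than the default preset to converge
    everywhere, without changing what the tests demonstrate.
    """
    from tibfem.simulate import EquilibriumSettings
    return EquilibriumSettings(tol_force=0.02, tol_torque=0.02)


@pytest.fixture(scope="session")
def initialized_coarse_knee(coarse_knee, coarse_settings):
    """Coarse knee with slack lengths initialized from full extension."""
    from tibfem import simulate
    model, cycles = coarse_knee
    simulate.initialize_from_full_extension(model, start_alpha_deg=10.0,
                                            settings=coarse_settings)
    return model, cycles
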