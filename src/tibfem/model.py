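"""Shared model containers: ligament registry, contact parameters, knee model.

Fifteen tensile elements span the tibiofemoral joint: double-bundle cruciates
(aACL/pACL, aPCL/pPCL), double-bundle deep and oblique medial collaterals
(dMCLa/dMCLp, oMCLa/oMCLp), and single-element superficial MCL, ALL, LCL,
oblique and arcuate popliteal ligaments, and medial/lateral capsule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .jcs import LandmarkSet

__all__ = [
    "LIGAMENT_NAMES",
    "LigamentSpec",
    "LigamentState",
    "ContactParams",
    "KneeModel",
]

LIGAMENT_NAMES = (
    "aACL", "pACL", "aPCL", "pPCL",
    "dMCLa", "dMCLp", "oMCLa", "oMCLp",
    "sMCL", "ALL", "LCL", "OPL", "APL", "mCAP", "lCAP",
)


@dataclass
class LigamentSpec:
    """One tensile element: insertions (body frames, mm) and material law.

    ``K_Q`` (N/mm^2) governs the quadratic toe region, ``K_L`` (N/mm) the
    linear region, ``e`` is the expansion constant relating the slack length
    to the full-extension length (``L0 = e * Le``).  ``L0`` and the
    transition strain ``epsilon1`` are populated by slack-length
    initialization and stay ``None`` until then.
    """

    name: str
    femoral_mm: np.ndarray
    tibial_mm: np.ndarray
    K_Q: float  # N/mm^2
    K_L: float  # N/mm
    e: float    # dimensionless expansion constant
    L0: float | None = None       # mm, slack length
    epsilon1: float | None = None  # transition strain

    def __post_init__(self) -> None:
        if self.name not in LIGAMENT_NAMES:
            raise ValueError(f"unknown ligament name {self.name!r}")
        self.femoral_mm = np.asarray(self.femoral_mm, float).reshape(3)
        self.tibial_mm = np.asarray(self.tibial_mm, float).reshape(3)
        if not (self.K_Q > 0 and self.K_L > 0):
            raise ValueError(f"{self.name}: stiffnesses must be positive")
        if not (0 < self.e <= 1.2):
            raise ValueError(f"{self.name}: expansion constant e={self.e} outside (0, 1.2]")
        if self.L0 is not None and self.L0 <= 0:
            raise ValueError(f"{self.name}: slack length must be positive")

    @property
    def initialized(self) -> bool:
        return self.L0 is not None and self.epsilon1 is not None


@dataclass
class LigamentState:
    """Instantaneous kinematic/force state of one element."""

    name: str
    L: float          # mm, insertion-to-insertion length
    epsilon: float    # strain
    tension: float    # N, >= 0
    direction: np.ndarray  # unit vector tibial insertion -> femoral insertion, ground frame

    def __post_init__(self) -> None:
        if self.tension < 0:
            raise ValueError(f"{self.name}: negative tension {self.tension}")
        if self.epsilon < 0 and self.tension != 0:
            raise ValueError(f"{self.name}: slack element carrying load")


@dataclass
class ContactParams:
    """Penalty-contact constants for cartilage-on-cartilage interaction.

    ``k`` = 500 N/mm^p with exponent ``p`` = 1.5, step transition interval
    ``delta_c`` = 0.01 mm and damping ``C`` = 5 kg/s; the damping term only
    contributes when penetration rates are non-zero (dynamic relaxation).
    ``aggregation`` selects between the area-weighted per-vertex sum
    (``"distributed"``, default) and a single force at the deepest point
    (``"deepest"``).
    """

    k: float = 500.0        # N/mm^p
    p: float = 1.5
    delta_c: float = 0.01   # mm
    C: float = 5.0          # kg/s = N*s/mm
    aggregation: str = "distributed"

    def __post_init__(self) -> None:
        if self.k <= 0 or self.p < 1 or self.delta_c <= 0 or self.C < 0:
            raise ValueError("invalid contact parameters")
        if self.aggregation not in ("distributed", "deepest"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class KneeModel:
    """Bones, cartilages, landmarks and tensile elements of one knee.

    Meshes are stored in their body frames (femoral meshes in the femoral
    frame, tibial in the tibial frame) so a single mesh object serves every
    pose; contact queries transform through the current rigid states.
    """

    landmarks: LandmarkSet
    femur_bone: "SurfaceMesh"
    femur_cartilage: "SurfaceMesh"
    tibia_bone: "SurfaceMesh"
    tibia_cartilage: "SurfaceMesh"
    ligaments: list[LigamentSpec]
    contact: ContactParams = field(default_factory=ContactParams)
    name: str = "knee"

    def __post_init__(self) -> None:
        names = [lig.name for lig in self.ligaments]
        if sorted(names) != sorted(LIGAMENT_NAMES):
            missing = set(LIGAMENT_NAMES) - set(names)
            extra = set(names) - set(LIGAMENT_NAMES)
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(
                f"ligament registry invalid: missing={sorted(missing)} "
                f"extra={sorted(extra)} duplicated={sorted(dupes)}")

    @property
    def side(self) -> str:
        return self.landmarks.side

    def ligament(self, name: str) -> LigamentSpec:
        for lig in self.ligaments:
            if lig.name == name:
                return lig
        raise KeyError(name)

    @property
    def initialized(self) -> bool:
        return all(lig.initialized for lig in self.ligaments)
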