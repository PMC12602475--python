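"""Anatomical body frames and the Grood–Suntay joint coordinate system.

The tibiofemoral pose is described by three rotations and three translations
that carry clinical meaning:

* flexion–extension ``alpha`` about the femoral medio-lateral axis ``X_F``,
* tibial internal–external rotation ``gamma`` about the tibial long axis
  ``Z_T``,
* abduction–adduction ``pi/2 - beta`` about a *floating* axis ``e2`` that is
  always perpendicular to both body-fixed axes.

The origin-to-origin vector ``H`` is resolved twice: into *joint
translations* ``S1..S3`` (components in the generally non-orthogonal basis
``{e1, e2, e3}``) and into *clinical translations* ``q1..q3`` (orthogonal
projections of ``H`` onto the same axes).  The drawer component along the
floating axis is the only one for which the two always agree (``S2 == q2``);
the other two pairs coincide exactly at zero adduction.

Angles are radians internally; every file boundary in :mod:`tibfem` uses
degrees and millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FEMORAL_LANDMARKS",
    "TIBIAL_LANDMARKS",
    "LandmarkSet",
    "BodyFrame",
    "RigidState",
    "JointCoordinates",
    "DegenerateGeometryError",
    "GimbalDegenerateError",
    "build_femoral_frame",
    "build_tibial_frame",
    "decompose_joint",
    "compose_joint",
    "joint_coordinates",
]

FEMORAL_LANDMARKS = ("Lepi", "Mepi", "Mppc", "Lppc", "Chip", "Ofem")
TIBIAL_LANDMARKS = ("Mctc", "Lctc", "Cank", "Otib")

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Landmark geometry does not admit a well-defined frame."""


class GimbalDegenerateError(ValueError):
    """Femoral flexion axis is parallel to the tibial long axis."""


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what} has (near-)zero length")
    return v / n


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points (mm) defining the femoral and tibial frames.

    Femoral: lateral/medial epicondyles (``Lepi``/``Mepi``), most-posterior
    condyle points (``Lppc``/``Mppc``), hip-ball centre ``Chip`` and femoral
    origin ``Ofem``.  Tibial: condyle centres ``Lctc``/``Mctc``, ankle centre
    ``Cank`` and tibial origin ``Otib`` (between the eminences).
    """

    points: dict[str, np.ndarray]
    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        pts = {}
        for name in FEMORAL_LANDMARKS + TIBIAL_LANDMARKS:
            if name not in self.points:
                raise ValueError(f"missing landmark {name!r}")
            p = np.asarray(self.points[name], dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} is not finite")
            pts[name] = p
        for a, b in (("Chip", "Ofem"), ("Mppc", "Lppc"), ("Otib", "Cank"), ("Mctc", "Lctc")):
            if np.linalg.norm(pts[a] - pts[b]) < 1e-9:
                raise DegenerateGeometryError(f"landmarks {a!r} and {b!r} coincide")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "units": "mm",
            "points": {k: [float(x) for x in v] for k, v in self.points.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        units = d.get("units", "mm")
        if units != "mm":
            raise ValueError(f"landmark units must be mm, got {units!r}")
        return cls(points={k: np.asarray(v, float) for k, v in d["points"].items()},
                   side=d.get("side", "right"))


@dataclass(frozen=True)
class BodyFrame:
    """Right-handed orthonormal triad plus origin (mm)."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "X", "Y", "Z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("frame is left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are X, Y, Z (body -> parent)."""
        return np.column_stack([self.X, self.Y, self.Z])

    def to_parent(self, local: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from this frame into its parent frame."""
        return np.asarray(local, float) @ self.rotation.T + self.origin

    def to_local(self, parent: np.ndarray) -> np.ndarray:
        return (np.asarray(parent, float) - self.origin) @ self.rotation


@dataclass(frozen=True)
class RigidState:
    """Pose of a body in the ground frame, with optional velocities.

    Velocities default to zero, which is the quasi-static regime used for
    passive-flexion simulation; a dynamic-relaxation solve may populate them.
    """

    frame: BodyFrame
    linear_velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))   # mm/s
    angular_velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # rad/s

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear_velocity",
                           np.asarray(self.linear_velocity, float).reshape(3))
        object.__setattr__(self, "angular_velocity",
                           np.asarray(self.angular_velocity, float).reshape(3))

    @classmethod
    def identity(cls) -> "RigidState":
        return cls(frame=BodyFrame(np.zeros(3), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2]))

    def point_velocity(self, point_ground: np.ndarray) -> np.ndarray:
        """Velocity of a material point given in ground coordinates."""
        r = np.asarray(point_ground, float) - self.frame.origin
        return self.linear_velocity + np.cross(self.angular_velocity, r)


@dataclass
class JointCoordinates:
    """Grood–Suntay coordinates of the tibia relative to the femur.

    ``alpha``/``beta``/``gamma`` in radians; ``S`` are the joint translations
    (components of ``H`` in the joint basis), ``q`` the clinical translations
    (projections of ``H`` on the joint axes); both in mm.
    """

    alpha: float = 0.0
    gamma: float = 0.0
    beta: float = np.pi / 2
    S1: float = 0.0
    S2: float = 0.0
    S3: float = 0.0
    q1: float | None = None
    q2: float | None = None
    q3: float | None = None
    H: np.ndarray | None = None
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None
    e3: np.ndarray | None = None

    @property
    def adduction(self) -> float:
        return np.pi / 2 - self.beta

    @property
    def alpha_deg(self) -> float:
        return float(np.degrees(self.alpha))

    @property
    def gamma_deg(self) -> float:
        return float(np.degrees(self.gamma))

    @property
    def adduction_deg(self) -> float:
        return float(np.degrees(self.adduction))

    @property
    def S(self) -> np.ndarray:
        return np.array([self.S1, self.S2, self.S3])

    @property
    def q(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3], dtype=float)


def joint_coordinates(alpha: float = 0.0, adduction: float = 0.0, gamma: float = 0.0,
                      S1: float = 0.0, S2: float = 0.0, S3: float = 0.0) -> JointCoordinates:
    """Convenience constructor from the five clinically named coordinates."""
    return JointCoordinates(alpha=alpha, beta=np.pi / 2 - adduction, gamma=gamma,
                            S1=S1, S2=S2, S3=S3)


def _medlat_direction(landmarks: LandmarkSet, medial: str, lateral: str) -> np.ndarray:
    # X is positive laterally on a right limb, medially on a left limb; the
    # medial->lateral landmark chord is flipped accordingly before crossing.
    d = landmarks[lateral] - landmarks[medial]
    if landmarks.side == "left":
        d = -d
    return _unit(d, f"{medial}->{lateral} chord")


def _frame_from_long_axis(origin: np.ndarray, z: np.ndarray, medlat: np.ndarray) -> BodyFrame:
    y = np.cross(z, medlat)
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateGeometryError("long axis is collinear with the medio-lateral chord")
    y = y / ny
    x = np.cross(y, z)  # unit by construction, right-handed: X x Y = Z
    return BodyFrame(origin=origin, X=x, Y=y, Z=z)


def build_femoral_frame(landmarks: LandmarkSet) -> BodyFrame:
    """Femoral frame: origin Ofem, Z along Ofem->Chip (proximal), Y anterior.

    Y is the normalised cross product of Z with the posterior-condyle chord
    Mppc->Lppc (flipped for a left limb), X completes the right-handed triad
    and points laterally (right limb) or medially (left limb).
    """
    z = _unit(landmarks["Chip"] - landmarks["Ofem"], "femoral long axis Ofem->Chip")
    medlat = _medlat_direction(landmarks, "Mppc", "Lppc")
    return _frame_from_long_axis(landmarks["Ofem"], z, medlat)


def build_tibial_frame(landmarks: LandmarkSet) -> BodyFrame:
    """Tibial frame: origin Otib, Z along Cank->Otib (the mechanical axis)."""
    z = _unit(landmarks["Otib"] - landmarks["Cank"], "tibial mechanical axis Cank->Otib")
    medlat = _medlat_direction(landmarks, "Mctc", "Lctc")
    return _frame_from_long_axis(landmarks["Otib"], z, medlat)


def decompose_joint(femur: RigidState, tibia: RigidState, side: str = "right") -> JointCoordinates:
    """Resolve the relative pose into Grood–Suntay coordinates.

    ``e1`` is the femoral ``X`` axis, ``e3`` the tibial ``Z`` axis and the
    floating axis ``e2`` their (normalised) cross product ``e3 x e1``.  The
    joint translations solve ``H = S1 e1 + S2 e2 + S3 e3`` in the
    (non-orthogonal for non-zero adduction) joint basis, which is the unique
    reading under which the drawer identity ``S2 == q2`` holds at every pose.

    For a left limb the reported adduction, internal rotation and
    medial-lateral translation are sign-flipped (clinical convention), so
    coordinates are invariant under mirroring a right knee to a left one.
    """
    Ff, Ft = femur.frame, tibia.frame
    e1 = Ff.X
    e3 = Ft.Z
    c = float(np.clip(np.dot(e1, e3), -1.0, 1.0))
    beta = float(np.arccos(c))
    cross = np.cross(e3, e1)
    s = np.linalg.norm(cross)
    if s < 1e-9:
        raise GimbalDegenerateError(
            f"flexion axis parallel to tibial long axis (beta={np.degrees(beta):.3f} deg)")
    e2 = cross / s

    # flexion positive when the shank swings posteriorly (anatomical flexion)
    alpha = float(np.arctan2(-np.dot(e2, Ff.Z), np.dot(e2, Ff.Y)))
    gamma = float(np.arctan2(np.dot(e2, Ft.X), np.dot(e2, Ft.Y)))

    H = Ft.origin - Ff.origin
    E = np.column_stack([e1, e2, e3])
    S = np.linalg.solve(E, H)
    q = E.T @ H
    if side == "left":
        beta = np.pi - beta
        gamma = -gamma
        S = S * np.array([-1.0, 1.0, 1.0])
        q = q * np.array([-1.0, 1.0, 1.0])
    elif side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return JointCoordinates(alpha=alpha, beta=beta, gamma=gamma,
                            S1=float(S[0]), S2=float(S[1]), S3=float(S[2]),
                            q1=float(q[0]), q2=float(q[1]), q3=float(q[2]),
                            H=H, e1=e1, e2=e2, e3=e3)


def compose_joint(jc: JointCoordinates, femur: RigidState, side: str = "right") -> RigidState:
    """Place the tibia at the given joint coordinates relative to the femur.

    Exact inverse of :func:`decompose_joint` (only ``alpha``, ``beta``,
    ``gamma`` and ``S1..S3`` are read; ``side`` must match the value used at
    decomposition).
    """
    if not (1e-9 < jc.beta < np.pi - 1e-9):
        raise GimbalDegenerateError(f"beta={jc.beta} outside (0, pi)")
    beta, gamma, S1 = jc.beta, jc.gamma, jc.S1
    if side == "left":
        beta = np.pi - beta
        gamma = -gamma
        S1 = -S1
    elif side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    Ff = femur.frame
    e1 = Ff.X
    e2 = np.cos(jc.alpha) * Ff.Y - np.sin(jc.alpha) * Ff.Z
    v = np.cross(e1, e2)
    e3 = np.cos(beta) * e1 + np.sin(beta) * v

    Yt = np.cos(gamma) * e2 + np.sin(gamma) * np.cross(e3, e2)
    Zt = e3
    Xt = np.cross(Yt, Zt)
    origin = Ff.origin + S1 * e1 + jc.S2 * e2 + jc.S3 * e3
    return RigidState(frame=BodyFrame(origin=origin, X=Xt, Y=Yt, Z=Zt))


def mirror_landmarks(landmarks: LandmarkSet) -> LandmarkSet:
    """Mirror a landmark set across the x=0 plane, flipping the side flag.

    Useful for turning a right-knee fixture into its left-knee twin; joint
    angles are invariant under this operation by the side convention.
    """
    M = np.diag([-1.0, 1.0, 1.0])
    pts = {k: M @ v for k, v in landmarks.points.items()}
    return replace(landmarks, points=pts, side="left" if landmarks.side == "right" else "right")
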