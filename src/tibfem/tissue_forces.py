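"""Constitutive laws for ligaments and cartilage contact, and force assembly.

Ligament tension follows the two-branch force-elongation law used throughout
the multibody knee-modelling literature: a quadratic "toe" region with
stiffness ``K_Q`` (N/mm^2) blending into a linear region with stiffness
``K_L`` (N/mm).  With the transition strain chosen per element as

    epsilon1 = K_L / (4 * K_Q * L0)

the quadratic branch on strains [0, 2*epsilon1] and the linear branch
``K_L * (L - L0*(1 + epsilon1))`` beyond meet with continuous value and
slope.  A ``literal`` mode switches branches at ``epsilon1`` itself
(discontinuous) for comparison.

Contact follows a penalty law ``F = k * delta^p + delta_rate * C * h(delta)``
with a cubic smooth step ``h`` over the transition interval ``delta_c``,
clamped below at zero so contact never pulls.  Default constants:
k = 500 N/mm^p, p = 1.5, delta_c = 0.01 mm, C = 5 kg/s.
"""

from __future__ import annotations

import numpy as np

from . import geometry
from .jcs import RigidState
from .model import ContactParams, KneeModel, LigamentSpec, LigamentState, LIGAMENT_NAMES

__all__ = [
    "DEFAULT_LIGAMENT_PARAMS",
    "strain",
    "slack_length",
    "transition_strain",
    "ligament_tension",
    "ligament_energy",
    "smooth_step",
    "contact_force",
    "contact_energy",
    "ligament_states",
    "assemble_wrench",
    "transport_torque",
]

# Default material table: (K_Q [N/mm^2], K_L [N/mm], e [-]) per element.
# The stiffnesses are literature-typical per-bundle values for multibody knee
# models; the expansion constants encode which structures carry load near full
# extension (e < 1: pre-tensioned there) versus engaging only in flexion
# (e >= 1).  All three are meant to be overridden per subject via the
# parameter YAML.
DEFAULT_LIGAMENT_PARAMS: dict[str, tuple[float, float, float]] = {
    "aACL":  (45.0, 110.0, 1.080),
    "pACL":  (40.0,  90.0, 0.985),
    "aPCL":  (40.0, 100.0, 1.060),
    "pPCL":  (50.0, 120.0, 1.037),
    "dMCLa": (20.0,  45.0, 1.080),
    "dMCLp": (20.0,  45.0, 0.987),
    "oMCLa": (18.0,  40.0, 0.989),
    "oMCLp": (18.0,  40.0, 0.990),
    "sMCL":  (25.0,  80.0, 0.995),
    "ALL":   (15.0,  35.0, 1.080),
    "LCL":   (30.0,  70.0, 0.993),
    "OPL":   (15.0,  40.0, 0.992),
    "APL":   (12.0,  35.0, 0.993),
    "mCAP":  (20.0,  50.0, 0.985),
    "lCAP":  (20.0,  50.0, 0.989),
}
assert set(DEFAULT_LIGAMENT_PARAMS) == set(LIGAMENT_NAMES)


def strain(L, L0):
    """Engineering strain (L - L0) / L0."""
    L0 = np.asarray(L0, float)
    if np.any(L0 <= 0):
        raise ValueError("slack length L0 must be positive")
    return (np.asarray(L, float) - L0) / L0


def slack_length(e: float, Le: float) -> float:
    """Slack length from the expansion constant and the full-extension length."""
    if e <= 0 or Le <= 0:
        raise ValueError("expansion constant and full-extension length must be positive")
    return e * Le


def transition_strain(K_Q: float, K_L: float, L0: float) -> float:
    """Per-element transition strain making the two branches C1-continuous."""
    if K_Q <= 0 or K_L <= 0 or L0 <= 0:
        raise ValueError("arguments must be positive")
    return K_L / (4.0 * K_Q * L0)


def _require_initialized(spec: LigamentSpec) -> None:
    if not spec.initialized:
        raise ValueError(f"ligament {spec.name!r} has no slack length; "
                         "run slack-length initialization first")


def ligament_tension(spec: LigamentSpec, L, mode: str = "smooth"):
    """Tension (N) of one element at insertion-to-insertion length ``L`` (mm).

    ``mode='smooth'`` (default): quadratic on strains [0, 2*eps1], linear
    beyond, continuous in value and slope.  ``mode='literal'`` switches
    branches at eps1 (the printed form, discontinuous there).
    """
    _require_initialized(spec)
    L = np.asarray(L, float)
    L0, eps1 = spec.L0, spec.epsilon1
    eps = strain(L, L0)
    quad = spec.K_Q * (L - L0) ** 2
    lin = spec.K_L * (L - L0 * (1.0 + eps1))
    if mode == "smooth":
        switch = 2.0 * eps1
    elif mode == "literal":
        switch = eps1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    F = np.where(eps < 0, 0.0, np.where(eps <= switch, quad, lin))
    F = np.maximum(F, 0.0)
    return float(F) if F.ndim == 0 else F


def ligament_energy(spec: LigamentSpec, L):
    """Strain energy (N*mm): integral of the smooth-mode tension over length."""
    _require_initialized(spec)
    L = np.asarray(L, float)
    L0, eps1, K_Q, K_L = spec.L0, spec.epsilon1, spec.K_Q, spec.K_L
    Lstar = L0 * (1.0 + 2.0 * eps1)
    E_quad = K_Q * np.clip(L - L0, 0.0, None) ** 3 / 3.0
    E_star = K_Q * (Lstar - L0) ** 3 / 3.0
    x = L - L0 * (1.0 + eps1)
    E_lin = E_star + 0.5 * K_L * (x ** 2 - (L0 * eps1) ** 2)
    E = np.where(L <= Lstar, E_quad, E_lin)
    return float(E) if E.ndim == 0 else E


def smooth_step(delta, delta_c: float):
    """Unity-gain cubic step: 0 below 0, 1 above ``delta_c``, C1 at both ends."""
    if delta_c <= 0:
        raise ValueError("delta_c must be positive")
    x = np.clip(np.asarray(delta, float) / delta_c, 0.0, 1.0)
    h = x * x * (3.0 - 2.0 * x)
    return float(h) if h.ndim == 0 else h


def contact_force(delta, delta_rate=0.0, params: ContactParams | None = None):
    """Scalar penalty contact law (N): ``k*delta^p`` plus smoothed damping.

    Zero for separated surfaces; clamped at zero so contact never adheres.
    """
    params = params or ContactParams()
    delta = np.asarray(delta, float)
    rate = np.asarray(delta_rate, float)
    static = params.k * np.clip(delta, 0.0, None) ** params.p
    damping = rate * params.C * smooth_step(delta, params.delta_c)
    F = np.where(delta < 0, 0.0, np.maximum(static + damping, 0.0))
    return float(F) if F.ndim == 0 else F


def contact_energy(contacts: geometry.ContactSet, params: ContactParams) -> float:
    """Penalty potential (N*mm) of the static part of the contact law."""
    if len(contacts) == 0:
        return 0.0
    per_point = params.k * contacts.deltas ** (params.p + 1.0) / (params.p + 1.0)
    if params.aggregation == "deepest":
        return float(np.max(per_point * contacts.weights))
    return float(np.sum(per_point * contacts.areas * contacts.weights))


def ligament_states(model: KneeModel, femur: RigidState, tibia: RigidState,
                    require_initialized: bool = True) -> list[LigamentState]:
    """Length, strain and tension of all 15 elements at the given pose."""
    states = []
    for lig in model.ligaments:
        f = femur.frame.to_parent(lig.femoral_mm)
        t = tibia.frame.to_parent(lig.tibial_mm)
        d = f - t
        L = float(np.linalg.norm(d))
        if lig.initialized:
            eps = float(strain(L, lig.L0))
            F = float(ligament_tension(lig, L))
        elif require_initialized:
            _require_initialized(lig)
        else:
            eps, F = 0.0, 0.0
        states.append(LigamentState(name=lig.name, L=L, epsilon=eps,
                                    tension=F, direction=d / L))
    return states


def _contact_point_forces(contacts: geometry.ContactSet, params: ContactParams):
    """Per-point force magnitudes on the tibia along the femoral outward normal."""
    mags = contact_force(contacts.deltas, contacts.delta_rates, params)
    if params.aggregation == "deepest":
        out = np.zeros(len(contacts))
        if len(contacts):
            i = int(np.argmax(contacts.deltas))
            out[i] = contact_force(float(contacts.deltas[i]),
                                   float(contacts.delta_rates[i]), params) \
                * contacts.weights[i]
        return out
    return mags * contacts.areas * contacts.weights


def assemble_wrench(model: KneeModel, femur: RigidState, tibia: RigidState):
    """Generalized force on the tibia about its origin.

    Returns ``(force [N], torque [N*mm], ligament states, contact set)``.
    The equal-and-opposite femoral wrench is ``(-force,
    transport_torque(-force, -torque, tibia origin, femur origin))``.
    """
    if not model.initialized:
        raise ValueError("model ligaments are not initialized")
    O_t = tibia.frame.origin
    force = np.zeros(3)
    torque = np.zeros(3)

    states = ligament_states(model, femur, tibia)
    for lig, st in zip(model.ligaments, states):
        if st.tension == 0.0:
            continue
        f_t = st.tension * st.direction          # pulls tibial insertion femur-ward
        r = tibia.frame.to_parent(lig.tibial_mm) - O_t
        force += f_t
        torque += np.cross(r, f_t)

    contacts = geometry.penetration_query(model.femur_cartilage, femur,
                                          model.tibia_cartilage, tibia)
    if len(contacts):
        mags = _contact_point_forces(contacts, model.contact)
        # contact pushes the tibia away from the femur: along -normal
        f_pts = -contacts.normals * mags[:, None]
        force += f_pts.sum(axis=0)
        torque += np.cross(contacts.locations - O_t, f_pts).sum(axis=0)
    return force, torque, states, contacts


def transport_torque(force: np.ndarray, torque: np.ndarray,
                     about: np.ndarray, to: np.ndarray) -> np.ndarray:
    """Re-express a wrench torque about a different reference point."""
    return np.asarray(torque, float) + np.cross(np.asarray(about, float) - np.asarray(to, float),
                                                np.asarray(force, float))
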