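"""Quasi-static passive-flexion simulation.

Flexion is the prescribed (independent) motion: the femur is hinged to
ground about its medio-lateral axis at the femoral origin, and at each
commanded flexion angle the remaining five joint coordinates of the tibia —
internal-external rotation, adduction, and the three joint translations —
are solved to static equilibrium.  Equilibrium is found by minimising the
total potential energy (ligament strain energy plus contact penalty energy)
over those five coordinates with an analytic gradient: the generalized force
conjugate to each coordinate is the tibial wrench projected onto the
coordinate's rigid-body tangent.

Slack lengths are initialised from the full-extension configuration: the
joint is brought to zero flexion under contact alone (with a light seating
preload standing in for the examiner's hands), the insertion-to-insertion
lengths ``Le`` are measured there, and ``L0 = e * Le`` per element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import geometry, tissue_forces
from .jcs import JointCoordinates, RigidState, BodyFrame, compose_joint, decompose_joint
from .model import KneeModel

__all__ = [
    "EquilibriumSettings",
    "EquilibriumReport",
    "TrajectorySet",
    "estimate_full_extension",
    "initialize_slack_lengths",
    "relax_to_equilibrium",
    "solve_at",
    "seat_pose",
    "run_passive_flexion",
    "femur_state_at",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "TRAJECTORY_COLUMNS",
]

logger = logging.getLogger(__name__)

_ANG_SCALE = 20.0  # mm-equivalent lever arm for the rotational coordinates


@dataclass(frozen=True)
class EquilibriumSettings:
    """Solver tolerances and continuation parameters.

    Residual tolerances are on the generalized forces: N for the three
    translations, N*mm for the two rotations.
    """

    tol_force: float = 1e-3      # N
    tol_torque: float = 1e-3     # N*mm
    max_iter: int = 800
    step_deg: float = 0.5        # continuation step in flexion
    min_step_deg: float = 0.0625  # halve-on-failure floor
    warm_start: bool = True
    mode: str = "quasi-static"
    trace_energy: bool = False
    # light axial compression (N) along the tibial long axis, standing in for
    # the examiner keeping the joint reduced during passive manipulation;
    # without it a pose with every ligament slack and no contact would be a
    # (physically meaningless) equilibrium
    preload_N: float = 20.0

    def __post_init__(self):
        if self.tol_force <= 0 or self.tol_torque <= 0 or self.step_deg <= 0:
            raise ValueError("tolerances and step must be positive")
        if self.mode not in ("quasi-static", "dynamic-relaxation"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class EquilibriumReport:
    converged: bool
    residual: np.ndarray          # generalized force [gamma, adduction, S1, S2, S3]
    residual_force: float         # max |Q| over translations, N
    residual_torque: float        # max |Q| over rotations, N*mm
    iterations: int
    energy: float
    x: np.ndarray                 # raw solved coordinates [gamma, add, S1, S2, S3]
    energy_trace: list = field(default_factory=list)
    lig_states: list = field(default_factory=list)   # at the solution
    contacts: object = None                          # ContactSet at the solution


def femur_state_at(alpha: float) -> RigidState:
    """Femoral pose for prescribed flexion ``alpha`` (rad): hinge to ground.

    Ground coincides with the femoral frame at full extension; the femur
    rotates by ``alpha`` about the common X axis at the femoral origin
    (thigh reclining posteriorly) so the relative tibiofemoral flexion
    equals ``alpha``.
    """
    c, s = np.cos(alpha), np.sin(alpha)
    return RigidState(frame=BodyFrame(origin=np.zeros(3),
                                      X=np.array([1.0, 0.0, 0.0]),
                                      Y=np.array([0.0, c, s]),
                                      Z=np.array([0.0, -s, c])))


def _raw_jc(alpha: float, x: np.ndarray) -> JointCoordinates:
    gamma, add, S1, S2, S3 = x
    return JointCoordinates(alpha=alpha, beta=np.pi / 2 - add, gamma=gamma,
                            S1=S1, S2=S2, S3=S3)


def _tibia_state(femur: RigidState, alpha: float, x: np.ndarray) -> RigidState:
    return compose_joint(_raw_jc(alpha, x), femur, side="right")


def _energy_and_gradient(model: KneeModel, femur: RigidState, alpha: float,
                         x: np.ndarray, include_ligaments: bool = True,
                         extra=None):
    """Total potential energy and its gradient w.r.t. the five coordinates.

    The gradient is minus the generalized force: the tibial wrench projected
    onto the rigid-body tangents of (gamma, adduction, S1, S2, S3).
    """
    gamma, add, S1, S2, S3 = x
    tibia = _tibia_state(femur, alpha, x)
    Ff = femur.frame
    e1 = Ff.X
    e2 = np.cos(alpha) * Ff.Y - np.sin(alpha) * Ff.Z
    v = np.cross(e1, e2)
    beta = np.pi / 2 - add
    e3 = np.cos(beta) * e1 + np.sin(beta) * v
    O_t = tibia.frame.origin

    E = 0.0
    F_net = np.zeros(3)
    T_net = np.zeros(3)
    lig_states = []

    if include_ligaments:
        lig_states = tissue_forces.ligament_states(model, femur, tibia)
        for lig, st in zip(model.ligaments, lig_states):
            E += tissue_forces.ligament_energy(lig, st.L)
            if st.tension > 0.0:
                f_vec = st.tension * st.direction
                r = tibia.frame.to_parent(lig.tibial_mm) - O_t
                F_net += f_vec
                T_net += np.cross(r, f_vec)

    contacts = geometry.penetration_query(model.femur_cartilage, femur,
                                          model.tibia_cartilage, tibia)
    if len(contacts):
        E += tissue_forces.contact_energy(contacts, model.contact)
        mags = tissue_forces._contact_point_forces(contacts, model.contact)
        f_pts = -contacts.normals * mags[:, None]  # push tibia away from femur
        F_net += f_pts.sum(axis=0)
        T_net += np.cross(contacts.locations - O_t, f_pts).sum(axis=0)

    e2xe3 = np.cross(e2, e3)
    Q = np.array([
        np.dot(T_net, e3),                              # gamma
        np.dot(F_net, S3 * e2xe3) + np.dot(T_net, e2),  # adduction
        np.dot(F_net, e1),                              # S1
        np.dot(F_net, e2),                              # S2
        np.dot(F_net, e3),                              # S3
    ])
    grad = -Q
    if extra is not None:
        E_x, g_x = extra(x)
        E += E_x
        grad = grad + g_x
    return E, grad, lig_states, contacts


def _residual_ok(grad: np.ndarray, settings: EquilibriumSettings) -> bool:
    return (np.max(np.abs(grad[2:])) < settings.tol_force
            and np.max(np.abs(grad[:2])) < settings.tol_torque)


def _fd_jacobian(fun_grad, x, g0=None):
    """Forward-difference Jacobian of the analytic gradient (5 extra evals)."""
    h = np.array([2e-6, 2e-6, 1e-5, 1e-5, 1e-5])
    if g0 is None:
        _, g0 = fun_grad(x)
    J = np.empty((5, 5))
    for j in range(5):
        xp = x.copy()
        xp[j] += h[j]
        _, gp = fun_grad(xp)
        J[:, j] = (gp - g0) / h[j]
    return J


def _newton_polish(fun_grad, x, settings: EquilibriumSettings, max_newton: int = 40,
                   J: np.ndarray | None = None):
    """Levenberg-damped Newton on the (analytic) generalized force.

    Solves ``Q(x) = 0`` with a finite-difference Jacobian that is reused
    between iterations (and can be warm-started via ``J``).  The Levenberg
    damping handles the zero-stiffness directions a frictionless contact
    landscape can have (e.g. sliding on the flat lateral plateau).
    Returns ``(x, grad, J)``.
    """
    scale = np.array([_ANG_SCALE, _ANG_SCALE, 1.0, 1.0, 1.0])
    _, g = fun_grad(x)
    lam = 1e-3
    rebuilt_here = False
    for _ in range(max_newton):
        if _residual_ok(g, settings):
            break
        if J is None:
            J = _fd_jacobian(fun_grad, x, g0=g)
            rebuilt_here = True
        Ju = J / scale[:, None] / scale[None, :]
        gu = g / scale
        accepted = False
        for _ in range(10):
            try:
                du = np.linalg.solve(Ju + lam * np.eye(5), -gu)
            except np.linalg.LinAlgError:
                du = np.linalg.lstsq(Ju + lam * np.eye(5), -gu, rcond=None)[0]
            if np.linalg.norm(du) > 10.0:  # scaled trust region, mm-equivalent
                du = du * (10.0 / np.linalg.norm(du))
            x_try = x + du / scale
            x_try[0] = np.clip(x_try[0], -1.2, 1.2)
            x_try[1] = np.clip(x_try[1], -np.pi / 2 + 0.05, np.pi / 2 - 0.05)
            _, g_try = fun_grad(x_try)
            if np.linalg.norm(g_try) < np.linalg.norm(g) * (1.0 - 1e-6):
                # Broyden rank-1 update keeps the cached Jacobian current
                # without finite-difference rebuilds
                dx = x_try - x
                dg = g_try - g
                denom = float(dx @ dx)
                if denom > 1e-24:
                    J = J + np.outer(dg - J @ dx, dx) / denom
                slow = np.linalg.norm(g_try) > 0.8 * np.linalg.norm(g)
                x, g = x_try, g_try
                lam = max(lam / 3.0, 1e-5)
                if slow and not rebuilt_here:
                    J = None  # stale Jacobian: rebuild next round
                accepted = True
                break
            lam *= 8.0
        if not accepted:
            if rebuilt_here:
                break  # fresh Jacobian, heavy damping, no progress: give up
            J = None
        if J is not None:
            rebuilt_here = False
    return x, g, J


def relax_to_equilibrium(model: KneeModel, femur: RigidState, tibia_guess,
                         alpha: float, settings: EquilibriumSettings | None = None,
                         include_ligaments: bool = True, extra=None,
                         _cache: dict | None = None):
    """Solve the five free coordinates to equilibrium at fixed flexion.

    ``tibia_guess`` may be a raw coordinate 5-vector ``[gamma, adduction,
    S1, S2, S3]``, a :class:`JointCoordinates`, or a :class:`RigidState`.
    Returns ``(tibia RigidState, EquilibriumReport)``.
    """
    settings = settings or EquilibriumSettings()
    if include_ligaments and not model.initialized:
        raise ValueError("model ligaments are not initialized; "
                         "run estimate_full_extension/initialize_slack_lengths first")
    if extra is None and settings.preload_N:
        extra = _axial_preload(settings.preload_N)
    if isinstance(tibia_guess, RigidState):
        jc = decompose_joint(femur, tibia_guess, side="right")
        x0 = np.array([jc.gamma, jc.adduction, jc.S1, jc.S2, jc.S3])
    elif isinstance(tibia_guess, JointCoordinates):
        x0 = np.array([tibia_guess.gamma, tibia_guess.adduction,
                       tibia_guess.S1, tibia_guess.S2, tibia_guess.S3])
    else:
        x0 = np.asarray(tibia_guess, float).reshape(5)

    scale = np.array([_ANG_SCALE, _ANG_SCALE, 1.0, 1.0, 1.0])
    trace: list[float] = []

    last_full = {}

    def fun_grad(x):
        E, g, st, cs = _energy_and_gradient(model, femur, alpha, x,
                                            include_ligaments=include_ligaments,
                                            extra=extra)
        last_full["x"], last_full["st"], last_full["cs"] = x, st, cs
        return E, g

    def fg_scaled(u):
        E, g = fun_grad(u / scale)
        return E, g / scale

    callback = None
    if settings.trace_energy:
        # record the energy at accepted iterates only (not line-search trials)
        callback = lambda uk: trace.append(fun_grad(uk / scale)[0])  # noqa: E731

    E0, g0 = fun_grad(x0)
    iters = 0
    x, g = x0, g0
    if not _residual_ok(g0, settings):
        # Newton on the analytic gradient, warm-started with the Jacobian
        # cached from the previous continuation step; this resolves the vast
        # majority of warm solves in a handful of evaluations.
        J_warm = (_cache or {}).get("J")
        x, g, J_new = _newton_polish(fun_grad, x0, settings, J=J_warm)
        iters += 1
        if not _residual_ok(g, settings):
            # globalized fallback: bounded L-BFGS descent into the basin,
            # then fresh Newton.  The box keeps line searches away from the
            # gimbal degeneracy at |adduction| = 90 deg and from physically
            # absurd poses.
            lo = np.array([x0[0] - 0.8, max(x0[1] - 0.5, -np.pi / 2 + 0.1),
                           x0[2] - 25.0, x0[3] - 25.0, x0[4] - 25.0])
            hi = np.array([x0[0] + 0.8, min(x0[1] + 0.5, np.pi / 2 - 0.1),
                           x0[2] + 25.0, x0[3] + 25.0, x0[4] + 25.0])
            if settings.trace_energy:
                trace.append(E0)
            res = minimize(fg_scaled, x0 * scale, jac=True, method="L-BFGS-B",
                           bounds=list(zip(lo * scale, hi * scale)),
                           callback=callback,
                           options={"maxiter": settings.max_iter, "ftol": 1e-16,
                                    "gtol": 0.02, "maxcor": 20})
            iters += int(res.nit)
            x, g, J_new = _newton_polish(fun_grad, res.x / scale, settings)
        if _cache is not None and J_new is not None:
            _cache["J"] = J_new
        E, g = fun_grad(x)
    else:
        E = E0

    tibia = _tibia_state(femur, alpha, x)
    if not (last_full and last_full["x"] is x):
        E, _ = fun_grad(x)
    report = EquilibriumReport(
        converged=_residual_ok(g, settings),
        residual=-g,
        residual_force=float(np.max(np.abs(g[2:]))),
        residual_torque=float(np.max(np.abs(g[:2]))),
        iterations=iters, energy=float(E), x=x, energy_trace=trace,
        lig_states=last_full["st"], contacts=last_full["cs"])
    if not report.converged:
        logger.warning("equilibrium not reached at alpha=%.2f deg: |Q|_F=%.2e N, "
                       "|Q|_T=%.2e N*mm, x=%s", np.degrees(alpha),
                       report.residual_force, report.residual_torque, x)
    return tibia, report


# ---------------------------------------------------------------------------
# seating and slack-length initialization
# ---------------------------------------------------------------------------

def _side_gaps(model: KneeModel, femur: RigidState, x: np.ndarray, alpha: float):
    """Minimum signed femoral-surface distance of medial/lateral plateau vertices."""
    tibia = _tibia_state(femur, alpha, x)
    prox = geometry._proximity(model.femur_cartilage)
    verts_ground = tibia.frame.to_parent(model.tibia_cartilage.vertices)
    pts = femur.frame.to_local(verts_ground)
    s, dist, tri = prox.nearest(pts, cutoff=None)
    nf = prox.mesh.face_normals[np.where(tri >= 0, tri, 0)]
    signed = np.where(np.einsum("ij,ij->i", pts - s, nf) >= 0, dist, -dist)
    tib_x = model.tibia_cartilage.vertices[:, 0]
    g_neg = float(np.min(signed[tib_x < 0]))
    g_pos = float(np.min(signed[tib_x > 0]))
    return np.array([g_neg, g_pos])


def seat_pose(model: KneeModel, alpha: float, target_penetration: float = 0.15,
              max_iter: int = 15) -> np.ndarray:
    """Initial coordinate guess seating both condyles onto the plateaus.

    2-variable Newton on (adduction, S3) driving the per-compartment minimum
    signed gap to a small target penetration; gamma, S1, S2 start at zero.
    """
    femur = femur_state_at(alpha)
    fem_ground = femur.frame.to_parent(model.femur_cartilage.vertices)
    S3_0 = float(fem_ground[:, 2].min() - model.tibia_cartilage.vertices[:, 2].max())
    x = np.array([0.0, 0.0, 0.0, 0.0, S3_0])
    target = np.array([-target_penetration, -target_penetration])
    h = np.array([np.radians(0.2), 0.05])  # FD steps for (adduction, S3)
    for _ in range(max_iter):
        g = _side_gaps(model, femur, x, alpha)
        if np.max(np.abs(g - target)) < 0.02:
            break
        J = np.empty((2, 2))
        for j, idx in enumerate((1, 4)):
            xp = x.copy()
            xp[idx] += h[j]
            J[:, j] = (_side_gaps(model, femur, xp, alpha) - g) / h[j]
        try:
            d = np.linalg.solve(J, target - g)
        except np.linalg.LinAlgError:
            d = np.linalg.lstsq(J, target - g, rcond=None)[0]
        d = np.clip(d, [-np.radians(3), -2.0], [np.radians(3), 2.0])
        x[1] += d[0]
        x[4] += d[1]
    return x


def _axial_preload(preload_N: float):
    """Constant compressive force along the tibial axis coordinate S3."""
    g = np.array([0.0, 0.0, 0.0, 0.0, -preload_N])

    def extra(x):
        return preload_N * (-x[4]), g
    return extra


def _seating_potential(preload_N: float = 50.0, k_center: float = 5.0,
                       k_rot: float = 500.0):
    """Regularizer for the contact-only full-extension phase.

    A light compressive preload (pulling the tibia proximally along e3) and
    centering springs emulate the examiner holding the joint reduced;
    without them a contact-only equilibrium is indeterminate because contact
    forces only push, and frictionless sliding on a flat plateau leaves
    near-zero-stiffness directions.  The springs bias the measured
    full-extension pose by well under a millimetre at these stiffnesses.
    """
    def extra(x):
        gamma, add, S1, S2, S3 = x
        E = (preload_N * (-S3)  # decreasing -S3 (moving proximally) lowers E
             + 0.5 * k_center * (S1 ** 2 + S2 ** 2)
             + 0.5 * k_rot * (gamma ** 2 + add ** 2) * _ANG_SCALE)
        g = np.array([k_rot * gamma * _ANG_SCALE, k_rot * add * _ANG_SCALE,
                      k_center * S1, k_center * S2, -preload_N])
        return E, g
    return extra


def estimate_full_extension(model: KneeModel, start_alpha_deg: float = 20.0,
                            settings: EquilibriumSettings | None = None,
                            start_guess: np.ndarray | None = None):
    """Bring the joint to zero flexion under contact alone and measure Le.

    Continuation from ``start_alpha_deg`` down to 0 in ``settings.step_deg``
    steps, solving a contact-only (ligaments inactive) seated equilibrium at
    each step.  Returns ``(femur_state, tibia_state, Le)`` at full extension,
    with ``Le`` the per-ligament insertion-to-insertion length table (mm).
    On non-convergence the last converged flexion angle is reported in the
    raised error.
    """
    settings = settings or EquilibriumSettings()
    # the seating phase is auxiliary (its output is the Le table, accurate to
    # ~0.1 mm); never chase tolerances tighter than the default here
    settings = replace(settings,
                       tol_force=max(settings.tol_force, 1e-3),
                       tol_torque=max(settings.tol_torque, 1e-3),
                       max_iter=max(settings.max_iter, 800))
    alphas = np.radians(np.arange(start_alpha_deg, -1e-9, -settings.step_deg))
    if alphas[-1] > 1e-12:
        alphas = np.append(alphas, 0.0)
    extra = _seating_potential()
    x = seat_pose(model, float(alphas[0])) if start_guess is None else np.asarray(start_guess, float)
    last_ok = None
    cache: dict = {}
    for a in alphas:
        femur = femur_state_at(float(a))
        tibia, rep = relax_to_equilibrium(model, femur, x, float(a), settings,
                                          include_ligaments=False, extra=extra,
                                          _cache=cache)
        if not rep.converged:
            # reseed from a fresh geometric seating before giving up
            tibia, rep = relax_to_equilibrium(model, femur,
                                              seat_pose(model, float(a)), float(a),
                                              settings, include_ligaments=False,
                                              extra=extra, _cache={})
        if not rep.converged:
            raise RuntimeError(
                f"full-extension continuation failed at alpha="
                f"{np.degrees(a):.2f} deg (last converged: "
                f"{'none' if last_ok is None else f'{np.degrees(last_ok):.2f} deg'})")
        x = rep.x
        last_ok = float(a)
    states = tissue_forces.ligament_states(model, femur, tibia,
                                           require_initialized=False)
    Le = {st.name: st.L for st in states}
    return femur, tibia, Le


def initialize_slack_lengths(model: KneeModel, Le: dict) -> KneeModel:
    """Store ``L0 = e * Le`` and the C1 transition strain on every element."""
    for lig in model.ligaments:
        if lig.name not in Le:
            raise KeyError(f"Le table missing element {lig.name!r}")
        L0 = tissue_forces.slack_length(lig.e, float(Le[lig.name]))
        lig.L0 = L0
        lig.epsilon1 = tissue_forces.transition_strain(lig.K_Q, lig.K_L, L0)
    return model


def initialize_from_full_extension(model: KneeModel, start_alpha_deg: float = 20.0,
                                   settings: EquilibriumSettings | None = None):
    """Convenience: full-extension estimate + slack-length initialization."""
    femur, tibia, Le = estimate_full_extension(model, start_alpha_deg, settings)
    initialize_slack_lengths(model, Le)
    return femur, tibia, Le


def solve_at(model: KneeModel, alpha: float, settings: EquilibriumSettings | None = None,
             guess: np.ndarray | None = None):
    """Direct (cold-start) equilibrium solve at one flexion angle."""
    settings = settings or EquilibriumSettings()
    femur = femur_state_at(alpha)
    x0 = seat_pose(model, alpha) if guess is None else np.asarray(guess, float)
    return relax_to_equilibrium(model, femur, x0, alpha, settings)


# ---------------------------------------------------------------------------
# passive flexion sweep
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = (
    ["cycle", "sample", "flexion_deg", "adduction_deg", "internal_rotation_deg",
     "S1_mm", "S2_mm", "S3_mm", "q1_mm", "q2_mm", "q3_mm"]
    + [f"lig_{n}_N" for n in
       ("aACL", "pACL", "aPCL", "pPCL", "dMCLa", "dMCLp", "oMCLa", "oMCLp",
        "sMCL", "ALL", "LCL", "OPL", "APL", "mCAP", "lCAP")]
    + ["contact_total_N", "converged", "residual_force_N", "residual_torque_Nmm"]
)


@dataclass
class TrajectorySet:
    """Per-sample joint coordinates and force traces of a flexion sweep."""

    frame: pd.DataFrame
    settings: EquilibriumSettings

    def __post_init__(self):
        ok = self.frame[self.frame["converged"]]
        if len(ok):
            if (ok["residual_force_N"] >= self.settings.tol_force).any() or \
               (ok["residual_torque_Nmm"] >= self.settings.tol_torque).any():
                raise AssertionError("accepted sample exceeds the equilibrium tolerance")

    @property
    def n_flagged(self) -> int:
        return int((~self.frame["converged"]).sum())

    def cycle(self, k: int) -> pd.DataFrame:
        return self.frame[self.frame["cycle"] == k]


def run_passive_flexion(model: KneeModel, cycles, settings: EquilibriumSettings | None = None):
    """Sweep the prescribed flexion cycles, solving equilibrium per sample.

    ``cycles`` is a sequence of flexion profiles in degrees.  Warm starts
    carry the solution between consecutive samples; a failing sample triggers
    step-halving sub-continuation down to ``settings.min_step_deg`` before
    the sample is flagged and the sweep continues.
    """
    settings = settings or EquilibriumSettings()
    if not model.initialized:
        raise ValueError("model ligaments are not initialized")

    rows = []
    x = x_prev = None
    prev_alpha = prev_alpha2 = None
    cache: dict = {}
    for ci, profile in enumerate(cycles):
        profile = np.asarray(profile, float)
        for si, a_deg in enumerate(profile):
            a = float(np.radians(a_deg))
            if x is None:
                x0 = seat_pose(model, a)
                femur = femur_state_at(a)
                tibia, rep = relax_to_equilibrium(model, femur, x0, a, settings,
                                                  _cache=cache)
                x = rep.x
            else:
                guess = x
                if x_prev is not None and prev_alpha != prev_alpha2:
                    # linear continuation predictor
                    r = (a - prev_alpha) / (prev_alpha - prev_alpha2)
                    r = float(np.clip(r, -2.0, 2.0))
                    guess = x + (x - x_prev) * r
                tibia, rep, xn = _advance(model, x, guess, prev_alpha, a,
                                          settings, cache)
                x_prev, x = x, xn
                femur = femur_state_at(a)
            prev_alpha2, prev_alpha = prev_alpha, a
            rows.append(_sample_row(model, femur, tibia, rep, ci, si, a_deg))
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    traj = TrajectorySet(frame=df, settings=settings)
    if traj.n_flagged:
        logger.warning("%d of %d samples did not converge and are flagged",
                       traj.n_flagged, len(df))
    return traj


def _advance(model, x, guess, a_from, a_to, settings, cache=None):
    """Warm-started solve at a_to, with halve-on-failure sub-continuation.

    ``guess`` may be an extrapolated predictor; ``x`` is the last converged
    solution and anchors the sub-continuation fallback.
    """
    femur = femur_state_at(a_to)
    tibia, rep = relax_to_equilibrium(model, femur, guess, a_to, settings, _cache=cache)
    if rep.converged:
        return tibia, rep, rep.x
    # a near-miss (residual within 50x tolerance) stalls on the same local
    # landscape regardless of step size: flag it without sub-continuation,
    # but keep its coordinates as the next warm start
    near_miss = (rep.residual_force < 50 * settings.tol_force
                 and rep.residual_torque < 50 * settings.tol_torque)
    if not near_miss:
        n_sub = 2
        min_step = np.radians(settings.min_step_deg)
        while abs(a_to - a_from) / n_sub >= min_step and n_sub <= 8:
            xi = x
            ok = True
            for a in np.linspace(a_from, a_to, n_sub + 1)[1:]:
                femur = femur_state_at(float(a))
                tibia, rep = relax_to_equilibrium(model, femur, xi, float(a),
                                                  settings, _cache=cache)
                if not rep.converged:
                    ok = False
                    break
                xi = rep.x
            if ok:
                return tibia, rep, rep.x
            n_sub *= 2
    # flagged: continue the sweep from the best coordinates available
    return tibia, rep, (rep.x if near_miss else x)


def _sample_row(model, femur, tibia, rep, cycle_idx, sample_idx, a_deg):
    jc = decompose_joint(femur, tibia, side=model.side)
    states = rep.lig_states or tissue_forces.ligament_states(model, femur, tibia)
    contacts = rep.contacts if rep.contacts is not None else \
        geometry.penetration_query(model.femur_cartilage, femur,
                                   model.tibia_cartilage, tibia)
    if len(contacts):
        mags = tissue_forces._contact_point_forces(contacts, model.contact)
        f_total = float(np.linalg.norm((-contacts.normals * mags[:, None]).sum(axis=0)))
    else:
        f_total = 0.0
    row = {
        "cycle": cycle_idx, "sample": sample_idx, "flexion_deg": float(a_deg),
        "adduction_deg": jc.adduction_deg, "internal_rotation_deg": jc.gamma_deg,
        "S1_mm": jc.S1, "S2_mm": jc.S2, "S3_mm": jc.S3,
        "q1_mm": jc.q1, "q2_mm": jc.q2, "q3_mm": jc.q3,
        "contact_total_N": f_total, "converged": bool(rep.converged),
        "residual_force_N": rep.residual_force,
        "residual_torque_Nmm": rep.residual_torque,
    }
    for st in states:
        row[f"lig_{st.name}_N"] = st.tension
    return row


def write_trajectory_csv(traj: TrajectorySet, path, seed=None, config_hash=None) -> None:
    """CSV with one metadata comment line then a single header line."""
    meta = [f"seed={seed}" if seed is not None else "seed=NA",
            f"config={config_hash}" if config_hash is not None else "config=NA"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# tibfem-trajectory " + " ".join(meta) + "\n")
        traj.frame.to_csv(fh, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
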