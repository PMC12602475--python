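"""Parametric synthetic-knee generator.

Builds a complete :class:`~tibfem.model.KneeModel` — bone and cartilage
surface meshes, anatomical landmarks, 15 ligament attachment pairs — plus
multi-cycle passive-flexion profiles, without any imaging input.  The
geometry reproduces the qualitative features a tibiofemoral contact model
needs and nothing more:

* two femoral condyles whose sagittal radius of curvature decreases from the
  distal/anterior region toward the posterior region (larger radius near
  extension contact, smaller in deep flexion),
* a concave (dished) medial tibial plateau and a flat lateral plateau,
* cartilage surfaces offset outward from the bone surfaces,
* anatomically plausible attachment sites for all 15 tensile elements.

Everything is deterministic for a given ``(preset, seed)``; the seed drives
small global size perturbations and cycle-to-cycle variation of the flexion
profiles, emulating repeat manual manipulation of one specimen.

All surfaces are emitted directly in their body frames: the frame-defining
landmark pairs are placed symmetrically so the frames reconstructed from
landmarks coincide with the generator's canonical axes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceMesh
from .jcs import LandmarkSet
from .model import ContactParams, KneeModel, LigamentSpec, LIGAMENT_NAMES
from .tissue_forces import DEFAULT_LIGAMENT_PARAMS

__all__ = ["PRESETS", "generate_synthetic_knee", "default_flexion_cycles"]


@dataclass(frozen=True)
class _Preset:
    """Mesh resolutions and scale of one synthetic-knee preset."""
    n_theta: int      # condyle sweep samples (sagittal direction)
    n_psi: int        # condyle cross-section samples
    n_r: int          # plateau radial rings
    n_t: int          # plateau angular samples
    bone_decimation: int  # coarse factor for bone (non-contact) meshes


PRESETS: dict[str, _Preset] = {
    # ~2.4k cartilage vertices per body (pair ~4.8k)
    "default": _Preset(n_theta=48, n_psi=25, n_r=20, n_t=56, bone_decimation=3),
    # fast fixture for unit tests (fine enough that faceting noise stays
    # well below the solver tolerance)
    "coarse": _Preset(n_theta=34, n_psi=19, n_r=14, n_t=40, bone_decimation=2),
    # refinement studies
    "fine": _Preset(n_theta=72, n_psi=37, n_r=30, n_t=84, bone_decimation=4),
}


def _sstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _grid_faces(n_u: int, n_v: int) -> np.ndarray:
    faces = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            v0 = i * n_v + j
            faces.append([v0, v0 + n_v, v0 + 1])
            faces.append([v0 + 1, v0 + n_v, v0 + n_v + 1])
    return np.asarray(faces, np.int64)


def _orient_outward(verts: np.ndarray, faces: np.ndarray, outward_ref: np.ndarray) -> np.ndarray:
    """Flip faces whose normal disagrees with a per-vertex outward hint."""
    tri = verts[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    hint = outward_ref[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", n, hint) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    return faces


def _condyle_surface(x_center: float, hub_y: float, hub_z: float,
                     r_ant: float, r_post: float, r_trans: float,
                     n_theta: int, n_psi: int,
                     t_range=(-35.0, 140.0), psi_max: float = 45.0):
    """One femoral condyle (femoral frame, mm): elliptic sagittal profile.

    The sagittal guide curve is an ellipse arc about the hub whose radius of
    curvature varies continuously from ``r_ant`` at the distal (extension)
    contact to ``r_post`` at the posterior (deep-flexion) contact — convex
    everywhere, which matters for the interior distance field the contact
    query relies on.  The cross-section is a circular arc of radius
    ``r_trans``; ``t = 0`` points distally, increasing toward posterior.
    """
    a = (r_ant ** 2 * r_post) ** (1.0 / 3.0)  # posterior semi-axis
    b = (r_post ** 2 * r_ant) ** (1.0 / 3.0)  # distal semi-axis
    t = np.radians(np.linspace(t_range[0], t_range[1], n_theta))
    ps = np.radians(np.linspace(-psi_max, psi_max, n_psi))
    T, PS = np.meshgrid(t, ps, indexing="ij")

    cy = -a * np.sin(T)          # ellipse arc about the hub
    cz = -b * np.cos(T)
    ny = -np.sin(T) / a          # outward sagittal normal (unnormalised)
    nz = -np.cos(T) / b
    nn = np.hypot(ny, nz)
    ny, nz = ny / nn, nz / nn

    x = x_center + r_trans * np.sin(PS)
    y = hub_y + cy - r_trans * (1.0 - np.cos(PS)) * ny
    z = hub_z + cz - r_trans * (1.0 - np.cos(PS)) * nz
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    # outward hint: away from the local tube centre
    qy = hub_y + cy - r_trans * ny
    qz = hub_z + cz - r_trans * nz
    hint = verts - np.column_stack([np.full(verts.shape[0], x_center),
                                    qy.ravel(), qz.ravel()])
    faces = _grid_faces(n_theta, n_psi)
    return verts, _orient_outward(verts, faces, hint)


def _condyle_semi_axes(r_ant: float, r_post: float):
    a = (r_ant ** 2 * r_post) ** (1.0 / 3.0)
    b = (r_post ** 2 * r_ant) ** (1.0 / 3.0)
    return a, b


def _disc_surface(center: np.ndarray, radius: float, n_r: int, n_t: int,
                  z_of_r, normal_up: bool = True):
    """Polar disc patch with height profile ``z_of_r(r)`` (tibial frame)."""
    verts = [np.array([center[0], center[1], center[2] + z_of_r(0.0)])]
    faces = []
    ring_start = [0]
    for i in range(1, n_r + 1):
        r = radius * i / n_r
        ang = np.linspace(0, 2 * np.pi, n_t, endpoint=False)
        ring_start.append(len(verts))
        for a in ang:
            verts.append(np.array([center[0] + r * np.cos(a),
                                   center[1] + r * np.sin(a),
                                   center[2] + z_of_r(r)]))
    verts = np.asarray(verts)
    # fan to first ring
    s1 = ring_start[1]
    for j in range(n_t):
        faces.append([0, s1 + j, s1 + (j + 1) % n_t])
    # quads between rings
    for i in range(1, n_r):
        a0, b0 = ring_start[i], ring_start[i + 1]
        for j in range(n_t):
            j1 = (j + 1) % n_t
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    faces = np.asarray(faces, np.int64)
    hint = np.tile([0.0, 0.0, 1.0 if normal_up else -1.0], (len(verts), 1))
    return verts, _orient_outward(verts, faces, hint)


def _merge(parts):
    verts, faces, off = [], [], 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + off)
        off += len(v)
    return np.vstack(verts), np.vstack(faces)


# --------------------------------------------------------------------------
# attachment sites (right knee, body frames, mm, at scale = 1)
# --------------------------------------------------------------------------
# Tibial points are anatomical footprints: intercondylar eminence region for
# the cruciates, plateau margins for the deep/oblique MCL and capsule, the
# distal medial tibia (sMCL) and the posterolateral tibia/fibular-head region
# (LCL, APL).  Femoral points cluster in the sagittal plane around the centre
# of the posterior condylar arc — the knee's effective flexion axis — which
# is what keeps ligament excursions over the flexion range down to a few mm
# (collaterals near-isometric, cruciate bundles reciprocally phased).  The
# residual sagittal offset of each femoral point sets the amplitude of its
# length-vs-flexion curve and the offset direction sets where in the arc the
# element is longest: posterior structures and pACL longest at extension,
# PCL bundles/dMCLa/ALL lengthening with flexion, aACL longest mid-flexion.
_ATTACHMENTS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    #            femoral (X lat, Y ant, Z prox)   tibial
    "aACL":  ((7.0, -5.5, 10.0),   (4.0, 12.0, -4.0)),
    "pACL":  ((8.0, -9.5, 14.5),   (0.0, 8.0, -4.0)),
    "aPCL":  ((-7.0, -12.5, 11.0), (-1.0, -20.0, -10.0)),
    "pPCL":  ((-8.0, -12.5, 11.0), (-3.0, -22.0, -13.0)),
    "dMCLa": ((-38.0, -7.5, 15.0), (-24.0, 8.0, -12.0)),
    "dMCLp": ((-38.0, -10.0, 15.5), (-24.0, -6.0, -12.0)),
    "oMCLa": ((-39.0, -10.0, 15.5), (-22.0, -12.0, -16.0)),
    "oMCLp": ((-38.0, -9.5, 16.5), (-18.0, -18.0, -16.0)),
    "sMCL":  ((-41.0, -10.5, 15.5), (-17.0, 3.0, -70.0)),
    "ALL":   ((40.0, -5.0, 7.0),   (27.0, 12.0, -22.0)),
    "LCL":   ((41.0, -7.0, 25.0),  (34.0, -12.0, -40.0)),
    # the popliteal ligaments run obliquely (crossed insertions)
    "OPL":   ((16.0, -4.0, 26.5),  (-14.0, -20.0, -12.0)),
    "APL":   ((-16.0, -11.0, 14.5), (30.0, -14.0, -36.0)),
    "mCAP":  ((-22.0, -14.0, 13.5), (-18.0, -16.0, -10.0)),
    "lCAP":  ((22.0, -5.5, 26.5),  (18.0, -16.0, -10.0)),
}
assert set(_ATTACHMENTS) == set(LIGAMENT_NAMES)


def default_flexion_cycles(seed: int, n_cycles: int = 4, step_deg: float = 0.5,
                           alpha_min: float = 7.0, alpha_max: float = 112.0):
    """Four up-down flexion profiles (deg) with seeded cycle-to-cycle variation.

    Each cycle runs from near-extension to deep flexion and back, the way a
    passive cycle is imposed by hand; the turning points wander by a fraction
    of a degree between repetitions.
    """
    rng = np.random.default_rng(np.uint32(seed) + 101)
    cycles = []
    for _ in range(n_cycles):
        lo = alpha_min + rng.uniform(0.05, 0.8)
        hi = alpha_max - rng.uniform(0.05, 1.2)
        up = np.arange(lo, hi, step_deg)
        down = up[::-1]
        cycles.append(np.concatenate([up, [hi], down]))
    return cycles


def generate_synthetic_knee(preset: str = "default", seed: int = 0):
    """Deterministic synthetic knee model plus four-cycle flexion profiles.

    Returns ``(KneeModel, cycles)`` where ``cycles`` is a list of flexion
    profiles in degrees.  Raises ``KeyError`` for an unknown preset.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    p = PRESETS[preset]
    rng = np.random.default_rng(np.uint32(seed))
    scale = 1.0 + 0.04 * float(rng.standard_normal())  # overall joint size
    cart = 2.5 * scale  # cartilage thickness offset, mm

    # ---- femoral condyles (femoral frame) --------------------------------
    # hubs are placed so the distal cartilage surface sits 12 mm below Ofem;
    # the centre of curvature of the extension contact then lies near
    # (y, z) = (-8, 20) mm, the effective flexion axis the attachment sites
    # cluster around
    hub_y = -8.0 * scale
    distal_z = -12.0 * scale
    r_trans = 18.0 * scale
    med = dict(x_center=-22.0 * scale, r_ant=32.5 * scale, r_post=20.0 * scale)
    lat = dict(x_center=22.0 * scale, r_ant=32.0 * scale, r_post=18.5 * scale)
    fem_cart_parts, fem_bone_parts = [], []
    hub_zs, post_ys = [], []
    for c in (med, lat):
        a, b = _condyle_semi_axes(c["r_ant"], c["r_post"])
        hub_z = distal_z + b
        hub_zs.append(hub_z)
        post_ys.append(hub_y - a)
        fem_cart_parts.append(_condyle_surface(
            c["x_center"], hub_y, hub_z, c["r_ant"], c["r_post"], r_trans,
            p.n_theta, p.n_psi))
        fem_bone_parts.append(_condyle_surface(
            c["x_center"], hub_y, hub_z, c["r_ant"] - cart, c["r_post"] - cart,
            r_trans - cart, max(8, p.n_theta // p.bone_decimation),
            max(5, p.n_psi // p.bone_decimation)))
    femur_cartilage = SurfaceMesh(*_merge(fem_cart_parts), frame="femur")
    femur_bone = SurfaceMesh(*_merge(fem_bone_parts), frame="femur")

    # ---- tibial plateaus (tibial frame) ----------------------------------
    plateau_z = -3.0 * scale
    plateau_r = 17.0 * scale
    dish_R = 40.0 * scale
    med_center = np.array([-20.0 * scale, -2.0 * scale, plateau_z])
    lat_center = np.array([20.0 * scale, -2.0 * scale, plateau_z])
    tib_cart_parts = [
        _disc_surface(med_center, plateau_r, p.n_r, p.n_t,
                      z_of_r=lambda r: r * r / (2.0 * dish_R)),     # concave medial
        _disc_surface(lat_center, plateau_r, p.n_r, p.n_t,
                      z_of_r=lambda r: 0.0),                        # flat lateral
    ]
    nrb, ntb = max(5, p.n_r // p.bone_decimation), max(12, p.n_t // p.bone_decimation)
    tib_bone_parts = [
        _disc_surface(med_center - [0, 0, cart], plateau_r, nrb, ntb,
                      z_of_r=lambda r: r * r / (2.0 * dish_R)),
        _disc_surface(lat_center - [0, 0, cart], plateau_r, nrb, ntb,
                      z_of_r=lambda r: 0.0),
    ]
    tibia_cartilage = SurfaceMesh(*_merge(tib_cart_parts), frame="tibia")
    tibia_bone = SurfaceMesh(*_merge(tib_bone_parts), frame="tibia")

    # ---- landmarks -------------------------------------------------------
    # Frame-defining pairs are exactly symmetric so the frames rebuilt from
    # landmarks coincide with the canonical body axes used above.
    post_y = float(np.mean(post_ys))  # most posterior condyle points
    ppc_z = float(np.mean(hub_zs))
    lm = {
        "Ofem": [0.0, 0.0, 0.0],
        "Chip": [0.0, 0.0, 400.0 * scale],
        "Mppc": [-22.0 * scale, post_y, ppc_z],
        "Lppc": [22.0 * scale, post_y, ppc_z],
        "Mepi": [-41.0 * scale, -8.0 * scale + 0.5 * rng.standard_normal(),
                 12.0 * scale],
        "Lepi": [41.0 * scale, -8.0 * scale + 0.5 * rng.standard_normal(),
                 12.0 * scale],
        "Otib": [0.0, 0.0, 0.0],
        "Cank": [0.0, 0.0, -360.0 * scale],
        "Mctc": [-20.0 * scale, -2.0 * scale, plateau_z],
        "Lctc": [20.0 * scale, -2.0 * scale, plateau_z],
    }
    landmarks = LandmarkSet(points={k: np.asarray(v, float) for k, v in lm.items()},
                            side="right")

    # ---- ligaments -------------------------------------------------------
    ligaments = []
    for name in LIGAMENT_NAMES:
        f, t = _ATTACHMENTS[name]
        K_Q, K_L, e = DEFAULT_LIGAMENT_PARAMS[name]
        ligaments.append(LigamentSpec(name=name,
                                      femoral_mm=np.asarray(f) * scale,
                                      tibial_mm=np.asarray(t) * scale,
                                      K_Q=K_Q, K_L=K_L, e=e))

    model = KneeModel(landmarks=landmarks,
                      femur_bone=femur_bone, femur_cartilage=femur_cartilage,
                      tibia_bone=tibia_bone, tibia_cartilage=tibia_cartilage,
                      ligaments=ligaments, contact=ContactParams(),
                      name=f"synthetic-{preset}-{seed}")
    cycles = default_flexion_cycles(seed)
    return model, cycles
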