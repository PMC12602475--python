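"""Surface meshes and cartilage-on-cartilage penetration queries.

Contact detection is asymmetric by design: each vertex of the tibial
cartilage is tested against the femoral cartilage surface.  Penetration depth
is the distance to the nearest point of the femoral surface; the force
assembly weights each point by its tributary area (one third of the incident
triangle areas), so the total converges under mesh refinement.

Meshes live in their body frames; queries transform through the current
rigid states, which lets a single proximity structure (a KD-tree over
triangle centroids) be built once per mesh and reused at every pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .jcs import RigidState
from .model import KneeModel  # re-exported: KneeModel is part of the geometry surface

__all__ = [
    "SurfaceMesh",
    "ContactPoint",
    "ContactSet",
    "KneeModel",
    "penetration_query",
    "sphere_plane_oracle",
    "meshed_sphere",
    "meshed_plane",
]

logger = logging.getLogger(__name__)


@dataclass
class SurfaceMesh:
    """Triangle mesh (mm) attached to a named body frame.

    ``normals`` are outward vertex normals; face orientation must already be
    consistent (the synthetic generator and common CAD exports guarantee it).
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame: str = "ground"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face indices out of range")
        if np.any(self.face_areas < 1e-9):
            raise ValueError("mesh contains degenerate triangles (area <= 1e-9 mm^2)")

    # -- derived quantities, computed once ---------------------------------
    def _get(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def triangles(self) -> np.ndarray:
        return self._get("tri", lambda: self.vertices[self.faces])

    @property
    def face_normals(self) -> np.ndarray:
        def fn():
            t = self.vertices[self.faces]
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            return n / np.linalg.norm(n, axis=1, keepdims=True)
        return self._get("fn", fn)

    @property
    def face_areas(self) -> np.ndarray:
        def fn():
            t = self.vertices[self.faces]
            return 0.5 * np.linalg.norm(
                np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        return self._get("fa", fn)

    @property
    def vertex_normals(self) -> np.ndarray:
        def fn():
            n = np.zeros_like(self.vertices)
            w = (self.face_normals * self.face_areas[:, None])
            for k in range(3):
                np.add.at(n, self.faces[:, k], w)
            return n / np.linalg.norm(n, axis=1, keepdims=True)
        return self._get("vn", fn)

    @property
    def vertex_tributary_areas(self) -> np.ndarray:
        """One third of the summed incident-triangle areas per vertex (mm^2)."""
        def fn():
            a = np.zeros(len(self.vertices))
            for k in range(3):
                np.add.at(a, self.faces[:, k], self.face_areas / 3.0)
            return a
        return self._get("va", fn)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, m: trimesh.Trimesh, frame: str = "ground") -> "SurfaceMesh":
        return cls(vertices=np.asarray(m.vertices, float),
                   faces=np.asarray(m.faces, np.int64), frame=frame)

    def save(self, path) -> None:
        """Write STL/PLY/OBJ (by extension) in mm."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path, frame: str = "ground") -> "SurfaceMesh":
        m = trimesh.load(str(path), force="mesh", process=False)
        # formats like STL store an unindexed triangle soup; shared vertices
        # must be merged or every face becomes its own connected patch
        m.merge_vertices()
        return cls.from_trimesh(m, frame=frame)

    def transformed(self, state: RigidState) -> "SurfaceMesh":
        """Copy of this mesh with vertices mapped into the parent frame."""
        return SurfaceMesh(vertices=state.frame.to_parent(self.vertices),
                           faces=self.faces.copy(), frame="ground")


@dataclass(frozen=True)
class ContactPoint:
    """One penetrating tibial-cartilage vertex.

    ``normal`` points from the tibial surface toward the femoral surface;
    ``delta`` is the (positive) penetration depth and ``delta_rate`` the
    closing rate (positive when deepening).
    """

    location: np.ndarray       # mm, ground frame
    normal: np.ndarray         # unit, tibial -> femoral
    delta: float               # mm, >= 0
    delta_rate: float          # mm/s
    tributary_area: float      # mm^2


class ContactSet:
    """Vectorised sequence of :class:`ContactPoint` for one mesh pair."""

    def __init__(self, locations, normals, deltas, delta_rates, areas, vertex_ids,
                 weights=None):
        self.locations = np.asarray(locations, float).reshape(-1, 3)
        self.normals = np.asarray(normals, float).reshape(-1, 3)
        self.deltas = np.asarray(deltas, float).reshape(-1)
        self.delta_rates = np.asarray(delta_rates, float).reshape(-1)
        self.areas = np.asarray(areas, float).reshape(-1)
        self.vertex_ids = np.asarray(vertex_ids, np.int64).reshape(-1)
        self.weights = (np.ones_like(self.deltas) if weights is None
                        else np.asarray(weights, float).reshape(-1))
        if np.any(self.deltas < 0):
            raise ValueError("reported penetration depth must be non-negative")

    @classmethod
    def empty(cls) -> "ContactSet":
        return cls(np.empty((0, 3)), np.empty((0, 3)), [], [], [], [])

    def __len__(self) -> int:
        return len(self.deltas)

    def __getitem__(self, i: int) -> ContactPoint:
        return ContactPoint(self.locations[i], self.normals[i], float(self.deltas[i]),
                            float(self.delta_rates[i]), float(self.areas[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def deepest(self) -> ContactPoint | None:
        if len(self) == 0:
            return None
        return self[int(np.argmax(self.deltas))]


# ---------------------------------------------------------------------------
# closest point on a triangle soup
# ---------------------------------------------------------------------------

def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to each point ``p[i]``.

    Standard Voronoi-region case analysis (Ericson), vectorised over pairs.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def take(mask, value):
        nonlocal done
        m = mask & ~done
        if np.any(m):
            out[m] = value[m] if value.ndim == 2 else value
            done = done | m

    with np.errstate(divide="ignore", invalid="ignore"):
        take((d1 <= 0) & (d2 <= 0), a)                       # vertex A
        take((d3 >= 0) & (d4 <= d3), b)                      # vertex B
        take((d6 >= 0) & (d5 <= d6), c)                      # vertex C
        v = np.where(d1 != d3, d1 / (d1 - d3), 0.0)
        take((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v[:, None] * ab)   # edge AB
        w = np.where(d2 != d6, d2 / (d2 - d6), 0.0)
        take((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w[:, None] * ac)   # edge AC
        den = (d4 - d3) + (d5 - d6)
        w2 = np.where(den != 0, (d4 - d3) / den, 0.0)
        take((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
             b + w2[:, None] * (c - b))                                 # edge BC
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v3 = vb / denom
        w3 = vc / denom
        take(np.ones(len(p), dtype=bool), a + v3[:, None] * ab + w3[:, None] * ac)
    return out


class _ComponentProximity:
    """Nearest-point queries against one connected surface patch."""

    K = 10  # candidate triangles per query point

    def __init__(self, mesh: SurfaceMesh, face_ids: np.ndarray):
        self.mesh = mesh
        self.face_ids = np.asarray(face_ids, np.int64)
        tri = mesh.triangles[self.face_ids]
        self.triangles = tri
        self.centroids = tri.mean(axis=1)
        self.face_normals = mesh.face_normals[self.face_ids]
        self.tree = cKDTree(self.centroids)
        # circumradius bound: beyond this the centroid distance is a tight proxy
        self.max_tri_radius = float(np.max(np.linalg.norm(
            tri - self.centroids[:, None, :], axis=2)))
        # loose axis-aligned bounds for cheap far-field rejection of whole
        # query batches (e.g. the opposite compartment's vertices)
        self.lo = self.centroids.min(axis=0) - self.max_tri_radius
        self.hi = self.centroids.max(axis=0) + self.max_tri_radius

    def nearest(self, points: np.ndarray, cutoff: float | None = None):
        """Return (surface point, distance, global triangle index) per point.

        Points whose nearest centroid is farther than ``cutoff`` on the
        *outside* half-space are returned with distance ``inf`` and index
        ``-1``; interpenetrating points are never rejected, however deep, or
        the contact energy barrier would have finite thickness.
        """
        points = np.asarray(points, float).reshape(-1, 3)
        n = len(points)
        k = min(self.K, len(self.centroids))
        s = np.full((n, 3), np.nan)
        dist = np.full(n, np.inf)
        tri_idx = np.full(n, -1, dtype=np.int64)

        if cutoff is None:
            near = np.ones(n, dtype=bool)
        else:
            # cheap batch rejection: outside the padded component box there
            # can be neither contact nor interpenetration
            pad = cutoff
            near = np.all((points >= self.lo - pad) & (points <= self.hi + pad),
                          axis=1)
        if not np.any(near):
            return s, dist, tri_idx
        pts = points[near]

        d1, i1 = self.tree.query(pts, k=1)
        if cutoff is None:
            active = np.ones(len(pts), dtype=bool)
        else:
            approx_out = np.einsum("ij,ij->i", pts - self.centroids[i1],
                                   self.face_normals[i1]) > 0
            active = (d1 <= cutoff + self.max_tri_radius) | ~approx_out

        if np.any(active):
            pa = pts[active]
            _, idx = self.tree.query(pa, k=k)
            idx = np.asarray(idx).reshape(len(pa), k)
            cand_tri = self.triangles[idx.ravel()]
            rep = np.repeat(pa, k, axis=0)
            cp = _closest_point_on_triangles(rep, cand_tri).reshape(len(pa), k, 3)
            d = np.linalg.norm(cp - pa[:, None, :], axis=2)
            best = np.argmin(d, axis=1)
            rows = np.arange(len(pa))
            where = np.where(near)[0][active]
            s[where] = cp[rows, best]
            dist[where] = d[rows, best]
            tri_idx[where] = self.face_ids[idx[rows, best]]
        return s, dist, tri_idx

    def is_inside(self, points: np.ndarray, s: np.ndarray, dist: np.ndarray,
                  tri_idx: np.ndarray):
        """Inside test along the (smoothed) surface normal, with border weight.

        Returns ``(inside, weight)``.  The weight ramps smoothly from 0 to 1
        as the offset direction aligns with the inward normal, which both
        rejects spurious "inside" hits at the open borders of a cartilage
        patch and keeps the contact force field continuous there (a binary
        test would switch whole point forces on and off).
        """
        inside = np.zeros(len(points), dtype=bool)
        weight = np.zeros(len(points))
        valid = np.where(tri_idx >= 0)[0]
        if len(valid) == 0:
            return inside, weight
        sv, pv, dv = s[valid], points[valid], dist[valid]
        nf = interpolated_normals(self.mesh, sv, tri_idx[valid])
        signed = np.einsum("ij,ij->i", pv - sv, nf)
        ratio = np.where(dv > 1e-9, -signed / np.where(dv > 0, dv, 1.0), 1.0)
        x = np.clip((ratio - 0.35) / 0.30, 0.0, 1.0)
        w = x * x * (3.0 - 2.0 * x)
        m = (signed < 0) & (w > 0)
        idx = valid[m]
        inside[idx] = True
        weight[idx] = w[m]
        return inside, weight


class _SurfaceProximity:
    """Proximity structure for a (possibly multi-patch) surface mesh.

    Queries run per connected component: penetration is defined with respect
    to the patch a vertex is actually inside, so a vertex squeezed between
    two patches (e.g. the intercondylar gap) cannot flip its classification
    because the *other* patch's border happens to be globally nearer.
    """

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        labels = _face_components(mesh)
        self.components = [_ComponentProximity(mesh, np.where(labels == c)[0])
                           for c in np.unique(labels)]
        self.watertight = bool(mesh.to_trimesh().is_watertight)
        if not self.watertight:
            logger.warning(
                "surface mesh is not watertight; inside tests use signed "
                "distance along the nearest-point normal")

    def nearest(self, points: np.ndarray, cutoff: float | None = None):
        """Globally nearest surface point over all components."""
        points = np.asarray(points, float).reshape(-1, 3)
        s = np.full((len(points), 3), np.nan)
        dist = np.full(len(points), np.inf)
        tri_idx = np.full(len(points), -1, dtype=np.int64)
        for comp in self.components:
            sc, dc, tc = comp.nearest(points, cutoff=cutoff)
            better = dc < dist
            s[better] = sc[better]
            dist[better] = dc[better]
            tri_idx[better] = tc[better]
        return s, dist, tri_idx

    def penetrations(self, points: np.ndarray, cutoff: float | None):
        """Per-component inside tests; deepest wins if a point is inside two.

        Returns ``(s, dist, tri_idx, inside)`` with the penetration depth of
        the owning component.
        """
        points = np.asarray(points, float).reshape(-1, 3)
        n = len(points)
        s = np.full((n, 3), np.nan)
        dist = np.full(n, -np.inf)
        tri_idx = np.full(n, -1, dtype=np.int64)
        inside = np.zeros(n, dtype=bool)
        weight = np.zeros(n)
        for comp in self.components:
            sc, dc, tc = comp.nearest(points, cutoff=cutoff)
            inc, wc = comp.is_inside(points, sc, dc, tc)
            take = inc & (~inside | (dc > dist))
            s[take] = sc[take]
            dist[take] = dc[take]
            tri_idx[take] = tc[take]
            weight[take] = wc[take]
            inside |= inc
        return s, dist, tri_idx, inside, weight


def interpolated_normals(mesh: SurfaceMesh, s: np.ndarray, tri_idx: np.ndarray) -> np.ndarray:
    """Outward normals at surface points, barycentrically interpolated.

    Phong-style interpolation of the vertex normals makes the contact normal
    field continuous across mesh edges; with flat face normals the direction
    jumps by the dihedral angle at every edge-equidistant ridge of the
    interior distance field, which puts a floor under achievable equilibrium
    residuals.
    """
    f = mesh.faces[tri_idx]
    a = mesh.vertices[f[:, 0]]
    v0 = mesh.vertices[f[:, 1]] - a
    v1 = mesh.vertices[f[:, 2]] - a
    v2 = np.nan_to_num(s) - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) > 1e-18, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    vn = mesh.vertex_normals
    n = (u[:, None] * vn[f[:, 0]] + v[:, None] * vn[f[:, 1]] + w[:, None] * vn[f[:, 2]])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _face_components(mesh: SurfaceMesh) -> np.ndarray:
    """Connected-component label per face (via shared vertices)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    nv = len(mesh.vertices)
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(nv, nv))
    _, vlabels = connected_components(adj, directed=False)
    return vlabels[f[:, 0]]


def _proximity(mesh: SurfaceMesh) -> _SurfaceProximity:
    if "prox" not in mesh._cache:
        mesh._cache["prox"] = _SurfaceProximity(mesh)
    return mesh._cache["prox"]


def penetration_query(femoral_cartilage: SurfaceMesh, femur: RigidState,
                      tibial_cartilage: SurfaceMesh, tibia: RigidState,
                      cutoff: float | None = 1.0) -> ContactSet:
    """Contact points where tibial-cartilage vertices penetrate the femoral surface.

    ``cutoff`` (mm) limits the exact nearest-point computation to tibial
    vertices near the femoral surface; pass ``None`` to query all vertices.
    """
    prox = _proximity(femoral_cartilage)
    verts_ground = tibia.frame.to_parent(tibial_cartilage.vertices)
    verts_fem = femur.frame.to_local(verts_ground)

    s_fem, dist, tri_idx, inside, weight = prox.penetrations(verts_fem, cutoff=cutoff)
    if not np.any(inside):
        return ContactSet.empty()

    ids = np.where(inside)[0]
    loc = verts_ground[ids]
    # smoothed (Phong-interpolated) outward normal at the nearest point: the
    # exact offset direction jumps by the dihedral angle across the interior
    # edge-equidistant ridges of a faceted surface, which would bound the
    # solver residual from below
    n_local = interpolated_normals(prox.mesh, s_fem[ids], tri_idx[ids])
    n_out = (femur.frame.rotation @ n_local.T).T

    v_rel = np.atleast_2d(tibia.point_velocity(loc)) - np.atleast_2d(femur.point_velocity(loc))
    rates = -np.einsum("ij,ij->i", v_rel, n_out)

    return ContactSet(locations=loc,
                      normals=-n_out,  # tibial -> femoral per convention
                      deltas=dist[ids],
                      delta_rates=rates,
                      areas=tibial_cartilage.vertex_tributary_areas[ids],
                      vertex_ids=ids,
                      weights=weight[ids])


def sphere_plane_oracle(radius: float, center_height: float):
    """Closed-form deepest penetration of a sphere above the plane z=0.

    Returns ``(delta, normal)`` with ``delta = max(0, radius - center_height)``
    and the plane normal ``(0, 0, 1)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return max(0.0, radius - center_height), np.array([0.0, 0.0, 1.0])


def meshed_sphere(radius: float, subdivisions: int = 4, frame: str = "ground") -> SurfaceMesh:
    """Icosphere with outward normals (watertight test fixture)."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh.from_trimesh(m, frame=frame)


def meshed_plane(half_width: float, n: int = 40, frame: str = "ground") -> SurfaceMesh:
    """Square grid patch of the plane z=0 with +z normals."""
    xs = np.linspace(-half_width, half_width, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v0 = i * n + j
            faces.append([v0, v0 + 1, v0 + n])
            faces.append([v0 + 1, v0 + n + 1, v0 + n])
    return SurfaceMesh(vertices=verts, faces=np.array(faces), frame=frame)
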