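"""Rigid ICP alignment and multi-resolution B-spline free-form deformation.

The correspondence chain mirrors a classical surface-based shape-model
pipeline: every subject surface is first aligned rigidly to a reference
surface with the iterative closest-point algorithm, then a coarse-to-fine
cubic B-spline lattice deforms the reference onto the subject so that the
reference vertices, projected onto the subject surface, yield point-to-point
correspondence on a shared topology.

Closest-point queries are exact point-to-triangle distances: a k-d tree on
triangle centroids proposes candidate faces, the exact distance is evaluated
on the candidates.  This keeps queries correct across meshes of different
resolution without brute-force cost.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized
from scipy.spatial import cKDTree

from .mesh_core import TriangleMesh


# ---------------------------------------------------------------------------
# exact closest point on a triangulated surface
# ---------------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points on triangles for each (point, candidate triangle) pair.

    p : (q, 3); tri : (q, k, 3, 3).  Returns (q, k, 3).
    Vectorised form of the barycentric region walk (Ericson).
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    pq = p[:, None, :]
    ab, ac = b - a, c - a
    ap = pq - a
    d1 = np.einsum("...i,...i", ab, ap)
    d2 = np.einsum("...i,...i", ac, ap)
    bp = pq - b
    d3 = np.einsum("...i,...i", ab, bp)
    d4 = np.einsum("...i,...i", ac, bp)
    cp = pq - c
    d5 = np.einsum("...i,...i", ab, cp)
    d6 = np.einsum("...i,...i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    out = a + ab * np.nan_to_num(v_in)[..., None] + ac * np.nan_to_num(w_in)[..., None]
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(cond_bc[..., None], b + np.nan_to_num(w_bc)[..., None] * (c - b), out)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[..., None], a + np.nan_to_num(w_ac)[..., None] * ac, out)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[..., None], a + np.nan_to_num(v_ab)[..., None] * ab, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)
    return out


class SurfaceLocator:
    """Exact closest-point queries against a fixed triangulated surface."""

    def __init__(self, mesh: TriangleMesh, k_candidates: int = 12):
        self.tri = mesh.vertices[mesh.faces]          # (m, 3, 3)
        self.k = min(k_candidates, len(self.tri))
        self._tree = cKDTree(self.tri.mean(axis=1))
        self.face_normals = mesh.face_normals()

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest points (q,3), distances (q,))."""
        closest, dist, _ = self.query_full(points)
        return closest, dist

    def query_full(self, points: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, face indices)."""
        points = np.atleast_2d(points)
        _, idx = self._tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        cand = _closest_on_triangles(points, self.tri[idx])
        d2 = ((cand - points[:, None, :]) ** 2).sum(axis=2)
        best = d2.argmin(axis=1)
        rows = np.arange(len(points))
        return cand[rows, best], np.sqrt(d2[rows, best]), idx[rows, best]


def mean_surface_distance(source: TriangleMesh, target: TriangleMesh,
                          symmetric: bool = True) -> float:
    """Mean vertex-to-surface distance, symmetrised by default (mm)."""
    d_fwd = SurfaceLocator(target).query(source.vertices)[1].mean()
    if not symmetric:
        return float(d_fwd)
    d_rev = SurfaceLocator(source).query(target.vertices)[1].mean()
    return float(0.5 * (d_fwd + d_rev))


# ---------------------------------------------------------------------------
# rigid ICP
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def rotation_angle_deg(self) -> float:
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


@dataclass
class ICPResult:
    transform: RigidTransform
    aligned: TriangleMesh
    rms: float
    n_iterations: int
    converged: bool


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping source onto target."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, tc - r @ sc)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Columns = eigenvectors of the point covariance, descending variance,
    as a proper rotation (det +1)."""
    c = np.cov((points - points.mean(axis=0)).T)
    _, v = np.linalg.eigh(c)
    v = v[:, ::-1]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def icp_align(moving: TriangleMesh, reference: TriangleMesh,
              max_iterations: int = 100, tolerance: float = 1e-6) -> ICPResult:
    """Rigidly align ``moving`` to ``reference`` by iterative closest point.

    Initialisation is deterministic: centroid alignment plus principal-axes
    alignment, with the axis-sign ambiguity resolved by the candidate with
    minimal RMS closest-point distance.  Iteration stops when the RMS
    improvement drops below ``tolerance`` (mm) or at ``max_iterations``.
    """
    moving.validate()
    reference.validate()
    locator = SurfaceLocator(reference)
    v0 = moving.vertices

    em = _principal_axes(v0)
    er = _principal_axes(reference.vertices)
    candidates = [RigidTransform.identity()]
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            s = np.diag([sx, sy, sx * sy])      # keeps det = +1
            r = er @ s @ em.T
            t = reference.vertices.mean(axis=0) - r @ v0.mean(axis=0)
            candidates.append(RigidTransform(r, t))

    def rms_of(tf: RigidTransform) -> float:
        return float(np.sqrt((locator.query(tf.apply(v0))[1] ** 2).mean()))

    transform = min(candidates, key=rms_of)
    initial_rms = rms_of(transform)
    best_rms = initial_rms
    best_tf = transform
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        targets, _ = locator.query(transform.apply(v0))
        transform = _kabsch(v0, targets)
        rms = rms_of(transform)
        if rms < best_rms:
            best_rms, best_tf = rms, transform
        if abs(prev_rms - rms) < tolerance:
            converged = True
            break
        prev_rms = rms
    if best_rms >= initial_rms and initial_rms > tolerance:
        warnings.warn("ICP did not reduce RMS; returning best iterate",
                      stacklevel=2)
    aligned = TriangleMesh(best_tf.apply(v0), moving.faces.copy(), moving.subject_id)
    return ICPResult(best_tf, aligned, best_rms, it, converged)


# ---------------------------------------------------------------------------
# cubic B-spline free-form deformation
# ---------------------------------------------------------------------------

def _bspline_basis(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values; t in [0,1), returns (..., 4)."""
    t2, t3 = t * t, t * t * t
    return np.stack([
        (1 - t) ** 3 / 6.0,
        (3 * t3 - 6 * t2 + 4) / 6.0,
        (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
        t3 / 6.0,
    ], axis=-1)


def _bspline_dbasis(t: np.ndarray) -> np.ndarray:
    """Derivatives of the four uniform cubic B-spline basis functions."""
    t2 = t * t
    return np.stack([
        -(1 - t) ** 2 / 2.0,
        (9 * t2 - 12 * t) / 6.0,
        (-9 * t2 + 6 * t + 3) / 6.0,
        t2 / 2.0,
    ], axis=-1)


@dataclass
class FFDLattice:
    """A cubic B-spline displacement lattice (mm).

    ``displacements`` has shape (nx, ny, nz, 3); the control point (i, j, k)
    sits at ``origin + spacing * (i, j, k)``.  The lattice must cover every
    evaluation point with a full 4x4x4 support neighbourhood.
    """

    origin: np.ndarray
    spacing: np.ndarray
    displacements: np.ndarray
    level: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if (self.spacing <= 0).any():
            raise ValueError("lattice spacing must be positive")
        if self.displacements.ndim != 4 or self.displacements.shape[3] != 3:
            raise ValueError("displacements must have shape (nx, ny, nz, 3)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    def _support(self, points: np.ndarray):
        u = (points - self.origin) / self.spacing
        i0 = np.floor(u).astype(int) - 1
        t = u - np.floor(u)
        shape = np.array(self.grid_shape)
        if (i0 < 0).any() or (i0 + 3 >= shape).any():
            raise ValueError("evaluation point outside lattice support")
        return i0, t

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Displacement field at ``points`` (q, 3) -> (q, 3)."""
        points = np.atleast_2d(points)
        i0, t = self._support(points)
        bx = _bspline_basis(t[:, 0])
        by = _bspline_basis(t[:, 1])
        bz = _bspline_basis(t[:, 2])
        return self._tensor_eval(i0, bx, by, bz)

    def _tensor_eval(self, i0, bx, by, bz) -> np.ndarray:
        out = np.zeros((len(i0), 3))
        d = self.displacements
        for a in range(4):
            ia = i0[:, 0] + a
            wa = bx[:, a]
            for b in range(4):
                jb = i0[:, 1] + b
                wab = wa * by[:, b]
                for c in range(4):
                    kc = i0[:, 2] + c
                    out += (wab * bz[:, c])[:, None] * d[ia, jb, kc]
        return out

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """Jacobian of the *displacement* field: (q, 3, 3), d u_i / d x_j."""
        points = np.atleast_2d(points)
        i0, t = self._support(points)
        b = [_bspline_basis(t[:, ax]) for ax in range(3)]
        db = [_bspline_dbasis(t[:, ax]) / self.spacing[ax] for ax in range(3)]
        jac = np.zeros((len(points), 3, 3))
        d = self.displacements
        for a in range(4):
            for bb in range(4):
                for c in range(4):
                    ctrl = d[i0[:, 0] + a, i0[:, 1] + bb, i0[:, 2] + c]  # (q,3)
                    for ax, (wx, wy, wz) in enumerate([
                        (db[0][:, a], b[1][:, bb], b[2][:, c]),
                        (b[0][:, a], db[1][:, bb], b[2][:, c]),
                        (b[0][:, a], b[1][:, bb], db[2][:, c]),
                    ]):
                        jac[:, :, ax] += (wx * wy * wz)[:, None] * ctrl
        return jac

    def basis_matrix(self, points: np.ndarray) -> sparse.csr_matrix:
        """Sparse (q, n_ctrl) tensor-product basis weights at ``points``."""
        points = np.atleast_2d(points)
        i0, t = self._support(points)
        bx = _bspline_basis(t[:, 0])
        by = _bspline_basis(t[:, 1])
        bz = _bspline_basis(t[:, 2])
        nx, ny, nz = self.grid_shape
        q = len(points)
        rows = np.repeat(np.arange(q), 64)
        cols = np.empty((q, 64), dtype=np.int64)
        vals = np.empty((q, 64))
        idx = 0
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    cols[:, idx] = ((i0[:, 0] + a) * ny + (i0[:, 1] + b)) * nz + (i0[:, 2] + c)
                    vals[:, idx] = bx[:, a] * by[:, b] * bz[:, c]
                    idx += 1
        return sparse.csr_matrix((vals.ravel(), (rows, cols.ravel())),
                                 shape=(q, nx * ny * nz))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "spacing": self.spacing.tolist(),
            "grid_shape": list(self.grid_shape),
            "level": self.level,
            "displacements": self.displacements.ravel().tolist(),  # row-major
        }

    @staticmethod
    def from_dict(d: dict) -> "FFDLattice":
        shape = tuple(d["grid_shape"]) + (3,)
        return FFDLattice(np.array(d["origin"]), np.array(d["spacing"]),
                          np.array(d["displacements"]).reshape(shape),
                          int(d.get("level", 0)))


def save_lattices(lattices: list[FFDLattice], path: str | Path) -> None:
    Path(path).write_text(json.dumps([l.to_dict() for l in lattices]))


def load_lattices(path: str | Path) -> list[FFDLattice]:
    return [FFDLattice.from_dict(d) for d in json.loads(Path(path).read_text())]


def make_lattice(bounds_min: np.ndarray, bounds_max: np.ndarray, spacing: float,
                 level: int = 0) -> FFDLattice:
    """Zero-displacement lattice covering a box with >= 1 control margin."""
    bounds_min = np.asarray(bounds_min, dtype=float)
    bounds_max = np.asarray(bounds_max, dtype=float)
    sp = np.full(3, float(spacing))
    origin = bounds_min - 1.5 * sp
    extent = bounds_max - bounds_min
    n = np.floor(extent / sp + 1.5).astype(int) + 4
    return FFDLattice(origin, sp, np.zeros((n[0], n[1], n[2], 3)), level)


def apply_lattices(points: np.ndarray, lattices: list[FFDLattice]) -> np.ndarray:
    """Additive multi-level field: p + sum_l u_l(p)."""
    out = np.array(points, dtype=float)
    for lat in lattices:
        out = out + lat.evaluate(points)
    return out


def _second_difference_operator(shape: tuple[int, int, int]) -> sparse.csr_matrix:
    """Discrete bending penalty: stacked second differences along each axis."""
    nx, ny, nz = shape
    n = nx * ny * nz
    blocks = []
    idx = np.arange(n).reshape(shape)
    for ax, m in enumerate(shape):
        if m < 3:
            continue
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl0[ax] = slice(0, m - 2)
        sl1[ax] = slice(1, m - 1)
        sl2[ax] = slice(2, m)
        i0 = idx[tuple(sl0)].ravel()
        i1 = idx[tuple(sl1)].ravel()
        i2 = idx[tuple(sl2)].ravel()
        q = len(i0)
        rows = np.repeat(np.arange(q), 3)
        cols = np.stack([i0, i1, i2], axis=1).ravel()
        vals = np.tile([1.0, -2.0, 1.0], q)
        blocks.append(sparse.csr_matrix((vals, (rows, cols)), shape=(q, n)))
    return sparse.vstack(blocks).tocsr()


def crease_edges(mesh: TriangleMesh, angle_deg: float = 45.0) -> np.ndarray:
    """Edges whose two incident faces meet at more than ``angle_deg``.

    Returns (n, 2) vertex-index pairs: the sharp feature curves of the
    surface (rim and corner curves, cap boundaries).
    """
    f = mesh.faces
    edges = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]),
                    axis=1)
    face_ids = np.tile(np.arange(len(f)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, face_ids = edges[order], face_ids[order]
    paired = (edges[:-1] == edges[1:]).all(axis=1)
    idx = np.flatnonzero(paired)
    normals = mesh.face_normals()
    cosang = np.einsum("ij,ij->i", normals[face_ids[idx]],
                       normals[face_ids[idx + 1]])
    sharp = cosang < np.cos(np.radians(angle_deg))
    return edges[idx[sharp]]


def chain_crease_curves(mesh: TriangleMesh, angle_deg: float = 30.0,
                        min_length: int = 5) -> list[np.ndarray]:
    """Order the crease edges into open polyline curves (vertex-index paths).

    Crease curves of a meniscal surface are the rim and corner curves
    running from horn tip to horn tip plus the cap boundaries; only open
    chains of at least ``min_length`` vertices are returned.
    """
    edges = crease_edges(mesh, angle_deg)
    neighbors: dict[int, list[int]] = {}
    for a, b in edges:
        neighbors.setdefault(int(a), []).append(int(b))
        neighbors.setdefault(int(b), []).append(int(a))
    # junctions: curve endpoints or branch points of the crease network
    junctions = sorted(v for v, ns in neighbors.items() if len(ns) != 2)
    visited: set[tuple[int, int]] = set()

    def take(a, b):
        visited.add((min(a, b), max(a, b)))

    def taken(a, b):
        return (min(a, b), max(a, b)) in visited

    chains = []
    for start in junctions:
        for first in sorted(neighbors[start]):
            if taken(start, first):
                continue
            chain = [start, first]
            take(start, first)
            cur, prev = first, start
            while len(neighbors[cur]) == 2:
                nxt = [n for n in neighbors[cur] if n != prev]
                if not nxt or taken(cur, nxt[0]):
                    break
                take(cur, nxt[0])
                prev, cur = cur, nxt[0]
                chain.append(cur)
            if len(chain) >= min_length:
                chains.append(np.array(chain, dtype=np.int64))
    return chains


def _arc_positions(points: np.ndarray) -> np.ndarray:
    """Normalised cumulative arc length in [0, 1] along a polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s / max(s[-1], 1e-30)


def _curve_positions(points: np.ndarray) -> np.ndarray:
    """Normalised monotone parameterisation of a feature curve in [0, 1].

    Curves that are clearly circular arcs (rim and corner curves of a
    crescent) are parameterised by the unwrapped polar angle about the
    best-fit circle centre — the circumferential coordinate natural to
    meniscal anatomy.  Short or nearly straight curves fall back to
    normalised arc length.
    """
    s_arc = _arc_positions(points)
    if len(points) < 8:
        return s_arc
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    xy = centered @ vt[:2].T
    # algebraic (Kasa) circle fit: x^2 + y^2 = 2 a x + 2 b y + c, fitted on
    # the central half of the curve where crescent curvature is most
    # uniform (the tapering ends would bias the centre)
    mid = (s_arc >= 0.25) & (s_arc <= 0.75)
    a_mat = np.column_stack([2 * xy[mid], np.ones(int(mid.sum()))])
    rhs = (xy[mid] ** 2).sum(axis=1)
    (cx, cy, c0), *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    radius = np.sqrt(max(c0 + cx ** 2 + cy ** 2, 1e-30))
    length = max(np.linalg.norm(np.diff(points, axis=0), axis=1).sum(), 1e-30)
    # straight-ish curve: circle fit is ill-conditioned, use arc length
    if radius > 20.0 * length:
        return s_arc
    ang = np.unwrap(np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx))
    span = ang[-1] - ang[0]
    # angle must advance monotonically over a substantial span, otherwise
    # the curve is not arc-like about the fitted centre
    if abs(span) < np.radians(30.0) \
            or np.any(np.diff(ang) * np.sign(span) <= 0):
        return s_arc
    return (ang - ang[0]) / span


def _interp_polyline(points: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Points at normalised curve positions ``s`` along a polyline."""
    sp = _curve_positions(points)
    return np.column_stack([np.interp(s, sp, points[:, c]) for c in range(3)])


def _match_curves_by_arclength(mov_chains: list[np.ndarray],
                               mov_coords: np.ndarray,
                               ref_chains: list[np.ndarray],
                               ref_coords: np.ndarray,
                               mov_coords_param: np.ndarray | None = None,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Pair feature curves and map each moving curve vertex to the point at
    the same normalised curve position on its partner curve.

    Pairing and orientation are chosen by minimal mean distance between
    resampled polylines (the meshes are already globally aligned when this
    runs); a pairing whose mean distance exceeds ``gate`` mm is dropped
    rather than allowed to corrupt the registration.  Returns
    (vertex indices, target points).
    """
    gate = 3.0
    if mov_coords_param is None:
        mov_coords_param = mov_coords
    probe = np.linspace(0.0, 1.0, 16)
    ref_samples = []
    for ch in ref_chains:
        pts = ref_coords[ch]
        ref_samples.append(_interp_polyline(pts, probe))
    idx_all, tgt_all = [], []
    for ch in mov_chains:
        pts = mov_coords[ch]
        mov_sample = _interp_polyline(pts, probe)
        best = (np.inf, None, False)
        for j, rs in enumerate(ref_samples):
            d_fwd = np.linalg.norm(mov_sample - rs, axis=1).mean()
            d_rev = np.linalg.norm(mov_sample - rs[::-1], axis=1).mean()
            if d_fwd < best[0]:
                best = (d_fwd, j, False)
            if d_rev < best[0]:
                best = (d_rev, j, True)
        if best[1] is None or best[0] > gate:
            continue
        ref_pts = ref_coords[ref_chains[best[1]]]
        if best[2]:
            ref_pts = ref_pts[::-1]
        # the curve parameterisation is intrinsic: compute it on the
        # original (pre-affine) coordinates so anisotropic alignment
        # cannot distort the circumferential coordinate
        s = _curve_positions(mov_coords_param[ch])
        idx_all.append(ch)
        tgt_all.append(_interp_polyline(ref_pts, s))
    if not idx_all:
        return np.empty(0, dtype=np.int64), np.empty((0, 3))
    return np.concatenate(idx_all), np.vstack(tgt_all)


def _affine_icp(v0: np.ndarray, locator: SurfaceLocator,
                iterations: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Global affine stage: closest point + point-to-plane affine LS fit.

    Point-to-plane matching lets points slide tangentially, so the varying
    normals across a curved surface jointly determine all twelve affine
    parameters in a few iterations (point-to-point matching recovers the
    tangential part only geometrically slowly).
    """
    hom = np.column_stack([v0, np.ones(len(v0))])
    m = np.eye(4)[:, :3]                       # maps hom -> coords
    for _ in range(iterations):
        warped = hom @ m
        targets, _, faces = locator.query_full(warped)
        normals = locator.face_normals[faces]
        # rows: n . (hom @ M) = n . q, unknowns M (12)
        design = (hom[:, :, None] * normals[:, None, :]).reshape(len(v0), 12)
        rhs = np.einsum("ij,ij->i", normals, targets)
        sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        m = sol.reshape(4, 3)
    return m[:3].T, m[3]


@dataclass
class FFDResult:
    """Global affine stage plus coarse-to-fine B-spline lattices."""

    lattices: list[FFDLattice]
    level_residuals: list[float]        # symmetric mean surface distance, mm
    warped: TriangleMesh
    affine: np.ndarray                  # 3x3, identity if disabled
    affine_translation: np.ndarray
    foldover_count: int = 0

    def warp_points(self, points: np.ndarray) -> np.ndarray:
        """Map points through the composed deformation (affine then FFD)."""
        p = np.atleast_2d(points) @ self.affine.T + self.affine_translation
        return apply_lattices(p, self.lattices)


def ffd_register(moving: TriangleMesh, reference: TriangleMesh,
                 levels=(20.0, 10.0, 5.0), iterations_per_level: int = 8,
                 bending_weight: float = 0.01,
                 affine_init: bool = True,
                 plane_min_spacing: float = np.inf,
                 tangential_weight: float = 0.02,
                 feature_weight: float = 1.0) -> FFDResult:
    """Deform ``moving`` toward ``reference`` with a coarse-to-fine lattice.

    A global affine stage (closest-point iterations with a full affine
    least-squares fit) first absorbs overall scaling and stretch — the
    component a closest-point data term cannot recover tangentially — and
    the multi-resolution lattice then fits the non-affine residual.

    Each level alternates exact closest-point correspondence with a
    regularized sparse least-squares update of the control displacements
    (data term: mean squared residual at the moving vertices; regularizer:
    discrete bending energy of the lattice).  The total deformation is the
    affine map followed by the additive sum of the per-level fields
    evaluated at the affinely mapped vertices.

    A fold-over check (non-positive determinant of the total-map Jacobian
    at the vertices) emits a warning with the offending count.
    """
    moving.validate()
    reference.validate()
    locator = SurfaceLocator(reference)
    if affine_init:
        aff, aff_t = _affine_icp(moving.vertices, locator)
    else:
        aff, aff_t = np.eye(3), np.zeros(3)
    v0 = moving.vertices @ aff.T + aff_t
    lo = np.minimum(v0.min(axis=0), reference.vertices.min(axis=0))
    hi = np.maximum(v0.max(axis=0), reference.vertices.max(axis=0))

    # sharp feature curves matched by normalised arc length anchor the
    # tangential parameterisation that surface closest-point data leaves free
    feat_idx = feat_targets = None
    if feature_weight > 0:
        mov_chains = chain_crease_curves(moving)
        ref_chains = chain_crease_curves(reference)
        if mov_chains and ref_chains:
            feat_idx, feat_targets = _match_curves_by_arclength(
                mov_chains, v0, ref_chains, reference.vertices,
                mov_coords_param=moving.vertices)
            if feat_idx.size == 0:
                feat_idx = feat_targets = None

    lattices: list[FFDLattice] = []
    residuals: list[float] = []
    total_disp = np.zeros_like(v0)

    for level, spacing in enumerate(levels):
        lat = make_lattice(lo, hi, spacing, level)
        w = lat.basis_matrix(v0)
        n_pts = w.shape[0]
        n_ctrl = w.shape[1]
        l_op = _second_difference_operator(lat.grid_shape)
        k_reg = (l_op.T @ l_op) / max(l_op.shape[0], 1)

        # Coarse levels use a point-to-plane data term: residuals are only
        # constrained along the target normal, so the smooth tangential
        # part of the deformation (invisible to point-to-point matching)
        # is filled in by the bending-minimal lattice interpolation.  The
        # finest level refines normally with the cheap separable solve.
        use_plane = spacing >= plane_min_spacing
        wtw = (w.T @ w) / n_pts
        if feat_idx is not None:
            w_f = w[feat_idx]
            n_feat = len(feat_idx)
            wtw_f = (w_f.T @ w_f) / n_feat
        if use_plane:
            block_k = sparse.block_diag([k_reg] * 3).tocsr()
            block_wtw = sparse.block_diag([wtw] * 3).tocsr()
            if feat_idx is not None:
                block_wtw_f = sparse.block_diag([wtw_f] * 3).tocsr()
        else:
            a_sep = wtw + bending_weight * k_reg
            if feat_idx is not None:
                a_sep = a_sep + feature_weight * wtw_f
            solve = factorized(a_sep.tocsc())

        d = np.zeros((n_ctrl, 3))
        for _ in range(iterations_per_level):
            warped = v0 + total_disp + w @ d
            if use_plane:
                # anisotropic data term (1 - a_t) n n^T + a_t I: full weight
                # along the target normal, a small point-to-point weight
                # tangentially to damp drift of the unconstrained directions
                targets, _, fidx = locator.query_full(warped)
                normals = locator.face_normals[fidx]
                resid = targets - warped
                dmat = sparse.hstack(
                    [w.multiply(normals[:, c:c + 1]) for c in range(3)]).tocsr()
                a_mat = ((1 - tangential_weight) * (dmat.T @ dmat) / n_pts
                         + tangential_weight * block_wtw
                         + bending_weight * block_k)
                resid_n = np.einsum("ij,ij->i", normals, resid)
                rhs = ((1 - tangential_weight) * (dmat.T @ resid_n) / n_pts
                       + tangential_weight * (w.T @ resid).T.ravel() / n_pts
                       - bending_weight * (block_k @ d.T.ravel()))
                if feat_idx is not None:
                    a_mat = a_mat + feature_weight * block_wtw_f
                    rf = (w_f.T @ (feat_targets - warped[feat_idx])) / n_feat
                    rhs = rhs + feature_weight * rf.T.ravel()
                delta = sparse.linalg.spsolve(a_mat.tocsc(), rhs)
                d = d + delta.reshape(3, n_ctrl).T
            else:
                targets, _ = locator.query(warped)
                resid = targets - warped
                rhs = (w.T @ resid) / n_pts - bending_weight * (k_reg @ d)
                if feat_idx is not None:
                    rhs = rhs + feature_weight * (
                        w_f.T @ (feat_targets - warped[feat_idx])) / n_feat
                d = d + np.column_stack([solve(rhs[:, c]) for c in range(3)])
        lat.displacements = d.reshape(lat.grid_shape + (3,))
        lattices.append(lat)
        total_disp = total_disp + w @ d

        warped_mesh = TriangleMesh(v0 + total_disp, moving.faces.copy(),
                                   moving.subject_id)
        residuals.append(mean_surface_distance(warped_mesh, reference))

    jac = np.eye(3) + sum(lat.jacobian(v0) for lat in lattices)
    dets = np.linalg.det(jac) * np.linalg.det(aff)
    n_fold = int((dets <= 0).sum())
    if n_fold:
        warnings.warn(f"FFD fold-over at {n_fold} vertices", stacklevel=2)
    return FFDResult(lattices, residuals, warped_mesh, aff, aff_t, n_fold)


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------

@dataclass
class CorrespondedShape:
    """Shape vector (x1..xn, y1..yn, z1..zn) on the shared reference topology."""

    coordinates: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).ravel()
        if len(self.coordinates) % 3:
            raise ValueError("coordinate vector length must be 3 * n_points")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates in shape vector")

    @property
    def n_points(self) -> int:
        return len(self.coordinates) // 3

    @property
    def points(self) -> np.ndarray:
        return self.coordinates.reshape(3, -1).T

    @staticmethod
    def from_points(points: np.ndarray, subject_id: str | None = None
                    ) -> "CorrespondedShape":
        points = np.asarray(points, dtype=float)
        return CorrespondedShape(
            np.concatenate([points[:, 0], points[:, 1], points[:, 2]]), subject_id)

    def to_mesh(self, faces: np.ndarray, subject_id: str | None = None) -> TriangleMesh:
        return TriangleMesh(self.points, np.asarray(faces).copy(),
                            subject_id or self.subject_id)


class CorrespondenceError(RuntimeError):
    def __init__(self, indices, distances):
        self.indices = indices
        self.distances = distances
        super().__init__(
            f"{len(indices)} mapped points farther than the gate from the target "
            f"surface (max {max(distances):.2f} mm); indices {list(indices)[:10]}")


def establish_correspondence(reference_shape: CorrespondedShape,
                             target_surface: TriangleMesh,
                             deformation: "FFDResult | list[FFDLattice]",
                             gate: float = 5.0,
                             subject_id: str | None = None) -> CorrespondedShape:
    """Map reference points through the deformation, project onto the target.

    The deformation must come from :func:`ffd_register` with the reference
    surface as the moving mesh and ``target_surface`` as the fixed mesh
    (a bare lattice list is also accepted and applied without an affine
    stage).  Any mapped point farther than ``gate`` mm from the target
    raises :class:`CorrespondenceError` listing the offending indices.
    """
    if isinstance(deformation, FFDResult):
        mapped = deformation.warp_points(reference_shape.points)
    else:
        mapped = apply_lattices(reference_shape.points, deformation)
    projected, dist = SurfaceLocator(target_surface).query(mapped)
    bad = np.flatnonzero(dist > gate)
    if bad.size:
        raise CorrespondenceError(bad.tolist(), dist[bad].tolist())
    return CorrespondedShape.from_points(
        projected, subject_id or target_surface.subject_id)
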