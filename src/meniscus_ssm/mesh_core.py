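"""Triangle-mesh data model, standard-format I/O, smoothing and area measures.

All coordinates are in millimetres. Meshes in other units must be converted
at ingest via the ``unit_scale`` argument of :func:`read_mesh`.

Vertex order is part of the I/O contract for PLY and OBJ: correspondence
vectors index vertices positionally, so readers and writers never reorder
or merge vertices for those formats.  STL stores an unindexed triangle soup;
on import exact duplicate vertices are welded in first-occurrence order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh


class MeshValidationError(ValueError):
    """Raised when a mesh violates the TriangleMesh invariants."""


_FORMATS = ("ply", "stl", "obj")


@dataclass
class TriangleMesh:
    """A closed (or open) triangle surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Triplets of vertex indices, counter-clockwise for outward normals.
    subject_id : str, optional
        Opaque label carried through the pipeline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    # -- invariants -------------------------------------------------------
    def validate(self) -> "TriangleMesh":
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) == 0:
            raise MeshValidationError("faces must be a non-empty (m, 3) array")
        if not np.isfinite(v).all():
            raise MeshValidationError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshValidationError("face indices out of range")
        if (np.diff(np.sort(f, axis=1), axis=1) == 0).any():
            raise MeshValidationError("face with repeated vertex index")
        referenced = np.zeros(len(v), dtype=bool)
        referenced[f.ravel()] = True
        if not referenced.all():
            unref = np.flatnonzero(~referenced)
            raise MeshValidationError(f"unreferenced vertices: {unref[:10].tolist()}")
        if self.area() <= 0:
            raise MeshValidationError("surface area must be strictly positive")
        return self

    # -- geometry ---------------------------------------------------------
    def triangle_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return cross / norm

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.subject_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Return a rigidly moved copy: v -> v @ R.T + t."""
        return TriangleMesh(
            self.vertices @ np.asarray(rotation).T + np.asarray(translation),
            self.faces.copy(),
            self.subject_id,
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class DisplacementStats:
    """Per-vertex movement report of a smoothing pass (mm)."""

    mean_displacement: float
    max_displacement: float
    n_vertices: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_displacement <= self.max_displacement + 1e-15:
            raise ValueError("require 0 <= mean_displacement <= max_displacement")


def _infer_format(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
    return fmt


def read_mesh(path: str | Path, format: str | None = None, unit_scale: float = 1.0,
              subject_id: str | None = None) -> TriangleMesh:
    """Read a PLY/STL/OBJ surface, preserving vertex order from the file.

    STL files carry no shared vertex indexing; exact duplicates are welded
    in first-occurrence order so the result has a well-defined topology.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    loaded = trimesh.load(str(path), file_type=fmt, process=False, maintain_order=True)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if len(geoms) != 1:
            raise MeshValidationError(f"expected a single mesh in {path}")
        loaded = geoms[0]
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if fmt == "stl" and len(vertices):
        vertices, faces = _weld(vertices, faces)
    mesh = TriangleMesh(vertices * float(unit_scale), faces,
                        subject_id or path.stem)
    return mesh.validate()


def _weld(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge exactly-equal vertices, keeping first-occurrence order."""
    _, first, inverse = np.unique(vertices, axis=0, return_index=True,
                                  return_inverse=True)
    order = np.argsort(first)               # unique ids by first appearance
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[np.sort(first)], rank[inverse][faces]


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh to PLY (binary little-endian), STL (binary) or OBJ."""
    path = Path(path)
    fmt = _infer_format(path, format)
    mesh.validate()
    tm = mesh.to_trimesh()
    try:
        tm.export(str(path), file_type=fmt)
    except OSError as exc:                                  # pragma: no cover
        raise IOError(f"cannot write {path}: {exc}") from exc


def vertex_adjacency(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique edges plus a per-vertex neighbour census.

    Returns (edges, neighbor_counts, boundary_mask) where boundary vertices
    are those on an edge used by exactly one face.
    """
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
    boundary = np.zeros(len(mesh.vertices), dtype=bool)
    boundary[uniq[counts == 1].ravel()] = True
    deg = np.bincount(uniq.ravel(), minlength=len(mesh.vertices))
    return uniq, deg, boundary


def smooth_mesh(mesh: TriangleMesh, iterations: int = 1, step: float = 0.5,
                ) -> tuple[TriangleMesh, DisplacementStats]:
    """Uniform-weight Laplacian smoothing with fixed boundary vertices.

    Each iteration moves every interior vertex a fraction ``step`` of the
    way toward the mean of its edge neighbours; topology is untouched.  The
    returned :class:`DisplacementStats` reports total per-vertex movement
    across all iterations, the quality figure quoted for surface-model
    noise reduction.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mesh.validate()
    edges, deg, boundary = vertex_adjacency(mesh)
    v0 = mesh.vertices
    v = v0.copy()
    deg_safe = np.maximum(deg, 1)[:, None]
    movable = ~boundary
    for _ in range(iterations):
        acc = np.zeros_like(v)
        np.add.at(acc, edges[:, 0], v[edges[:, 1]])
        np.add.at(acc, edges[:, 1], v[edges[:, 0]])
        target = acc / deg_safe
        v[movable] += step * (target[movable] - v[movable])
    disp = np.linalg.norm(v - v0, axis=1)
    stats = DisplacementStats(float(disp.mean()), float(disp.max()), len(v))
    return TriangleMesh(v, mesh.faces.copy(), mesh.subject_id), stats


def surface_area(mesh: TriangleMesh, face_subset=None) -> float:
    """Sum of triangle areas (mm^2), optionally over a subset of faces."""
    areas = mesh.triangle_areas()
    if face_subset is None:
        return float(areas.sum())
    idx = np.asarray(sorted(face_subset), dtype=np.int64)
    if idx.size == 0:
        warnings.warn("empty face subset: surface area is zero", stacklevel=2)
        return 0.0
    if idx.min() < 0 or idx.max() >= len(areas):
        raise IndexError("face subset index out of range")
    return float(areas[idx].sum())
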