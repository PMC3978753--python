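"""Morphometric measurement of crescent-shaped meniscal surfaces.

Every measurement is taken in a deterministic anatomical frame recovered
from the geometry alone (lateral +x, anterior +y, superior +z, mm):

* the superior axis is the normal of the best-fit plane of all vertices,
  oriented so the flat tibial face (the dominant set of near-planar faces)
  points inferiorly (-z);
* the lateral axis points from the area centroid of the convex hull of the
  projected outline toward the vertex centroid — for a crescent, away from
  the open gap between the horns;
* the anterior axis completes the right-handed frame.

Left-knee surfaces are mirrored at ingest (``side="left"``) so one set of
conventions serves both sides.

Measured quantities:

* seven landmark distances — posterior/anterior horn width (PH_Wid,
  AH_Wid), horn lengths (PH_Len, AH_Len), inter-horn distance (PA_Dis),
  lateral peripheral horn thickness and width (LPH_Thic, LPH_Wid);
* projected areas — tibial-plateau coverage (Cov_Area), inter-horn gap
  (Gap_Area), femoral contact (Con_Area), all as planar projections onto
  the axial plane;
* derived indices — Cov_Pct = Cov_Area / (Gap_Area + Cov_Area),
  Tcon_Area = Gap_Area + Con_Area, RDL = PA_Dis / ((PH_Len + AH_Len) / 2);
* change rates Delta f = (f(+2 lambda) - f(-2 lambda)) / f(mean) of every
  quantity along each shape-model mode.

Gap_Area is computed as area(convex hull of the inferior footprint) minus
area(footprint): for a crescent the hull closes the opening between the
horn end faces, which is exactly the region exposed to cartilage; for a
half-annulus it reduces to the half-disc enclosed by the inner rim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .mesh_core import TriangleMesh
from .registration import CorrespondedShape
from .shape_model import ShapeModel, sample_mode

_FLAT_FACE_COS = np.cos(np.radians(10.0))


class PoseError(RuntimeError):
    """Raised when no crescent-like anatomical frame can be recovered."""


@dataclass
class AnatomicalFrame:
    """Right-handed measurement frame: rows are lateral, anterior, superior."""

    origin: np.ndarray
    axes: np.ndarray          # (3, 3), rows unit vectors

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame must be right-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (points - self.origin) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return points @ self.axes + self.origin


def standardize_pose(mesh: TriangleMesh, side: str = "right"
                     ) -> tuple[TriangleMesh, AnatomicalFrame]:
    """Express a meniscal surface in the canonical anatomical frame.

    Raises :class:`PoseError` for degenerate inputs (near-spherical, or no
    separable crescent axis).  ``side="left"`` mirrors the lateral axis
    after standardisation so measurements match the right-knee convention.
    """
    mesh.validate()
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    v = mesh.vertices
    origin = v.mean(axis=0)
    centered = v - origin
    # first pass: best-fit plane of all vertices
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[2] / svals[0] > 0.5:
        raise PoseError("no separable flat axis: surface is near-spherical")
    z_axis = vt[2]

    # orient superior axis: the flat tibial face points inferiorly
    normals = mesh.face_normals()
    areas = mesh.triangle_areas()
    ndotz = normals @ z_axis
    area_down = areas[ndotz < -_FLAT_FACE_COS].sum()
    area_up = areas[ndotz > _FLAT_FACE_COS].sum()
    if area_down + area_up == 0:
        raise PoseError("no near-planar faces: cannot orient the superior axis")
    if area_up > area_down:
        z_axis = -z_axis

    # second pass: refit the axial plane to the flat inferior facet alone,
    # so the sloped superior surface cannot tilt the frame
    flat_faces = mesh.faces[(normals @ z_axis) < -_FLAT_FACE_COS]
    flat_idx = np.unique(flat_faces)
    flat_pts = v[flat_idx] - v[flat_idx].mean(axis=0)
    _, _, vt2 = np.linalg.svd(flat_pts, full_matrices=False)
    refined = vt2[2]
    z_axis = refined if refined @ z_axis > 0 else -refined

    # in-plane: lateral axis points away from the inter-horn gap
    e1 = vt[0] - (vt[0] @ z_axis) * z_axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(z_axis, e1)
    proj = np.column_stack([centered @ e1, centered @ e2])
    hull = MultiPoint(proj).convex_hull
    gap_dir = np.array(hull.centroid.coords[0]) - proj.mean(axis=0)
    span = float(np.linalg.norm(proj.max(axis=0) - proj.min(axis=0)))
    if np.linalg.norm(gap_dir) < 1e-3 * span:
        raise PoseError("no crescent opening detectable: hull and vertex "
                        "centroids coincide")
    lateral2d = -gap_dir / np.linalg.norm(gap_dir)
    x_axis = lateral2d[0] * e1 + lateral2d[1] * e2
    x_axis -= (x_axis @ z_axis) * z_axis
    x_axis /= np.linalg.norm(x_axis)
    y_axis = np.cross(z_axis, x_axis)

    frame = AnatomicalFrame(origin, np.stack([x_axis, y_axis, z_axis]))
    local = frame.to_local(v)
    faces = mesh.faces.copy()
    if side == "left":
        # the lateral and superior axes are derived from the geometry for
        # either knee; a left knee is chirally mirrored, so reflect the
        # anterior axis to express it in right-knee convention
        local = local * np.array([1.0, -1.0, 1.0])
        faces = faces[:, ::-1]
    return TriangleMesh(local, faces, mesh.subject_id), frame


# ---------------------------------------------------------------------------
# face / vertex classification
# ---------------------------------------------------------------------------

def classify_faces(mesh: TriangleMesh, normal_threshold: float = 0.5) -> np.ndarray:
    """Label faces by outward-normal z: +1 superior, -1 inferior, 0 peripheral."""
    nz = mesh.face_normals()[:, 2]
    labels = np.zeros(len(mesh.faces), dtype=int)
    labels[nz > normal_threshold] = 1
    labels[nz < -normal_threshold] = -1
    return labels


def _vertex_class_mask(mesh: TriangleMesh, labels: np.ndarray, which: int
                       ) -> np.ndarray:
    mask = np.zeros(len(mesh.vertices), dtype=bool)
    mask[mesh.faces[labels == which].ravel()] = True
    return mask


# ---------------------------------------------------------------------------
# landmarks and distances
# ---------------------------------------------------------------------------

_BAND_FRACTION = 0.1      # mid-body band: |y| <= 10% of the y half-extent


def find_landmarks(mesh: TriangleMesh, normal_threshold: float = 0.5) -> dict:
    """Twelve named extreme points of a pose-standardised meniscus.

    The horn partition is deterministic: vertices medial of the midpoint of
    the x-extent belong to the posterior horn (y < 0) or anterior horn
    (y > 0); the mid-body band is |y| within 10% of the y half-extent.
    Coordinate ties are broken by the lowest vertex index (numpy argmin /
    argmax return the first occurrence).
    """
    v = mesh.vertices
    labels = classify_faces(mesh, normal_threshold)
    superior_v = _vertex_class_mask(mesh, labels, 1)
    inferior_v = _vertex_class_mask(mesh, labels, -1)

    x, y = v[:, 0], v[:, 1]
    x_split = 0.5 * (x.min() + x.max())
    post = np.flatnonzero((x < x_split) & (y < 0))
    ant = np.flatnonzero((x < x_split) & (y > 0))
    band = np.flatnonzero(np.abs(y) <= _BAND_FRACTION * np.abs(y).max())
    if post.size == 0 or ant.size == 0:
        raise PoseError("empty horn partition: surface is not crescent-like")
    if band.size == 0:
        raise PoseError("empty mid-body band")

    def at(indices, coord, extremum):
        vals = v[indices, coord]
        i = indices[np.argmin(vals) if extremum == "min" else np.argmax(vals)]
        return v[i]

    landmarks = {
        "ph_posterior": at(post, 1, "min"),
        "ph_anterior": at(post, 1, "max"),
        "ah_anterior": at(ant, 1, "max"),
        "ah_posterior": at(ant, 1, "min"),
        "ph_medial": at(post, 0, "min"),
        "ah_medial": at(ant, 0, "min"),
        "body_lateral": v[np.argmax(x)],
        "body_medial": at(band, 0, "min"),
        "body_lateral_mid": at(band, 0, "max"),
    }
    band_sup = band[superior_v[band]]
    band_inf = band[inferior_v[band]]
    if band_sup.size == 0 or band_inf.size == 0:
        raise PoseError("mid-body band lacks superior or inferior vertices")
    landmarks["body_lateral_superior"] = at(band_sup, 0, "max")
    landmarks["body_lateral_inferior"] = at(band_inf, 0, "max")
    landmarks["gap_chord_mid"] = 0.5 * (landmarks["ph_medial"]
                                        + landmarks["ah_medial"])
    return landmarks


def measure_distances(landmarks: dict) -> dict:
    """The seven landmark distances (mm) from a complete landmark set.

    Widths, lengths and the inter-horn distance are axial-plane (x-y)
    measures; only the peripheral thickness involves the superior axis.
    """
    lm = landmarks

    def d_axial(a, b):
        return float(np.linalg.norm(lm[a][:2] - lm[b][:2]))

    def d_3d(a, b):
        return float(np.linalg.norm(lm[a] - lm[b]))

    return {
        "PH_Wid": d_axial("ph_anterior", "ph_posterior"),
        "AH_Wid": d_axial("ah_anterior", "ah_posterior"),
        "PH_Len": d_axial("body_lateral", "ph_medial"),
        "AH_Len": d_axial("body_lateral", "ah_medial"),
        "PA_Dis": float(abs(lm["ah_medial"][1] - lm["ph_medial"][1])),
        "LPH_Thic": d_3d("body_lateral_superior", "body_lateral_inferior"),
        "LPH_Wid": d_axial("body_lateral_mid", "body_medial"),
    }


# ---------------------------------------------------------------------------
# areas
# ---------------------------------------------------------------------------

def _projected_region(mesh: TriangleMesh, face_mask: np.ndarray):
    tris = mesh.vertices[mesh.faces[face_mask]][:, :, :2]
    polys = []
    for t in tris:
        p = Polygon(t)
        if p.is_valid and p.area > 1e-12:
            polys.append(p)
    if not polys:
        return None
    region = unary_union(polys)
    if region.geom_type == "MultiPolygon":
        parts = sorted(region.geoms, key=lambda g: g.area, reverse=True)
        if sum(p.area for p in parts[1:]) > 0.01 * parts[0].area:
            raise PoseError("projected footprint is disconnected")
        region = parts[0]
    return region


def coverage_areas(mesh: TriangleMesh, normal_threshold: float = 0.5
                   ) -> tuple[float, float, float]:
    """(Cov_Area, Gap_Area, Con_Area) in mm^2 on a standardised mesh.

    Faces are classified by outward-normal z against ``normal_threshold``;
    the inferior and superior face sets are projected onto the axial plane
    and unioned.  Gap_Area is the area the convex hull of the inferior
    footprint adds over the footprint itself — the region enclosed between
    the inner rim, the horn end faces and the chord closing the opening.
    """
    labels = classify_faces(mesh, normal_threshold)
    inferior = _projected_region(mesh, labels == -1)
    superior = _projected_region(mesh, labels == 1)
    if inferior is None or superior is None:
        raise PoseError("no inferior or superior faces at this normal threshold")
    cov = inferior.area
    gap = inferior.convex_hull.area - cov
    con = superior.area
    return float(cov), float(gap), float(con)


# ---------------------------------------------------------------------------
# derived indices
# ---------------------------------------------------------------------------

def coverage_percentage(cov_area: float, gap_area: float) -> float:
    """Fraction of the (covered + gap) plateau region occupied by the meniscus."""
    if cov_area <= 0:
        raise ValueError("Cov_Area must be positive")
    if gap_area < 0:
        raise ValueError("Gap_Area must be non-negative")
    return cov_area / (gap_area + cov_area)


def total_contact_area(gap_area: float, con_area: float) -> float:
    """Total knee-joint contact area: gap (cartilage) + meniscus superior face."""
    if gap_area < 0 or con_area < 0:
        raise ValueError("areas must be non-negative")
    return gap_area + con_area


def rdl(pa_dis: float, ph_len: float, ah_len: float) -> float:
    """Ratio of inter-horn distance to mean horn length (dimensionless)."""
    denom = 0.5 * (ph_len + ah_len)
    if denom <= 0:
        raise ValueError("mean horn length must be positive")
    return pa_dis / denom


def change_rate(f_mean: float, f_plus: float, f_minus: float) -> float:
    """Relative change of a parameter between the +2 and -2 sigma shapes.

    Delta f = (f_plus - f_minus) / f_mean, signed.
    """
    if f_mean == 0:
        raise ValueError("f_mean must be non-zero for a change rate")
    return (f_plus - f_minus) / f_mean


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class MorphometricRecord:
    """All quantitative shape parameters of one meniscal surface."""

    subject_id: str | None
    PH_Wid: float
    AH_Wid: float
    PH_Len: float
    AH_Len: float
    PA_Dis: float
    LPH_Thic: float
    LPH_Wid: float
    Cov_Area: float
    Gap_Area: float
    Con_Area: float
    Cov_Pct: float
    Tcon_Area: float
    RDL: float

    PARAMETERS = ("PH_Wid", "AH_Wid", "PH_Len", "AH_Len", "PA_Dis",
                  "LPH_Thic", "LPH_Wid", "Cov_Area", "Gap_Area", "Con_Area",
                  "Cov_Pct", "Tcon_Area", "RDL")

    def validate(self) -> "MorphometricRecord":
        for name in self.PARAMETERS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not np.isclose(self.Cov_Pct,
                          self.Cov_Area / (self.Gap_Area + self.Cov_Area)):
            raise ValueError("Cov_Pct identity violated")
        if not np.isclose(self.Tcon_Area, self.Gap_Area + self.Con_Area):
            raise ValueError("Tcon_Area identity violated")
        if not np.isclose(self.RDL,
                          self.PA_Dis / (0.5 * (self.PH_Len + self.AH_Len))):
            raise ValueError("RDL identity violated")
        return self

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.PARAMETERS}


def measure_record(mesh: TriangleMesh, standardized: bool = False,
                   side: str = "right", normal_threshold: float = 0.5
                   ) -> MorphometricRecord:
    """Measure every morphometric parameter of one surface."""
    if not standardized:
        mesh, _ = standardize_pose(mesh, side=side)
    dist = measure_distances(find_landmarks(mesh, normal_threshold))
    cov, gap, con = coverage_areas(mesh, normal_threshold)
    return MorphometricRecord(
        subject_id=mesh.subject_id,
        **dist,
        Cov_Area=cov, Gap_Area=gap, Con_Area=con,
        Cov_Pct=coverage_percentage(cov, gap),
        Tcon_Area=total_contact_area(gap, con),
        RDL=rdl(dist["PA_Dis"], dist["PH_Len"], dist["AH_Len"]),
    ).validate()


def measure_shape(shape: CorrespondedShape, faces: np.ndarray,
                  **kwargs) -> MorphometricRecord:
    """Measure a shape vector on the reference topology."""
    return measure_record(shape.to_mesh(faces), **kwargs)


def records_table(records: list[MorphometricRecord]) -> pd.DataFrame:
    """Per-shape records as a DataFrame with the canonical column names."""
    rows = [{"subject_id": r.subject_id, **r.as_dict()} for r in records]
    return pd.DataFrame(rows).set_index("subject_id")


_TABLE_COLUMNS = ("dCov_Area", "dCov_Pct", "dPH_Wid", "dAH_Wid", "dPA_Dis",
                  "dPH_Len", "dAH_Len", "dLPH_Thic", "dLPH_Wid", "dRDL",
                  "dCon_Area", "dTcon_Area")


def mode_change_table(model: ShapeModel, faces: np.ndarray, k_modes: int = 6,
                      normal_threshold: float = 0.5) -> pd.DataFrame:
    """Change rates (percent) of every parameter along each model mode.

    For mode k the parameters are measured on the mean shape and on the
    shapes at +2 and -2 standard deviations along that mode; the table cell
    is 100 * (f(+2) - f(-2)) / f(mean).  Modes beyond the model's non-zero
    rank yield all-zero rows; individual measurement failures yield NaN
    cells with a warning.
    """
    mean_rec = measure_shape(
        CorrespondedShape(model.mean_shape, "mean"), faces,
        normal_threshold=normal_threshold)
    rows = []
    params = [c[1:] for c in _TABLE_COLUMNS]        # strip the 'd' prefix
    for k in range(1, k_modes + 1):
        if k > model.n_modes or model.mode_stddevs[k - 1] <= 0:
            rows.append(dict.fromkeys(_TABLE_COLUMNS, 0.0))
            continue
        row = {}
        try:
            rec_plus = measure_shape(sample_mode(model, k, +2.0), faces,
                                     normal_threshold=normal_threshold)
            rec_minus = measure_shape(sample_mode(model, k, -2.0), faces,
                                      normal_threshold=normal_threshold)
        except (PoseError, ValueError) as exc:
            warnings.warn(f"mode {k}: measurement failed ({exc})", stacklevel=2)
            rows.append(dict.fromkeys(_TABLE_COLUMNS, np.nan))
            continue
        for col, p in zip(_TABLE_COLUMNS, params):
            try:
                row[col] = 100.0 * change_rate(getattr(mean_rec, p),
                                               getattr(rec_plus, p),
                                               getattr(rec_minus, p))
            except ValueError as exc:
                warnings.warn(f"mode {k}, {p}: {exc}", stacklevel=2)
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, index=pd.RangeIndex(1, k_modes + 1, name="mode"))
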