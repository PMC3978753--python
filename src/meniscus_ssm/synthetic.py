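"""Parametric meniscus-like surfaces and linked anthropometric covariates.

The generator sweeps a wedge cross-section (flat inferior edge, vertical
peripheral wall, sloped superior face tapering to the inner rim) along a
circular arc: a crescent opening toward -x (medial), body toward +x
(lateral), superior +z.  An ``opening_half_angle`` of alpha degrees leaves
a gap of 2*alpha between the horn tips, i.e. the sweep covers the arc
+/- (180 - alpha) degrees.  Horn taper scales each cross-section about its
own centroid, which keeps the three generative variation modes (overall
size, horn openness, horn-width taper) close to mutually orthogonal in
vertex space.

Every mesh comes with analytic ground truth computed from the continuous
sweep geometry (dense corner curves, never the mesh), so each stage of the
shape-analysis pipeline can be checked against known values.  A cohort
draws per-subject latent scores for the three modes, links anthropometric
covariates to the latent size score at configurable correlations, and
assigns sex alternately for an exactly balanced cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh as _trimesh
from shapely.geometry import Polygon

from .correlations import AnthropometricRecord
from .mesh_core import TriangleMesh
from .registration import FFDLattice, make_lattice


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class MeniscusParams:
    """Geometry of one synthetic lateral meniscus (mm, degrees).

    Defaults are loosely sized to an adult lateral meniscus; they are
    fixture constants defining the synthetic study conditions.
    """

    arc_radius: float = 17.5            # crescent midline radius
    opening_half_angle: float = 60.0    # half the angular gap between horns
    body_width: float = 10.0            # radial wedge width at mid-body
    horn_width_scale: float = 0.55      # cross-section scale at the horn tips
    peripheral_thickness: float = 6.0   # wedge height at the outer wall
    scale: float = 1.0                  # global size multiplier
    noise_sigma: float = 0.0            # per-coordinate Gaussian noise, mm
    resolution: tuple = (161, 14)       # stations along arc, points per section
    side: str = "right"

    def validate(self) -> "MeniscusParams":
        for name in ("arc_radius", "body_width", "horn_width_scale",
                     "peripheral_thickness", "scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 10.0 < self.opening_half_angle < 85.0:
            raise ValueError("opening_half_angle must be in (10, 85) degrees")
        if not 0.2 <= self.horn_width_scale <= 0.95:
            raise ValueError("horn_width_scale must be in [0.2, 0.95]: "
                             "horns taper toward the tips without collapsing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.resolution[0] < 40 or self.resolution[1] < 12:
            raise ValueError("resolution must be at least (40, 12)")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        return self


# ---------------------------------------------------------------------------
# cross-section template and sweep machinery
# ---------------------------------------------------------------------------

def _wedge_template(n_cs: int) -> np.ndarray:
    """Closed wedge loop in normalised (delta, zeta): delta in [-1/2, 1/2]
    across the width, zeta in [0, 1] over the thickness.  Corners: inner rim
    I=(-1/2, 0), outer-bottom A=(1/2, 0), outer-top B=(1/2, 1)."""
    n_bottom = max(2, round(0.4 * n_cs))
    n_wall = max(2, round(0.2 * n_cs))
    n_slope = n_cs - n_bottom - n_wall
    if n_slope < 2:
        raise ValueError("cross-section resolution too low for the wedge")
    bottom = np.stack([np.linspace(-0.5, 0.5, n_bottom + 1)[:-1],
                       np.zeros(n_bottom)], axis=1)
    wall = np.stack([np.full(n_wall, 0.5),
                     np.linspace(0.0, 1.0, n_wall + 1)[:-1]], axis=1)
    t = np.linspace(0.0, 1.0, n_slope + 1)[:-1]
    slope = np.stack([0.5 - t, 1.0 - t], axis=1)
    return np.concatenate([bottom, wall, slope])


def _taper(u: np.ndarray, horn_width_scale: float) -> np.ndarray:
    """Cross-section scale along the arc; u = |phi| / phi_max in [0, 1].

    Full size over the central half of the arc, then a smoothstep taper to
    ``horn_width_scale`` at the tips.
    """
    u = np.asarray(u, dtype=float)
    t = np.clip((u - 0.5) / 0.5, 0.0, 1.0)
    g = 3 * t ** 2 - 2 * t ** 3
    return 1.0 - (1.0 - horn_width_scale) * g


def _profiles(params: MeniscusParams, phi: np.ndarray) -> np.ndarray:
    """(n_phi, n_cs, 2) profile curves: (radius, z) at each arc station.

    The horn taper scales the cross-section width about its mean radial
    offset (which keeps the size and horn-width variation fields nearly
    orthogonal) and the thickness about z = 0, so the inferior tibial
    facet stays exactly planar along the whole crescent.
    """
    template = _wedge_template(params.resolution[1])
    d_bar = template[:, 0].mean()
    c = _taper(np.abs(phi) / np.radians(180.0 - params.opening_half_angle),
               params.horn_width_scale)
    delta = d_bar + c[:, None] * (template[None, :, 0] - d_bar)
    zeta = c[:, None] * template[None, :, 1]
    radius = params.arc_radius + delta * params.body_width
    z = zeta * params.peripheral_thickness
    return np.stack([radius, z], axis=-1)


def _sweep(profiles: np.ndarray, phi: np.ndarray, closed: bool = False
           ) -> tuple[np.ndarray, np.ndarray]:
    """Sweep per-station (radius, z) loops along arc angles ``phi``.

    Open sweeps are capped with triangle fans to the end-loop centroids.
    Returns (vertices, faces) with consistent winding (not yet oriented).
    """
    n_phi, n_cs = profiles.shape[:2]
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    verts = np.empty((n_phi, n_cs, 3))
    verts[..., 0] = profiles[..., 0] * cos_p[:, None]
    verts[..., 1] = profiles[..., 0] * sin_p[:, None]
    verts[..., 2] = profiles[..., 1]
    vertices = verts.reshape(-1, 3)

    def vid(i, j):
        return i * n_cs + j % n_cs

    faces = []
    n_seg = n_phi if closed else n_phi - 1
    for i in range(n_seg):
        i2 = (i + 1) % n_phi
        for j in range(n_cs):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i2, j), vid(i2, j + 1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    if not closed:
        c0 = len(vertices)
        c1 = c0 + 1
        vertices = np.vstack([vertices, verts[0].mean(axis=0),
                              verts[-1].mean(axis=0)])
        for j in range(n_cs):
            faces.append([c0, vid(0, j + 1), vid(0, j)])
            faces.append([c1, vid(n_phi - 1, j), vid(n_phi - 1, j + 1)])
    return vertices, np.array(faces, dtype=np.int64)


def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip all faces if the signed volume is negative."""
    if _trimesh.Trimesh(vertices, faces, process=False).volume < 0:
        return faces[:, ::-1].copy()
    return faces


# ---------------------------------------------------------------------------
# single-mesh generation with analytic ground truth
# ---------------------------------------------------------------------------

@dataclass
class MeniscusTruth:
    """Analytic ground truth of a noise-free parametric meniscus."""

    params: MeniscusParams
    horn_tip_posterior: np.ndarray      # cap centroid, canonical pose
    horn_tip_anterior: np.ndarray
    landmarks: dict                     # analytic counterparts of find_landmarks
    distances: dict                     # the seven landmark distances
    cov_area: float
    gap_area: float
    con_area: float


def generate_meniscus(params: MeniscusParams | None = None, seed: int = 0
                      ) -> tuple[TriangleMesh, MeniscusTruth]:
    """Build one synthetic meniscus mesh plus its analytic ground truth.

    The mesh is closed and manifold, in canonical pose (lateral +x,
    anterior +y, superior +z, arc centre at the origin).  Ground truth is
    evaluated on the continuous sweep geometry, independent of the mesh.
    """
    params = (params or MeniscusParams()).validate()
    phi_max = np.radians(180.0 - params.opening_half_angle)
    phi = np.linspace(-phi_max, phi_max, params.resolution[0])
    profiles = _profiles(params, phi)
    vertices, faces = _sweep(profiles, phi, closed=False)
    vertices = vertices * params.scale
    faces = _orient_outward(vertices, faces)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vertices = vertices + rng.normal(0.0, params.noise_sigma,
                                         vertices.shape)
    if params.side == "left":
        vertices = vertices * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1].copy()

    truth = analytic_truth(params)
    mesh = TriangleMesh(vertices, faces, subject_id=f"synthetic_{seed}")
    mesh.validate()
    if not mesh.to_trimesh().is_watertight:
        raise RuntimeError("generated mesh is not watertight")
    return mesh, truth


def analytic_truth(params: MeniscusParams, n_dense: int = 2001) -> MeniscusTruth:
    """Ground-truth landmarks, distances and projected areas from the
    continuous sweep geometry (densely sampled corner curves)."""
    params.validate()
    phi_max = np.radians(180.0 - params.opening_half_angle)
    phi = np.linspace(-phi_max, phi_max, n_dense)
    template = _wedge_template(params.resolution[1])
    d_bar = template[:, 0].mean()
    c = _taper(np.abs(phi) / phi_max, params.horn_width_scale)

    def corner_curve(delta, zeta):
        d = d_bar + c * (delta - d_bar)
        z = c * zeta
        r = params.arc_radius + d * params.body_width
        return params.scale * np.stack(
            [r * np.cos(phi), r * np.sin(phi),
             z * params.peripheral_thickness], axis=1)

    curve_inner = corner_curve(-0.5, 0.0)     # inner rim (bottom and slope)
    curve_outer_lo = corner_curve(0.5, 0.0)   # outer-bottom corner
    curve_outer_hi = corner_curve(0.5, 1.0)   # outer-top corner

    inferior = np.vstack([curve_inner, curve_outer_lo])
    superior = np.vstack([curve_inner, curve_outer_hi])
    allpts = np.vstack([curve_inner, curve_outer_lo, curve_outer_hi])

    x, y = allpts[:, 0], allpts[:, 1]
    x_split = 0.5 * (x.min() + x.max())
    post = allpts[(x < x_split) & (y < 0)]
    ant = allpts[(x < x_split) & (y > 0)]
    band_mask = np.abs(y) <= 0.1 * np.abs(y).max()
    band = allpts[band_mask]

    def extreme(pts, coord, kind):
        return pts[np.argmin(pts[:, coord]) if kind == "min"
                   else np.argmax(pts[:, coord])]

    lm = {
        "ph_posterior": extreme(post, 1, "min"),
        "ph_anterior": extreme(post, 1, "max"),
        "ah_anterior": extreme(ant, 1, "max"),
        "ah_posterior": extreme(ant, 1, "min"),
        "ph_medial": extreme(post, 0, "min"),
        "ah_medial": extreme(ant, 0, "min"),
        "body_lateral": extreme(allpts, 0, "max"),
        "body_medial": extreme(band, 0, "min"),
        "body_lateral_mid": extreme(band, 0, "max"),
    }
    band_sup = superior[np.abs(superior[:, 1]) <= 0.1 * np.abs(y).max()]
    band_inf = inferior[np.abs(inferior[:, 1]) <= 0.1 * np.abs(y).max()]
    lm["body_lateral_superior"] = extreme(band_sup, 0, "max")
    lm["body_lateral_inferior"] = extreme(band_inf, 0, "max")
    lm["gap_chord_mid"] = 0.5 * (lm["ph_medial"] + lm["ah_medial"])

    def d_axial(a, b):
        return float(np.linalg.norm(lm[a][:2] - lm[b][:2]))

    distances = {
        "PH_Wid": d_axial("ph_anterior", "ph_posterior"),
        "AH_Wid": d_axial("ah_anterior", "ah_posterior"),
        "PH_Len": d_axial("body_lateral", "ph_medial"),
        "AH_Len": d_axial("body_lateral", "ah_medial"),
        "PA_Dis": float(abs(lm["ah_medial"][1] - lm["ph_medial"][1])),
        "LPH_Thic": float(np.linalg.norm(lm["body_lateral_superior"]
                                         - lm["body_lateral_inferior"])),
        "LPH_Wid": d_axial("body_lateral_mid", "body_medial"),
    }

    # projected areas of the continuous footprint (annular strip)
    r_in = np.hypot(curve_inner[:, 0], curve_inner[:, 1])
    r_out = np.hypot(curve_outer_lo[:, 0], curve_outer_lo[:, 1])
    cov_area = float(np.trapezoid(0.5 * (r_out ** 2 - r_in ** 2), phi))
    ring = np.vstack([curve_outer_lo[:, :2], curve_inner[::-1, :2]])
    footprint = Polygon(ring)
    gap_area = float(footprint.convex_hull.area - footprint.area)

    # horn-tip cap centroids (cross-section loop centroid at the end stations)
    def tip(sign):
        cc = float(_taper(1.0, params.horn_width_scale))
        delta = d_bar + cc * (template[:, 0] - d_bar)
        r = params.arc_radius + delta * params.body_width
        pts = params.scale * np.stack(
            [r * np.cos(sign * phi_max), r * np.sin(sign * phi_max),
             cc * template[:, 1] * params.peripheral_thickness], axis=1)
        return pts.mean(axis=0)

    return MeniscusTruth(
        params=params,
        horn_tip_posterior=tip(-1.0),
        horn_tip_anterior=tip(+1.0),
        landmarks=lm,
        distances=distances,
        cov_area=cov_area,
        gap_area=gap_area,
        con_area=cov_area,      # superior face projects onto the same strip
    )


# ---------------------------------------------------------------------------
# fixture surfaces
# ---------------------------------------------------------------------------

def annulus_slab(r_inner: float = 10.0, r_outer: float = 15.0,
                 height: float = 2.0, angle_deg: float = 180.0,
                 n_arc: int = 96, n_edge: int = 3) -> TriangleMesh:
    """Flat-topped annular slab (half-annulus by default), a geometry whose
    projected coverage and gap areas have closed forms."""
    corners = np.array([[r_inner, 0.0], [r_outer, 0.0],
                        [r_outer, height], [r_inner, height]])
    loop = []
    for k in range(4):
        a, b = corners[k], corners[(k + 1) % 4]
        seg = np.linspace(0.0, 1.0, n_edge + 1)[:-1]
        loop.extend(a + seg[:, None] * (b - a))
    loop = np.asarray(loop)
    closed = np.isclose(angle_deg, 360.0)
    theta = (np.linspace(0.0, 2 * np.pi, n_arc, endpoint=False) if closed
             else np.linspace(0.0, np.radians(angle_deg), n_arc))
    profiles = np.broadcast_to(loop, (len(theta),) + loop.shape)
    vertices, faces = _sweep(np.array(profiles), theta, closed=closed)
    faces = _orient_outward(vertices, faces)
    return TriangleMesh(vertices, faces, subject_id="annulus_slab").validate()


def make_smooth_lattice(mesh: TriangleMesh, spacing: float = 10.0,
                        amplitude: float = 0.5, seed: int = 0) -> FFDLattice:
    """Random smooth B-spline displacement field covering a mesh (test fixture)."""
    lat = make_lattice(mesh.vertices.min(axis=0), mesh.vertices.max(axis=0),
                       spacing)
    rng = np.random.default_rng(seed)
    lat.displacements = rng.normal(0.0, amplitude, lat.displacements.shape)
    return lat


def apply_known_deformation(mesh: TriangleMesh, lattice: FFDLattice
                            ) -> TriangleMesh:
    """Displace mesh vertices by a B-spline field; topology unchanged.

    Raises if the field folds the surface (det(I + grad u) <= 0 anywhere).
    """
    jac = np.eye(3) + lattice.jacobian(mesh.vertices)
    dets = np.linalg.det(jac)
    if (dets <= 0).any():
        raise ValueError(f"deformation folds the surface at "
                         f"{int((dets <= 0).sum())} vertices")
    return TriangleMesh(mesh.vertices + lattice.evaluate(mesh.vertices),
                        mesh.faces.copy(), mesh.subject_id)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: covariate -> (mean, stddev, correlation with the latent size score)
DEFAULT_ANTHRO_LINK = {
    "height": (169.1, 9.7, 0.6),
    "weight": (70.93, 11.98, 0.6),
    "condyle_width": (75.0, 4.5, 0.6),
    "axial_rotation": (7.07, 7.12, 0.0),
}

MODE_NAMES = ("size", "openness", "horn_width")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    The three generative modes perturb global scale, opening half-angle and
    horn-width taper.  ``mode_effect_ratio`` fixes the *vertex-space*
    magnitudes of the three modes relative to each other; the absolute
    magnitude is anchored by ``size_rel_sd``, the relative standard
    deviation of overall size (6% by default, a realistic adult
    between-subject size spread).  BMI is derived from the sampled height
    and weight, so the three are exactly consistent.
    """

    n_subjects: int = 50
    mean_params: MeniscusParams = field(default_factory=MeniscusParams)
    size_rel_sd: float = 0.06
    mode_effect_ratio: tuple = (3.0, 2.0, 1.0)
    anthro_link: dict = field(default_factory=lambda: dict(DEFAULT_ANTHRO_LINK))
    noise_sigma: float = 0.05
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for name, (_, sd, rho) in self.anthro_link.items():
            if sd <= 0:
                raise ValueError(f"{name}: stddev must be positive")
            if not -1 < rho < 1:
                raise ValueError(f"{name}: correlation must be in (-1, 1)")
        if self.size_rel_sd <= 0 or min(self.mode_effect_ratio) <= 0:
            raise ValueError("effect sizes must be positive")
        self.mean_params.validate()
        return self


def _flat(vertices: np.ndarray) -> np.ndarray:
    return np.concatenate([vertices[:, 0], vertices[:, 1], vertices[:, 2]])


def generative_mode_fields(params: MeniscusParams) -> tuple[np.ndarray, np.ndarray]:
    """Linearised vertex-space fields of the three generative modes.

    Central finite differences of the noise-free generator with respect to
    (log scale, opening half-angle, horn-width scale).  Returns
    (fields (3, 3n), norms (3,)) where field k is d x / d parameter_k.
    """
    base = replace(params, noise_sigma=0.0)

    def verts(p):
        phi_max = np.radians(180.0 - p.opening_half_angle)
        phi = np.linspace(-phi_max, phi_max, p.resolution[0])
        v, _ = _sweep(_profiles(p, phi), phi, closed=False)
        return _flat(v * p.scale)

    steps = {"scale": 0.01 * base.scale, "opening_half_angle": 0.25,
             "horn_width_scale": 0.01}
    fields = []
    for name, h in steps.items():
        hi = verts(replace(base, **{name: getattr(base, name) + h}))
        lo = verts(replace(base, **{name: getattr(base, name) - h}))
        fields.append((hi - lo) / (2 * h))
    fields = np.stack(fields)
    return fields, np.linalg.norm(fields, axis=1)


def pose_filtered_fields(params: MeniscusParams
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Generative mode fields with their rigid-motion components removed.

    A pose-invariant shape analysis cannot see the component of a
    variation field that is an infinitesimal rigid motion of the mean
    shape (3 translations + 3 linearised rotations).  Projecting those six
    directions out of the generative fields gives the vertex-space mode
    magnitudes such an analysis should recover.  Returns (fields, norms).
    """
    fields, _ = generative_mode_fields(params)
    phi_max = np.radians(180.0 - params.opening_half_angle)
    phi = np.linspace(-phi_max, phi_max, params.resolution[0])
    mean_pts, _ = _sweep(_profiles(params, phi), phi, closed=False)
    mean_pts = mean_pts * params.scale
    centered = mean_pts - mean_pts.mean(axis=0)
    n = len(mean_pts)
    rigid = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        rigid.append(_flat(t))
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        rigid.append(_flat(np.cross(axis, centered)))
    q, _ = np.linalg.qr(np.stack(rigid).T)
    filtered = fields - (fields @ q) @ q.T
    return filtered, np.linalg.norm(filtered, axis=1)


def generative_mode_basis(spec: CohortSpec
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray]:
    """Orthogonalised generative modes and their study-condition magnitudes.

    The three raw parameter directions (scale, opening angle, horn taper)
    have pose-filtered vertex-space fields that are not mutually
    orthogonal — notably, opening the horns also changes the crescent's
    apparent size.  A principal-component analysis can only recover
    orthogonal directions, so the cohort plants orthogonalised modes:
    Gram-Schmidt in pose-filtered field space, applied to the parameter
    directions in order size, openness, horn width.  Mode 2 is therefore
    "openness at fixed apparent size" (an opening-angle change with a small
    compensating scale adjustment), and so on.

    Magnitudes are measured on the pose-filtered fields (a rigid shift of
    the whole crescent is pose, not shape).  The size anchor sets
    lambda_1 = size_rel_sd * |pose-filtered size field|; the remaining SDs
    follow ``mode_effect_ratio``.

    Returns (directions, param_sds, lambdas, fields): ``directions`` rows
    are parameter-space combinations of (scale, opening_half_angle,
    horn_width_scale) per unit mode; ``fields`` rows are the matching
    orthogonal pose-filtered vertex fields per unit mode.
    """
    fields_raw, _ = pose_filtered_fields(spec.mean_params)
    u = fields_raw.copy()
    directions = np.eye(3)
    for k in range(1, 3):
        for j in range(k):
            b = (u[j] @ fields_raw[k]) / (u[j] @ u[j])
            u[k] = u[k] - b * u[j]
            directions[k] = directions[k] - b * directions[j]
    norms = np.linalg.norm(u, axis=1)
    lambda1 = spec.size_rel_sd * spec.mean_params.scale * norms[0]
    ratio = np.asarray(spec.mode_effect_ratio, dtype=float)
    lambdas = lambda1 * ratio / ratio[0]
    param_sds = lambdas / norms
    return directions, param_sds, lambdas, u


def generative_mode_sds(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode parameter SDs and vertex-space SDs (the target lambdas)."""
    _, param_sds, lambdas, _ = generative_mode_basis(spec)
    return param_sds, lambdas


@dataclass
class CohortResult:
    meshes: list
    anthro: list
    truth: pd.DataFrame                 # latent scores and per-subject params
    generative_stddevs: np.ndarray      # vertex-space lambdas of the 3 modes
    spec: CohortSpec


def generate_cohort(spec: CohortSpec | None = None) -> CohortResult:
    """Draw a cohort of meshes plus linked anthropometrics and ground truth.

    Latent mode scores are independent standard normals per subject; the
    anthropometric covariates are drawn conditionally on the latent size
    score at the configured correlations.  Sex alternates male/female for
    exact balance.  Parameter draws violating the geometric invariants are
    redrawn (more than 100 redraws raises).
    """
    spec = (spec or CohortSpec()).validate()
    rng = np.random.default_rng(spec.seed)
    directions, param_sds, lambdas, _ = generative_mode_basis(spec)
    base = spec.mean_params

    meshes, anthro, rows = [], [], []
    n_redraws = 0
    for i in range(spec.n_subjects):
        subject = f"S{i:03d}"
        while True:
            z = rng.normal(size=3)
            offset = (z * param_sds) @ directions
            try:
                params = replace(
                    base,
                    scale=base.scale + offset[0],
                    opening_half_angle=base.opening_half_angle + offset[1],
                    horn_width_scale=base.horn_width_scale + offset[2],
                    noise_sigma=spec.noise_sigma,
                ).validate()
                break
            except ValueError:
                n_redraws += 1
                if n_redraws > 100:
                    raise RuntimeError(
                        "more than 100 redraws of infeasible parameters")
        mesh, _ = generate_meniscus(params, seed=spec.seed + 101 + i)
        mesh.subject_id = subject
        meshes.append(mesh)

        cov = {}
        for name, (mu, sd, rho) in spec.anthro_link.items():
            eps = rng.normal()
            cov[name] = mu + sd * (rho * z[0] + np.sqrt(1 - rho ** 2) * eps)
        bmi = cov["weight"] / (cov["height"] / 100.0) ** 2
        sex = "male" if i % 2 == 0 else "female"
        anthro.append(AnthropometricRecord(
            subject_id=subject, height=cov["height"], weight=cov["weight"],
            bmi=bmi, condyle_width=cov["condyle_width"],
            axial_rotation=cov["axial_rotation"], sex=sex).validate())
        rows.append({"subject_id": subject, "z_size": z[0],
                     "z_openness": z[1], "z_horn_width": z[2],
                     "scale": params.scale,
                     "opening_half_angle": params.opening_half_angle,
                     "horn_width_scale": params.horn_width_scale,
                     "sex": sex})
    truth = pd.DataFrame(rows).set_index("subject_id")
    return CohortResult(meshes, anthro, truth, lambdas, spec)
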