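"""Point-distribution shape model over corresponded surface point sets.

Given shape vectors x = (x1..xn, y1..yn, z1..zn) on a shared topology, the
model is the arithmetic mean shape plus the principal axes of the sample
covariance (normalised by n_subjects - 1).  The standard deviation along
principal axis k is lambda_k = sqrt(eigenvalue_k); a training cohort of N
shapes has at most N - 1 non-zero axes.  Each axis is a principal
morphological variation (PMV): new shapes are synthesised as
mean + score * lambda_k * mode_k, with score conventionally swept over
[-2, +2] to visualise a mode at +/- 2 standard deviations.

The decomposition is computed through the SVD of the centered data matrix
(the dual / Gram route), so the 3n x 3n covariance is never formed.  No
scaling normalisation is ever applied, so overall size remains inside the
model and dominates the first mode; :func:`procrustes_align` offers a
rigid-only (rotation + translation) re-alignment to the cohort mean that
removes residual pose scatter before the PCA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .registration import CorrespondedShape

_EIGVAL_FLOOR = 1e-10          # relative to the leading eigenvalue


@dataclass
class ShapeModel:
    """Mean shape, orthonormal modes, per-mode standard deviations, scores.

    Attributes
    ----------
    mean_shape : (3n,) array, mm
    modes : (k, 3n) array
        Unit-norm principal axes, ordered by decreasing lambda.
    mode_stddevs : (k,) array, mm
        lambda_k, the standard deviation of the training scores on mode k.
    scores : (n_subjects, k) array
        Per-subject coefficients; column k has zero mean and stddev lambda_k.
    subject_ids : list of str
    """

    mean_shape: np.ndarray
    modes: np.ndarray
    mode_stddevs: np.ndarray
    scores: np.ndarray
    subject_ids: list

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.mode_stddevs = np.asarray(self.mode_stddevs, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def n_points(self) -> int:
        return len(self.mean_shape) // 3

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean_shape": self.mean_shape.tolist(),
            "modes": self.modes.tolist(),
            "mode_stddevs": self.mode_stddevs.tolist(),
            "scores": self.scores.tolist(),
            "subject_ids": list(self.subject_ids),
        }))

    @staticmethod
    def load(path: str | Path) -> "ShapeModel":
        d = json.loads(Path(path).read_text())
        return ShapeModel(np.array(d["mean_shape"]), np.array(d["modes"]),
                          np.array(d["mode_stddevs"]), np.array(d["scores"]),
                          d["subject_ids"])


def _kabsch_rigid(source: np.ndarray, target: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rotation + translation (no scaling) mapping source onto target."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ sc

def procrustes_align(shapes: list[CorrespondedShape],
                     iterations: int = 3) -> list[CorrespondedShape]:
    """Rigidly re-align corresponded shapes to their evolving mean.

    Rotation and translation only — overall size is deliberately left in
    the shapes, so the first principal axis of a subsequent PCA captures
    size.  This removes the residual pose scatter that surface-based ICP
    alignment leaves between differently shaped subjects, which otherwise
    leaks rigid-motion variance into the shape model.
    """
    pts = [s.points for s in shapes]
    for _ in range(iterations):
        mean = np.mean(pts, axis=0)
        for i, p in enumerate(pts):
            r, t = _kabsch_rigid(p, mean)
            pts[i] = p @ r.T + t
    return [CorrespondedShape.from_points(p, s.subject_id)
            for p, s in zip(pts, shapes)]


def build_ssm(shapes: list[CorrespondedShape]) -> ShapeModel:
    """Fit the point-distribution model to corresponded shape vectors.

    Modes are the right singular vectors of the centered (N, 3n) data
    matrix; lambda_k = s_k / sqrt(N - 1).  Numerically-zero modes (singular
    value below 1e-10 of the leading one) are dropped, and each retained
    mode's sign is fixed so its largest-magnitude coefficient is positive.
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 shapes to build a model")
    n_points = shapes[0].n_points
    for s in shapes:
        if s.n_points != n_points:
            raise ValueError(
                f"shape {s.subject_id!r} has {s.n_points} points, expected {n_points}")
    data = np.stack([s.coordinates for s in shapes])          # (N, 3n)
    mean = data.mean(axis=0)
    centered = data - mean

    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    n = len(shapes)
    keep = min(n - 1, len(svals))
    svals, u, vt = svals[:keep], u[:, :keep], vt[:keep]
    if svals[0] > 0:
        nz = svals > _EIGVAL_FLOOR * svals[0]
    else:
        nz = np.zeros(keep, dtype=bool)
    svals, u, vt = svals[nz], u[:, nz], vt[nz]

    stddevs = svals / np.sqrt(n - 1)
    scores = u * svals                                         # (N, k)

    # deterministic mode orientation
    for k in range(vt.shape[0]):
        imax = np.argmax(np.abs(vt[k]))
        if vt[k, imax] < 0:
            vt[k] = -vt[k]
            scores[:, k] = -scores[:, k]

    return ShapeModel(mean, vt, stddevs, scores,
                      [s.subject_id for s in shapes])


def project(shape: CorrespondedShape, model: ShapeModel) -> np.ndarray:
    """Scores of a shape on the model axes (inner products after centering)."""
    if shape.n_points != model.n_points:
        raise ValueError("shape has wrong number of points for this model")
    return model.modes @ (shape.coordinates - model.mean_shape)


def reconstruction_residual(shape: CorrespondedShape, model: ShapeModel) -> float:
    """RMS residual (mm per coordinate) after full-mode reconstruction."""
    centered = shape.coordinates - model.mean_shape
    recon = model.modes.T @ (model.modes @ centered)
    return float(np.sqrt(np.mean((centered - recon) ** 2)))


def sample_mode(model: ShapeModel, mode_index: int, score: float
                ) -> CorrespondedShape:
    """Shape at ``score`` standard deviations along one mode (1-based index).

    ``score`` is in multiples of lambda: +2 gives mean + 2 lambda_k mode_k.
    """
    if not 1 <= mode_index <= model.n_modes:
        raise ValueError(f"mode_index must be in 1..{model.n_modes}")
    lam = model.mode_stddevs[mode_index - 1]
    if lam <= 0:
        raise ValueError(f"mode {mode_index} has zero variance")
    coords = model.mean_shape + score * lam * model.modes[mode_index - 1]
    return CorrespondedShape(coords, f"mode{mode_index}_{score:+g}sd")


def variance_explained(model: ShapeModel, k: int) -> float:
    """Fraction of total shape variance captured by the first k modes."""
    if not 0 <= k <= model.n_modes:
        raise ValueError(f"k must be in 0..{model.n_modes}")
    var = model.mode_stddevs ** 2
    total = var.sum()
    if total == 0:
        return 1.0
    return float(var[:k].sum() / total)
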