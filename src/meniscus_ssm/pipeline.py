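"""End-to-end shape-analysis pipeline over a cohort of meniscus surfaces.

Stages: optional single-iteration noise-reduction smoothing, rigid ICP
alignment of every subject to a reference subject, multi-resolution
B-spline correspondence of the reference topology onto each aligned
subject, PCA shape model over the corresponded shape vectors, per-mode
morphometric change-rate table, and correlation of the per-subject mode
scores with anthropometric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlations import pmv_correlation_table
from .mesh_core import DisplacementStats, TriangleMesh, smooth_mesh
from .morphometry import mode_change_table
from .registration import (CorrespondedShape, establish_correspondence,
                           ffd_register, icp_align)
from .shape_model import ShapeModel, build_ssm, procrustes_align


@dataclass
class PipelineResult:
    model: ShapeModel
    shapes: list                        # CorrespondedShape per subject
    reference_id: str
    reference_faces: np.ndarray
    scores: pd.DataFrame                # subjects x pmv columns
    smoothing: dict                     # subject_id -> DisplacementStats
    icp_rms: dict                       # subject_id -> final RMS (mm)
    ffd_residuals: dict                 # subject_id -> per-level residuals

    def change_table(self, k_modes: int = 6) -> pd.DataFrame:
        return mode_change_table(self.model, self.reference_faces, k_modes)

    def correlations(self, anthro: list, **kwargs) -> pd.DataFrame:
        return pmv_correlation_table(self.scores, anthro, **kwargs)


def build_correspondences(meshes: list[TriangleMesh],
                          reference_id: str | None = None,
                          levels=(20.0, 10.0, 5.0),
                          smooth_iterations: int = 1,
                          gate: float = 5.0):
    """Align and correspond a cohort onto a common reference topology.

    The reference defaults to the first subject id in sorted order.  The
    reference subject's corresponded shape is its own vertex set; every
    other subject is rigidly aligned to the reference, the reference
    surface is deformed onto it, and the deformed reference vertices are
    projected onto the subject surface.
    """
    by_id = {m.subject_id: m for m in meshes}
    if len(by_id) != len(meshes):
        raise ValueError("duplicate subject ids in cohort")
    ids = sorted(by_id)
    reference_id = reference_id or ids[0]
    if reference_id not in by_id:
        raise ValueError(f"unknown reference id {reference_id!r}")

    smoothing: dict[str, DisplacementStats] = {}
    if smooth_iterations > 0:
        for sid in ids:
            by_id[sid], smoothing[sid] = smooth_mesh(by_id[sid],
                                                     smooth_iterations)
    reference = by_id[reference_id]
    ref_shape = CorrespondedShape.from_points(reference.vertices, reference_id)

    shapes, icp_rms, ffd_residuals = [], {}, {}
    for sid in ids:
        if sid == reference_id:
            shapes.append(ref_shape)
            icp_rms[sid] = 0.0
            ffd_residuals[sid] = [0.0] * len(levels)
            continue
        icp = icp_align(by_id[sid], reference)
        icp_rms[sid] = icp.rms
        ffd = ffd_register(reference, icp.aligned, levels=levels)
        ffd_residuals[sid] = ffd.level_residuals
        shapes.append(establish_correspondence(ref_shape, icp.aligned,
                                               ffd, gate=gate,
                                               subject_id=sid))
    return shapes, reference, smoothing, icp_rms, ffd_residuals


def run_pipeline(meshes: list[TriangleMesh],
                 reference_id: str | None = None,
                 levels=(20.0, 10.0, 5.0),
                 smooth_iterations: int = 1,
                 gate: float = 5.0,
                 procrustes: bool = True) -> PipelineResult:
    """Full cohort analysis: correspondence, shape model, score table.

    ``procrustes`` re-aligns the corresponded shapes rigidly (no scaling)
    to their mean before the PCA, removing residual ICP pose scatter while
    keeping size inside the model.
    """
    shapes, reference, smoothing, icp_rms, ffd_res = build_correspondences(
        meshes, reference_id, levels, smooth_iterations, gate)
    if procrustes:
        shapes = procrustes_align(shapes)
    model = build_ssm(shapes)
    scores = pd.DataFrame(
        model.scores,
        index=pd.Index(model.subject_ids, name="subject_id"),
        columns=[f"pmv{k}" for k in range(1, model.n_modes + 1)])
    return PipelineResult(model, shapes, reference.subject_id,
                          reference.faces.copy(), scores, smoothing,
                          icp_rms, ffd_res)
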