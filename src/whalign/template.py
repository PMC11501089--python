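"""Group functional template construction (PCA-Procrustes searchlight algorithm).

The template M is a time x vertex matrix representative of a training cohort
both in representational geometry and in cortical topography.  Per
searchlight: (1) group PCA of the participant data concatenated along
vertices yields local PC score time series whose geometry summarizes the
group; (2) an orthogonal Procrustes rotation maps the PC axes back onto
cortical vertices so topography is also representative; (3) local templates
are aggregated into a whole-brain template by a distance-weighted average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .data import (
    InvalidInputError,
    Searchlight,
    SubjectTimeseries,
    SurfaceGeometry,
    aggregation_weight,
    build_searchlights,
)


@dataclass
class LocalTemplate:
    """Per-searchlight template: PC scores, Procrustes rotation, product."""

    searchlight: Searchlight
    pc_scores: np.ndarray      # (t, v_sl) scaled PC time series
    rotation: np.ndarray       # (v_sl, v_sl), orthogonal
    vertex_template: np.ndarray  # (t, v_sl) = pc_scores @ rotation

    def __post_init__(self):
        q = self.rotation.shape[0]
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(q), atol=1e-8):
            raise InvalidInputError("rotation is not orthogonal")


@dataclass
class FunctionalTemplate:
    """Whole-brain group template M (time x vertex)."""

    data: np.ndarray
    n_train: int
    radius_mm: float
    pc_scale: str = "sqrt_n"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("template contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


def _fix_svd_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-magnitude loading positive.

    Removes the sign indeterminacy of the SVD so that results do not depend
    on participant ordering or LAPACK internals.
    """
    big = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), big])
    signs[signs == 0] = 1.0
    return u * signs, vt * signs[:, None]


def _truncated_group_svd(concat: np.ndarray, q: int):
    """Top-q singular triplets of ``concat`` via the smaller-side Gram matrix.

    Equivalent to the thin SVD truncated to q components (up to the usual
    eigensolver tolerance); much faster than a full SVD when only the leading
    components are kept.  Returns (scores, vt) with scores = U_q * s_q.
    """
    t, w = concat.shape
    q = min(q, t, w)
    if t <= w:
        G = concat @ concat.T
        eigvals, U = linalg.eigh(G, subset_by_index=[t - q, t - 1])
        order = np.argsort(eigvals)[::-1]
        eigvals, U = eigvals[order], U[:, order]
        s = np.sqrt(np.clip(eigvals, 0.0, None))
        safe = np.where(s > 0, s, 1.0)
        vt = (concat.T @ U / safe).T
    else:
        G = concat.T @ concat
        eigvals, V = linalg.eigh(G, subset_by_index=[w - q, w - 1])
        order = np.argsort(eigvals)[::-1]
        eigvals, V = eigvals[order], V[:, order]
        s = np.sqrt(np.clip(eigvals, 0.0, None))
        vt = V.T
        safe = np.where(s > 0, s, 1.0)
        U = concat @ V / safe
    U, vt = _fix_svd_signs(U, vt)
    return U * s, s, vt


def local_group_pca(blocks: list[np.ndarray], pc_scale: str = "sqrt_n") -> np.ndarray:
    """Group-PCA score time series for one searchlight.

    Concatenates the n participant blocks (each t x v_sl) along vertices and
    takes the SVD of the t x (n*v_sl) matrix.  Returns the first v_sl PC
    score time series (U*Sigma truncated), divided by sqrt(n) so that the
    total variance matches a single participant's block.  ``pc_scale="n"``
    divides by n instead.

    If t < v_sl only rank components exist; the remainder are zero columns
    (a rank warning is emitted).
    """
    n = len(blocks)
    if n < 1:
        raise InvalidInputError("need at least one participant block")
    t, q = blocks[0].shape
    if any(b.shape != (t, q) for b in blocks):
        raise InvalidInputError("all blocks must share shape (t, v_sl)")
    concat = np.concatenate(blocks, axis=1)
    scores, _, _ = _truncated_group_svd(concat, q)
    divisor = np.sqrt(n) if pc_scale == "sqrt_n" else float(n)
    scores = scores / divisor
    if scores.shape[1] < q:
        warnings.warn(
            f"rank-deficient searchlight (t={t} < v_sl={q}); zero-padding components",
            RuntimeWarning,
        )
        scores = np.pad(scores, ((0, 0), (0, q - scores.shape[1])))
    return scores[:, :q]


def procrustes_solve(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal matrix R minimizing ||source @ R - target||_F.

    Computed from the SVD of the cross-covariance source.T @ target as
    U @ Vt.  A degenerate (all-zero) covariance returns the identity with a
    warning.
    """
    if source.shape != target.shape:
        raise InvalidInputError("source and target must share shape")
    cov = source.T @ target
    if not np.any(np.abs(cov) > 0):
        warnings.warn("degenerate zero covariance in Procrustes; returning identity",
                      RuntimeWarning)
        return np.eye(source.shape[1])
    u, _, vt = linalg.svd(cov, full_matrices=False)
    return u @ vt


def rotate_local_template(pc_scores: np.ndarray,
                          participant_blocks: list[np.ndarray],
                          searchlight: Searchlight | None = None) -> LocalTemplate:
    """Rotate PC scores into vertex space against the participants' blocks.

    The rotation solves argmin_R sum_p ||pc_scores @ R - B_p||_F^2, which for
    the stacked formulation equals the Procrustes solution for the SVD of
    sum_p pc_scores.T @ B_p.  The summed cross-covariance is used directly
    (algebraically identical to stacking n copies of the PC matrix against
    the n blocks).
    """
    # sum_p pc.T @ B_p == pc.T @ sum_p B_p, so the stacked problem reduces to
    # a single Procrustes solve against the participant sum
    block_sum = np.add.reduce(participant_blocks)
    rotation = procrustes_solve(pc_scores, block_sum)
    if searchlight is None:
        q = pc_scores.shape[1]
        searchlight = Searchlight(0, np.arange(q), np.zeros(q), 1.0)
    return LocalTemplate(searchlight, pc_scores, rotation, pc_scores @ rotation)


def aggregate_to_whole_brain(local_templates: list[LocalTemplate],
                             geom: SurfaceGeometry) -> np.ndarray:
    """Distance-weighted average of local templates into a t x v matrix.

    Each vertex's profile is the convex combination of the profiles assigned
    by every searchlight containing it, weighted by (r - d)/r where d is the
    distance from the searchlight center.
    """
    v = geom.n_vertices
    t = local_templates[0].vertex_template.shape[0]
    num = np.zeros((t, v))
    den = np.zeros(v)
    for lt in local_templates:
        w = aggregation_weight(lt.searchlight.distances, lt.searchlight.radius)
        num[:, lt.searchlight.members] += lt.vertex_template * w
        den[lt.searchlight.members] += w
    uncovered = np.nonzero(den <= 0)[0]
    if uncovered.size:
        raise InvalidInputError(
            f"vertices not covered by any searchlight (or only at zero weight): "
            f"{uncovered.tolist()[:20]}")
    return num / den


class FunctionalTemplateBuilder(BaseEstimator):
    """Builds the group functional template M from a training cohort.

    Parameters
    ----------
    geometry : SurfaceGeometry
        Vertex coordinates shared by the cohort.
    radius_mm : float, default 20.0
        Searchlight radius in mm.
    pc_scale : {"sqrt_n", "n"}, default "sqrt_n"
        Divisor convention for the group-PCA scores.

    Attributes
    ----------
    template_ : FunctionalTemplate
        The aggregated whole-brain template.
    searchlights_ : list of Searchlight
    """

    def __init__(self, geometry: SurfaceGeometry = None, radius_mm: float = 20.0,
                 pc_scale: str = "sqrt_n"):
        self.geometry = geometry
        self.radius_mm = radius_mm
        self.pc_scale = pc_scale

    def fit(self, X, y=None):
        """Fit on a cohort: a list of SubjectTimeseries or (t, v) arrays."""
        arrays = [x.data if isinstance(x, SubjectTimeseries) else np.asarray(x, float)
                  for x in X]
        if len(arrays) < 1:
            raise InvalidInputError("empty cohort")
        t, v = arrays[0].shape
        if any(a.shape != (t, v) for a in arrays):
            raise InvalidInputError("cohort matrices must share shape (t, v)")
        if v != self.geometry.n_vertices:
            raise InvalidInputError("cohort width does not match geometry")
        self.searchlights_ = build_searchlights(self.geometry, self.radius_mm)
        locals_ = []
        for sl in self.searchlights_:
            blocks = [a[:, sl.members] for a in arrays]
            pc = local_group_pca(blocks, pc_scale=self.pc_scale)
            locals_.append(rotate_local_template(pc, blocks, searchlight=sl))
        data = aggregate_to_whole_brain(locals_, self.geometry)
        self.template_ = FunctionalTemplate(data, n_train=len(arrays),
                                            radius_mm=self.radius_mm,
                                            pc_scale=self.pc_scale)
        return self


def build_template(cohort: list[SubjectTimeseries], geom: SurfaceGeometry,
                   radius_mm: float = 20.0, pc_scale: str = "sqrt_n") -> FunctionalTemplate:
    """Functional wrapper over :class:`FunctionalTemplateBuilder`."""
    builder = FunctionalTemplateBuilder(geometry=geom, radius_mm=radius_mm,
                                        pc_scale=pc_scale)
    return builder.fit(cohort).template_
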