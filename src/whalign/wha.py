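"""Warp hyperalignment: sparse whole-brain linear maps from template to subject.

Each participant's response matrix B_p is modeled as the template M times a
linear transformation W_p (plus noise).  Unlike orthogonal Procrustes
hyperalignment, the transformation is an unconstrained ridge-regularized
linear map, so it can warp representational geometry, capturing individual
differences in information content as well as topography.  W_p is estimated
per searchlight with a bagged ridge ensemble and aggregated column-wise with
distance weights into a sparse vertex x vertex matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from .bagging import BaggingConfig, FoldPlan, RidgeConfig, make_fold_plan
from .data import (
    InvalidInputError,
    SubjectTimeseries,
    SurfaceGeometry,
    aggregation_weight,
    build_searchlights,
)
from .template import FunctionalTemplate, procrustes_solve


@dataclass
class WholeBrainTransform:
    """Sparse whole-brain transformation W_p (v x v) for one participant.

    Nonzeros occur only where source and target vertex co-occur in at least
    one searchlight.  ``matrix`` maps template columns to subject columns:
    modeled responses are M @ W.
    """

    subject_id: str
    matrix: sparse.csr_matrix
    metadata: dict

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]


def fit_local_transform(M_sl: np.ndarray, B_sl: np.ndarray, plan: FoldPlan,
                        ridge_cfg: RidgeConfig) -> np.ndarray:
    """Bagged ridge estimate of the local transform for one searchlight.

    Averages the per-model closed-form ridge solutions, each fit on its
    bootstrapped rows (with multiplicity).
    """
    if M_sl.shape != B_sl.shape:
        raise InvalidInputError("template and subject blocks must share shape")
    q = M_sl.shape[1]
    acc = np.zeros((q, q))
    eye = ridge_cfg.lam * np.eye(q)
    for m in range(plan.n_models):
        c = plan.train_counts[m].astype(float)
        A = M_sl * c[:, None]
        G = A.T @ M_sl + eye
        acc += np.linalg.solve(G, A.T @ B_sl)
    return acc / plan.n_models


def _bagged_local_solutions(M: np.ndarray, B: np.ndarray, plan: FoldPlan,
                            lam: float, searchlights, chunk: int = 32,
                            max_batch: int = 512):
    """Mean bagged ridge transform per searchlight, vectorized across models.

    The per-model local Gram M_sl' diag(c) M_sl is a submatrix of the
    whole-brain weighted Gram M' diag(c) M, so the latter is formed once per
    model chunk and sliced per searchlight; systems of equal size are stacked
    across searchlights and solved in large batches.  Numerically identical
    to :func:`fit_local_transform` per searchlight.
    """
    n_models = plan.n_models
    sums = [np.zeros((sl.size, sl.size)) for sl in searchlights]
    by_size: dict[int, list[int]] = {}
    for i, sl in enumerate(searchlights):
        by_size.setdefault(sl.size, []).append(i)
    for start in range(0, n_models, chunk):
        counts = plan.train_counts[start:start + chunk].astype(float)
        nm = counts.shape[0]
        A = counts[:, :, None] * M[None, :, :]          # (c, t, v)
        F = np.matmul(A.transpose(0, 2, 1), M)          # (c, v, v) weighted Grams
        H = np.matmul(A.transpose(0, 2, 1), B)          # (c, v, v) cross terms
        for q, sl_ids in by_size.items():
            eye = lam * np.eye(q)
            group = max(1, max_batch // nm)
            for g0 in range(0, len(sl_ids), group):
                ids = sl_ids[g0:g0 + group]
                G = np.empty((len(ids), nm, q, q))
                R = np.empty((len(ids), nm, q, q))
                for j, i in enumerate(ids):
                    idx = searchlights[i].members
                    G[j] = F[:, idx[:, None], idx[None, :]] + eye
                    R[j] = H[:, idx[:, None], idx[None, :]]
                sol = np.linalg.solve(G.reshape(-1, q, q), R.reshape(-1, q, q))
                sol = sol.reshape(len(ids), nm, q, q).sum(axis=1)
                for j, i in enumerate(ids):
                    sums[i] += sol[j]
    return [s / n_models for s in sums]


def _aggregate_columns(local_mats, searchlights, v: int) -> sparse.csr_matrix:
    """Column-wise distance-weighted average of local transforms.

    Column j of W (the modeled profile of target vertex j) averages the
    corresponding columns of every local transform whose searchlight contains
    j, weighted by (r - d_j)/r.
    """
    den = np.zeros(v)
    rows, cols, vals = [], [], []
    for W_loc, sl in zip(local_mats, searchlights):
        w = aggregation_weight(sl.distances, sl.radius)
        idx = sl.members
        block = W_loc * w[None, :]
        rr, cc = np.meshgrid(idx, idx, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        vals.append(block.ravel())
        den[idx] += w
    num = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(v, v)).tocsr()
    uncovered = np.nonzero(den <= 0)[0]
    if uncovered.size:
        raise InvalidInputError(f"vertices with no searchlight coverage: {uncovered.tolist()[:20]}")
    return num @ sparse.diags(1.0 / den)


class WarpHyperalignment(BaseEstimator):
    """Fits the warp-hyperalignment transform W for one participant.

    Parameters
    ----------
    template : FunctionalTemplate
        Group template M (time x vertex), time axis matching the subject.
    geometry : SurfaceGeometry
    radius_mm : float, default 20.0
    lam : float, default 1e3
        Ridge penalty of the local regressions.
    k_folds, repetitions, buffer_seconds, segment_seconds : bagging plan.
    random_state : int, default 0
        Master seed; the fold plan is shared across searchlights.

    Attributes
    ----------
    W_ : WholeBrainTransform
    plan_ : FoldPlan
    """

    def __init__(self, template: FunctionalTemplate = None,
                 geometry: SurfaceGeometry = None, radius_mm: float = 20.0,
                 lam: float = 1e3, k_folds: int = 5, repetitions: int = 20,
                 buffer_seconds: float = 10.0, segment_seconds: float = 10.0,
                 random_state: int = 0):
        self.template = template
        self.geometry = geometry
        self.radius_mm = radius_mm
        self.lam = lam
        self.k_folds = k_folds
        self.repetitions = repetitions
        self.buffer_seconds = buffer_seconds
        self.segment_seconds = segment_seconds
        self.random_state = random_state

    def _validate(self, ts: SubjectTimeseries):
        if ts.data.shape != self.template.data.shape:
            raise InvalidInputError(
                f"subject shape {ts.data.shape} does not match template "
                f"{self.template.data.shape}")

    def fit(self, X: SubjectTimeseries, y=None):
        ts = X if isinstance(X, SubjectTimeseries) else SubjectTimeseries("anon", np.asarray(X))
        self._validate(ts)
        cfg = BaggingConfig(k_folds=self.k_folds, repetitions=self.repetitions,
                            buffer_seconds=self.buffer_seconds,
                            segment_seconds=self.segment_seconds,
                            seed=self.random_state)
        self.plan_ = make_fold_plan(ts.n_timepoints, ts.tr_seconds, cfg,
                                    run_boundaries=ts.run_boundaries)
        sls = build_searchlights(self.geometry, self.radius_mm)
        locals_ = _bagged_local_solutions(self.template.data, ts.data,
                                          self.plan_, self.lam, sls)
        mat = _aggregate_columns(locals_, sls, self.geometry.n_vertices)
        self.W_ = WholeBrainTransform(
            ts.subject_id, mat,
            metadata={"lam": self.lam, "k_folds": self.k_folds,
                      "repetitions": self.repetitions,
                      "buffer_seconds": self.buffer_seconds,
                      "segment_seconds": self.segment_seconds,
                      "radius_mm": self.radius_mm, "seed": self.random_state,
                      "method": "wha"})
        return self

    def reconstruct(self) -> np.ndarray:
        """Modeled responses B_hat = M @ W for the fitted participant."""
        return apply_transform(self.template, self.W_)


class ProcrustesAlignment(WarpHyperalignment):
    """Baseline: per-searchlight orthogonal Procrustes transforms.

    Same searchlight-and-aggregate scheme as warp hyperalignment but each
    local map is the rigid (improper) rotation minimizing the Frobenius
    error, i.e. the classic hyperalignment constraint.
    """

    def fit(self, X: SubjectTimeseries, y=None):
        ts = X if isinstance(X, SubjectTimeseries) else SubjectTimeseries("anon", np.asarray(X))
        self._validate(ts)
        sls = build_searchlights(self.geometry, self.radius_mm)
        M = self.template.data
        locals_ = [procrustes_solve(M[:, sl.members], ts.data[:, sl.members])
                   for sl in sls]
        mat = _aggregate_columns(locals_, sls, self.geometry.n_vertices)
        self.W_ = WholeBrainTransform(
            ts.subject_id, mat,
            metadata={"radius_mm": self.radius_mm, "method": "procrustes"})
        return self


def fit_wha(template: FunctionalTemplate, ts: SubjectTimeseries,
            geom: SurfaceGeometry, radius_mm: float = 20.0,
            ridge_cfg: RidgeConfig | None = None,
            bagging_cfg: BaggingConfig | None = None) -> WholeBrainTransform:
    """Functional wrapper over :class:`WarpHyperalignment`."""
    ridge_cfg = ridge_cfg or RidgeConfig()
    bagging_cfg = bagging_cfg or BaggingConfig()
    est = WarpHyperalignment(
        template=template, geometry=geom, radius_mm=radius_mm,
        lam=ridge_cfg.lam, k_folds=bagging_cfg.k_folds,
        repetitions=bagging_cfg.repetitions,
        buffer_seconds=bagging_cfg.buffer_seconds,
        segment_seconds=bagging_cfg.segment_seconds,
        random_state=bagging_cfg.seed)
    return est.fit(ts).W_


def fit_procrustes_baseline(template: FunctionalTemplate, ts: SubjectTimeseries,
                            geom: SurfaceGeometry,
                            radius_mm: float = 20.0) -> WholeBrainTransform:
    """Functional wrapper over :class:`ProcrustesAlignment`."""
    est = ProcrustesAlignment(template=template, geometry=geom, radius_mm=radius_mm)
    return est.fit(ts).W_


def apply_transform(template: FunctionalTemplate, W: WholeBrainTransform) -> np.ndarray:
    """Modeled subject responses B_hat = M @ W_p."""
    if template.n_vertices != W.n_vertices:
        raise InvalidInputError("template width does not match transform")
    return np.asarray(template.data @ W.matrix)
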