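"""Stimulus/tuning separation: B_hat = S @ T_p.

The modeled responses of all participants share a stimulus matrix S (time x
feature) whose columns form an orthogonal, unit-variance basis of response
profiles, obtained from a group SVD.  Each participant's tuning matrix T_p
(feature x vertex) expresses every vertex's response profile as weights on
that shared basis; the weights are stimulus-general, so the same T_p can be
estimated from different subsets of stimuli (e.g. different movie halves).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .data import InvalidInputError
from .template import _fix_svd_signs


@dataclass
class StimulusMatrix:
    """Shared stimulus matrix S (time x feature).

    ``basis_id`` fingerprints the basis; tuning matrices may only be compared
    when estimated under the same basis.  ``row_index`` maps rows to the
    stimulus time points they describe.
    """

    data: np.ndarray
    basis_id: str
    scale: str = "unit_variance"
    row_index: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.row_index is None:
            self.row_index = np.arange(self.data.shape[0])
        self.row_index = np.asarray(self.row_index, dtype=int)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def restrict(self, rows) -> "StimulusMatrix":
        """Rows of S for an observed subset of stimuli (same basis)."""
        rows = np.asarray(rows, dtype=int)
        return StimulusMatrix(self.data[rows], self.basis_id, self.scale,
                              row_index=self.row_index[rows])


@dataclass
class TuningMatrix:
    """Individual tuning matrix T_p (feature x vertex)."""

    subject_id: str
    data: np.ndarray
    basis_id: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("tuning matrix contains non-finite values")


def check_same_basis(*objs):
    ids = {o.basis_id for o in objs}
    if len(ids) > 1:
        raise InvalidInputError(
            f"cannot compare objects estimated under different bases: {sorted(ids)}")


def _basis_fingerprint(S: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(np.round(S, 8))).hexdigest()[:16]


class TuningModel(BaseEstimator):
    """Group SVD stimulus basis with per-participant tuning estimation.

    Parameters
    ----------
    scale : {"unit_variance", "sqrt_n"}, default "unit_variance"
        Column scaling of S.  ``unit_variance`` rescales each left singular
        vector to unit variance, which keeps the scale of estimated tuning
        matrices comparable across different amounts of data.  ``sqrt_n``
        multiplies U by sqrt(n_participants) instead.
    rank_rtol : float, default 1e-10
        Singular values below ``rank_rtol * s_max`` are discarded, so the
        number of features k equals the numerical rank of the concatenation.

    Attributes
    ----------
    S_ : StimulusMatrix
    rank_ : int
    """

    def __init__(self, scale: str = "unit_variance", rank_rtol: float = 1e-10):
        self.scale = scale
        self.rank_rtol = rank_rtol

    def fit(self, X, y=None):
        """Fit the basis from per-participant modeled response matrices (t x v)."""
        arrays = [np.asarray(a, dtype=float) for a in X]
        t = arrays[0].shape[0]
        if any(a.shape[0] != t for a in arrays):
            raise InvalidInputError("participant matrices must share the time axis")
        concat = np.concatenate(arrays, axis=1)
        u, s, vt = linalg.svd(concat, full_matrices=False)
        u, vt = _fix_svd_signs(u, vt)
        rank = int(np.sum(s > self.rank_rtol * s[0])) if s.size else 0
        u = u[:, :rank]
        if self.scale == "unit_variance":
            sd = u.std(axis=0)
            sd[sd <= 0] = 1.0
            S = u / sd
        elif self.scale == "sqrt_n":
            S = u * np.sqrt(len(arrays))
        else:
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        self.rank_ = rank
        self.S_ = StimulusMatrix(S, basis_id=_basis_fingerprint(S), scale=self.scale)
        return self

    def transform(self, modeled: np.ndarray, rows=None,
                  subject_id: str = "anon") -> TuningMatrix:
        """Estimate T from modeled responses on the observed rows of S."""
        S_rows = self.S_ if rows is None else self.S_.restrict(rows)
        return estimate_tuning(S_rows, np.asarray(modeled, dtype=float),
                               subject_id=subject_id)


def compute_stimulus_matrix(modeled: list[np.ndarray],
                            scale: str = "unit_variance") -> StimulusMatrix:
    """Functional wrapper over :class:`TuningModel` basis fitting."""
    return TuningModel(scale=scale).fit(modeled).S_


def estimate_tuning(S_rows: StimulusMatrix, modeled_rows: np.ndarray,
                    subject_id: str = "anon") -> TuningMatrix:
    """Minimum-norm least squares T = pinv(S_rows) @ modeled_rows.

    When the observed rows of S have full column rank this is the unique
    least-squares solution; with fewer rows than features the minimum-norm
    solution is returned.
    """
    modeled_rows = np.asarray(modeled_rows, dtype=float)
    if modeled_rows.shape[0] == 0:
        raise InvalidInputError("no observed rows")
    if S_rows.data.shape[0] != modeled_rows.shape[0]:
        raise InvalidInputError("row counts of S and modeled responses differ")
    T = linalg.lstsq(S_rows.data, modeled_rows, lapack_driver="gelsd")[0]
    return TuningMatrix(subject_id, T, S_rows.basis_id)


def extend_stimulus_matrix(new_responses: dict[str, np.ndarray],
                           tunings: list[TuningMatrix],
                           ensemble_cfg=None) -> np.ndarray:
    """Estimate stimulus descriptors S_new for stimuli absent from the basis.

    ``new_responses`` maps subject_id -> (n_stim x v) response rows; every
    such participant must have a tuning matrix in ``tunings``.  Descriptors
    are estimated with the ensemble ridge regression of the prediction
    module, regressing responses on tuning columns across the concatenated
    vertices of the participating subjects.  Returns an (n_stim x k) array of
    rows in the same basis.
    """
    from .prediction import EnsembleRegressionConfig, ensemble_ridge_descriptors

    check_same_basis(*tunings)
    by_id = {t.subject_id: t for t in tunings}
    missing = [sid for sid in new_responses if sid not in by_id]
    if missing:
        raise InvalidInputError(f"no tuning matrix for participants {missing}")
    cfg = ensemble_cfg or EnsembleRegressionConfig()
    subj_ids = list(new_responses)
    maps = [np.atleast_2d(np.asarray(new_responses[sid], float)) for sid in subj_ids]
    tl = [by_id[sid] for sid in subj_ids]
    return ensemble_ridge_descriptors(maps, tl, cfg)
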