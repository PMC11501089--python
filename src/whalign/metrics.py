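"""Reliability, distinctiveness, psychometric and circular evaluation metrics.

Tuning matrices estimated from independent data of the same person should be
similar, and those of different people dissimilar.  The cross-movie-part
similarity matrix quantifies this; the distinctiveness index is a Cohen's-d
style contrast of a participant's within-subject similarity against the
between-subject distribution (on Fisher-z values), from which a normal-model
identification error rate follows.  The psychometric helpers (Cronbach's
alpha, Spearman-Brown, the sqrt(rho_i rho_j) expected correlation) provide
the reliability ceiling against which predicted maps are judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import InvalidInputError, RegionMask, SurfaceGeometry, build_searchlights
from .prediction import RetinotopicMap
from .tuning import TuningMatrix, check_same_basis


@dataclass
class SimilarityMatrix:
    """Cross-part similarity of tuning matrices.

    Rows index first-half estimates, columns second-half estimates; the
    diagonal holds within-subject similarities.  ``fisher_z`` is the
    arctanh-transformed copy used for all averaging.
    """

    values: np.ndarray
    subject_ids: list[str]

    @property
    def fisher_z(self) -> np.ndarray:
        return np.arctanh(np.clip(self.values, -1 + 1e-15, 1 - 1e-15))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class DistinctivenessResult:
    """Per-subject distinctiveness summary for a cohort."""

    subject_ids: list[str]
    d: np.ndarray                # per-subject distinctiveness index
    within_z: np.ndarray
    between_z_mean: np.ndarray
    between_z_sd: np.ndarray
    error_rate: float            # Phi(-mean d)

    @property
    def mean_d(self) -> float:
        return float(np.mean(self.d))


@dataclass
class ReliabilityEstimate:
    """Reliability of a k-run average map."""

    k_runs: int
    alpha: float
    single_run_rho: float


def _flatten_corr(A: np.ndarray, B: np.ndarray) -> float:
    a = A.ravel() - A.mean()
    b = B.ravel() - B.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 0 or nb <= 0:
        return 0.0
    return float(a @ b / (na * nb))


def tuning_similarity_matrix(tunings_half1: list[TuningMatrix],
                             tunings_half2: list[TuningMatrix]) -> SimilarityMatrix:
    """Pearson correlations between flattened tuning matrices across halves."""
    if len(tunings_half1) != len(tunings_half2):
        raise InvalidInputError("halves must contain the same subjects")
    ids1 = [t.subject_id for t in tunings_half1]
    ids2 = [t.subject_id for t in tunings_half2]
    if ids1 != ids2:
        raise InvalidInputError("subject order must match across halves")
    check_same_basis(*tunings_half1)
    check_same_basis(*tunings_half2)
    n = len(tunings_half1)
    vals = np.empty((n, n))
    for i, ti in enumerate(tunings_half1):
        for j, tj in enumerate(tunings_half2):
            vals[i, j] = _flatten_corr(ti.data, tj.data)
    return SimilarityMatrix(vals, ids1)


def distinctiveness_index(sim: SimilarityMatrix, subject_row: int) -> float:
    """(z_within - mean z_between) / SD(z_between) for one subject's row.

    Uses that subject's row of the Fisher-z similarity matrix only, with the
    sample SD (ddof=1).  A zero between-subject SD yields +/-inf with a
    warning (degenerate cohort).
    """
    if sim.n_subjects < 3:
        raise InvalidInputError("need >= 3 subjects for a between-subject SD")
    z = sim.fisher_z[subject_row]
    within = z[subject_row]
    between = np.delete(z, subject_row)
    sd = between.std(ddof=1)
    diff = within - between.mean()
    if sd <= 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero between-subject SD; distinctiveness is infinite",
                      RuntimeWarning)
        return float(np.sign(diff) * np.inf)
    return float(diff / sd)


def cohort_distinctiveness(sim: SimilarityMatrix) -> DistinctivenessResult:
    """Distinctiveness indices for every subject plus the cohort error rate.

    The identification error rate is evaluated at the cohort-average d.
    """
    n = sim.n_subjects
    d = np.array([distinctiveness_index(sim, i) for i in range(n)])
    z = sim.fisher_z
    within = np.diag(z)
    bet_mean = np.array([np.delete(z[i], i).mean() for i in range(n)])
    bet_sd = np.array([np.delete(z[i], i).std(ddof=1) for i in range(n)])
    return DistinctivenessResult(sim.subject_ids, d, within, bet_mean, bet_sd,
                                 identification_error_rate(float(np.mean(d))))


def identification_error_rate(d: float) -> float:
    """Standard-normal upper tail beyond d: Phi(-d).

    Treats the distinctiveness index as a z-statistic of the Fisher-z
    similarity gap; strictly decreasing in d, 0.5 at d = 0.
    """
    if not np.isfinite(d):
        return 0.0 if d > 0 else 1.0
    return float(norm.sf(d))


def nearest_neighbor_identification(sim: SimilarityMatrix) -> float:
    """Fraction of subjects whose own second-half tuning is the best match.

    One-nearest-neighbor identification over the similarity matrix rows; a
    row counts as correct only when the diagonal entry is the strict maximum.
    """
    C = sim.values
    off = C.copy()
    np.fill_diagonal(off, -np.inf)
    return float(np.mean(np.diag(C) > off.max(axis=1)))


def cronbach_alpha(run_maps: list[np.ndarray]) -> float:
    """Cronbach's alpha of the average of k parallel maps, over vertices."""
    k = len(run_maps)
    if k < 2:
        raise InvalidInputError("need at least 2 runs")
    X = np.asarray(run_maps, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("run maps must be equal-length vectors")
    total_var = X.sum(axis=0).var(ddof=1)
    if total_var <= 0:
        raise InvalidInputError("zero total variance; alpha undefined")
    item_var = X.var(axis=1, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def reliability_from_runs(run_maps: list[np.ndarray]) -> ReliabilityEstimate:
    """Cronbach's alpha of k runs plus the implied single-run reliability.

    The single-run reliability is the Spearman-Brown inversion
    rho_1 = alpha / (k - (k-1) alpha), so the stored triple satisfies
    alpha == spearman_brown(rho_1, k).
    """
    k = len(run_maps)
    alpha = cronbach_alpha(run_maps)
    rho1 = alpha / (k - (k - 1) * alpha)
    return ReliabilityEstimate(k_runs=k, alpha=alpha, single_run_rho=rho1)


def spearman_brown(rho_single: float, k: float) -> float:
    """Predicted reliability of a k-test average: k*rho / (1 + (k-1)*rho)."""
    if not (0 <= rho_single <= 1) or k <= 0:
        raise InvalidInputError("need 0 <= rho <= 1 and k > 0")
    return float(k * rho_single / (1 + (k - 1) * rho_single))


def expected_map_correlation(rho_i: float, rho_j: float) -> float:
    """Expected correlation sqrt(rho_i * rho_j) of two noisy maps of one truth."""
    if not (0 <= rho_i <= 1 and 0 <= rho_j <= 1):
        raise InvalidInputError("reliabilities must lie in [0, 1]")
    return float(np.sqrt(rho_i * rho_j))


def equivalent_localizer_minutes(alpha_k0: float, k0_runs: int,
                                 run_minutes: float, observed_r: float) -> float:
    """Localizer minutes whose average map matches the predicted map's quality.

    Model-dependent inference chain: invert Spearman-Brown for the single-run
    reliability rho_1 = alpha / (k0 - (k0-1)*alpha); infer the predicted
    map's reliability rho_pred = r^2 / alpha from r = sqrt(rho_pred *
    rho_avg); solve Spearman-Brown for the k* with that reliability and
    return k* * run_minutes.  Returns +inf when rho_pred >= 1.
    """
    if not (0 < alpha_k0 < 1) or observed_r <= 0 or k0_runs < 1 or run_minutes <= 0:
        raise InvalidInputError("invalid reliability inversion inputs")
    rho1 = alpha_k0 / (k0_runs - (k0_runs - 1) * alpha_k0)
    rho_pred = observed_r ** 2 / alpha_k0
    if rho_pred >= 1:
        return float("inf")
    # SB(rho1, k*) = rho_pred  =>  k* = rho_pred (1 - rho1) / (rho1 (1 - rho_pred))
    k_star = rho_pred * (1 - rho1) / (rho1 * (1 - rho_pred))
    return float(k_star * run_minutes)


def circular_phase_difference(map_a: RetinotopicMap, map_b: RetinotopicMap,
                              mask: RegionMask | None = None) -> float:
    """Mean absolute circular difference (degrees, in [0, 180]) over a mask."""
    if map_a.kind != map_b.kind:
        raise InvalidInputError("maps must be of the same kind")
    idx = slice(None) if mask is None else mask.members
    a = map_a.phase[idx]
    b = map_b.phase[idx]
    if np.size(a) == 0:
        raise InvalidInputError("empty mask")
    diff = np.abs(a - b) % 360.0
    return float(np.mean(np.minimum(diff, 360.0 - diff)))


def searchlight_distinctiveness_map(tunings_half1: list[TuningMatrix],
                                    tunings_half2: list[TuningMatrix],
                                    geom: SurfaceGeometry,
                                    radius_mm: float = 20.0) -> np.ndarray:
    """Cohort-mean distinctiveness per searchlight, assigned to the center.

    Restricts the tuning matrices to each searchlight's member vertices,
    recomputes the similarity matrix locally, and averages the per-subject
    distinctiveness indices; non-finite local indices (degenerate local
    cohorts) are excluded from the average.
    """
    if len(tunings_half1) < 3:
        raise InvalidInputError("need >= 3 subjects")
    sls = build_searchlights(geom, radius_mm)
    out = np.zeros(geom.n_vertices)
    for sl in sls:
        h1 = [TuningMatrix(t.subject_id, t.data[:, sl.members], t.basis_id)
              for t in tunings_half1]
        h2 = [TuningMatrix(t.subject_id, t.data[:, sl.members], t.basis_id)
              for t in tunings_half2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sim = tuning_similarity_matrix(h1, h2)
            d = np.array([distinctiveness_index(sim, i) for i in range(sim.n_subjects)])
        finite = d[np.isfinite(d)]
        out[sl.center_vertex] = finite.mean() if finite.size else 0.0
    return out
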