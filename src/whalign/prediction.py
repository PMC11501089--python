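"""Predicting individualized maps and response patterns from tuning matrices.

Three prediction arms share one idea: a response map to a new stimulus is a
row of stimulus descriptors times the participant's tuning matrix.  For
category-selectivity maps the descriptor row is estimated from training
participants' localizer maps with a bagged ridge ensemble; retinotopic maps
are first re-expressed as two linear weight maps (x = A cos theta,
y = A sin theta) so that the circular phase can be predicted linearly; and
movie response patterns are predicted directly from held-out rows of the
stimulus matrix, then compared to measured patterns by time-point
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .data import InvalidInputError, SubjectTimeseries
from .tuning import StimulusMatrix, TuningMatrix, check_same_basis


# --------------------------------------------------------------------------
# selectivity maps and the ensemble descriptor estimator

@dataclass
class SelectivityMap:
    """Per-vertex contrast statistic for one condition (e.g. faces)."""

    subject_id: str
    values: np.ndarray
    condition: str = ""
    run_maps: list[np.ndarray] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()


def _default_lambda_grid():
    return np.logspace(-2, 2, 21)


@dataclass
class EnsembleRegressionConfig:
    """Bagged ridge ensemble over participants.

    50 models by default (5 folds x 10 repetitions).  Each model bootstraps
    the candidate training participants with replacement and, per chosen
    participant, bootstraps ``n_run_bootstrap`` localizer runs and averages
    them.  The ridge penalty is a single value from ``lambda_grid`` chosen by
    out-of-bag squared error pooled over all models.
    """

    k_folds: int = 5
    repetitions: int = 10
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    n_run_bootstrap: int = 4
    seed: int = 0

    @property
    def models_total(self) -> int:
        return self.k_folds * self.repetitions


def _ridge_path(X: np.ndarray, Y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ridge coefficients for every penalty via one SVD of X.

    Returns (n_lambda, q, p) for X (m x q), Y (m x p).
    """
    u, s, vt = linalg.svd(X, full_matrices=False)
    uty = u.T @ Y
    out = np.empty((len(lambdas), X.shape[1], Y.shape[1]))
    for i, lam in enumerate(lambdas):
        out[i] = (vt.T * (s / (s ** 2 + lam))) @ uty
    return out


def ensemble_ridge_descriptors(maps: list[np.ndarray], tunings: list[TuningMatrix],
                               cfg: EnsembleRegressionConfig,
                               run_maps: list[list[np.ndarray]] | None = None
                               ) -> np.ndarray:
    """Estimate (n_stim x k) stimulus descriptors from participants' maps.

    ``maps[p]`` is the participant's (n_stim x v) response map (used for
    out-of-bag evaluation); ``run_maps[p]``, when given, holds per-run maps
    bootstrapped within each model.  Vertices of the bootstrapped
    participants are concatenated and the maps regressed on tuning columns.
    """
    check_same_basis(*tunings)
    n = len(maps)
    if n != len(tunings):
        raise InvalidInputError("one tuning matrix per participant required")
    maps = [np.atleast_2d(np.asarray(m, float)) for m in maps]
    n_stim = maps[0].shape[0]
    rng = np.random.default_rng(cfg.seed)
    lambdas = np.asarray(cfg.lambda_grid, dtype=float)
    k = tunings[0].data.shape[0]

    def design_for(p: int, bootstrap_runs: bool) -> np.ndarray:
        if bootstrap_runs and run_maps is not None and run_maps[p]:
            runs = run_maps[p]
            picks = rng.integers(0, len(runs), size=cfg.n_run_bootstrap)
            m = np.mean([np.atleast_2d(runs[i]) for i in picks], axis=0)
        else:
            m = maps[p]
        return m

    # degenerate single-model configuration: plain ridge on everyone
    if cfg.k_folds <= 1 or n < 2:
        if len(lambdas) != 1:
            raise InvalidInputError(
                "out-of-bag lambda selection needs >= 2 participants and k_folds >= 2; "
                "pass a single-value lambda_grid for the degenerate configuration")
        X = np.concatenate([t.data.T for t in tunings], axis=0)
        Y = np.concatenate([m.T for m in maps], axis=0)
        return _ridge_path(X, Y, lambdas)[0].T

    betas = np.empty((cfg.models_total, len(lambdas), k, n_stim))
    oob_sets: list[np.ndarray] = []
    m_i = 0
    for _rep in range(cfg.repetitions):
        perm = rng.permutation(n)
        folds = np.array_split(perm, cfg.k_folds)
        for fold in folds:
            cand = np.setdiff1d(perm, fold)
            if cand.size < 1:
                raise InvalidInputError("too few participants for the fold scheme")
            boot = rng.choice(cand, size=cand.size, replace=True)
            X = np.concatenate([tunings[p].data.T for p in boot], axis=0)
            Y = np.concatenate([design_for(p, True).T for p in boot], axis=0)
            betas[m_i] = _ridge_path(X, Y, lambdas)
            oob_sets.append(np.setdiff1d(np.arange(n), np.unique(boot)))
            m_i += 1

    # pooled out-of-bag squared error per lambda
    errs = np.zeros(len(lambdas))
    for m_i in range(cfg.models_total):
        for p in oob_sets[m_i]:
            # (n_lam, n_stim, v) predictions for this out-of-bag participant
            pred = np.einsum("lks,kv->lsv", betas[m_i], tunings[p].data)
            resid = pred - maps[p][None, :, :]
            errs += np.sum(resid ** 2, axis=(1, 2))
    best = int(np.argmin(errs))
    return betas[:, best].mean(axis=0).T


class EnsembleRidgeDescriptor(BaseEstimator):
    """sklearn-style wrapper: fit stimulus descriptors from maps + tunings.

    Attributes
    ----------
    coef_ : ndarray (n_stim, k)
    """

    def __init__(self, k_folds: int = 5, repetitions: int = 10,
                 lambda_grid=None, n_run_bootstrap: int = 4, random_state: int = 0):
        self.k_folds = k_folds
        self.repetitions = repetitions
        self.lambda_grid = lambda_grid
        self.n_run_bootstrap = n_run_bootstrap
        self.random_state = random_state

    def fit(self, X: list[TuningMatrix], y: list[np.ndarray], run_maps=None):
        cfg = EnsembleRegressionConfig(
            k_folds=self.k_folds, repetitions=self.repetitions,
            lambda_grid=(np.asarray(self.lambda_grid, float)
                         if self.lambda_grid is not None else _default_lambda_grid()),
            n_run_bootstrap=self.n_run_bootstrap, seed=self.random_state)
        self.coef_ = ensemble_ridge_descriptors(y, X, cfg, run_maps=run_maps)
        return self


def estimate_contrast_descriptor(maps: list[SelectivityMap],
                                 tunings: list[TuningMatrix],
                                 cfg: EnsembleRegressionConfig | None = None
                                 ) -> np.ndarray:
    """Stimulus descriptor row (length k) for one contrast condition."""
    cfg = cfg or EnsembleRegressionConfig()
    if cfg.k_folds > 1 and len(maps) < 2:
        raise InvalidInputError("need at least 2 training participants")
    arrs = [m.values[None, :] for m in maps]
    runs = [[r[None, :] if np.ndim(r) == 1 else np.atleast_2d(r)
             for r in (m.run_maps or [])] for m in maps]
    runs = runs if any(len(r) for r in runs) else None
    return ensemble_ridge_descriptors(arrs, tunings, cfg, run_maps=runs)[0]


def predict_selectivity_map(descriptor: np.ndarray, tuning: TuningMatrix,
                            condition: str = "") -> SelectivityMap:
    """Model-predicted map: descriptor row times the tuning matrix."""
    descriptor = np.asarray(descriptor, dtype=float).ravel()
    if descriptor.size != tuning.data.shape[0]:
        raise InvalidInputError("descriptor length does not match tuning features")
    return SelectivityMap(tuning.subject_id, descriptor @ tuning.data, condition)


# --------------------------------------------------------------------------
# retinotopy

@dataclass
class RetinotopicMap:
    """Amplitude and preferred-phase map of a traveling-wave localizer.

    Phase in degrees, wrapped to [0, 360).  Convention: eccentricity 0 deg =
    center of gaze, 360 deg = periphery; polar angle 0/180 deg = vertical
    meridians, 90/270 deg = horizontal.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    kind: str = "eccentricity"

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.mod(np.asarray(self.phase, dtype=float), 360.0)
        if np.any(self.amplitude < 0):
            raise InvalidInputError("amplitude must be non-negative")


@dataclass
class RetinoEncoding:
    """Linear encoding x = A cos(theta), y = A sin(theta)."""

    x: np.ndarray
    y: np.ndarray
    kind: str = "eccentricity"


def encode_retinotopy(m: RetinotopicMap) -> RetinoEncoding:
    rad = np.deg2rad(m.phase)
    return RetinoEncoding(m.amplitude * np.cos(rad), m.amplitude * np.sin(rad), m.kind)


def decode_retinotopy(enc: RetinoEncoding) -> RetinotopicMap:
    """Inverse of :func:`encode_retinotopy` wherever amplitude > 0.

    The two-argument arctangent is taken as atan2(y, x): with that order
    decode(encode(m)) is the identity, which fixes the convention.  Zero
    amplitude decodes to phase 0 by convention.
    """
    amp = np.hypot(enc.x, enc.y)
    phase = np.degrees(np.arctan2(enc.y, enc.x))
    phase = np.where(amp > 0, np.mod(phase, 360.0), 0.0)
    return RetinotopicMap(amp, phase, enc.kind)


def predict_retinotopic_map(descriptor_x: np.ndarray, descriptor_y: np.ndarray,
                            tuning: TuningMatrix,
                            kind: str = "eccentricity") -> RetinotopicMap:
    """Predict x and y weight maps from two descriptor rows, then decode."""
    x = np.asarray(descriptor_x, float).ravel() @ tuning.data
    y = np.asarray(descriptor_y, float).ravel() @ tuning.data
    return decode_retinotopy(RetinoEncoding(x, y, kind))


def fourier_phase_map(run: SubjectTimeseries, n_cycles: int = 5,
                      n_timepoints: int = 80, delay_seconds: float = 5.0,
                      cycle_seconds: float = 32.0, onset_timepoints: int = 0,
                      kind: str = "eccentricity") -> RetinotopicMap:
    """Amplitude/phase of the stimulus-frequency Fourier component per vertex.

    Takes the discrete Fourier coefficient at ``n_cycles`` over the
    ``n_timepoints`` stimulation window, scaled 2/n so a pure cosine of
    amplitude A yields amplitude A.  The measured phase is corrected for
    hemodynamic delay by subtracting 360 * delay_seconds / cycle_seconds
    degrees.
    """
    data = run.data[onset_timepoints:onset_timepoints + n_timepoints]
    if data.shape[0] < n_timepoints:
        raise InvalidInputError(
            f"run too short: need {n_timepoints} time points after onset, "
            f"got {data.shape[0]}")
    t = np.arange(n_timepoints)
    basis = np.exp(-2j * np.pi * n_cycles * t / n_timepoints)
    coef = (2.0 / n_timepoints) * (basis @ data)
    amplitude = np.abs(coef)
    measured_phase = -np.degrees(np.angle(coef))
    correction = 360.0 * delay_seconds / cycle_seconds
    return RetinotopicMap(amplitude, measured_phase - correction, kind)


def combine_retinotopy_runs(forward: RetinotopicMap,
                            reversed_: RetinotopicMap) -> RetinotopicMap:
    """Average a forward- and reversed-direction run into one map.

    The reversed run encodes the negated phase, so its phase is mirrored
    into the forward convention before circular averaging; residual
    hemodynamic-delay phase errors of opposite sign cancel exactly.  The
    amplitude is the arithmetic mean of the two runs.
    """
    if forward.kind != reversed_.kind:
        raise InvalidInputError("cannot combine maps of different kinds")
    amp = 0.5 * (forward.amplitude + reversed_.amplitude)
    zf = np.exp(1j * np.deg2rad(forward.phase))
    zr = np.exp(-1j * np.deg2rad(reversed_.phase))  # mirror into forward convention
    phase = np.degrees(np.angle(zf + zr))
    return RetinotopicMap(amp, phase, forward.kind)


# --------------------------------------------------------------------------
# movie response patterns

def predict_movie_patterns(S_rows: StimulusMatrix, tuning: TuningMatrix) -> np.ndarray:
    """Predicted response patterns to held-out stimuli: S_rows @ T_p."""
    check_same_basis(S_rows, tuning)
    return S_rows.data @ tuning.data


def reduce_patterns_pca(train_patterns: np.ndarray,
                        apply_patterns: list[np.ndarray],
                        n_components: int) -> list[np.ndarray]:
    """Project patterns onto normalized principal components.

    PCA is fit on ``train_patterns`` (time points as samples, vertices as
    features); every matrix in ``apply_patterns`` is projected and each
    component divided by its training-set standard deviation, so similarity
    comparisons weight components equally.
    """
    train_patterns = np.asarray(train_patterns, float)
    if n_components > min(train_patterns.shape):
        raise InvalidInputError("n_components exceeds min(t, v)")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(train_patterns)
    sd = np.sqrt(pca.explained_variance_)
    sd[sd <= 0] = 1.0
    return [pca.transform(np.asarray(a, float)) / sd for a in apply_patterns]


def _row_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of A with every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    An = np.linalg.norm(Ac, axis=1)
    Bn = np.linalg.norm(Bc, axis=1)
    An[An <= 0] = 1.0
    Bn[Bn <= 0] = 1.0
    return (Ac / An[:, None]) @ (Bc / Bn[:, None]).T


def classify_timepoints_binary(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Two-alternative forced-choice time-point classification accuracy.

    For every target time point and every foil, the trial counts as correct
    when the measured pattern correlates more with the same-time-point
    prediction than with the foil prediction; ties count 0.5.  Chance = 0.5.
    """
    measured, predicted = np.asarray(measured, float), np.asarray(predicted, float)
    if measured.shape != predicted.shape:
        raise InvalidInputError("measured and predicted must share shape")
    t = measured.shape[0]
    if t < 2:
        raise InvalidInputError("need at least 2 time points")
    C = _row_correlations(measured, predicted)
    diag = np.diag(C)
    wins = (diag[:, None] > C).sum(axis=1) + 0.5 * (diag[:, None] == C).sum(axis=1)
    # remove the self comparison, counted above as an exact tie
    wins -= 0.5
    return float(np.mean(wins / (t - 1)))


def classify_timepoints_multiclass(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Fraction of time points whose own prediction is the strict best match.

    All predicted time points (including immediate temporal neighbors) serve
    as candidate classes; ties score as incorrect.  Chance = 1 / n_timepoints.
    """
    measured, predicted = np.asarray(measured, float), np.asarray(predicted, float)
    if measured.shape != predicted.shape:
        raise InvalidInputError("measured and predicted must share shape")
    t = measured.shape[0]
    if t < 2:
        raise InvalidInputError("need at least 2 time points")
    C = _row_correlations(measured, predicted)
    diag = np.diag(C).copy()
    off = C.copy()
    np.fill_diagonal(off, -np.inf)
    correct = diag > off.max(axis=1)
    return float(np.mean(correct))
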