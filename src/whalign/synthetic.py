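"""Synthetic multi-subject cohorts with the statistical structure the
individualized-tuning model assumes.

Each participant's response matrix is generated from a shared orthogonal
stimulus basis S_true and an individual tuning matrix T_p that mixes a
cohort-shared component with an idiosyncratic one, optionally scrambled by a
topographic warp, plus i.i.d. Gaussian noise:

    B_p = S_true (T_p W_p) / sqrt(k) + noise_sd * E_p,   then z-scored.

The 1/sqrt(k) factor gives the signal approximately unit vertex variance, so
``noise_sd`` reads as a noise:signal SD ratio.  Localizer and traveling-wave
retinotopy fixtures reuse the same ground-truth tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data import (
    InvalidInputError,
    SubjectTimeseries,
    SurfaceGeometry,
    grid_geometry,
    normalize_timeseries,
    sphere_geometry,
)
from .prediction import SelectivityMap


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults define the standard desk-scale cohort: 10 participants, 600 TRs
    at 1 s, a 20 x 20 grid of vertices with 3 mm spacing, 40 latent features,
    a between-subject tuning correlation of 0.5 and moderate noise
    (noise SD equal to the signal SD).
    """

    n_subjects: int = 10
    t_time: int = 600
    v_vertex: int = 400
    k_latent: int = 40
    tr_seconds: float = 1.0
    noise_sd: float = 1.0
    tuning_between_subject_corr: float = 0.5
    topographic_warp: str = "none"  # none | local_rotation | smooth_displacement
    geometry_kind: str = "grid"     # grid | sphere
    spacing_mm: float = 3.0
    warp_block: int = 4             # vertices per side of a local-rotation block
    seed: int = 0

    def __post_init__(self):
        if self.k_latent > min(self.t_time, self.v_vertex):
            raise InvalidInputError("k_latent must be <= min(t, v)")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not (0 <= self.tuning_between_subject_corr < 1):
            raise InvalidInputError("tuning correlation target must lie in [0, 1)")
        if self.topographic_warp not in ("none", "local_rotation", "smooth_displacement"):
            raise InvalidInputError(f"unknown warp {self.topographic_warp!r}")


@dataclass
class GroundTruth:
    """Generating quantities of a synthetic cohort.

    ``T_true`` holds the pre-warp tuning matrices; the effective generator is
    B_p = S_true @ (T_true_p @ W_true_p) + noise, with W_true_p the identity
    when no warp is requested.
    """

    S_true: np.ndarray                  # (t, k), orthogonal unit-variance columns
    T_true: dict[str, np.ndarray]       # subject_id -> (k, v)
    W_true: dict[str, np.ndarray] = field(default_factory=dict)
    geometry: SurfaceGeometry = None
    spec: CohortSpec = None


def _orthogonal_stimulus_basis(t: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random t x k basis: zero-mean, mutually orthogonal, unit-variance columns."""
    g = rng.standard_normal((t, k + 1))
    g[:, 0] = 1.0  # orthogonalize against the constant so columns are zero-mean
    q, _ = np.linalg.qr(g)
    basis = q[:, 1:k + 1]
    return basis / basis.std(axis=0)


def _geometry_for(spec: CohortSpec) -> SurfaceGeometry:
    if spec.geometry_kind == "grid":
        side = int(round(np.sqrt(spec.v_vertex)))
        if side * side != spec.v_vertex:
            raise InvalidInputError("grid geometry needs a square vertex count")
        return grid_geometry(side, side, spacing_mm=spec.spacing_mm)
    if spec.geometry_kind == "sphere":
        return sphere_geometry(spec.v_vertex)
    raise InvalidInputError(f"unknown geometry {spec.geometry_kind!r}")


def _warp_matrix(spec: CohortSpec, geom: SurfaceGeometry,
                 rng: np.random.Generator) -> np.ndarray:
    v = spec.v_vertex
    if spec.topographic_warp == "none":
        return np.eye(v)
    if spec.topographic_warp == "local_rotation":
        # random orthogonal mixing within non-overlapping vertex blocks
        W = np.zeros((v, v))
        order = np.arange(v)
        block = max(2, spec.warp_block ** 2)
        for start in range(0, v, block):
            idx = order[start:start + block]
            g = rng.standard_normal((idx.size, idx.size))
            q, r = np.linalg.qr(g)
            q *= np.sign(np.diag(r))
            W[np.ix_(idx, idx)] = q
        return W
    # smooth_displacement: resample each vertex from a smoothly displaced
    # position via inverse-distance weights of its 4 nearest grid vertices
    coords = geom.coordinates
    span = coords.max(axis=0) - coords.min(axis=0)
    span[span <= 0] = 1.0
    phases = rng.uniform(0, 2 * np.pi, size=(2, 3))
    amp = spec.spacing_mm
    disp = np.stack([
        amp * np.sin(2 * np.pi * coords[:, (d + 1) % 2] / span[(d + 1) % 2] + phases[0, d])
        * np.cos(2 * np.pi * coords[:, d % 2] / span[d % 2] + phases[1, d])
        for d in range(2)], axis=1)
    moved = coords.copy()
    moved[:, :2] += disp
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    dist, nbr = tree.query(moved, k=4)
    wgt = 1.0 / np.maximum(dist, 1e-6)
    wgt /= wgt.sum(axis=1, keepdims=True)
    W = np.zeros((v, v))
    for j in range(v):
        W[nbr[j], j] = wgt[j]
    return W


def make_cohort(spec: CohortSpec) -> tuple[list[SubjectTimeseries], GroundTruth]:
    """Generate a cohort and its ground truth.  Deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    geom = _geometry_for(spec)
    S = _orthogonal_stimulus_basis(spec.t_time, spec.k_latent, rng)
    c = spec.tuning_between_subject_corr
    T_base = rng.standard_normal((spec.k_latent, spec.v_vertex))
    cohort, T_true, W_true = [], {}, {}
    for p in range(spec.n_subjects):
        sid = f"sub-{p:02d}"
        T_ind = rng.standard_normal((spec.k_latent, spec.v_vertex))
        T_p = np.sqrt(c) * T_base + np.sqrt(1 - c) * T_ind
        W_p = _warp_matrix(spec, geom, rng)
        signal = (S @ (T_p @ W_p)) / np.sqrt(spec.k_latent)
        noise = spec.noise_sd * rng.standard_normal(signal.shape)
        ts = SubjectTimeseries(sid, signal + noise, tr_seconds=spec.tr_seconds)
        cohort.append(normalize_timeseries(ts))
        T_true[sid] = T_p
        W_true[sid] = W_p
    return cohort, GroundTruth(S, T_true, W_true, geom, spec)


def make_localizer_fixture(truth: GroundTruth, n_runs: int = 4,
                           run_noise_sd: float = 1.0,
                           condition: str = "faces",
                           seed: int = 0) -> tuple[dict[str, SelectivityMap], np.ndarray]:
    """Per-subject selectivity maps with per-run noisy repeats.

    The true map of subject p is s* @ T_true_p for one drawn condition
    descriptor s* (scaled to unit map variance); each run adds i.i.d. noise
    of SD ``run_noise_sd``, so the single-run reliability is approximately
    var_T / (var_T + run_noise_sd^2) and Cronbach's alpha of the runs follows
    Spearman-Brown.  Returns the maps and the descriptor s*.
    """
    rng = np.random.default_rng(seed)
    k = truth.S_true.shape[1]
    s_star = rng.standard_normal(k) / np.sqrt(k)
    out = {}
    for sid, T_p in truth.T_true.items():
        W_p = truth.W_true.get(sid)
        T_eff = T_p if W_p is None else T_p @ W_p
        true_map = s_star @ T_eff
        runs = [true_map + run_noise_sd * rng.standard_normal(true_map.shape)
                for _ in range(n_runs)]
        out[sid] = SelectivityMap(sid, np.mean(runs, axis=0), condition=condition,
                                  run_maps=runs)
    return out, s_star


def smooth_phase_field(geom: SurfaceGeometry, kind: str = "eccentricity") -> np.ndarray:
    """Deterministic smooth phase map (degrees) over the vertex coordinates.

    Eccentricity grows radially from the patch center (0 deg at center, near
    360 deg at the corners); polar angle follows the angular position.
    """
    coords = geom.coordinates[:, :2]
    center = coords.mean(axis=0)
    rel = coords - center
    if kind == "eccentricity":
        r = np.linalg.norm(rel, axis=1)
        return 359.0 * r / max(r.max(), 1e-9)
    return np.mod(np.degrees(np.arctan2(rel[:, 1], rel[:, 0])), 360.0)


def make_retinotopy_fixture(geom: SurfaceGeometry, phase_field: np.ndarray,
                            amplitude_field: np.ndarray | None = None,
                            n_timepoints: int = 80, n_cycles: int = 5,
                            tr_seconds: float = 2.0, delay_seconds: float = 5.0,
                            noise_sd: float = 0.0, seed: int = 0,
                            subject_id: str = "sub-00"
                            ) -> tuple[SubjectTimeseries, SubjectTimeseries]:
    """Forward and reversed traveling-wave runs for one subject.

    Each vertex responds as A(v) * cos(omega (t - delay) -/+ theta(v)) with
    omega the stimulus frequency (n_cycles over the run), so the measured
    Fourier phase carries the hemodynamic delay; the reversed run traverses
    the stimulus cycle in the opposite direction (phase negated).
    """
    v = geom.n_vertices
    A = np.ones(v) if amplitude_field is None else np.asarray(amplitude_field, float)
    theta = np.deg2rad(np.asarray(phase_field, float))
    rng = np.random.default_rng(seed)
    t_sec = np.arange(n_timepoints) * tr_seconds
    cycle_seconds = n_timepoints * tr_seconds / n_cycles
    omega = 2 * np.pi / cycle_seconds
    arg = omega * (t_sec - delay_seconds)
    fwd = A[None, :] * np.cos(arg[:, None] - theta[None, :])
    rev = A[None, :] * np.cos(arg[:, None] + theta[None, :])
    if noise_sd > 0:
        fwd = fwd + noise_sd * rng.standard_normal(fwd.shape)
        rev = rev + noise_sd * rng.standard_normal(rev.shape)
    return (SubjectTimeseries(subject_id, fwd, tr_seconds=tr_seconds),
            SubjectTimeseries(subject_id, rev, tr_seconds=tr_seconds))


def tuning_recovery_score(T_hat: np.ndarray, T_true: np.ndarray) -> float:
    """Mean canonical correlation between estimated and true tuning row spaces.

    Tuning is identified only up to an invertible change of basis and
    per-vertex gain (the pipeline z-scores every vertex), so columns are
    normalized to unit length and recovery judged by the principal angles
    between the row spaces of the two matrices, restricted to the true
    latent dimensionality.
    """
    def orth_rows(T):
        norms = np.linalg.norm(T, axis=0)
        T = T / np.where(norms > 0, norms, 1.0)
        q, r = np.linalg.qr(T.T)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        return q[:, keep]

    k = min(np.linalg.matrix_rank(T_true), T_true.shape[0])
    Qh, Qt = orth_rows(T_hat), orth_rows(T_true)
    sv = linalg.svd(Qh.T @ Qt, compute_uv=False)
    sv = np.sort(sv)[::-1][:k]
    return float(np.mean(np.clip(sv, 0, 1)))


def recovery_report(spec: CohortSpec, truth: GroundTruth, split_half_result,
                    sweep: list[dict] | None = None) -> dict:
    """Structured report of pipeline recovery against the generating truth.

    Tabulates per-subject tuning recovery, identification accuracy and
    distinctiveness; with ``sweep`` records, also the distinctiveness trend
    over data volume.  Deterministic given the upstream seeds.
    """
    res = split_half_result
    recov = {}
    for T_hat in res.tunings_half1:
        W = truth.W_true.get(T_hat.subject_id)
        T_eff = truth.T_true[T_hat.subject_id]
        if W is not None:
            T_eff = T_eff @ W
        recov[T_hat.subject_id] = tuning_recovery_score(T_hat.data, T_eff)
    z = res.similarity.fisher_z
    n = res.similarity.n_subjects
    report = {
        "schema_version": 1,
        "spec": {"n_subjects": spec.n_subjects, "t_time": spec.t_time,
                 "v_vertex": spec.v_vertex, "k_latent": spec.k_latent,
                 "noise_sd": spec.noise_sd,
                 "tuning_between_subject_corr": spec.tuning_between_subject_corr,
                 "topographic_warp": spec.topographic_warp, "seed": spec.seed},
        "identification_accuracy": res.identification_accuracy,
        "mean_distinctiveness": res.distinctiveness.mean_d,
        "within_subject_similarity_mean": float(np.tanh(np.diag(z).mean())),
        "between_subject_similarity_mean": float(np.tanh(
            z[~np.eye(n, dtype=bool)].mean())),
        "tuning_recovery": recov,
    }
    if sweep is not None:
        report["volume_sweep"] = sweep
    return report
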