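"""End-to-end experiment drivers: split-half reliability, leave-one-subject-out
map prediction, and the data-volume sweep.

These functions orchestrate the pipeline stages (template -> warp
hyperalignment -> stimulus/tuning decomposition -> metrics) the way the
benchmarking analyses combine them, with a single master seed fanned out to
named substreams so that individual arms can be re-run reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .bagging import BaggingConfig, RidgeConfig
from .data import InvalidInputError, SubjectTimeseries, SurfaceGeometry
from .metrics import (
    DistinctivenessResult,
    SimilarityMatrix,
    cohort_distinctiveness,
    nearest_neighbor_identification,
    tuning_similarity_matrix,
)
from .prediction import EnsembleRegressionConfig, estimate_contrast_descriptor, \
    predict_selectivity_map
from .template import FunctionalTemplate, build_template
from .tuning import StimulusMatrix, TuningMatrix, compute_stimulus_matrix, \
    estimate_tuning
from .wha import apply_transform, fit_wha


def substream_seed(master_seed: int, name: str, index: int = 0) -> int:
    """Deterministic 31-bit seed for a named substream of the master seed."""
    return (zlib.crc32(f"{master_seed}:{name}:{index}".encode()) & 0x7FFFFFFF)


@dataclass
class ExperimentConfig:
    """Consolidated pipeline parameters (defaults are the standard values)."""

    radius_mm: float = 20.0
    wha_lambda: float = 1e3
    bagging_k: int = 5
    bagging_repetitions: int = 20
    buffer_seconds: float = 10.0
    segment_seconds: float = 10.0
    ensemble_k: int = 5
    ensemble_repetitions: int = 10
    lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-2, 2, 21))
    n_run_bootstrap: int = 4
    pca_components: list[int] = field(default_factory=lambda: list(range(10, 310, 10)))
    sweep_durations_minutes: list[float] = field(default_factory=list)
    seed: int = 0

    def bagging(self, seed: int) -> BaggingConfig:
        return BaggingConfig(k_folds=self.bagging_k,
                             repetitions=self.bagging_repetitions,
                             buffer_seconds=self.buffer_seconds,
                             segment_seconds=self.segment_seconds, seed=seed)

    def ridge(self) -> RidgeConfig:
        return RidgeConfig(lam=self.wha_lambda)

    def ensemble(self, seed: int) -> EnsembleRegressionConfig:
        return EnsembleRegressionConfig(
            k_folds=self.ensemble_k, repetitions=self.ensemble_repetitions,
            lambda_grid=np.asarray(self.lambda_grid, float),
            n_run_bootstrap=self.n_run_bootstrap, seed=seed)


def slice_timeseries(ts: SubjectTimeseries, start: int, stop: int) -> SubjectTimeseries:
    """Row slice with run boundaries remapped into the slice."""
    rb = [b - start for b in ts.run_boundaries if start <= b < stop]
    if not rb or rb[0] != 0:
        rb = [0] + rb
    return SubjectTimeseries(ts.subject_id, ts.data[start:stop],
                             tr_seconds=ts.tr_seconds, run_boundaries=rb)


def _template_rows(tpl: FunctionalTemplate, rows: np.ndarray) -> FunctionalTemplate:
    return FunctionalTemplate(tpl.data[rows], n_train=tpl.n_train,
                              radius_mm=tpl.radius_mm, pc_scale=tpl.pc_scale)


@dataclass
class SplitHalfResult:
    """Output of the split-half tuning reliability analysis."""

    template: FunctionalTemplate
    S: StimulusMatrix
    tunings_half1: list[TuningMatrix]
    tunings_half2: list[TuningMatrix]
    similarity: SimilarityMatrix
    distinctiveness: DistinctivenessResult
    identification_accuracy: float


def split_half_tuning_analysis(cohort: list[SubjectTimeseries],
                               geom: SurfaceGeometry,
                               cfg: ExperimentConfig | None = None,
                               template: FunctionalTemplate | None = None,
                               half_timepoints: int | None = None
                               ) -> SplitHalfResult:
    """Estimate each subject's tuning matrix from each half of the data.

    One template and one stimulus basis are shared by the whole cohort (a
    shared basis is required to compare tuning matrices across subjects); the
    warp transform is refit per half, and the stimulus matrix rows are split
    so both half-estimates live in the same basis.  ``half_timepoints``
    optionally truncates each half (data-volume sweep).
    """
    cfg = cfg or ExperimentConfig()
    t = cohort[0].n_timepoints
    if any(ts.n_timepoints != t for ts in cohort):
        raise InvalidInputError("cohort time axes must match")
    if template is None:
        template = build_template(cohort, geom, radius_mm=cfg.radius_mm)
    half = t // 2
    use = half if half_timepoints is None else min(half_timepoints, half)
    spans = [(0, use), (half, half + use)]
    row_blocks = [np.arange(a, b) for a, b in spans]

    modeled = {h: [] for h in (0, 1)}
    transforms = {h: [] for h in (0, 1)}
    for p, ts in enumerate(cohort):
        for h, (a, b) in enumerate(spans):
            ts_h = slice_timeseries(ts, a, b)
            tpl_h = _template_rows(template, row_blocks[h])
            W = fit_wha(tpl_h, ts_h, geom, radius_mm=cfg.radius_mm,
                        ridge_cfg=cfg.ridge(),
                        bagging_cfg=cfg.bagging(substream_seed(cfg.seed, "wha", 2 * p + h)))
            transforms[h].append(W)
            modeled[h].append(apply_transform(tpl_h, W))

    # The stimulus basis comes from full-length modeled responses under the
    # subject's pooled transform ensemble (mean of the two half ensembles), so
    # every basis component has a consistent time course across halves; the
    # per-half modeled data enter only the tuning estimates, keeping the two
    # estimates of T_p independent.
    stacked = [np.asarray(template.data @
                          ((transforms[0][p].matrix + transforms[1][p].matrix) * 0.5))
               for p in range(len(cohort))]
    S = compute_stimulus_matrix(stacked)
    S_halves = [S.restrict(row_blocks[0]), S.restrict(row_blocks[1])]
    tunings = {h: [estimate_tuning(S_halves[h], modeled[h][p],
                                   subject_id=cohort[p].subject_id)
                   for p in range(len(cohort))] for h in (0, 1)}
    sim = tuning_similarity_matrix(tunings[0], tunings[1])
    return SplitHalfResult(
        template=template, S=S,
        tunings_half1=tunings[0], tunings_half2=tunings[1],
        similarity=sim,
        distinctiveness=cohort_distinctiveness(sim),
        identification_accuracy=nearest_neighbor_identification(sim))


@dataclass
class LosoFoldResult:
    subject_id: str
    predicted_map: np.ndarray
    within_correlation: float
    between_correlations: dict[str, float]


def run_loso_experiment(cohort: list[SubjectTimeseries], geom: SurfaceGeometry,
                        localizers: dict[str, "SelectivityMap"],
                        cfg: ExperimentConfig | None = None) -> list[LosoFoldResult]:
    """Leave-one-subject-out category-map prediction.

    Per fold: template and stimulus basis from the n-1 training subjects;
    tuning matrices for everyone under that basis; contrast descriptor from
    the training subjects' localizer maps by ensemble ridge; the test
    subject's predicted map is descriptor @ T_test, scored by correlation
    against the subject's own localizer map and everyone else's predictions.
    """
    cfg = cfg or ExperimentConfig()
    if len(cohort) < 3:
        raise InvalidInputError("leave-one-subject-out needs >= 3 subjects")
    results = []
    ids = [ts.subject_id for ts in cohort]
    for f, test_ts in enumerate(cohort):
        train = [ts for ts in cohort if ts.subject_id != test_ts.subject_id]
        template = build_template(train, geom, radius_mm=cfg.radius_mm)
        modeled, tunings = {}, {}
        for p, ts in enumerate(cohort):
            W = fit_wha(template, ts, geom, radius_mm=cfg.radius_mm,
                        ridge_cfg=cfg.ridge(),
                        bagging_cfg=cfg.bagging(substream_seed(cfg.seed, f"loso{f}", p)))
            modeled[ts.subject_id] = apply_transform(template, W)
        S = compute_stimulus_matrix([modeled[ts.subject_id] for ts in train])
        for ts in cohort:
            tunings[ts.subject_id] = estimate_tuning(S, modeled[ts.subject_id],
                                                     subject_id=ts.subject_id)
        train_maps = [localizers[ts.subject_id] for ts in train]
        train_tunings = [tunings[ts.subject_id] for ts in train]
        desc = estimate_contrast_descriptor(
            train_maps, train_tunings,
            cfg.ensemble(substream_seed(cfg.seed, "ensemble", f)))
        predicted = {sid: predict_selectivity_map(desc, tunings[sid]) for sid in ids}
        own = localizers[test_ts.subject_id].values
        within = float(np.corrcoef(own, predicted[test_ts.subject_id].values)[0, 1])
        between = {sid: float(np.corrcoef(own, predicted[sid].values)[0, 1])
                   for sid in ids if sid != test_ts.subject_id}
        results.append(LosoFoldResult(test_ts.subject_id,
                                      predicted[test_ts.subject_id].values,
                                      within, between))
    return results


def run_volume_sweep(cohort: list[SubjectTimeseries], geom: SurfaceGeometry,
                     durations_minutes: list[float],
                     cfg: ExperimentConfig | None = None) -> list[dict]:
    """Split-half distinctiveness as a function of per-estimate data volume."""
    cfg = cfg or ExperimentConfig()
    if not durations_minutes:
        raise InvalidInputError("empty duration list")
    tr = cohort[0].tr_seconds
    half = cohort[0].n_timepoints // 2
    template = build_template(cohort, geom, radius_mm=cfg.radius_mm)
    out = []
    for minutes in durations_minutes:
        n_tp = int(round(minutes * 60.0 / tr))
        if n_tp > half:
            import warnings
            warnings.warn(f"duration {minutes} min exceeds half the data; skipped")
            continue
        res = split_half_tuning_analysis(cohort, geom, cfg, template=template,
                                         half_timepoints=n_tp)
        out.append({"minutes": float(minutes), "n_timepoints": n_tp,
                    "mean_distinctiveness": res.distinctiveness.mean_d,
                    "identification_accuracy": res.identification_accuracy})
    return out
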