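"""k-fold bagging for time series ridge regression.

Classic bagging can leave time points with no out-of-bag model.  The k-fold
bagging scheme divides the time series into short segments, assigns segments
to k folds, and bootstraps training samples from the folds not held out, so
that after one repetition every time point has at least one out-of-bag
model.  A temporal buffer keeps every training/test pair of time points at
least ``buffer_seconds`` apart, preventing the models from exploiting
temporal autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import InvalidInputError


@dataclass
class RidgeConfig:
    """Ridge penalty for warp hyperalignment (no intercept; inputs z-scored)."""

    lam: float = 1e3

    def __post_init__(self):
        if self.lam <= 0:
            raise InvalidInputError("lambda must be positive")


@dataclass
class BaggingConfig:
    """k-fold bagging ensemble configuration.

    Defaults follow the standard recipe: 5 folds repeated 20 times (100
    models), 10-second segments and a 10-second train/test buffer, so every
    time point is predicted by at least 20 out-of-bag models.
    """

    k_folds: int = 5
    repetitions: int = 20
    buffer_seconds: float = 10.0
    segment_seconds: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise InvalidInputError("k_folds must be >= 2")
        if self.buffer_seconds < 0 or self.segment_seconds <= 0:
            raise InvalidInputError("invalid buffer/segment lengths")

    @property
    def models_total(self) -> int:
        return self.k_folds * self.repetitions


@dataclass
class FoldPlan:
    """Realized bagging plan for one time series.

    ``train_counts[m]`` is the bootstrap multiplicity of each time point in
    model m's training sample; ``test_mask[m]`` marks the time points model m
    may be evaluated on (candidate test plus unsampled candidate training,
    all at least the buffer away from every sampled training point).
    """

    n_timepoints: int
    tr_seconds: float
    config: BaggingConfig
    segment_of: np.ndarray            # (t,) segment id of each time point
    train_counts: np.ndarray          # (n_models, t) int
    test_mask: np.ndarray             # (n_models, t) bool
    repetition_of: np.ndarray = field(default=None)  # (n_models,)

    @property
    def n_models(self) -> int:
        return self.train_counts.shape[0]

    def oob_model_count(self) -> np.ndarray:
        """Number of models for which each time point is eligible test data."""
        return self.test_mask.sum(axis=0)


def _segments(t_time: int, tr: float, segment_seconds: float,
              run_boundaries: list[int]) -> np.ndarray:
    """Assign each time point to a segment; segments never span runs."""
    seg_len = max(1, int(np.ceil(segment_seconds / tr)))
    seg_of = np.empty(t_time, dtype=int)
    seg_id = 0
    bounds = list(run_boundaries) + [t_time]
    for start, stop in zip(bounds[:-1], bounds[1:]):
        for s in range(start, stop, seg_len):
            seg_of[s:min(s + seg_len, stop)] = seg_id
            seg_id += 1
    return seg_of


def make_fold_plan(t_time: int, tr_seconds: float, cfg: BaggingConfig,
                   run_boundaries: list[int] | None = None,
                   rng: np.random.Generator | None = None) -> FoldPlan:
    """Draw a k-fold bagging plan.

    For each repetition, segments are shuffled into k folds.  Per fold:
    candidate test = that fold's time points; candidate training = points at
    least ``buffer_seconds`` from every candidate test point (within the same
    run; cross-run pairs are never temporally adjacent); the training sample
    bootstraps |candidate training| points with replacement; eligible test =
    every point at least the buffer away from all *sampled* training points.
    """
    if run_boundaries is None:
        run_boundaries = [0]
    if t_time * tr_seconds < cfg.k_folds * cfg.segment_seconds:
        raise InvalidInputError("time series too short for the requested folds")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    seg_of = _segments(t_time, tr_seconds, cfg.segment_seconds, run_boundaries)
    n_seg = seg_of.max() + 1
    buf_trs = int(np.ceil(cfg.buffer_seconds / tr_seconds))

    run_of = np.zeros(t_time, dtype=int)
    bounds = list(run_boundaries) + [t_time]
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        run_of[a:b] = i
    tidx = np.arange(t_time)

    def too_close(mask: np.ndarray) -> np.ndarray:
        """Points whose gap to any point in ``mask`` is < buffer (same run only)."""
        out = np.zeros(t_time, dtype=bool)
        pts = tidx[mask]
        if pts.size == 0:
            return out
        for a, b in zip(bounds[:-1], bounds[1:]):
            run_pts = pts[(pts >= a) & (pts < b)]
            if run_pts.size == 0:
                continue
            hit = np.zeros(b - a, dtype=bool)
            for p in run_pts:
                lo = max(a, p - buf_trs + 1)
                hi = min(b, p + buf_trs)
                hit[lo - a:hi - a] = True
            out[a:b] |= hit
        return out

    n_models = cfg.models_total
    train_counts = np.zeros((n_models, t_time), dtype=np.int32)
    test_mask = np.zeros((n_models, t_time), dtype=bool)
    rep_of = np.zeros(n_models, dtype=int)
    m = 0
    for rep in range(cfg.repetitions):
        perm = rng.permutation(n_seg)
        fold_of_seg = np.empty(n_seg, dtype=int)
        fold_of_seg[perm] = np.arange(n_seg) % cfg.k_folds
        for fold in range(cfg.k_folds):
            cand_test = fold_of_seg[seg_of] == fold
            cand_train = ~too_close(cand_test)
            cand_train &= ~cand_test
            n_train = int(cand_train.sum())
            if n_train == 0:
                raise InvalidInputError(
                    "buffer leaves no candidate training data; shorten buffer or segments")
            pool = tidx[cand_train]
            sample = rng.choice(pool, size=n_train, replace=True)
            np.add.at(train_counts[m], sample, 1)
            sampled = train_counts[m] > 0
            test_mask[m] = ~too_close(sampled) & ~sampled
            rep_of[m] = rep
            m += 1
    return FoldPlan(t_time, tr_seconds, cfg, seg_of, train_counts, test_mask, rep_of)


def ridge_fit(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution (X'X + lam*I)^-1 X'Y, no intercept."""
    q = X.shape[1]
    G = X.T @ X + lam * np.eye(q)
    return np.linalg.solve(G, X.T @ Y)
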