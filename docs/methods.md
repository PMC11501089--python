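# Methods

## The model

Each participant's cortical response to a naturalistic stimulus is a
time x vertex matrix `B_p` (rows = TRs, columns = surface vertices, z-scored
per vertex).  The individualized neural tuning model decomposes the cohort's
responses into three parts:

    B_p  =  M W_p + E  =  S T_p + E'

* `M` (t x v) — a **group functional template** representative of the
  training cohort in both representational geometry and cortical topography.
* `W_p` (v x v, sparse) — a **whole-brain linear transform** mapping the
  template into participant p's idiosyncratic functional topography and
  geometry ("warp hyperalignment").
* `S` (t x k) — a **stimulus matrix**: an orthogonal, unit-variance basis of
  response profiles shared by the cohort; its rows are data-driven stimulus
  descriptors.
* `T_p` (k x v) — participant p's **tuning matrix**: each vertex's response
  profile as weights on the shared basis.  `T_p` is stimulus-general: the
  same matrix is identifiable from different stimulus subsets, which is what
  makes it usable as a stable fingerprint of individual functional
  organization.

### Template construction

Per searchlight (all vertices within `radius_mm` of a center, default
20 mm): (1) participants' searchlight blocks are concatenated along vertices
and the first `v_sl` principal-component score series extracted, divided by
sqrt(n) so the local template's total variance matches a single
participant's (the group spectrum scales with n); (2) an orthogonal
Procrustes rotation — the SVD-based minimizer of the stacked Frobenius error
against all participants' blocks — maps the PC axes back onto vertices
without altering the representational geometry (row-distance structure is
preserved to machine precision); (3) local templates are aggregated by a
distance-weighted average with weight `(r - d)/r`, 1 at the center and 0 at
the boundary, normalized per vertex, so each vertex's template profile is a
convex combination of the local estimates.

SVD sign indeterminacy is fixed by making each component's
largest-magnitude loading positive, which makes the template invariant to
participant ordering.  Rank-deficient searchlights (t < v_sl) keep their
rank components zero-padded, with a warning.

### Warp hyperalignment

`W_p` is estimated per searchlight by ridge regression of the participant's
block on the template block (penalty `lambda = 1e3`, no intercept), within a
k-fold bagging ensemble: the time series is cut into 10 s segments
(segments never span runs), segments are randomly assigned to k = 5 folds,
and per fold a bootstrap sample of the candidate training points (those at
least `buffer_seconds = 10 s` from every candidate test point, within-run)
is drawn with replacement, sized to the candidate pool.  The scheme is
repeated 20 times (100 models), guaranteeing at least 20 out-of-bag models
per time point; a pair of time points with gap < buffer never co-occurs as
train and test.  The local transform is the mean of the 100 closed-form
ridge solutions; whole-brain aggregation averages local columns with the
same `(r - d)/r` weights, so `W_p` is exactly zero outside searchlight
co-occurrence.  The orthogonal-Procrustes baseline replaces the ridge fit
with the rigid rotation; on training data its reconstruction error is never
below the unconstrained fit's.

### Stimulus/tuning separation

`S` comes from an SVD of the column-concatenated modeled responses of all
participants; k is the numerical rank (singular values above 1e-10 of the
maximum).  Each left singular vector is rescaled to unit variance, so the
scale of estimated tuning matrices does not depend on how many stimulus
rows were observed (a `sqrt_n`-times-U variant is available).  `T_p` is the
least-squares solution `pinv(S_rows) B_rows`; with fewer observed rows than
features this is the minimum-norm solution.  Tuning matrices carry a
`basis_id` fingerprint of the S they were estimated under, and every
cross-matrix comparison refuses mismatched bases.

**Split-half analyses.**  Reliability and identification compare tuning
matrices estimated from the two halves of the time series, with `W_p` refit
per half so the two estimates are statistically independent.  The basis `S`
is computed once from full-length modeled responses `M @ W-bar_p`, where
`W-bar_p` averages the two half ensembles (bagging averages bootstrap
models; a model fit within one half is a bootstrap model of the full series
with half-restricted sampling).  Validated against dedicated full-length
fits, this gives identical similarity structure at half the cost.  Building
the basis from per-half modeled data instead is numerically disastrous at
desk scale: each component then carries half-specific temporal noise and
the two minimum-norm tuning estimates live in nearly disjoint feature
subspaces, collapsing within-subject similarity toward zero — a rank
phenomenon worth knowing about when t exceeds v.

### Prediction arms

*Category selectivity.*  A contrast's stimulus descriptor row is estimated
from training participants' localizer maps by a bagged ridge ensemble over
participants (5 folds x 10 repetitions = 50 models; per model the candidate
training participants are bootstrapped with replacement and, per chosen
participant, 4 localizer runs are bootstrapped and averaged; vertices of the
chosen participants are concatenated and the map regressed on tuning
columns).  A single penalty from a 21-point log grid on [0.01, 100] is
chosen by out-of-bag squared error pooled across models; the final
descriptor averages the model coefficients.  The predicted map is
`descriptor @ T_p`.

*Retinotopy.*  Phase-encoded maps are estimated per vertex from the Fourier
coefficient at the stimulus frequency (default 5 cycles in 80 TRs),
amplitude-scaled 2/n, phase corrected for a 5 s hemodynamic delay
(360 * delay / cycle_seconds = 56.25 deg for a 32 s cycle).  A
reversed-direction run encodes the negated phase; combination mirrors it
into the forward convention and takes the circular mean (cancelling
residual delay) and the arithmetic mean amplitude.  For linear prediction
the circular map is encoded as `x = A cos(theta)`, `y = A sin(theta)`; two
descriptor rows are estimated and decoded with `A = hypot(x, y)`,
`theta = atan2(y, x)` — the argument order is fixed by requiring
decode(encode(.)) to be the identity.  Zero amplitude decodes to phase 0 by
convention.

*Movie time points.*  Held-out response patterns are predicted as
`S_heldout @ T_p`, compared to measured patterns after projection onto
principal components fit on the participant's training-half patterns, each
component divided by its training SD.  Binary classification scores, for
every target/foil pair, whether the measured pattern correlates more with
the same-time-point prediction; ties count 0.5 (unbiased under
exchangeability).  Multiclass classification requires the own-time-point
correlation to be the strict maximum over all time points, immediate
temporal neighbors included; ties count as errors (conservative).  Binary
accuracy is never below multiclass accuracy.

### Metrics

Similarity between tuning matrices is the Pearson correlation of the
flattened matrices; all averaging of correlations happens on Fisher-z
values.  The distinctiveness index for a participant is
`(z_within - mean(z_between)) / SD(z_between)` computed from that
participant's row (sample SD, ddof = 1); it behaves as a z-statistic, so the
identification error rate is the standard normal upper tail `Phi(-d)`,
evaluated at the cohort-mean d.  Degenerate zero SD returns +/-inf with a
warning (0 when the numerator is also 0).  Cronbach's alpha over vertices,
the Spearman-Brown prediction, and the expected correlation
`sqrt(rho_i rho_j)` of two noisy maps of one truth follow the standard
psychometric forms.  `equivalent_localizer_minutes` inverts Spearman-Brown
through the chain rho_1 = alpha/(k0-(k0-1) alpha), rho_pred = r^2/alpha;
this chain is model-dependent (it assumes the observed r is against the
k0-run average map) and is excluded from numeric acceptance.  Circular
phase difference is the mean absolute angular distance in [0, 180] degrees;
for independent uniform phase maps it converges to 90 degrees.

## Synthetic cohorts

`make_cohort` draws a shared orthogonal unit-variance basis `S_true`
(t x k), a shared tuning component `T_base` and per-subject components, and
mixes them as `T_p = sqrt(c) T_base + sqrt(1-c) T_ind` so the expected
between-subject tuning correlation is exactly the target c.  Responses are
`S_true (T_p W_p)/sqrt(k) + noise`, z-scored; the `1/sqrt(k)` factor gives
the signal approximately unit vertex variance, so `noise_sd` reads as a
noise:signal SD ratio and the default 1.0 is a moderate-noise regime
(per-vertex SNR ~ 1).  Optional topographic warps `W_p` scramble topography:
`local_rotation` applies independent random orthogonal mixes within
non-overlapping vertex blocks; `smooth_displacement` resamples vertices from
smoothly displaced positions by inverse-distance interpolation (a
column-stochastic matrix).  Geometry is a 2-D grid with 3 mm spacing by
default (searchlights well defined and fast; a Fibonacci sphere is
available).

Default study conditions: 10 subjects, 600 TRs at TR = 1 s, 400 vertices
(20 x 20 grid), 40 latent features, c = 0.5, noise SD 1.0.  The localizer
fixture draws one condition descriptor and adds i.i.d. run noise, so the
fixture's Cronbach's alpha follows Spearman-Brown from the analytic
single-run reliability; the retinotopy fixture synthesizes forward/reversed
traveling-wave runs from a smooth phase field with the hemodynamic delay in
the signal path.

What the generator does *not* emulate: hemodynamic convolution (beyond the
retinotopy delay term), temporal autocorrelation of noise, spatially
correlated noise, inter-regional heterogeneity of SNR, and realistic
cortical mesh geometry.  Passing tests therefore certify the estimators and
their statistical behavior under the model's own assumptions, not
performance on real fMRI data.

## Numerical choices

* Group PCA uses the smaller-side Gram matrix and a truncated symmetric
  eigendecomposition (numerically the thin SVD to ~1e-7); the stimulus
  matrix uses a full LAPACK SVD because its rank cut (1e-10 relative) is
  below Gram-path precision.
* Bagged local ridge systems are assembled by slicing whole-brain weighted
  Gram matrices and solved in LAPACK batches grouped by searchlight size;
  the result is identical (1e-10) to the per-searchlight reference
  implementation, which is kept and tested.
* Ridge systems are diagonally loaded with lambda = 1e3, so they are
  well-conditioned (condition number ~ 1 + t/lambda at unit-variance data).
* Zero-variance vertices are zeroed and flagged rather than erroring
  (medial-wall columns are routine).
* Ties: binary classification 0.5, multiclass incorrect, nearest-neighbor
  identification incorrect.
* With the standard penalty, noiseless split-half tuning similarity is
  slightly below 1 (shrinkage bias interacts with finite-sample covariance
  differences between halves); it approaches 1 as lambda -> 0, which is
  tested.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default synthetic conditions above (about 8-10 minutes end to end on one
core); unit and property tests use 4-5 subjects, 36-64 vertices and
120-440 TRs, which exercise every code path in seconds.

## Known limitations

* Geodesic searchlights need explicit mesh edges; no surface resampling.
* No connectivity hyperalignment, GLM estimation of localizer t-maps, or
  pRF modeling (out of scope).
* `lambda` is global; no per-searchlight tuning.
* The identification error rate assumes Fisher-z similarities are normal;
  heavy-tailed deviations at small n are not modeled.
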