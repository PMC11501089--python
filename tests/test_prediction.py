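"""Map prediction, retinotopy, and movie time-point classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import Ridge

import whalign as wa
from whalign.data import InvalidInputError
from whalign.prediction import RetinoEncoding, _row_correlations


class TestEnsembleDescriptor:
    def test_recovers_planted_descriptor(self, rng):
        k, v, n = 6, 500, 5
        s_star = rng.standard_normal(k)
        tunings = [wa.TuningMatrix(f"s{i}", rng.standard_normal((k, v)), "b")
                   for i in range(n)]
        maps = [wa.SelectivityMap(t.subject_id, s_star @ t.data, "faces")
                for t in tunings]
        cfg = wa.EnsembleRegressionConfig(k_folds=2, repetitions=2,
                                          lambda_grid=np.array([1e-4, 1e-2, 1.0]),
                                          seed=1)
        est = wa.estimate_contrast_descriptor(maps, tunings, cfg)
        assert np.linalg.norm(est - s_star) / np.linalg.norm(s_star) < 0.05

    def test_zero_maps_give_zero_descriptor(self, rng):
        tunings = [wa.TuningMatrix(f"s{i}", rng.standard_normal((4, 30)), "b")
                   for i in range(3)]
        maps = [wa.SelectivityMap(t.subject_id, np.zeros(30), "c") for t in tunings]
        cfg = wa.EnsembleRegressionConfig(k_folds=2, repetitions=1, seed=0)
        est = wa.estimate_contrast_descriptor(maps, tunings, cfg)
        np.testing.assert_allclose(est, 0.0, atol=1e-10)

    def test_degenerate_config_equals_plain_ridge(self, rng):
        k, v = 5, 80
        T = wa.TuningMatrix("s0", rng.standard_normal((k, v)), "b")
        y = rng.standard_normal(v)
        cfg = wa.EnsembleRegressionConfig(k_folds=1, repetitions=1,
                                          lambda_grid=np.array([7.0]), seed=0)
        est = wa.ensemble_ridge_descriptors([y[None, :]], [T], cfg)[0]
        oracle = Ridge(alpha=7.0, fit_intercept=False).fit(T.data.T, y).coef_
        np.testing.assert_allclose(est, oracle, atol=1e-8)

    def test_too_few_participants_rejected(self, rng):
        T = wa.TuningMatrix("s0", rng.standard_normal((3, 10)), "b")
        m = wa.SelectivityMap("s0", np.zeros(10))
        with pytest.raises(InvalidInputError):
            wa.estimate_contrast_descriptor([m], [T])

    def test_run_bootstrap_used_when_available(self, rng):
        k, v, n = 4, 200, 4
        s_star = rng.standard_normal(k)
        tunings = [wa.TuningMatrix(f"s{i}", rng.standard_normal((k, v)), "b")
                   for i in range(n)]
        maps = []
        for t in tunings:
            true = s_star @ t.data
            runs = [true + 0.3 * rng.standard_normal(v) for _ in range(4)]
            maps.append(wa.SelectivityMap(t.subject_id, np.mean(runs, axis=0),
                                          "faces", run_maps=runs))
        cfg = wa.EnsembleRegressionConfig(k_folds=2, repetitions=3, seed=2)
        est = wa.estimate_contrast_descriptor(maps, tunings, cfg)
        assert np.corrcoef(est, s_star)[0, 1] > 0.98


class TestPredictSelectivityMap:
    def test_zero_descriptor_and_identity_tuning(self, rng):
        T = wa.TuningMatrix("s", np.eye(4), "b")
        m = wa.predict_selectivity_map(np.zeros(4), T)
        np.testing.assert_allclose(m.values, 0.0)
        desc = rng.standard_normal(4)
        np.testing.assert_allclose(wa.predict_selectivity_map(desc, T).values, desc)

    def test_matches_dense_multiply(self, rng):
        T = wa.TuningMatrix("s", rng.standard_normal((5, 9)), "b")
        desc = rng.standard_normal(5)
        np.testing.assert_allclose(wa.predict_selectivity_map(desc, T).values,
                                   desc @ T.data, atol=1e-12)


class TestRetinotopyCodec:
    @pytest.mark.parametrize("amp,phase,x,y", [(1, 0, 1, 0), (1, 90, 0, 1),
                                               (2, 180, -2, 0)])
    def test_reference_encodings(self, amp, phase, x, y):
        m = wa.RetinotopicMap(np.array([amp]), np.array([phase]))
        enc = wa.encode_retinotopy(m)
        np.testing.assert_allclose([enc.x[0], enc.y[0]], [x, y], atol=1e-12)
        dec = wa.decode_retinotopy(enc)
        assert dec.amplitude[0] == pytest.approx(amp)
        assert dec.phase[0] == pytest.approx(phase)

    def test_round_trip_bijection(self):
        rng = np.random.default_rng(5)
        amp = rng.uniform(0.01, 5.0, size=10000)
        phase = rng.uniform(0.0, 360.0, size=10000)
        m = wa.RetinotopicMap(amp, phase)
        dec = wa.decode_retinotopy(wa.encode_retinotopy(m))
        np.testing.assert_allclose(dec.amplitude, m.amplitude, atol=1e-10)
        dphi = np.abs(dec.phase - m.phase) % 360.0
        assert np.minimum(dphi, 360 - dphi).max() < 1e-10

    def test_zero_amplitude_decodes_to_zero_phase(self):
        dec = wa.decode_retinotopy(RetinoEncoding(np.zeros(3), np.zeros(3)))
        np.testing.assert_allclose(dec.phase, 0.0)


class TestFourierPhaseMap:
    def test_constructed_sinusoid(self):
        t = np.arange(80)
        sig = 2.0 * np.cos(2 * np.pi * 5 * t / 80 - np.deg2rad(30))
        run = wa.SubjectTimeseries("s", sig[:, None], tr_seconds=2.0)
        m = wa.fourier_phase_map(run, delay_seconds=0.0)
        assert m.amplitude[0] == pytest.approx(2.0, abs=1e-6)
        assert m.phase[0] == pytest.approx(30.0, abs=1e-6)

    def test_delay_correction_is_56_25_degrees(self):
        t = np.arange(80)
        sig = np.cos(2 * np.pi * 5 * t / 80)
        run = wa.SubjectTimeseries("s", sig[:, None], tr_seconds=2.0)
        m0 = wa.fourier_phase_map(run, delay_seconds=0.0)
        m5 = wa.fourier_phase_map(run, delay_seconds=5.0, cycle_seconds=32.0)
        dphi = (m0.phase[0] - m5.phase[0]) % 360
        assert dphi == pytest.approx(56.25, abs=1e-9)

    def test_noise_gives_uniform_phase_small_amplitude(self):
        rng = np.random.default_rng(8)
        run = wa.SubjectTimeseries("s", rng.standard_normal((80, 2000)),
                                   tr_seconds=2.0)
        m = wa.fourier_phase_map(run)
        assert np.mean(m.amplitude) < 0.5
        # uniform phases: circular resultant near zero
        z = np.exp(1j * np.deg2rad(m.phase))
        assert np.abs(z.mean()) < 0.05

    def test_too_short_run_rejected(self):
        run = wa.SubjectTimeseries("s", np.zeros((40, 1)), tr_seconds=2.0)
        with pytest.raises(InvalidInputError):
            wa.fourier_phase_map(run, n_timepoints=80)


class TestCombineRetinotopyRuns:
    def test_matching_phases_preserved(self):
        a = wa.RetinotopicMap(np.ones(3), np.array([10.0, 200.0, 350.0]))
        b = wa.RetinotopicMap(np.ones(3), -np.array([10.0, 200.0, 350.0]))
        out = wa.combine_retinotopy_runs(a, b)
        np.testing.assert_allclose(out.phase, [10.0, 200.0, 350.0], atol=1e-9)

    def test_delay_residual_cancels(self):
        theta, delta = 123.0, 17.0
        fwd = wa.RetinotopicMap(np.ones(1), np.array([theta + delta]))
        rev = wa.RetinotopicMap(np.ones(1), np.array([-(theta - delta)]))
        out = wa.combine_retinotopy_runs(fwd, rev)
        assert out.phase[0] == pytest.approx(theta, abs=1e-9)

    def test_amplitude_arithmetic_mean(self):
        a = wa.RetinotopicMap(np.array([1.0]), np.zeros(1))
        b = wa.RetinotopicMap(np.array([3.0]), np.zeros(1))
        assert wa.combine_retinotopy_runs(a, b).amplitude[0] == pytest.approx(2.0)

    def test_kind_mismatch_rejected(self):
        a = wa.RetinotopicMap(np.ones(1), np.zeros(1), kind="eccentricity")
        b = wa.RetinotopicMap(np.ones(1), np.zeros(1), kind="polar_angle")
        with pytest.raises(InvalidInputError):
            wa.combine_retinotopy_runs(a, b)


class TestPredictRetinotopicMap:
    def test_recovers_constructed_maps(self, rng):
        k, v = 6, 300
        T = wa.TuningMatrix("s", rng.standard_normal((k, v)), "b")
        sx, sy = rng.standard_normal(k), rng.standard_normal(k)
        m = wa.predict_retinotopic_map(sx, sy, T)
        enc = wa.encode_retinotopy(m)
        np.testing.assert_allclose(enc.x, sx @ T.data, atol=1e-9)
        np.testing.assert_allclose(enc.y, sy @ T.data, atol=1e-9)

    def test_zero_descriptors(self, rng):
        T = wa.TuningMatrix("s", rng.standard_normal((4, 10)), "b")
        m = wa.predict_retinotopic_map(np.zeros(4), np.zeros(4), T)
        np.testing.assert_allclose(m.amplitude, 0.0)
        np.testing.assert_allclose(m.phase, 0.0)


class TestMoviePatterns:
    def test_identity_tuning_returns_rows(self, rng):
        S = wa.StimulusMatrix(rng.standard_normal((20, 5)), basis_id="b")
        T = wa.TuningMatrix("s", np.eye(5), "b")
        np.testing.assert_allclose(wa.predict_movie_patterns(S, T), S.data)

    def test_basis_mismatch_rejected(self, rng):
        S = wa.StimulusMatrix(rng.standard_normal((20, 5)), basis_id="b1")
        T = wa.TuningMatrix("s", np.eye(5), "b2")
        with pytest.raises(InvalidInputError):
            wa.predict_movie_patterns(S, T)

    def test_noiseless_split_half_prediction(self, rng):
        # held-out rows of S times the tuning reproduce held-out data
        g = rng.standard_normal((60, 7))
        g -= g.mean(axis=0)
        q, _ = np.linalg.qr(g)
        Sdata = q / q.std(axis=0)
        T_true = rng.standard_normal((7, 25))
        B = Sdata @ T_true
        S = wa.StimulusMatrix(Sdata, basis_id="b")
        T = wa.estimate_tuning(S.restrict(np.arange(30)), B[:30])
        pred = wa.predict_movie_patterns(S.restrict(np.arange(30, 60)), T)
        corr = [np.corrcoef(pred[i], B[30 + i])[0, 1] for i in range(30)]
        assert min(corr) > 0.99


class TestReducePatternsPCA:
    def test_full_rank_projection_is_lossless(self, rng):
        X = rng.standard_normal((12, 8))
        red = wa.reduce_patterns_pca(X, [X], n_components=8)[0]
        # distances preserved up to per-component scaling: rank preserved
        assert np.linalg.matrix_rank(red) == 8

    def test_training_components_unit_variance(self, rng):
        X = rng.standard_normal((30, 10))
        red = wa.reduce_patterns_pca(X, [X], n_components=5)[0]
        np.testing.assert_allclose(red.var(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((5, 8))
        Y = rng.standard_normal((3, 8))
        red = wa.reduce_patterns_pca(X, [Y], n_components=3)[0]
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / 4)
        order = np.argsort(evals)[::-1][:3]
        proj = (Y - X.mean(axis=0)) @ evecs[:, order] / np.sqrt(evals[order])
        np.testing.assert_allclose(np.abs(red), np.abs(proj), atol=1e-8)

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            wa.reduce_patterns_pca(rng.standard_normal((5, 8)), [], 6)


class TestClassification:
    def test_perfect_prediction(self, rng):
        X = rng.standard_normal((10, 6))
        assert wa.classify_timepoints_binary(X, X) == 1.0
        assert wa.classify_timepoints_multiclass(X, X) == 1.0

    def test_shifted_orthogonal_rows_score_by_exhaustive_pairs(self, rng):
        # exactly orthogonal zero-mean Walsh rows, predictions shifted by one:
        # per target the matched prediction correlates 0, one foil is the
        # target itself (corr 1, a loss) and the other foil ties at exactly 0
        X = np.array([[1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]], dtype=float)
        shifted = np.roll(X, 1, axis=0)
        assert wa.classify_timepoints_binary(X, shifted) == pytest.approx(0.25)
        assert wa.classify_timepoints_multiclass(X, shifted) == 0.0

    def test_anticorrelated_predictions_fail_completely(self):
        X = np.array([[1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]], dtype=float)
        assert wa.classify_timepoints_binary(X, -X) == 0.0
        assert wa.classify_timepoints_multiclass(X, -X) == 0.0

    def test_independent_noise_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 30))
        Y = rng.standard_normal((200, 30))
        acc = wa.classify_timepoints_binary(X, Y)
        assert acc == pytest.approx(0.5, abs=0.05)
        mc = wa.classify_timepoints_multiclass(X, Y)
        assert mc <= 0.05

    def test_uniform_multiclass_chance_level(self):
        # C equiprobable classes: expected accuracy 1/C
        rng = np.random.default_rng(4)
        accs = [wa.classify_timepoints_multiclass(rng.standard_normal((20, 10)),
                                                  rng.standard_normal((20, 10)))
                for _ in range(60)]
        assert np.mean(accs) == pytest.approx(1 / 20, abs=0.02)

    def test_identical_predictions_tie_rules(self, rng):
        X = rng.standard_normal((6, 5))
        pred = np.tile(X[0], (6, 1))
        # binary: every comparison ties -> 0.5; multiclass: ties incorrect -> 0
        assert wa.classify_timepoints_binary(X, pred) == pytest.approx(0.5)
        assert wa.classify_timepoints_multiclass(X, pred) == 0.0

    def test_binary_at_least_multiclass(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((15, 8))
            Y = X + r.standard_normal((15, 8))
            assert (wa.classify_timepoints_binary(X, Y)
                    >= wa.classify_timepoints_multiclass(X, Y))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(InvalidInputError):
            wa.classify_timepoints_binary(np.ones((1, 4)), np.ones((1, 4)))


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_row_correlation_matches_corrcoef(seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((4, 7))
    B = rng.standard_normal((4, 7))
    C = _row_correlations(A, B)
    for i in range(4):
        for j in range(4):
            assert C[i, j] == pytest.approx(np.corrcoef(A[i], B[j])[0, 1], abs=1e-10)
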