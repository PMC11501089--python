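"""Reliability, distinctiveness, psychometric and circular metrics."""

import numpy as np
import pytest

import whalign as wa
from whalign.data import InvalidInputError
from whalign.metrics import SimilarityMatrix


def _tunings(n, k, v, rng, basis="b", shared=None, noise=1.0):
    out = []
    for i in range(n):
        data = noise * rng.standard_normal((k, v))
        if shared is not None:
            data += shared[i]
        out.append(wa.TuningMatrix(f"s{i}", data, basis))
    return out


class TestSimilarityMatrix:
    def test_identical_halves_have_unit_diagonal(self, rng):
        h = _tunings(4, 5, 20, rng)
        sim = wa.tuning_similarity_matrix(h, h)
        np.testing.assert_allclose(np.diag(sim.values), 1.0, atol=1e-12)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(1)
        h1 = _tunings(3, 100, 100, rng)
        h2 = _tunings(3, 100, 100, rng)
        sim = wa.tuning_similarity_matrix(h1, h2)
        assert np.abs(sim.values).max() < 0.05

    def test_subject_order_must_match(self, rng):
        h1 = _tunings(3, 4, 10, rng)
        h2 = list(reversed(_tunings(3, 4, 10, rng)))
        with pytest.raises(InvalidInputError):
            wa.tuning_similarity_matrix(h1, h2)


class TestDistinctiveness:
    def test_zero_when_within_equals_between_mean(self):
        z = np.array([[0.5, 0.4, 0.6], [0.4, 0.5, 0.6], [0.6, 0.4, 0.5]])
        sim = SimilarityMatrix(np.tanh(z), ["a", "b", "c"])
        assert wa.distinctiveness_index(sim, 0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # within z=1.0, between z in {0.4, 0.5, 0.6}: (1-0.5)/0.1 = 5 (sample SD)
        z = np.array([[1.0, 0.4, 0.5, 0.6],
                      [0.4, 1.0, 0.5, 0.6],
                      [0.4, 0.5, 1.0, 0.6],
                      [0.4, 0.5, 0.6, 1.0]])
        sim = SimilarityMatrix(np.tanh(z), list("abcd"))
        assert wa.distinctiveness_index(sim, 0) == pytest.approx(5.0, rel=1e-9)

    def test_monotone_in_within_similarity(self):
        base = np.tanh(np.array([[0.5, 0.2, 0.3], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]]))
        d0 = wa.distinctiveness_index(SimilarityMatrix(base, list("abc")), 0)
        higher = base.copy()
        higher[0, 0] = np.tanh(0.9)
        d1 = wa.distinctiveness_index(SimilarityMatrix(higher, list("abc")), 0)
        assert d1 > d0

    def test_too_few_subjects_rejected(self):
        sim = SimilarityMatrix(np.eye(2) * 0.5, ["a", "b"])
        with pytest.raises(InvalidInputError):
            wa.distinctiveness_index(sim, 0)

    def test_degenerate_zero_sd(self):
        vals = np.tanh(np.array([[0.8, 0.3, 0.3], [0.3, 0.8, 0.3], [0.3, 0.3, 0.8]]))
        sim = SimilarityMatrix(vals, list("abc"))
        with pytest.warns(RuntimeWarning):
            assert wa.distinctiveness_index(sim, 0) == np.inf


class TestIdentificationErrorRate:
    def test_published_tail_probabilities(self):
        # printed to 3 significant figures of d; tail known to ~5 % there
        assert wa.identification_error_rate(12.92) == pytest.approx(1.73e-38,
                                                                    rel=5e-3)
        assert wa.identification_error_rate(9.67) == pytest.approx(2.1e-22,
                                                                   rel=0.05)

    def test_symmetry_and_monotonicity(self):
        assert wa.identification_error_rate(0.0) == pytest.approx(0.5)
        for d in [0.5, 1.0, 3.0, 6.0]:
            assert (wa.identification_error_rate(d)
                    + wa.identification_error_rate(-d)) == pytest.approx(1.0,
                                                                         abs=1e-12)
        rates = [wa.identification_error_rate(d) for d in np.linspace(-2, 8, 30)]
        assert all(a > b for a, b in zip(rates, rates[1:]))


class TestNearestNeighborIdentification:
    def test_perfect_when_diagonal_dominates(self, rng):
        vals = 0.2 + 0.05 * rng.standard_normal((5, 5))
        np.fill_diagonal(vals, 0.9)
        assert wa.nearest_neighbor_identification(
            SimilarityMatrix(vals, list("abcde"))) == 1.0

    def test_counts_row_failures(self):
        vals = np.array([[0.9, 0.1, 0.1], [0.8, 0.2, 0.1], [0.1, 0.1, 0.9]])
        assert wa.nearest_neighbor_identification(
            SimilarityMatrix(vals, list("abc"))) == pytest.approx(2 / 3)


class TestCronbachAlpha:
    def test_identical_maps_give_one(self, rng):
        m = rng.standard_normal(100)
        assert wa.cronbach_alpha([m] * 4) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        maps = [rng.standard_normal(100000) for _ in range(4)]
        assert wa.cronbach_alpha(maps) == pytest.approx(0.0, abs=0.02)

    def test_matches_spearman_brown_model(self):
        # truth and noise of equal variance: rho=0.5, k=4 -> alpha ~ 0.8
        rng = np.random.default_rng(3)
        truth = rng.standard_normal(100000)
        maps = [truth + rng.standard_normal(100000) for _ in range(4)]
        assert wa.cronbach_alpha(maps) == pytest.approx(0.8, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            wa.cronbach_alpha([np.zeros(10), np.zeros(10)])


class TestSpearmanBrown:
    @pytest.mark.parametrize("rho,k,expected", [(0.5, 4, 0.8), (0.3, 1, 0.3),
                                                (1.0, 7, 1.0), (0.0, 5, 0.0)])
    def test_formula(self, rho, k, expected):
        assert wa.spearman_brown(rho, k) == pytest.approx(expected)

    def test_reliability_estimate_round_trips(self):
        rng = np.random.default_rng(7)
        truth = rng.standard_normal(5000)
        runs = [truth + 0.8 * rng.standard_normal(5000) for _ in range(3)]
        est = wa.reliability_from_runs(runs)
        assert est.k_runs == 3
        assert wa.spearman_brown(est.single_run_rho, 3) == pytest.approx(
            est.alpha, abs=1e-10)

    def test_alpha_consistency_invariant(self):
        # stored alpha must satisfy alpha = k rho / (1 + (k-1) rho)
        rho, k = 0.37, 6
        alpha = wa.spearman_brown(rho, k)
        back = alpha / (k - (k - 1) * alpha)
        assert back == pytest.approx(rho, abs=1e-10)


class TestExpectedMapCorrelation:
    def test_values(self):
        assert wa.expected_map_correlation(0.6, 0.6) == pytest.approx(0.6)
        assert wa.expected_map_correlation(0.64, 0.25) == pytest.approx(0.4)

    def test_empirical_simulation(self):
        rng = np.random.default_rng(4)
        v = 200000
        truth = rng.standard_normal(v)
        # map i has reliability rho_i = 1/(1+s_i^2) for noise SD s_i
        rho_i, rho_j = 0.8, 0.4
        si = np.sqrt(1 / rho_i - 1)
        sj = np.sqrt(1 / rho_j - 1)
        mi = truth + si * rng.standard_normal(v)
        mj = truth + sj * rng.standard_normal(v)
        r = np.corrcoef(mi, mj)[0, 1]
        assert r == pytest.approx(wa.expected_map_correlation(rho_i, rho_j),
                                  abs=0.01)


class TestEquivalentLocalizerMinutes:
    def test_fixed_point_when_prediction_matches_average_map(self):
        # a predicted map exactly as reliable as the k0-run average correlates
        # with it at r = sqrt(alpha * alpha) = alpha, and inverts to k0 runs
        alpha, k0, mins = 0.7, 4, 5.0
        out = wa.equivalent_localizer_minutes(alpha, k0, mins, alpha)
        assert out == pytest.approx(k0 * mins, rel=1e-9)

    def test_algebraic_example(self):
        # alpha=0.5, k0=2 -> rho1=1/3; r^2/alpha=0.5 -> k*=2
        out = wa.equivalent_localizer_minutes(0.5, 2, 3.0, np.sqrt(0.25))
        assert out == pytest.approx(6.0, rel=1e-9)

    def test_vanishing_r_needs_no_data(self):
        out = wa.equivalent_localizer_minutes(0.6, 4, 5.0, 1e-6)
        assert out < 1e-9

    def test_superior_prediction_is_infinite(self):
        assert wa.equivalent_localizer_minutes(0.5, 4, 5.0, 0.9) == np.inf


class TestCircularPhaseDifference:
    def test_identical_maps_zero(self, rng):
        m = wa.RetinotopicMap(np.ones(10), rng.uniform(0, 360, 10))
        assert wa.circular_phase_difference(m, m) == pytest.approx(0.0)

    def test_wrap_around(self):
        a = wa.RetinotopicMap(np.ones(1), np.array([359.0]))
        b = wa.RetinotopicMap(np.ones(1), np.array([1.0]))
        assert wa.circular_phase_difference(a, b) == pytest.approx(2.0)

    def test_symmetric_and_bounded(self, rng):
        a = wa.RetinotopicMap(np.ones(50), rng.uniform(0, 360, 50))
        b = wa.RetinotopicMap(np.ones(50), rng.uniform(0, 360, 50))
        dab = wa.circular_phase_difference(a, b)
        dba = wa.circular_phase_difference(b, a)
        assert dab == pytest.approx(dba)
        assert 0 <= dab <= 180

    def test_independent_uniform_phases_average_90(self):
        rng = np.random.default_rng(5)
        n = 100000
        a = wa.RetinotopicMap(np.ones(n), rng.uniform(0, 360, n))
        b = wa.RetinotopicMap(np.ones(n), rng.uniform(0, 360, n))
        assert wa.circular_phase_difference(a, b) == pytest.approx(90.0, abs=1.0)

    def test_mask_restriction_and_empty_mask(self, rng):
        a = wa.RetinotopicMap(np.ones(10), np.zeros(10))
        b = wa.RetinotopicMap(np.ones(10), np.r_[np.full(5, 90.0), np.zeros(5)])
        mask = wa.RegionMask("front", np.arange(5))
        assert wa.circular_phase_difference(a, b, mask) == pytest.approx(90.0)
        with pytest.raises(InvalidInputError):
            wa.circular_phase_difference(a, b, wa.RegionMask("empty", []))


class TestSearchlightDistinctiveness:
    def test_elevated_where_individual_signal_lives(self, grid6):
        # individual signal only in the left half of the grid
        rng = np.random.default_rng(6)
        n, k, v = 5, 30, 36
        region_a = np.nonzero(grid6.coordinates[:, 0] < 7.5)[0]
        shared = rng.standard_normal((k, v))
        h1, h2 = [], []
        for i in range(n):
            indiv = np.zeros((k, v))
            indiv[:, region_a] = rng.standard_normal((k, region_a.size))
            for half, noise_seed in ((h1, 0), (h2, 1)):
                noisy = shared + indiv + 0.3 * rng.standard_normal((k, v))
                half.append(wa.TuningMatrix(f"s{i}", noisy, "b"))
        dmap = wa.searchlight_distinctiveness_map(h1, h2, grid6, radius_mm=6.0)
        inside = dmap[region_a].mean()
        outside = np.delete(dmap, region_a).mean()
        assert inside > outside + 2.0

    def test_single_searchlight_reduces_to_global(self, rng):
        geom = wa.SurfaceGeometry(np.zeros((8, 3)))
        h1 = _tunings(4, 6, 8, rng, shared=None)
        h2 = [wa.TuningMatrix(t.subject_id, t.data + 0.1 * rng.standard_normal(t.data.shape), "b")
              for t in h1]
        dmap = wa.searchlight_distinctiveness_map(h1, h2, geom, radius_mm=5.0)
        sim = wa.tuning_similarity_matrix(h1, h2)
        expected = np.mean([wa.distinctiveness_index(sim, i) for i in range(4)])
        np.testing.assert_allclose(dmap, expected, atol=1e-9)
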