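"""Splits, pseudo-trials, network training, confusion and bias statistics."""

import numpy as np
import pytest

import lipdecode as L
from lipdecode import decoder as dec
from lipdecode.tuning import GRID_T, GRID_X, GRID_Y


def _gaussian_maps(n_neurons, seed=0, sigma=1.5, peak=50.0, base=5.0):
    """Analytic window-averaged rate maps for Gaussian-tuned neurons."""
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(GRID_X, GRID_Y, indexing="ij")
    maps = np.empty((n_neurons, 81, 81))
    for j in range(n_neurons):
        cx, cy = rng.uniform(-3.5, 3.5, 2)
        maps[j] = base + (peak - base) * np.exp(
            -((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
    return maps


class TestSplitTrials:
    labels = [p for p in range(17) for _ in range(10)]

    def test_seventy_thirty_partition_per_position(self):
        splits = dec.split_trials(self.labels, n_repeats=3, seed=0)
        labels = np.asarray(self.labels)
        for train, val in splits:
            for p in range(17):
                assert (labels[train] == p).sum() == 7
                assert (labels[val] == p).sum() == 3

    def test_disjoint_and_exhaustive(self):
        for train, val in dec.split_trials(self.labels, n_repeats=5, seed=1):
            assert len(np.intersect1d(train, val)) == 0
            assert len(np.union1d(train, val)) == len(self.labels)

    def test_reproducible_from_seed(self):
        a = dec.split_trials(self.labels, n_repeats=4, seed=9)
        b = dec.split_trials(self.labels, n_repeats=4, seed=9)
        for (t1, v1), (t2, v2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(v1, v2)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            dec.split_trials([0, 0, 1], n_repeats=1)


class TestExpectedCount:
    def test_constant_field_count_is_rate_times_duration(self):
        anchors = L.stationary_target_layout()
        resp = np.full((17, len(GRID_T)), 10.0)
        field = L.build_tuning_field(anchors, resp)
        assert L.expected_count(field, (0.3, -0.7), (-100, 100)) == pytest.approx(2.0)

    def test_zero_field_gives_zero(self):
        anchors = L.stationary_target_layout()
        field = L.build_tuning_field(anchors, np.zeros((17, len(GRID_T))))
        assert L.expected_count(field, (1.0, 1.0)) == 0.0

    def test_position_outside_grid_rejected(self):
        anchors = L.stationary_target_layout()
        field = L.build_tuning_field(anchors, np.ones((17, len(GRID_T))))
        with pytest.raises(ValueError):
            L.expected_count(field, (5.0, 0.0))

    def test_generator_neuron_matches_numeric_integral(self):
        # field built from the analytic rate model; the expected count at the
        # tuning center must match the numerically integrated rate
        from scipy.integrate import quad
        spec = L.NeuronSpec("n", (8.0, 0.0), (0.0, 0.0), 1.5, 40.0, 4.0, 0.0, 60.0)
        anchors = L.stationary_target_layout()
        resp = np.stack([
            np.asarray(L.neuron_rate(spec, a, GRID_T)) for a in anchors
        ])
        field = L.build_tuning_field(anchors, resp)
        got = L.expected_count(field, spec.spatial_center, (-100, 100))
        integral, _ = quad(lambda t: L.neuron_rate(spec, spec.spatial_center, t),
                           -100, 100)
        # the count is the inclusive-sample mean times the window duration, a
        # slightly different quadrature than the continuous integral
        assert got == pytest.approx(integral / 1000.0, rel=0.05)


class TestGeneratePseudoTrials:
    def test_poisson_mean_equals_variance(self):
        maps = np.full((3, 81, 81), 25.0)
        pseudo = dec.generate_pseudo_trials(maps, n=20_000, window=(-100, 100),
                                            seed=3, grid_x=GRID_X, grid_y=GRID_Y)
        lam = 25.0 * 0.2
        se = np.sqrt(lam / 20_000)
        for j in range(3):
            assert pseudo.counts[:, j].mean() == pytest.approx(lam, abs=3 * se)
            assert pseudo.counts[:, j].var() == pytest.approx(lam, rel=0.05)

    def test_empty_request_gives_empty_set(self):
        maps = np.full((2, 81, 81), 5.0)
        pseudo = dec.generate_pseudo_trials(maps, n=0, grid_x=GRID_X, grid_y=GRID_Y)
        assert pseudo.counts.shape == (0, 2)
        assert pseudo.positions.shape == (0, 2)

    def test_fixed_seed_reproduces_counts(self):
        maps = _gaussian_maps(4)
        a = dec.generate_pseudo_trials(maps, n=500, seed=11, grid_x=GRID_X, grid_y=GRID_Y)
        b = dec.generate_pseudo_trials(maps, n=500, seed=11, grid_x=GRID_X, grid_y=GRID_Y)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_positions_inside_square(self):
        maps = _gaussian_maps(2)
        pseudo = dec.generate_pseudo_trials(maps, n=1000, seed=0,
                                            grid_x=GRID_X, grid_y=GRID_Y)
        assert np.abs(pseudo.positions).max() <= 4.0


@pytest.fixture(scope="module")
def trained_small_decoder():
    maps = _gaussian_maps(12, seed=4)
    pseudo = dec.generate_pseudo_trials(maps, n=6000, seed=5,
                                        grid_x=GRID_X, grid_y=GRID_Y)
    model = dec.train_decoder(pseudo, seed=5, max_iter=300)
    return maps, model


class TestTrainAndPredict:
    def test_positions_recovered_from_population_activity(self, trained_small_decoder):
        maps, model = trained_small_decoder
        pts = np.array([[1.0, 1.0], [-2.0, 0.5], [0.0, -1.5], [2.5, -2.0]])
        lam = dec.expected_count_matrix(maps, pts, (-100, 100), GRID_X, GRID_Y)
        rng = np.random.default_rng(0)
        for i, p in enumerate(pts):
            counts = rng.poisson(lam[i], size=(300, maps.shape[0]))
            pred = dec.predict_endpoints(model, counts).mean(axis=0)
            assert np.linalg.norm(pred - p) < 0.4

    def test_uninformative_neurons_predict_grid_mean(self):
        maps = np.full((6, 81, 81), 20.0)  # no spatial information
        pseudo = dec.generate_pseudo_trials(maps, n=4000, seed=2,
                                            grid_x=GRID_X, grid_y=GRID_Y)
        model = dec.train_decoder(pseudo, seed=2, max_iter=200)
        preds = dec.predict_endpoints(
            model, np.random.default_rng(0).poisson(4.0, (500, 6)))
        assert np.linalg.norm(preds.mean(axis=0)) < 0.3

    def test_duplicated_neurons_do_not_change_accuracy_much(self):
        # a duplicated column carries the same counts as its original and is
        # fully redundant: validation error stays within 10% (plus a small
        # absolute allowance for retraining noise)
        maps = _gaussian_maps(10, seed=6)
        pts = np.array([[1.5, 0.0], [0.0, 1.5], [-1.5, 0.0], [0.0, -1.5]])
        pseudo = dec.generate_pseudo_trials(maps, n=5000, seed=7,
                                            grid_x=GRID_X, grid_y=GRID_Y)
        dup = dec.PseudoTrialSet(
            counts=np.concatenate([pseudo.counts, pseudo.counts], axis=1),
            positions=pseudo.positions, window=pseudo.window, seed=pseudo.seed)
        lam = dec.expected_count_matrix(maps, pts, (-100, 100), GRID_X, GRID_Y)
        rng = np.random.default_rng(8)
        eval_counts = [rng.poisson(lam[i], size=(200, maps.shape[0]))
                       for i in range(len(pts))]

        def eval_error(model, tile):
            errs = []
            for i, p in enumerate(pts):
                counts = np.concatenate([eval_counts[i]] * tile, axis=1)
                errs.append(np.linalg.norm(
                    dec.predict_endpoints(model, counts).mean(axis=0) - p))
            return float(np.mean(errs))

        e1 = eval_error(dec.train_decoder(pseudo, seed=7, max_iter=300), 1)
        e2 = eval_error(dec.train_decoder(dup, seed=7, max_iter=300), 2)
        assert abs(e2 - e1) < max(0.1 * e1, 0.08)

    def test_zero_vector_input_is_finite(self, trained_small_decoder):
        _, model = trained_small_decoder
        pred = dec.predict_endpoints(model, np.zeros(model.n_neurons))
        assert np.isfinite(pred).all()

    def test_prediction_is_deterministic(self, trained_small_decoder):
        _, model = trained_small_decoder
        x = np.arange(model.n_neurons, dtype=float)
        np.testing.assert_array_equal(dec.predict_endpoints(model, x),
                                      dec.predict_endpoints(model, x))

    def test_wrong_length_rejected(self, trained_small_decoder):
        _, model = trained_small_decoder
        with pytest.raises(ValueError):
            dec.predict_endpoints(model, np.zeros(model.n_neurons + 1))

    def test_non_finite_training_inputs_rejected(self):
        pseudo = dec.PseudoTrialSet(counts=np.array([[1.0, np.nan]]),
                                    positions=np.zeros((1, 2)), window=(-100, 100))
        with pytest.raises(ValueError):
            dec.train_decoder(pseudo)


def _ring(radius=1.7, k=8):
    ang = np.radians(np.arange(0, 360, 360 // k, dtype=float))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


class TestConfusion:
    def test_exact_predictions_are_fully_correct(self):
        tested = _ring()
        dirs = np.arange(0, 360, 45, dtype=float)
        ev = dec.evaluate_predictions(
            [np.tile(p, (10, 1)) for p in tested], tested, dirs)
        assert ev.pct_correct == pytest.approx(100.0)
        np.testing.assert_allclose(np.diag(ev.confusion), 1.0)

    def test_rows_sum_to_one(self, rng):
        tested = _ring()
        dirs = np.arange(0, 360, 45, dtype=float)
        preds = [rng.uniform(-3, 3, (50, 2)) for _ in tested]
        ev = dec.evaluate_predictions(preds, tested, dirs)
        np.testing.assert_allclose(ev.confusion.sum(axis=1), 1.0)

    def test_uniform_assignment_hits_chance_levels(self, rng):
        tested = _ring()
        dirs = np.arange(0, 360, 45, dtype=float)
        n = 20_000
        preds = [tested[rng.integers(0, 8, n // 8)] for _ in range(8)]
        ev = dec.evaluate_predictions(preds, tested, dirs)
        se_pct = 100 * np.sqrt(0.125 * 0.875 / n)
        assert ev.pct_correct == pytest.approx(12.5, abs=3 * se_pct)
        se_pct3 = 100 * np.sqrt(0.375 * 0.625 / n)
        assert ev.pct_correct_or_neighbor == pytest.approx(37.5, abs=3 * se_pct3)

    def test_nearest_assignment_tie_breaks_to_lowest_index(self):
        tested = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assign = dec.assign_nearest(np.array([[0.0, 0.0]]), tested)
        assert assign[0] == 0


class TestCenterBias:
    def test_zero_when_prediction_matches(self):
        assert dec.center_bias((1.5, 0.0), (1.5, 0.0), 0.0) == 0.0

    def test_compression_toward_center_is_positive(self):
        # tested at intercept 1.5 deg, prediction at 0.75 deg along alpha
        assert dec.center_bias((1.5, 0.0), (0.75, 0.0), 0.0) == pytest.approx(0.75)

    def test_overshoot_is_negative(self):
        assert dec.center_bias((1.5, 0.0), (1.7, 0.0), 0.0) == pytest.approx(-0.2)


class TestSlidingWindows:
    def test_window_enumeration(self):
        windows = dec.sliding_windows()
        assert len(windows) == 14
        assert windows[0] == (-400.0, -300.0)
        assert windows[-1] == (250.0, 350.0)
        centers = [(lo + hi) / 2 for lo, hi in windows]
        assert centers[0] == -350.0 and centers[-1] == 300.0


class TestBiasToTimeLag:
    @pytest.mark.parametrize("bias, speed, expected", [
        (0.3, 10.0, 30.0),
        (0.8, 10.0, 80.0),
        (0.0, 25.0, 0.0),
    ])
    def test_conversion(self, bias, speed, expected):
        assert dec.bias_to_time_lag(bias, speed) == pytest.approx(expected)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            dec.bias_to_time_lag(0.3, 0.0)
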