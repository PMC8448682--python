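"""Response functions, field interpolation, window averages, similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipdecode as L
from lipdecode.tuning import GRID_T, GRID_X, GRID_Y, disk_mask, window_maps


class TestResponseFunction:
    def test_no_spikes_gives_zero_rate(self):
        out = L.response_function([np.empty(0), np.empty(0)])
        np.testing.assert_array_equal(out, 0.0)

    def test_single_spike_peak_value(self):
        # unit-area Gaussian (sigma=20 ms) scaled to spikes/s peaks at
        # 1000 / (20 * sqrt(2*pi)) at the spike time
        out = L.response_function([np.array([0.0])])
        i0 = np.argmin(np.abs(GRID_T))
        assert out[i0] == pytest.approx(1000.0 / (20.0 * np.sqrt(2 * np.pi)), rel=1e-6)

    def test_homogeneous_poisson_rate_recovered(self, rng):
        rate = 30.0  # spikes/s over [-500, 450] ms
        trials = []
        for _ in range(2000):
            n = rng.poisson(rate * 0.95)
            trials.append(rng.uniform(-500, 450, n))
        out = L.response_function(trials)
        interior = (GRID_T > -380) & (GRID_T < 330)
        assert np.abs(out[interior] - rate).max() < 2.0
        assert abs(out[interior].mean() - rate) < 1.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            L.response_function([])


def _const_field(value, anchors=None):
    if anchors is None:
        anchors = L.stationary_target_layout()
    resp = np.full((anchors.shape[0], len(GRID_T)), float(value))
    return L.build_tuning_field(anchors, resp)


class TestBuildTuningField:
    def test_constant_anchor_values_give_constant_field(self):
        field = _const_field(7.5)
        assert field.activity.shape == (81, 81, 76)
        np.testing.assert_allclose(field.activity, 7.5)

    def test_interpolation_exact_at_anchor_nodes(self):
        anchors = L.stationary_target_layout()
        vals = np.arange(anchors.shape[0], dtype=float)
        resp = np.repeat(vals[:, None], len(GRID_T), axis=1)
        field = L.build_tuning_field(anchors, resp)
        # (2, 0) and (0, 0) are grid nodes as well as anchors
        for k, (ax, ay) in enumerate(anchors):
            ix = np.argmin(np.abs(GRID_X - ax))
            iy = np.argmin(np.abs(GRID_Y - ay))
            if abs(GRID_X[ix] - ax) < 1e-9 and abs(GRID_Y[iy] - ay) < 1e-9:
                assert field.activity[ix, iy, 0] == pytest.approx(vals[k], abs=1e-9)

    def test_outside_hull_uses_nearest_anchor(self):
        anchors = L.stationary_target_layout()
        vals = np.linspace(1.0, 5.0, anchors.shape[0])
        resp = np.repeat(vals[:, None], len(GRID_T), axis=1)
        field = L.build_tuning_field(anchors, resp)
        # brute-force nearest-anchor oracle at the grid corners
        for ix, iy in [(0, 0), (0, 80), (80, 0), (80, 80)]:
            p = np.array([GRID_X[ix], GRID_Y[iy]])
            nearest = np.argmin(np.linalg.norm(anchors - p, axis=1))
            assert field.activity[ix, iy, 0] == pytest.approx(vals[nearest])

    def test_collinear_anchors_rejected(self):
        anchors = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        resp = np.zeros((4, len(GRID_T)))
        with pytest.raises(ValueError):
            L.build_tuning_field(anchors, resp)

    def test_activity_nonnegative(self, small_model):
        field = small_model.tuning_field(0, "regular")
        assert field.activity.min() >= 0.0


class TestWindowAverage:
    def test_constant_in_time_returns_same_map(self):
        field = _const_field(3.0)
        np.testing.assert_allclose(L.window_average(field, -100, 100), 3.0)

    def test_single_slice_window(self):
        field = _const_field(1.0)
        field.activity[:, :, 10] = 9.0
        t = field.grid_t[10]
        np.testing.assert_allclose(L.window_average(field, t, t), 9.0)

    def test_linear_in_time_gives_midpoint(self):
        field = _const_field(0.0)
        field.activity[:] = field.grid_t[None, None, :]  # value = t
        out = L.window_average(field, -100, 100)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_empty_window_rejected(self):
        field = _const_field(1.0)
        with pytest.raises(ValueError):
            L.window_average(field, 401, 402)

    def test_window_maps_stacks_windows(self):
        field = _const_field(2.0)
        maps = window_maps(field, [(-100, 100), (0, 100)])
        assert maps.shape == (81, 81, 2)


class TestSimilarityIndex:
    def test_identical_maps_give_unity(self, rng):
        m = rng.normal(10, 3, (20, 20))
        res = L.similarity_index(m, m.copy())
        assert res.si == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_sign_flipped_z_map_gives_zero(self, rng):
        m = rng.normal(10, 3, (20, 20))
        flipped = 2 * m.mean() - m  # z(flipped) = -z(m)
        res = L.similarity_index(m, flipped)
        assert res.si == pytest.approx(0.0, abs=1e-12)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_hand_computed_two_by_two(self):
        # R=[[1,2],[3,4]], I=[[1,2],[4,3]]: z-maps differ only in the last
        # two entries (+-0.894427); SI = 1 - 1.264911/4, r = 0.8
        res = L.similarity_index(np.array([[1.0, 2.0], [3.0, 4.0]]),
                                 np.array([[1.0, 2.0], [4.0, 3.0]]))
        assert res.si == pytest.approx(1.0 - 1.2649110640673518 / 4.0, abs=1e-9)
        assert res.pearson_r == pytest.approx(0.8, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(a=st.floats(0.1, 10), b=st.floats(-20, 20), seed=st.integers(0, 100))
    def test_invariant_under_positive_affine_rescaling(self, a, b, seed):
        r = np.random.default_rng(seed)
        m1 = r.normal(5, 2, (8, 8))
        m2 = r.normal(5, 2, (8, 8))
        base = L.similarity_index(m1, m2)
        scaled = L.similarity_index(a * m1 + b, m2)
        assert scaled.si == pytest.approx(base.si, abs=1e-9)
        assert scaled.pearson_r == pytest.approx(base.pearson_r, abs=1e-9)

    def test_symmetric_in_arguments(self, rng):
        m1 = rng.normal(0, 1, (10, 10))
        m2 = rng.normal(0, 1, (10, 10))
        assert (L.similarity_index(m1, m2).si
                == pytest.approx(L.similarity_index(m2, m1).si))

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            L.similarity_index(np.ones((4, 4)), np.arange(16.0).reshape(4, 4))

    def test_si_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            res = L.similarity_index(rng.normal(0, 1, (6, 6)), rng.normal(0, 1, (6, 6)))
            assert 0.0 <= res.si <= 1.0


class TestSelectSubpopulation:
    def _sim(self, r, si):
        return L.SimilarityResult(pearson_r=r, si=si)

    def test_threshold_logic_is_strict(self):
        sims = {
            "a": self._sim(0.6, 0.4),   # in
            "b": self._sim(0.6, 0.2),   # SI too low
            "c": self._sim(0.4, 0.6),   # r too low
            "d": self._sim(0.5, 0.3),   # exactly at the boundary -> excluded
        }
        assert L.select_subpopulation(sims) == ["a"]

    def test_cohort_with_matched_tuning_all_selected(self):
        # tau = 0 with large trial counts: regular and interceptive fields
        # share their spatial tuning, so every neuron passes the selection
        cohort = L.make_cohort(10, seed=5, tau=0.0)
        cfg = L.SessionConfig(n_neurons=10, n_regular_per_position=20,
                              n_interceptive_per_direction=30, seed=5)
        model = L.SaccadeDecodingModel(L.simulate_session(cohort, cfg))
        assert len(model.select_subpopulation()) == 10

    def test_snapshot_cohort_decorrelates_fields(self):
        # a large snapshot offset dissociates the two tuning maps: (almost)
        # no neuron passes the similarity selection
        cohort = L.make_cohort(10, seed=5, tau=-300.0)
        cfg = L.SessionConfig(n_neurons=10, n_regular_per_position=20,
                              n_interceptive_per_direction=30, seed=5)
        model = L.SaccadeDecodingModel(L.simulate_session(cohort, cfg))
        assert len(model.select_subpopulation()) <= 2


class TestDiskMask:
    def test_mask_radius(self):
        mask = disk_mask(1.5)
        gx, gy = np.meshgrid(GRID_X, GRID_Y, indexing="ij")
        assert mask[np.hypot(gx, gy) > 1.5].sum() == 0
        assert mask[40, 40]  # center included
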