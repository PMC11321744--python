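import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pursuit3d import detectors as det
from pursuit3d import simulator as sim
from pursuit3d.geometry import unwrap_phi


def _fill_window(rng, n_objects=3, capacity=40, gaze_like=None):
    """Random full window; optionally make object 'obj0' identical to gaze."""
    w = det.SampleWindow(capacity, [f"obj{i}" for i in range(n_objects)])
    gaze = rng.normal(size=(capacity, 3)).cumsum(axis=0)
    objs = {f"obj{i}": rng.normal(size=(capacity, 3)).cumsum(axis=0) for i in range(n_objects)}
    if gaze_like is not None:
        objs[gaze_like] = gaze.copy()
    for k in range(capacity):
        w.push(gaze[k], {i: objs[i][k] for i in objs}, t=k / 60.0)
    return w, gaze, objs


class TestSampleWindow:
    def test_push_and_joint_eviction(self):
        w = det.SampleWindow(40, ["a"])
        for k in range(41):
            w.push((k, 0, 0), {"a": (k, 1, 1)}, t=k / 60.0)
        assert len(w) == 40
        assert w.timestamps()[0] == pytest.approx(1 / 60)      # oldest gone
        assert w.gaze_array()[0, 0] == 1                        # evicted jointly
        assert w.object_array("a")[0, 0] == 1

    def test_push_into_empty(self):
        w = det.SampleWindow(40, ["a"])
        w.push((0, 0, 0), {"a": (0, 0, 0)}, t=0.0)
        assert len(w) == 1 and not w.full

    def test_non_monotone_timestamp_rejected(self):
        w = det.SampleWindow(40, ["a"])
        w.push((0, 0, 0), {"a": (0, 0, 0)}, t=0.5)
        with pytest.raises(ValueError, match="monotone"):
            w.push((0, 0, 0), {"a": (0, 0, 0)}, t=0.5)

    def test_object_set_mismatch_rejected(self):
        w = det.SampleWindow(40, ["a", "b"])
        with pytest.raises(ValueError, match="object-id"):
            w.push((0, 0, 0), {"a": (0, 0, 0)}, t=0.0)


class TestCorrelationScore:
    def test_identical_series_scores_one(self):
        w, _, _ = _fill_window(np.random.default_rng(0), gaze_like="obj0")
        assert det.correlation_score(w, "obj0") == pytest.approx(1.0)

    def test_time_reversed_series_scores_minus_one(self):
        rng = np.random.default_rng(1)
        w = det.SampleWindow(40, ["a"])
        gaze = rng.normal(size=(40, 3)).cumsum(axis=0)
        rev = gaze[::-1]
        for k in range(40):
            w.push(gaze[k], {"a": rev[k]}, t=k / 60)
        # reversing time anti-correlates each dimension's trend but not exactly;
        # use an exactly negated series for the clean -1 case
        w2 = det.SampleWindow(40, ["a"])
        for k in range(40):
            w2.push(gaze[k], {"a": -gaze[k]}, t=k / 60)
        assert det.correlation_score(w2, "a") == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(2)
        w, gaze, objs = _fill_window(rng)
        for key, series in objs.items():
            expected = np.mean([stats.pearsonr(gaze[:, d], series[:, d]).statistic
                                for d in range(3)])
            assert det.correlation_score(w, key) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_dimension_contributes_zero(self):
        w = det.SampleWindow(40, ["a"])
        rng = np.random.default_rng(3)
        gaze = rng.normal(size=(40, 3)).cumsum(axis=0)
        obj = gaze.copy()
        obj[:, 0] = 5.0          # constant radius: Pearson undefined -> 0
        for k in range(40):
            w.push(gaze[k], {"a": obj[k]}, t=k / 60)
        assert det.correlation_score(w, "a") == pytest.approx(2.0 / 3.0)

    def test_warm_up_gives_no_score(self):
        w = det.SampleWindow(40, ["a"])
        for k in range(39):
            w.push((k, k, k), {"a": (k, k, k)}, t=k / 60)
        assert det.correlation_score(w, "a") is None
        assert det.correlation_detect(w, 0.0) is None


class TestCorrelationDetect:
    def test_highest_above_threshold_selected(self):
        w, _, _ = _fill_window(np.random.default_rng(4), gaze_like="obj1")
        d = det.correlation_detect(w, 0.75)
        assert d.selected_object == "obj1"
        assert d.score_per_object["obj1"] > 0.75

    def test_none_when_all_below_threshold(self):
        w, _, _ = _fill_window(np.random.default_rng(5))
        d = det.correlation_detect(w, 0.999)
        assert d.selected_object is None

    def test_duplicate_trajectories_tie_break(self):
        rng = np.random.default_rng(6)
        w = det.SampleWindow(40, ["b", "a"])
        gaze = rng.normal(size=(40, 3)).cumsum(axis=0)
        for k in range(40):
            w.push(gaze[k], {"a": gaze[k], "b": gaze[k]}, t=k / 60)
        d = det.correlation_detect(w, 0.5)
        assert d.selected_object == "a"      # lowest id wins
        assert d.tied


class TestMovementVector:
    def test_constant_series(self):
        assert np.allclose(det.movement_vector(np.full((40, 3), 2.0)), 0.0)

    def test_linear_ramp(self):
        series = np.arange(1, 41, dtype=float)[:, None] * np.ones(3)
        assert np.allclose(det.movement_vector(series), 20.0)   # 30.5 - 10.5

    def test_odd_length_older_half_gets_extra(self):
        series = np.arange(1, 6, dtype=float)[:, None]          # halves: 1,2,3 | 4,5
        assert det.movement_vector(series)[0] == pytest.approx(4.5 - 2.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            det.movement_vector(np.ones((1, 3)))

    def test_unwrapped_seam_crossing_gives_small_delta(self):
        phi = np.linspace(170, 190, 40)          # crosses +-180 after wrapping
        wrapped = (phi + 180) % 360 - 180
        un = unwrap_phi(wrapped)
        delta = det.movement_vector(un[:, None])[0]
        assert abs(delta) < 15                    # ~10 deg, not ~350


class TestDifferenceCoefficient:
    def test_printed_anchor_values(self):
        assert det.difference_coefficient(10, 10) == 0.0
        assert det.difference_coefficient(0, 10) == 0.5
        assert math.isnan(det.difference_coefficient(-10, 10))
        assert det.difference_coefficient(-5, 10) > 0.5

    def test_limit_of_fast_gaze(self):
        assert det.difference_coefficient(1e9, 10) == pytest.approx(0.5, abs=1e-7)

    @given(st.floats(0.1, 4.0))
    def test_log10_symmetry(self, x):
        obj = 10.0
        hi = det.difference_coefficient(10 * 10 ** x, obj)
        lo = det.difference_coefficient(10 * 10 ** (-x), obj)
        assert hi == pytest.approx(lo, rel=1e-9)

    @given(st.floats(-50, -0.01), st.floats(0.01, 50))
    def test_opposite_signs_exceed_half(self, dg, do):
        c = det.difference_coefficient(dg, do)
        if not math.isnan(c):
            assert c > 0.5

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(8)
        dg = rng.normal(size=20)
        do = rng.normal(size=20)
        vec = det._coefficients(dg, do)
        for i in range(20):
            s = det.difference_coefficient(dg[i], do[i])
            assert (math.isnan(s) and math.isnan(vec[i])) or s == pytest.approx(vec[i])


class TestDifferenceDetect:
    def test_perfect_fit_selected_at_any_positive_threshold(self):
        w, _, _ = _fill_window(np.random.default_rng(9), gaze_like="obj2")
        d = det.difference_detect(w, 1e-9)
        assert d.selected_object == "obj2"
        assert d.score_per_object["obj2"] == pytest.approx(0.0, abs=1e-12)

    def test_stationary_gaze_rejects_moving_objects(self):
        w = det.SampleWindow(40, ["a", "b"])
        ramp = np.arange(40, dtype=float)[:, None] * np.array([0.01, 0.5, 0.5])
        for k in range(40):
            w.push((1.0, 0.0, 0.0), {"a": 1 + ramp[k], "b": 2 + 2 * ramp[k]}, t=k / 60)
        d = det.difference_detect(w, 0.07)
        assert d.selected_object is None
        # stationary gaze vs moving object: each dimension sits at 0.5
        assert d.score_per_object["a"] == pytest.approx(0.5)

    def test_undefined_dimensions_skipped_and_renormalised(self):
        w = det.SampleWindow(4, ["a"])
        # gaze phi moves exactly opposite to the object: that dim is undefined
        gaze = np.array([[1, 1, 0], [1, 1, 1], [1, 1, 2], [1, 1, 3]], float)
        obj = np.array([[1, 1, 3], [1, 1, 2], [1, 1, 1], [1, 1, 0]], float)
        for k in range(4):
            w.push(gaze[k], {"a": obj[k]}, t=k / 60)
        score = det.difference_score(w, "a")
        assert score == pytest.approx(0.0)   # r and theta fit perfectly; phi skipped
        d = det.difference_detect(w, 0.07)
        assert d.selected_object == "a"


@pytest.fixture(scope="module")
def noisy_trial():
    cfg = sim.TrialConfig(target="lnt", movement="linear",
                          object_labels=("lnt", "rfb", "t"), seed=12)
    return sim.simulate_trial(cfg, sim.OculomotorParams(angular_noise_sd=0.5))


class TestTraces:

    def test_no_decision_before_window_fills(self, noisy_trial):
        for alg in ("correlation", "difference"):
            tr = det.score_trace(noisy_trial, alg)
            assert tr.frame_index[0] == det.WINDOW_SIZE
            d = tr.decide(0.0 if alg == "correlation" else np.inf)
            assert d.frame_index >= det.WINDOW_SIZE

    def test_correlation_trace_matches_streaming(self, noisy_trial):
        t, gaze, objs = noisy_trial.analysis_series()
        tr = det.correlation_trace(t, gaze, objs)
        w = det.SampleWindow(det.WINDOW_SIZE, list(objs))
        col = 0
        for k in range(len(t)):
            w.push(gaze[k], {i: objs[i][k] for i in objs}, t[k])
            if w.full:
                for j, obj_id in enumerate(tr.object_ids):
                    assert det.correlation_score(w, obj_id) == pytest.approx(
                        tr.scores[j, col], abs=1e-10)
                col += 1
        assert col == tr.scores.shape[1]

    def test_difference_trace_matches_streaming(self, noisy_trial):
        t, gaze, objs = noisy_trial.analysis_series()
        tr = det.difference_trace(t, gaze, objs, smooth=True)
        stream = det.DifferenceDetector(threshold=-1.0, smooth=True)
        col = 0
        for k in range(len(t)):
            d = stream.update(gaze[k], {i: objs[i][k] for i in objs}, t[k])
            if d is not None:
                for j, obj_id in enumerate(tr.object_ids):
                    assert d.score_per_object[obj_id] == pytest.approx(
                        tr.scores[j, col], rel=1e-6, abs=1e-9, nan_ok=True)
                col += 1
        assert col == tr.scores.shape[1]

    def test_scores_bounded(self, noisy_trial):
        corr = det.score_trace(noisy_trial, "correlation").scores
        assert np.nanmax(corr) <= 1.0 and np.nanmin(corr) >= -1.0
        diff = det.score_trace(noisy_trial, "difference").scores
        assert np.nanmin(diff) >= 0.0

    def test_object_subset_selection(self, noisy_trial):
        tr = det.score_trace(noisy_trial, "correlation", objects=("lnt", "t"))
        assert set(tr.object_ids) == {"lnt", "t"}
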