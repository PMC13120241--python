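"""Feature extraction: 7 V summary features, EWMA, windowed stats, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enofuse.features import (
    EWMA_ALPHAS,
    FeatureScaler,
    build_feature_vector,
    cont_features,
    diff_response,
    ewma_max,
    ewma_smooth,
    max_response,
)
from enofuse.patterns import DAQ10
from enofuse.signal_processing import ModulationSegments, split_modulation_levels
from enofuse.synthetic import SimConfig, simulate_trace


def brute_force_ewma(x: np.ndarray, alpha: float) -> np.ndarray:
    """Independent oracle: the explicit normalised weighted sum."""
    out = np.empty_like(x, dtype=float)
    for m in range(len(x)):
        w = (1.0 - alpha) ** (m - np.arange(m + 1))
        out[m] = np.sum(w * x[: m + 1]) / np.sum(w)
    return out


class TestSummaryFeatures:
    def test_max_response(self):
        np.testing.assert_allclose(max_response([[0.2, 0.8, 0.5]]), [0.8])
        np.testing.assert_allclose(max_response(np.full((5, 9), 3.0)), 3.0)

    def test_max_dominates_every_element(self, rng):
        seg = rng.normal(size=(5, 30))
        assert np.all(max_response(seg)[:, None] >= seg)

    def test_diff_response(self):
        np.testing.assert_allclose(diff_response([[0.2, 0.8, 0.5]]), [0.6])
        np.testing.assert_allclose(diff_response(np.full((2, 4), 1.0)), 0.0)

    def test_diff_invariant_under_sign_flip(self, rng):
        seg = rng.normal(size=(5, 30))
        np.testing.assert_allclose(diff_response(seg), diff_response(-seg))


class TestEwma:
    def test_hand_evaluated_two_point_signal(self):
        # weights (0.5, 1): smoothed = [0, (0.5*0 + 1*1)/1.5]
        smoothed = ewma_smooth(np.array([[0.0, 1.0]]), alpha=0.5)
        np.testing.assert_allclose(smoothed, [[0.0, 2.0 / 3.0]], atol=1e-12)
        np.testing.assert_allclose(
            ewma_max(np.array([[0.0, 1.0]]), 0.5), [2.0 / 3.0], atol=1e-12
        )

    def test_alpha_one_reduces_to_max(self, rng):
        seg = rng.normal(size=(5, 20))
        np.testing.assert_allclose(ewma_max(seg, 1.0), max_response(seg))

    def test_constant_signal_unchanged(self):
        seg = np.full((3, 15), 4.2)
        for a in EWMA_ALPHAS:
            np.testing.assert_allclose(ewma_max(seg, a), 4.2)

    def test_invalid_alpha_rejected(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="alpha"):
                ewma_max(np.ones((1, 5)), bad)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        x=st.lists(
            st.floats(min_value=-100, max_value=100), min_size=1, max_size=50
        ),
        alpha=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_recursion_matches_brute_force_oracle(self, x, alpha):
        x = np.asarray(x)
        recursive = ewma_smooth(x[None, :], alpha)[0]
        np.testing.assert_allclose(recursive, brute_force_ewma(x, alpha), atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        x=st.lists(
            st.floats(min_value=-50, max_value=50), min_size=2, max_size=40
        ),
        alpha=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_ewma_max_bounded_by_segment_range(self, x, alpha):
        seg = np.asarray(x)[None, :]
        val = ewma_max(seg, alpha)[0]
        assert seg.min() - 1e-9 <= val <= seg.max() + 1e-9


@pytest.fixture(scope="module")
def segments() -> ModulationSegments:
    cfg = SimConfig(seed=3)
    trace = simulate_trace(cfg, "ripe", day=1, seed=9, sample_id="s0")
    return split_modulation_levels(trace, DAQ10)


class TestFeatureVector:

    def test_large_set_has_85_entries(self, segments):
        vec = build_feature_vector(segments, "large")
        assert len(vec) == 85  # 2*5 + 3*5*5

    def test_small_set_has_10_entries(self, segments):
        assert len(build_feature_vector(segments, "small")) == 10

    def test_name_order_is_max_diff_then_level_major_ewma(self, segments):
        names = build_feature_vector(segments, "large").names
        assert names[:5] == [f"m7V_s{s}" for s in range(1, 6)]
        assert names[5:10] == [f"d7V_s{s}" for s in range(1, 6)]
        assert names[10] == "ewma_7V_s1_a0.1"
        assert names[12] == "ewma_7V_s1_a0.001"
        assert names[25] == "ewma_5.5V_s1_a0.1"  # next level after all 5 sensors

    def test_constant_trace_degenerates(self):
        segs = ModulationSegments(
            segments={v: np.full((5, 50), 1.7) for v in DAQ10.active_levels}
        )
        vec = build_feature_vector(segs, "large")
        s = vec.as_series()
        assert np.allclose(s.filter(like="m7V"), 1.7)
        assert np.allclose(s.filter(like="d7V"), 0.0)
        assert np.allclose(s.filter(like="ewma"), 1.7)

    def test_missing_level_named_in_error(self, segments):
        broken = dict(segments.segments)
        del broken[7.0]
        broken[9.9] = np.ones((5, 10))
        with pytest.raises(KeyError, match="7 V"):
            build_feature_vector(
                ModulationSegments(segments=broken), "large"
            )

    def test_deterministic(self, segments):
        a = build_feature_vector(segments, "large").values
        b = build_feature_vector(segments, "large").values
        np.testing.assert_array_equal(a, b)


class TestContFeatures:
    def test_constant_window(self):
        vec = cont_features(np.full((5, 100), 2.0))
        assert len(vec) == 25
        s = vec.as_series()
        for stat, expect in [("mean", 2), ("sd", 0), ("max", 2), ("min", 2), ("rms", 2)]:
            assert np.allclose(s.filter(like=f"cont_{stat}"), expect)

    def test_two_point_arithmetic(self):
        vec = cont_features(np.array([[3.0, -3.0]])[[0, 0, 0, 0, 0], :])
        s = vec.as_series()
        assert s["cont_mean_s1"] == pytest.approx(0.0)
        assert s["cont_sd_s1"] == pytest.approx(3.0)  # population sd
        assert s["cont_max_s1"] == pytest.approx(3.0)
        assert s["cont_min_s1"] == pytest.approx(-3.0)
        assert s["cont_rms_s1"] == pytest.approx(3.0)


class TestScaler:
    def test_worked_example(self):
        sc = FeatureScaler().fit(np.array([[2.0], [4.0], [6.0]]))
        assert sc.transform(np.array([[4.0]]))[0, 0] == pytest.approx(0.5)
        assert sc.transform(np.array([[2.0]]))[0, 0] == pytest.approx(0.0)
        assert sc.transform(np.array([[6.0]]))[0, 0] == pytest.approx(1.0)

    def test_test_values_not_clipped(self):
        sc = FeatureScaler().fit(np.array([[2.0], [6.0]]))
        assert sc.transform(np.array([[8.0]]))[0, 0] == pytest.approx(1.5)

    def test_training_data_maps_into_unit_interval(self, rng):
        X = rng.normal(size=(30, 8))
        out = FeatureScaler().fit_transform(X)
        assert out.min() >= -1e-12 and out.max() <= 1 + 1e-12

    def test_zero_range_warns_and_maps_to_zero(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.warns(UserWarning, match="zero-range"):
            sc = FeatureScaler().fit(X)
        assert np.all(sc.transform(X)[:, 0] == 0.0)

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError, match="fitted"):
            FeatureScaler().transform(np.ones((2, 2)))

    def test_json_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(10, 3))
        sc = FeatureScaler().fit(X)
        sc.names = ["a", "b", "c"]
        p = tmp_path / "scaler.json"
        sc.to_json(p)
        sc2 = FeatureScaler.from_json(p)
        np.testing.assert_allclose(sc.transform(X), sc2.transform(X))
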