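"""Synthetic campaign generator: shapes, determinism, nulls, statistics."""

import numpy as np
import pytest

from enofuse.classification import make_cv_plan, run_suite
from enofuse.pipeline import extract_features
from enofuse.synthetic import (
    DetectQuality,
    SimConfig,
    simulate_dataset,
    simulate_detections,
    simulate_trace,
)


class TestTrace:
    def test_daq10_shape(self):
        tr = simulate_trace(SimConfig(seed=0), "ripe", day=0, seed=1)
        assert tr.values.shape == (5, 6000)
        assert tr.has_env

    def test_daq48_shape(self):
        cfg = SimConfig(pattern_id="DAQ48", seed=0)
        assert simulate_trace(cfg, "ripe", 0, 1).values.shape == (5, 28_800)

    def test_seeded_determinism(self):
        cfg = SimConfig(seed=4)
        a = simulate_trace(cfg, "unripe", day=2, seed=77)
        b = simulate_trace(cfg, "unripe", day=2, seed=77)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.temp_c, b.temp_c)

    def test_degenerate_null_classes_identical(self):
        amps = {"ripe": (1.0,) * 5, "unripe": (1.0,) * 5}
        cfg = SimConfig(
            noise_sd_v=0.0,
            drift_rate=0.0,
            day_effect_sd=0.0,
            distort_with_surface=False,
            class_amplitudes=amps,
            seed=8,
        )
        r = simulate_trace(cfg, "ripe", day=1, seed=5, hour=12.0)
        u = simulate_trace(cfg, "unripe", day=1, seed=5, hour=12.0)
        np.testing.assert_array_equal(r.values, u.values)

    def test_no_drift_baseline_stable_across_month(self):
        cfg = SimConfig(
            noise_sd_v=0.0, drift_rate=0.0, day_effect_sd=0.0,
            distort_with_surface=False, seed=8,
        )
        d0 = simulate_trace(cfg, "ripe", day=0, seed=3, hour=9.0)
        d30 = simulate_trace(cfg, "ripe", day=30, seed=3, hour=9.0)
        # first sample precedes any response build-up: pure baseline
        np.testing.assert_allclose(d0.values[:, 0], d30.values[:, 0], atol=1e-9)

    def test_drift_scales_baseline(self):
        cfg = SimConfig(
            noise_sd_v=0.0, drift_rate=0.01, day_effect_sd=0.0,
            distort_with_surface=False, seed=8,
        )
        d0 = simulate_trace(cfg, "ripe", day=0, seed=3, hour=9.0)
        d10 = simulate_trace(cfg, "ripe", day=10, seed=3, hour=9.0)
        np.testing.assert_allclose(
            d10.values[:, 0] / d0.values[:, 0], 1.1, rtol=1e-6
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError, match="amplitudes"):
            simulate_trace(SimConfig(seed=0), "rotten", 0, 1)


class TestDetections:
    def test_night_has_no_image(self):
        assert simulate_detections(SimConfig(seed=0), "ripe", "night", 1) is None

    def test_degenerate_confidence(self):
        dq = {
            "well_lit": DetectQuality(
                p_detect={"ripe": 1.0, "unripe": 1.0},
                conf_mean={"ripe": 0.9, "unripe": 0.9},
                conf_sd=0.0,
                p_misclass=0.0,
            )
        }
        cfg = SimConfig(seed=0, detect_quality=dq, n_fruits_mean=0.0)
        dets = simulate_detections(cfg, "ripe", "well_lit", seed=2)
        assert len(dets) == 1
        assert dets[0].cls == "ripe"
        assert dets[0].conf == pytest.approx(0.9)

    def test_detection_rate_matches_binomial(self):
        dq = {
            "well_lit": DetectQuality(
                p_detect={"ripe": 0.4, "unripe": 0.4},
                conf_mean={"ripe": 0.8, "unripe": 0.8},
                conf_sd=0.05,
                p_misclass=0.0,
            )
        }
        cfg = SimConfig(seed=0, detect_quality=dq, n_fruits_mean=0.0)
        n = 10_000
        hits = sum(
            len(simulate_detections(cfg, "ripe", "well_lit", seed=s)) for s in range(n)
        )
        p_hat = hits / n
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(p_hat - 0.4) < 3 * se

    def test_unknown_lighting_rejected(self):
        with pytest.raises(KeyError, match="lighting"):
            simulate_detections(SimConfig(seed=0), "ripe", "strobe", 1)

    def test_backlit_ordering_enforced_by_validation(self):
        dq = {
            "well_lit": DetectQuality(
                p_detect={"ripe": 0.5, "unripe": 0.9},
                conf_mean={"ripe": 0.6, "unripe": 0.8},
            ),
            "backlit": DetectQuality(
                p_detect={"ripe": 0.9, "unripe": 0.9},  # better than well-lit: invalid
                conf_mean={"ripe": 0.9, "unripe": 0.8},
            ),
        }
        with pytest.raises(ValueError, match="backlit"):
            SimConfig(seed=0, detect_quality=dq)


class TestDataset:
    def test_sample_counts(self, fast_dataset, fast_config):
        n = 2 * fast_config.n_samples_per_class
        assert fast_dataset.n_samples == n
        assert len(fast_dataset.labels) == n
        counts = {c: fast_dataset.labels.count(c) for c in fast_config.classes}
        assert all(v == fast_config.n_samples_per_class for v in counts.values())

    def test_night_samples_have_no_detections(self, fast_dataset):
        for avail, det in zip(fast_dataset.image_available, fast_dataset.detections):
            assert avail == (det is not None)

    def test_time_ordering(self, fast_dataset):
        ts = [t.timestamp for t in fast_dataset.traces]
        assert ts == sorted(ts)
        assert np.all(np.diff(fast_dataset.day_index) >= 0)

    def test_batch_boundary_at_drift_onset(self, fast_dataset, fast_config):
        for day, batch in zip(fast_dataset.day_index, fast_dataset.batch_id):
            assert batch == (0 if day < fast_config.drift_onset_day else 1)

    def test_seed_determinism(self, fast_config):
        a = simulate_dataset(fast_config)
        b = simulate_dataset(fast_config)
        assert a.labels == b.labels
        assert a.lighting == b.lighting
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.values, tb.values)

    def test_night_fraction_binomial(self):
        # light-weight acquisition so 1000 samples stay cheap
        cfg = SimConfig(
            pattern_id="DAQcont", cont_duration_s=10.0,
            n_samples_per_class=500, night_fraction=0.5,
            distort_with_surface=False, seed=9,
        )
        ds = simulate_dataset(cfg)
        frac = 1.0 - ds.image_available.mean()
        se = np.sqrt(0.5 * 0.5 / 1000)
        assert abs(frac - 0.5) < 4 * se

    def test_write_round_trip(self, tmp_path):
        cfg = SimConfig(n_samples_per_class=2, n_days=3, seed=10)
        ds = simulate_dataset(cfg)
        ds.write(tmp_path)
        assert (tmp_path / "metadata.csv").exists()
        assert (tmp_path / "detections.jsonl").exists()
        from enofuse.core import ResponseTrace, read_detections_jsonl

        tr = ResponseTrace.from_csv(
            tmp_path / "traces" / f"{ds.sample_ids[0]}.csv"
        )
        np.testing.assert_allclose(tr.values, ds.traces[0].values)
        dets = read_detections_jsonl(tmp_path / "detections.jsonl")
        assert set(dets) == set(ds.sample_ids)


def test_monotone_separability():
    """A wider between-class amplitude gap never hurts linear-classifier CV."""
    base_ripe = np.array([1.15, 1.0, 1.35, 1.2, 1.3])
    base_unripe = np.array([1.0, 0.85, 1.15, 1.0, 1.1])
    mid = (base_ripe + base_unripe) / 2
    accs = []
    for gap in (0.0, 1.0, 2.5):
        amps = {
            "ripe": tuple(mid + gap * (base_ripe - mid)),
            "unripe": tuple(mid - gap * (mid - base_unripe)),
        }
        cfg = SimConfig(
            n_samples_per_class=25, n_days=10, class_amplitudes=amps, seed=31
        )
        ds = simulate_dataset(cfg)
        feats = extract_features(ds, "small")
        meta = ds.metadata()
        plan = make_cv_plan(meta, "stratified_kfold", {"k": 5}, seed=31)
        rep = run_suite(
            feats, meta["label"], plan, ["LR"], n_repeats=1, base_seed=31,
            sample_ids=list(feats.index),
        )["LR"]
        accs.append(rep.mean_accuracy)
    assert accs[0] <= accs[1] + 1e-9 and accs[1] <= accs[2] + 1e-9
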