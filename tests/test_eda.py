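"""EDA artifact detection/repair, filtering, normalization, stage means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresskit import eda
from stresskit.errors import ParameterError, ValidationError
from stresskit.io_formats import StageSchedule
from stresskit.synthetic import scaled_config, simulate_eda

from conftest import make_eda


class TestDetect:
    def test_constant_series_unflagged(self):
        s = eda.detect_artifacts(make_eda(np.full(200, 2.0)))
        assert not s.artifact_mask.any()

    def test_slow_ramp_below_threshold_unflagged(self):
        # slope 0.005 uS per sample, under the 0.01 uS jump threshold
        s = eda.detect_artifacts(make_eda(2.0 + 0.005 * np.arange(400)))
        assert not s.artifact_mask.any()

    def test_injected_drop_flagged_exactly(self):
        rng = np.random.default_rng(3)
        values = 2.0 + 0.02 * np.sin(np.arange(1200) / 40.0) \
            + rng.normal(0, 0.005, 1200)
        values[600:612] = 0.05  # 3-s detachment at 4 Hz
        s = eda.detect_artifacts(make_eda(values))
        assert s.artifact_mask[600:612].all()
        assert s.artifact_mask.sum() == 12

    def test_values_untouched_by_detection(self):
        values = np.full(100, 2.0)
        values[50] = 4.0
        s = eda.detect_artifacts(make_eda(values))
        np.testing.assert_array_equal(s.values, values)

    def test_all_flagged_raises(self):
        # zero-width bands (k = 0) flag every sample of a 2-point series
        with pytest.raises(ValidationError, match="anchor"):
            eda.detect_artifacts(make_eda([1.0, 2.0]), band_k=0.0,
                                 global_k_low=0.0, global_k_high=0.0)


class TestRepair:
    def test_linear_interpolation_forced(self):
        values = np.array([2.0, 0.0, 0.0, 0.0, 0.0, 3.0])
        s = make_eda(values)
        s.artifact_mask = np.array([0, 1, 1, 1, 1, 0], dtype=bool)
        out = eda.repair_artifacts(s)
        np.testing.assert_allclose(out.values,
                                   [2.0, 2.2, 2.4, 2.6, 2.8, 3.0])

    def test_head_artifact_backfilled(self):
        s = make_eda([9.0, 9.0, 1.5, 1.6])
        s.artifact_mask = np.array([1, 1, 0, 0], dtype=bool)
        out = eda.repair_artifacts(s)
        np.testing.assert_allclose(out.values, [1.5, 1.5, 1.5, 1.6])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        s = make_eda(2.0 + rng.normal(0, 0.01, 300))
        s.values[100:110] = 0.05
        flagged = eda.detect_artifacts(s)
        once = eda.repair_artifacts(flagged)
        twice = eda.repair_artifacts(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_unflagged_samples_never_altered(self):
        rng = np.random.default_rng(1)
        s = make_eda(2.0 + rng.normal(0, 0.01, 300))
        s.values[50:60] = 0.05
        flagged = eda.detect_artifacts(s)
        repaired = eda.repair_artifacts(flagged)
        keep = ~flagged.artifact_mask
        np.testing.assert_array_equal(repaired.values[keep], s.values[keep])

    def test_no_valid_samples_raises(self):
        s = make_eda([1.0, 2.0])
        s.artifact_mask = np.array([True, True])
        with pytest.raises(ValidationError, match="no valid"):
            eda.repair_artifacts(s)

    def test_relevel_mode_continues_from_anchor(self):
        s = make_eda([2.0, 5.0, 5.1, 2.1])
        s.artifact_mask = np.array([0, 1, 1, 0], dtype=bool)
        out = eda.repair_artifacts(s, mode="relevel")
        np.testing.assert_allclose(out.values, [2.0, 2.0, 2.1, 2.1])

    def test_repair_halves_error_on_synthetic_detachments(self):
        """Post-repair RMSE against the clean trace is far below pre-repair."""
        cfg = scaled_config()
        rng = np.random.default_rng(11)
        for pid in ("a", "b", "c"):
            series_list, clean_list, seg_list = simulate_eda(cfg, rng, pid)
            series, clean = series_list[0], clean_list[0]
            pre = np.sqrt(np.mean((series.values - clean) ** 2))
            repaired = eda.repair_artifacts(eda.detect_artifacts(series))
            post = np.sqrt(np.mean((repaired.values - clean) ** 2))
            assert post <= 0.5 * pre


class TestLowpass:
    def test_dc_passes_unchanged(self):
        s = eda.lowpass(make_eda(np.full(400, 1.3)))
        np.testing.assert_allclose(s.values, 1.3, atol=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError, match="Nyquist"):
            eda.lowpass(make_eda(np.zeros(100) + 1, fs=4.0), cutoff_hz=2.0)

    def test_stopband_tone_attenuated_40db(self):
        # 1.5 Hz tone at 50 Hz sampling through the 0.5 Hz low-pass
        t = np.arange(50 * 60) / 50.0
        s = eda.lowpass(make_eda(np.sin(2 * np.pi * 1.5 * t), fs=50.0))
        mid = s.values[500:-500]
        amplitude = np.abs(mid).max()
        assert 20 * np.log10(amplitude) <= -40.0

    def test_length_preserved_and_linear(self):
        rng = np.random.default_rng(0)
        a = make_eda(rng.normal(size=500), fs=4.0)
        b = make_eda(rng.normal(size=500), fs=4.0)
        summed = make_eda(a.values + b.values, fs=4.0)
        fa, fb, fs = (eda.lowpass(x) for x in (a, b, summed))
        assert fa.values.size == 500
        np.testing.assert_allclose(fs.values, fa.values + fb.values,
                                   atol=1e-9)


class TestNormalize:
    def test_formula(self):
        out = eda.normalize_minmax(make_eda([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    def test_constant_maps_to_zeros(self):
        out = eda.normalize_minmax(make_eda(np.full(10, 3.3)))
        np.testing.assert_array_equal(out.values, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=50.0), min_size=2,
                    max_size=60))
    def test_bounds_for_any_input(self, values):
        out = eda.normalize_minmax(make_eda(values))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        if max(values) > min(values):
            assert out.values.min() == 0.0 and out.values.max() == 1.0


class TestStageSummaries:
    def test_constant_value_recovered(self, short_schedule):
        n = int(short_schedule.end_s * 4)
        s = make_eda(np.full(n, 0.3))
        out = eda.summarize_stages(s, short_schedule, window_s=30.0)
        assert len(out) == 7
        for summary in out:
            assert summary.tonic_mean == pytest.approx(0.3)

    def test_stage_shorter_than_window_rejected(self, short_schedule):
        n = int(short_schedule.end_s * 4)
        with pytest.raises(ParameterError, match="window"):
            eda.summarize_stages(make_eda(np.full(n, 0.3)), short_schedule,
                                 window_s=90.0)

    def test_stage_outside_recording_named(self):
        sched = StageSchedule((("baseline", 0.0, 60.0),
                               ("stress", 60.0, 600.0)))
        s = make_eda(np.full(400, 0.5))  # only 100 s at 4 Hz
        with pytest.raises(ValidationError, match="stress"):
            eda.summarize_stages(s, sched, window_s=30.0)

    def test_stress_tonic_exceeds_baseline_in_synthetic_cohort(self):
        """The generator's stress arousal increment survives the chain."""
        cfg = scaled_config()
        rng = np.random.default_rng(5)
        for pid in range(6):
            series = simulate_eda(cfg, rng, f"p{pid}")[0][0]
            cleaned = eda.preprocess(series)
            out = eda.summarize_stages(cleaned, cfg.schedule, window_s=30.0)
            by_stage = {s.stage_label: s.tonic_mean for s in out}
            assert by_stage["stress"] > by_stage["baseline"]


class TestDeviceFusion:
    def _summary(self, pid, stage, tonic, frac):
        return eda.EDAStageSummary(participant_id=pid, stage_label=stage,
                                   tonic_mean=tonic, n_valid_samples=100,
                                   fraction_repaired=frac)

    def test_both_devices_averaged(self):
        dev1 = [self._summary("p", "baseline", 0.2, 0.0)]
        dev2 = [self._summary("p", "baseline", 0.4, 0.1)]
        fused = eda.fuse_device_summaries([dev1, dev2])
        assert fused[0].tonic_mean == pytest.approx(0.3)

    def test_failing_device_dropped(self):
        dev1 = [self._summary("p", "baseline", 0.2, 0.0)]
        dev2 = [self._summary("p", "baseline", 0.9, 0.5)]  # 50% repaired
        fused = eda.fuse_device_summaries([dev1, dev2])
        assert fused[0].tonic_mean == pytest.approx(0.2)
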