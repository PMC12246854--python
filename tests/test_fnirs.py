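"""Beer-Lambert conversion, DPF, SCI quality control, filtering, summaries."""

import numpy as np
import pytest

from stresskit import fnirs
from stresskit.errors import ParameterError
from stresskit.io_formats import Channel, Montage, RawFNIRS


def make_raw(montage, od, fs=50.0, age=25.0, pid="p01"):
    return RawFNIRS(participant_id=pid, sample_rate=fs, montage=montage,
                    od=od, age_years=age)


def two_channel_montage(distance=3.0):
    return Montage(channels=(
        Channel("Tx1-Rx1", "right", 10, distance),
        Channel("Tx6-Rx5", "left", 10, distance)))


class TestDPF:
    def test_positive_on_validated_grid(self):
        for age in (18, 23, 30, 35, 60):
            for wl in (690, 760, 808, 850, 900):
                assert fnirs.compute_dpf(age, wl) > 0

    def test_monotone_in_age(self):
        ages = np.linspace(18, 35, 40)
        for wl in (760.0, 850.0):
            dpfs = [fnirs.compute_dpf(a, wl) for a in ages]
            assert all(b > a for a, b in zip(dpfs, dpfs[1:]))

    def test_wavelengths_distinct(self):
        assert fnirs.compute_dpf(25, 760.0) != fnirs.compute_dpf(25, 850.0)

    def test_plausible_adult_magnitude(self):
        # adult prefrontal DPF values are conventionally ~4-7
        assert 4.0 < fnirs.compute_dpf(23, 760.0) < 7.0
        assert 4.0 < fnirs.compute_dpf(23, 850.0) < 7.0

    @pytest.mark.parametrize("age,wl", [(0, 760), (101, 760), (25, 500),
                                        (25, 1100)])
    def test_out_of_range_rejected(self, age, wl):
        with pytest.raises(ParameterError):
            fnirs.compute_dpf(age, wl)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentrations(self):
        montage = two_channel_montage()
        od = {(c, wl): np.zeros(100) for c in ("Tx1-Rx1", "Tx6-Rx5")
              for wl in (760.0, 850.0)}
        hemo = fnirs.beer_lambert(make_raw(montage, od))
        for cid in hemo.retained_channels:
            np.testing.assert_array_equal(hemo.delta_ohb[cid], 0.0)
            np.testing.assert_array_equal(hemo.delta_hhb[cid], 0.0)

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(7)
        montage = two_channel_montage()
        true_o = rng.normal(0, 1.0, 3000)
        true_h = rng.normal(0, 0.5, 3000)
        od = {}
        for cid in ("Tx1-Rx1", "Tx6-Rx5"):
            fwd = fnirs.forward_od(true_o, true_h, (760.0, 850.0), 3.0, 25.0)
            for wl in (760.0, 850.0):
                od[(cid, wl)] = fwd[wl]
        hemo = fnirs.beer_lambert(make_raw(montage, od))
        scale = np.abs(true_o).max()
        for cid in hemo.retained_channels:
            np.testing.assert_allclose(hemo.delta_ohb[cid], true_o,
                                       atol=1e-6 * scale)
            np.testing.assert_allclose(hemo.delta_hhb[cid], true_h,
                                       atol=1e-6 * scale)

    def test_doubling_distance_halves_concentrations(self):
        rng = np.random.default_rng(8)
        od_vals = rng.normal(0, 0.01, 500)
        results = {}
        for dist in (3.0, 6.0):
            montage = two_channel_montage(distance=dist)
            od = {("Tx1-Rx1", wl): od_vals for wl in (760.0, 850.0)}
            od[("Tx6-Rx5", 760.0)] = od_vals
            od[("Tx6-Rx5", 850.0)] = od_vals
            hemo = fnirs.beer_lambert(make_raw(montage, od))
            results[dist] = hemo.delta_ohb["Tx1-Rx1"]
        np.testing.assert_allclose(results[6.0], results[3.0] / 2.0,
                                   rtol=1e-12)

    def test_singular_extinction_rejected(self):
        montage = two_channel_montage()
        od = {("Tx1-Rx1", wl): np.zeros(10) for wl in (760.0, 850.0)}
        od[("Tx6-Rx5", 760.0)] = np.zeros(10)
        od[("Tx6-Rx5", 850.0)] = np.zeros(10)
        singular = {760.0: (1.0, 1.0), 850.0: (2.0, 2.0)}
        with pytest.raises(fnirs.NumericalError):
            fnirs.beer_lambert(make_raw(montage, od), extinction=singular)


class TestSCI:
    def _montage(self):
        return two_channel_montage()

    def _raw_with(self, x760, x850, fs=50.0):
        od = {("Tx1-Rx1", 760.0): x760, ("Tx1-Rx1", 850.0): x850,
              ("Tx6-Rx5", 760.0): x760, ("Tx6-Rx5", 850.0): x850}
        return make_raw(self._montage(), od, fs=fs)

    def test_identical_traces_give_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.01, 5000)
        raw = self._raw_with(x, x.copy())
        assert fnirs.compute_sci(raw, "Tx1-Rx1") == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        raw = self._raw_with(rng.normal(0, 0.01, 30000),
                             rng.normal(0, 0.01, 30000))
        assert abs(fnirs.compute_sci(raw, "Tx1-Rx1")) < 0.1

    def test_shared_cardiac_with_noise_above_09(self):
        rng = np.random.default_rng(2)
        t = np.arange(30000) / 50.0
        pulse = 0.01 * np.sin(2 * np.pi * 1.1 * t)
        raw = self._raw_with(pulse + rng.normal(0, 0.002, t.size),
                             0.8 * pulse + rng.normal(0, 0.002, t.size))
        assert fnirs.compute_sci(raw, "Tx1-Rx1") > 0.9

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        t = np.arange(10000) / 50.0
        pulse = 0.01 * np.sin(2 * np.pi * 1.1 * t)
        a = pulse + rng.normal(0, 0.003, t.size)
        b = 0.7 * pulse + rng.normal(0, 0.003, t.size)
        sci_ab = fnirs.compute_sci(self._raw_with(a, b), "Tx1-Rx1")
        sci_ba = fnirs.compute_sci(self._raw_with(b, a), "Tx1-Rx1")
        sci_scaled = fnirs.compute_sci(self._raw_with(5.0 * a, 0.1 * b),
                                       "Tx1-Rx1")
        assert sci_ab == pytest.approx(sci_ba, abs=1e-12)
        assert sci_ab == pytest.approx(sci_scaled, abs=1e-9)

    def test_zero_variance_trace_scores_zero(self):
        raw = self._raw_with(np.zeros(1000), np.zeros(1000))
        assert fnirs.compute_sci(raw, "Tx1-Rx1") == 0.0

    def test_threshold_boundary_inclusive(self):
        report = fnirs.SCIReport(sci={"a": 0.75, "b": 0.7499999})
        assert report.keep["a"] is True
        assert report.keep["b"] is False

    def test_reject_matches_per_channel_sci(self):
        rng = np.random.default_rng(4)
        t = np.arange(6000) / 50.0
        pulse = 0.01 * np.sin(2 * np.pi * 1.1 * t)
        od = {("Tx1-Rx1", 760.0): pulse + rng.normal(0, 0.002, t.size),
              ("Tx1-Rx1", 850.0): 0.8 * pulse + rng.normal(0, 0.002, t.size),
              ("Tx6-Rx5", 760.0): rng.normal(0, 0.002, t.size),
              ("Tx6-Rx5", 850.0): rng.normal(0, 0.002, t.size)}
        raw = make_raw(self._montage(), od)
        report = fnirs.reject_channels(raw)
        for cid in ("Tx1-Rx1", "Tx6-Rx5"):
            assert report.sci[cid] == pytest.approx(
                fnirs.compute_sci(raw, cid), abs=1e-12)
        assert report.retained == ("Tx1-Rx1",)


class TestHemoFilters:
    def _hemo(self, trace, fs=50.0):
        return fnirs.HemoSeries(participant_id="p", sample_rate=fs,
                                delta_ohb={"Tx1-Rx1": trace},
                                delta_hhb={"Tx1-Rx1": trace.copy()},
                                retained_channels=("Tx1-Rx1",))

    def test_cardiac_tone_attenuated_40db(self):
        t = np.arange(50 * 600) / 50.0
        out = fnirs.bandpass_hemo(self._hemo(np.sin(2 * np.pi * 1.1 * t)))
        mid = out.delta_ohb["Tx1-Rx1"][5000:-5000]
        assert 20 * np.log10(np.abs(mid).max()) <= -40.0

    def test_mayer_band_tone_passes_within_3db(self):
        t = np.arange(50 * 600) / 50.0
        out = fnirs.bandpass_hemo(self._hemo(np.sin(2 * np.pi * 0.1 * t)))
        mid = out.delta_ohb["Tx1-Rx1"][5000:-5000]
        assert 20 * np.log10(np.abs(mid).max()) >= -3.0

    def test_zero_in_zero_out(self):
        out = fnirs.bandpass_hemo(self._hemo(np.zeros(2000)))
        np.testing.assert_allclose(out.delta_ohb["Tx1-Rx1"], 0.0, atol=1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            fnirs.bandpass_hemo(self._hemo(np.zeros(2000)), band=(0.18, 0.02))

    def test_zero_phase_symmetric_pulse(self):
        n = 12001
        pulse = np.exp(-0.5 * ((np.arange(n) - n // 2) / 100.0) ** 2)
        out = fnirs.bandpass_hemo(self._hemo(pulse, fs=10.0))
        filtered = out.delta_ohb["Tx1-Rx1"]
        assert int(np.argmax(filtered)) == n // 2
        np.testing.assert_allclose(filtered, filtered[::-1], atol=1e-9)

    def test_lowpass_retains_block_mean(self):
        fs = 10.0
        block = np.zeros(int(fs * 420))
        block[int(fs * 120):int(fs * 180)] = 1.0  # 60-s activation
        out = fnirs.lowpass_hemo(self._hemo(block, fs=fs))
        mid = out.delta_ohb["Tx1-Rx1"][int(fs * 140):int(fs * 160)]
        assert mid.mean() == pytest.approx(1.0, abs=0.05)


class TestStageAverages:
    def test_constant_trace_recovered_and_rejected_absent(self, short_schedule):
        fs = 10.0
        n = int(short_schedule.end_s * fs)
        hemo = fnirs.HemoSeries(
            participant_id="p", sample_rate=fs,
            delta_ohb={"Tx1-Rx1": np.full(n, 0.7),
                       "Tx6-Rx5": np.full(n, -0.2)},
            delta_hhb={"Tx1-Rx1": np.zeros(n), "Tx6-Rx5": np.zeros(n)},
            retained_channels=("Tx1-Rx1",))  # Tx6-Rx5 rejected
        out = fnirs.stage_averages(hemo, short_schedule, window_s=30.0)
        assert {s.channel_id for s in out} == {"Tx1-Rx1"}
        assert all(s.mean_delta_ohb == pytest.approx(0.7) for s in out)
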