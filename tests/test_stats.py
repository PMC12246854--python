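"""Statistical battery: elementary tests, mixed ANOVA, analysis plans."""

import numpy as np
import pandas as pd
import pytest

from stresskit import stats
from stresskit.errors import ConfigError, ValidationError


def long_frame(values, groups):
    """values: (n_subjects, n_stages) array; groups: per-subject labels."""
    rows = []
    stages = [f"s{j}" for j in range(values.shape[1])]
    for i in range(values.shape[0]):
        for j, stage in enumerate(stages):
            rows.append({"participant_id": f"p{i:03d}", "group": groups[i],
                         "stage": stage, "value": values[i, j]})
    return pd.DataFrame(rows)


class TestLevene:
    def test_identical_groups_not_rejected(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        res = stats.levene([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.9

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1.0, 50)
        b = rng.normal(0, 10.0, 50)
        assert stats.levene([a, b]).p < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            stats.levene([np.arange(5.0)])


class TestTTests:
    def test_identical_paired_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = stats.paired_t(x, x.copy())
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.effect_size == 0.0

    def test_paired_closed_form(self):
        # differences [1, 2, 3]: t = mean/sd * sqrt(3) = 2*sqrt(3) ~ 3.464
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])
        res = stats.paired_t(x, y)
        assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-9)
        assert res.df == 2.0
        assert res.effect_size == pytest.approx(2.0)

    def test_constant_nonzero_difference_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError, match="degenerate"):
            stats.paired_t(x + 1.0, x)

    def test_d_sign_matches_mean_difference(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        res = stats.independent_t(a, b)
        assert np.sign(res.effect_size) == np.sign(a.mean() - b.mean())
        res2 = stats.independent_t(b, a)
        assert res2.effect_size == pytest.approx(-res.effect_size)

    def test_independent_d_recovers_true_effect(self):
        """Simulation oracle: estimated d is unbiased for the standardized
        mean difference at the study's group sizes."""
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(1000):
            a = rng.normal(0.8, 1.0, 12)
            b = rng.normal(0.0, 1.0, 11)
            estimates.append(stats.cohens_d_independent(a, b))
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.1)


class TestRMAnova:
    def test_all_equal_values_give_zero_f(self):
        frame = long_frame(np.full((9, 3), 5.0), ["a"] * 9)
        for res in stats.rm_anova(frame):
            assert res.statistic == 0.0

    def test_two_level_one_group_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (14, 2)) + [0.0, 0.4]
        frame = long_frame(vals, ["a"] * 14)
        f_res = stats.rm_anova(frame)[0]
        t_res = stats.paired_t(vals[:, 1], vals[:, 0])
        assert f_res.statistic == pytest.approx(t_res.statistic ** 2,
                                                rel=1e-8)
        assert f_res.p == pytest.approx(t_res.p, rel=1e-8)

    def test_sums_of_squares_additive(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(10, 2, (35, 5))
        groups = ["a"] * 12 + ["b"] * 11 + ["c"] * 12
        dec = stats.anova_decomposition(long_frame(vals, groups))
        partition = (dec.ss_group + dec.ss_subjects_within + dec.ss_stage
                     + dec.ss_interaction + dec.ss_error_within)
        assert partition == pytest.approx(dec.ss_total, rel=1e-8)

    def test_matches_independent_mixed_anova_implementation(self):
        """Dual route: the hand decomposition against pingouin on an
        unbalanced 12/11/12 design."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        vals = rng.normal(10, 2, (35, 3))
        vals[:12] += np.array([0.0, 1.0, 0.5])  # group x stage structure
        groups = ["a"] * 12 + ["b"] * 11 + ["c"] * 12
        frame = long_frame(vals, groups)
        ours = {r.effect: r for r in stats.rm_anova(frame)}
        ref = pingouin.mixed_anova(data=frame, dv="value", within="stage",
                                   subject="participant_id", between="group")
        ref = ref.set_index("Source")
        assert ours["group"].statistic == pytest.approx(
            ref.loc["group", "F"], rel=1e-9)
        assert ours["stage"].statistic == pytest.approx(
            ref.loc["stage", "F"], rel=1e-9)
        assert ours["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert ours["stage"].effect_size == pytest.approx(
            ref.loc["stage", "np2"], rel=1e-9)

    def test_missing_cell_listed(self):
        frame = long_frame(np.ones((4, 2)), ["a"] * 4)
        frame = frame.drop(frame.index[1])
        with pytest.raises(ValidationError, match="p000"):
            stats.rm_anova(frame)

    def test_type_i_error_calibrated_under_null(self):
        """Within-effect rejection rate at alpha = 0.05 under pure noise."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            vals = rng.normal(0, 1, (12, 2)) \
                + rng.normal(0, 1, (12, 1))  # subject-level correlation
            res = stats.rm_anova(long_frame(vals, ["a"] * 12))[0]
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_greenhouse_geisser_reduces_df(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, (20, 1))
        vals = np.hstack([base + rng.normal(0, 0.1, (20, 1)),
                          base + rng.normal(0, 0.1, (20, 1)),
                          rng.normal(0, 3, (20, 1))])  # sphericity violated
        frame = long_frame(vals, ["a"] * 20)
        plain = stats.rm_anova(frame)[0]
        corrected = stats.rm_anova(frame, greenhouse_geisser=True)[0]
        assert corrected.df < plain.df
        assert corrected.statistic == pytest.approx(plain.statistic)


class TestFDR:
    def test_bh_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.9, 0.04])
        q = stats.bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestBattery:
    def _panel(self, seed=0):
        from stresskit.synthetic import SyntheticConfig, simulate_cortisol_panel
        return simulate_cortisol_panel(SyntheticConfig(),
                                       np.random.default_rng(seed))[0]

    def test_empty_plan_empty_results(self):
        assert stats.run_battery(cortisol_panel=self._panel(), plan=[]) == []

    def test_cortisol_anova_detects_stress_rise(self):
        results = stats.run_battery(
            cortisol_panel=self._panel(),
            plan=[{"measure": "cortisol", "test": "rm_anova",
                   "stages": ["baseline", "stress"]}])
        stage = [r for r in results if r.effect == "stage"][0]
        assert stage.significant
        assert stage.effect_size_kind == "partial_eta_sq"

    def test_plan_with_absent_channel_rejected(self):
        from stresskit.fnirs import HemoStageSummary
        summaries = [HemoStageSummary("p1", "Tx1-Rx1", "sound", 0.1, 0.0),
                     HemoStageSummary("p2", "Tx1-Rx1", "sound", 0.2, 0.0)]
        with pytest.raises(ConfigError, match="absent"):
            stats.run_battery(
                hemo_summaries=summaries,
                groups={"p1": "soothing", "p2": "silence"},
                plan=[{"measure": "hbo", "test": "independent_t",
                       "channels": ["Tx9-Rx9"], "stage": "sound",
                       "groups": ["soothing", "silence"]}])

    def test_default_plan_schema_on_synthetic_cohort(self, small_study_config):
        from stresskit.synthetic import generate_cohort_arrays
        from stresskit.pipeline import PipelineConfig, process_cohort
        from stresskit.io_formats import results_frame

        cohort = generate_cohort_arrays(small_study_config, seed=3)
        pc = PipelineConfig()
        pc.eda.window_s = 30.0
        pc.fnirs.window_s = 30.0
        out = process_cohort(cohort, pc)
        frame = results_frame(out["results"])
        assert not frame.empty
        assert {"test", "measure", "channel", "statistic", "df", "p",
                "effect_size", "hemisphere", "brodmann_area",
                "significant"} <= set(frame.columns)
        # per-channel rows carry montage annotations
        hbo = frame[(frame.measure == "hbo") & frame.channel.notna()]
        assert hbo.hemisphere.notna().all()
        assert hbo.brodmann_area.notna().all()
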