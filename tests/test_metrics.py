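"""Metric registry structure and per-domain computations."""

import numpy as np
import pandas as pd
import pytest

from actipat.labeling import LabelSeries, NightWindow, SEDENTARY, SLEEP
from actipat.metrics import (
    MVPA_VOLUME_FAMILY,
    build_registry,
    compute_all_metrics,
    compute_fragmentation,
    compute_morning,
    compute_night,
)
from actipat.preprocess import EpochSeries
from actipat.synthetic import ActivityModelParams, generate_cohort, simulate_recording


class TestRegistry:
    def test_counts(self):
        reg = build_registry()
        assert len(reg) == 145
        assert reg.n_registrations() == 147
        assert len(reg.domain_ids("total_volume")) == 77
        assert len(reg.domain_ids("morning")) == 30
        assert len(reg.domain_ids("night")) == 15
        assert len(reg.domain_ids("fragmentation")) == 25

    def test_exactly_two_dual_domain_metrics(self):
        duals = {d.metric_id for d in build_registry() if len(d.domains) == 2}
        assert duals == {"m10_level", "time_ge100_pct"}

    def test_deterministic(self):
        assert build_registry().ids == build_registry().ids

    def test_clock_metrics_tagged_linear(self):
        reg = build_registry()
        linear = {d.metric_id for d in reg if d.linear_scale}
        assert linear == {"sleep_midpoint_mean", "l5_midpoint", "m10_midpoint"}


def _full_week_series(values):
    return EpochSeries("2015-03-02", 30, values)


class TestTotalVolume:
    def test_constant_intensity_fills_one_bin(self):
        m = compute_all_metrics(_full_week_series(np.full(7 * 2880, 60.0)))
        assert m["bin_040_080_pct"] == pytest.approx(100.0)
        for lo in (0, 80, 120, 160, 200, 240, 280, 320, 360):
            hi = lo + 40
            assert m[f"bin_{lo:03d}_{hi:03d}_pct"] == pytest.approx(0.0)
        assert m["time_ge040_pct"] == pytest.approx(100.0)

    def test_constant_mvpa_weekly_minutes(self):
        m = compute_all_metrics(_full_week_series(np.full(7 * 2880, 150.0)))
        assert m["mvpa_weekly_min"] == pytest.approx(10080.0)
        assert m["time_ge100_pct"] == pytest.approx(100.0)

    def test_bin_percentages_close(self):
        rng = np.random.default_rng(0)
        m = compute_all_metrics(_full_week_series(rng.uniform(0, 500, 7 * 2880)))
        total = sum(
            m[f"bin_{lo:03d}_{lo + 40:03d}_pct"] for lo in range(0, 400, 40)
        )
        assert total < 100.0  # some epochs at >= 400 mg
        rng = np.random.default_rng(1)
        m = compute_all_metrics(_full_week_series(rng.uniform(0, 399, 7 * 2880)))
        total = sum(
            m[f"bin_{lo:03d}_{lo + 40:03d}_pct"] for lo in range(0, 400, 40)
        )
        assert total == pytest.approx(100.0)

    def test_zero_wear_days_all_missing(self):
        s = EpochSeries(
            "2015-03-02", 30, np.full(2880, 50.0), np.zeros(2880, bool)
        )
        m = compute_all_metrics(s)
        assert not np.isfinite(m["bin_040_080_pct"])


class TestMorning:
    def test_constant_magnitude_window_stats(self):
        s = _full_week_series(np.full(7 * 2880, 50.0))
        getups = [pd.Timestamp(f"2015-03-0{d} 07:00:00") for d in range(2, 9)]
        m = compute_morning(s, getups)
        assert m["morning_120m_mean"] == pytest.approx(50.0)
        assert m["morning_120m_auc"] == pytest.approx(6000.0)
        assert m["morning_120m_pct_ge040"] == pytest.approx(100.0)
        assert m["morning_120m_mvpa_min"] == pytest.approx(0.0)

    def test_ramp_mean(self):
        values = np.full(7 * 2880, 10.0)
        start = 7 * 120  # 07:00 on day one
        values[start : start + 240] = np.linspace(0, 100, 240)
        s = _full_week_series(values)
        m = compute_morning(s, [pd.Timestamp("2015-03-02 07:00:00")])
        assert m["morning_120m_mean"] == pytest.approx(50.0, abs=1.0)

    def test_no_getups_all_missing(self):
        m = compute_morning(_full_week_series(np.full(7 * 2880, 50.0)), [])
        assert all(not np.isfinite(v) for v in m.values())

    def test_window_past_end_excluded(self):
        s = EpochSeries("2015-03-02", 30, np.full(2880, 50.0))
        late = [pd.Timestamp("2015-03-02 23:00:00")]
        m = compute_morning(s, late)
        assert np.isfinite(m["morning_015m_mean"])
        assert not np.isfinite(m["morning_240m_mean"])  # 4 h crosses the end


def _window(start, end, sleep_epochs, movement, start_epoch, end_epoch):
    return NightWindow(
        night_index=0,
        start=pd.Timestamp(start),
        end=pd.Timestamp(end),
        sleep_epochs=sleep_epochs,
        movement_episodes=movement,
        start_epoch=start_epoch,
        end_epoch=end_epoch,
    )


class TestNight:
    def test_sleep_efficiency_definition(self):
        s = _full_week_series(np.full(7 * 2880, 20.0))
        labels = LabelSeries(
            "2015-03-02", 30, np.full(7 * 2880, SEDENTARY, dtype=np.int8)
        )
        # 480-min window with 432 min of sleep -> efficiency 90
        w = _window(
            "2015-03-02 23:00", "2015-03-03 07:00", 864, 6, 2760, 3720
        )
        m = compute_night(labels, [w], s)
        assert m["sleep_efficiency_mean"] == pytest.approx(90.0)
        # 10% non-sleep over 6 movement episodes
        assert m["rest_fragmentation_mean"] == pytest.approx(10.0 / 6.0)
        assert m["movement_episodes_per_night_mean"] == pytest.approx(6.0)
        assert m["sleep_midpoint_mean"] == pytest.approx(3.0)

    def test_zero_movement_episodes_zero_fragmentation(self):
        s = _full_week_series(np.full(7 * 2880, 20.0))
        labels = LabelSeries(
            "2015-03-02", 30, np.full(7 * 2880, SLEEP, dtype=np.int8)
        )
        w = _window("2015-03-02 23:00", "2015-03-03 07:00", 960, 0, 2760, 3720)
        m = compute_night(labels, [w], s)
        assert m["rest_fragmentation_mean"] == 0.0
        assert m["sleep_efficiency_mean"] == pytest.approx(100.0)

    def test_sinusoidal_profile_l5_m10_midpoints(self):
        hours = (np.arange(7 * 2880) % 2880) / 120.0
        values = 60.0 + 40.0 * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
        m = compute_night(None, [], _full_week_series(values))
        assert m["m10_midpoint"] == pytest.approx(14.0, abs=0.2)
        assert m["l5_midpoint"] == pytest.approx(2.0, abs=0.2)
        assert m["m10_level"] > 60.0 > m["l5_level"]

    def test_no_windows_night_metrics_missing(self):
        m = compute_night(None, [], _full_week_series(np.full(7 * 2880, 20.0)))
        assert not np.isfinite(m["sleep_efficiency_mean"])
        assert np.isfinite(m["m10_level"])  # L5/M10 need only a full day


class TestFragmentation:
    def test_hazard_from_completed_runs(self):
        values = np.array(
            [150.0] * 2 + [20.0] * 3 + [150.0] * 2 + [20.0] * 3 + [150.0] * 2
            + [20.0]
        )
        _, m = compute_fragmentation(None, EpochSeries("2015-03-02", 30, values))
        assert m["hazard_mvpa_to_nonmvpa"] == pytest.approx(0.5)

    def test_transition_probability_hand_count(self):
        # S S A A S S A at the 40 mg binarization
        values = np.array([20.0, 20.0, 60.0, 60.0, 20.0, 20.0, 60.0])
        _, m = compute_fragmentation(None, EpochSeries("2015-03-02", 30, values))
        assert m["tp_sed_to_active"] == pytest.approx(2 / 4)
        assert m["hazard_sed_to_active"] == pytest.approx(0.5)
        # trailing active run has no observed exit
        assert m["tp_active_to_sed"] == pytest.approx(1 / 3)
        assert m["run_active_mean"] == pytest.approx(np.mean([2, 1]) * 0.5)

    def test_constant_state_censored_missing(self):
        _, m = compute_fragmentation(
            None, EpochSeries("2015-03-02", 30, np.full(100, 150.0))
        )
        assert not np.isfinite(m["hazard_mvpa_to_nonmvpa"])
        assert not np.isfinite(m["tp_mvpa_to_nonmvpa"])
        assert np.isfinite(m["run_mvpa_mean"])  # censored run still described

    def test_hazard_equals_tp_on_geometric_runs(self):
        rng = np.random.default_rng(5)
        seq, state = [], 0
        for _ in range(3000):
            ln = rng.geometric(1 / 4 if state else 1 / 10)
            seq.append(np.full(ln, 150.0 if state else 20.0))
            state = 1 - state
        values = np.concatenate(seq)
        _, m = compute_fragmentation(None, EpochSeries("2015-03-02", 30, values))
        assert m["hazard_mvpa_to_nonmvpa"] == pytest.approx(
            m["tp_mvpa_to_nonmvpa"], rel=0.02
        )

    def test_nonwear_censors_runs(self):
        wear = np.ones(10, bool)
        wear[5] = False
        values = np.full(10, 150.0)
        _, m = compute_fragmentation(
            None, EpochSeries("2015-03-02", 30, values, wear)
        )
        # two wear segments, each a censored MVPA run
        assert not np.isfinite(m["hazard_mvpa_to_nonmvpa"])


@pytest.fixture(scope="module")
def recording():
    params = ActivityModelParams(nonwear_episodes_per_day=0.0)
    profile = generate_cohort(1, 2, seed=42)[0]
    return simulate_recording(profile, params, None, seed=42)


class TestOrchestration:
    def test_fully_worn_week_has_no_missing(self, recording):
        series, labels = recording
        m = compute_all_metrics(series, labels)
        missing = [k for k, v in m.items() if not np.isfinite(v)]
        assert missing == []
        assert len(m) == 145

    def test_percentages_within_range(self, recording):
        series, labels = recording
        m = compute_all_metrics(series, labels)
        for mid, v in m.items():
            if mid.endswith("_pct") or "efficiency" in mid:
                assert 0.0 <= v <= 100.0, mid

    def test_mvpa_bout_time_within_total(self, recording):
        series, labels = recording
        m = compute_all_metrics(series, labels)
        assert m["mvpa_bout_min_daily"] <= m["time_ge100_min_daily"] + 1e-9

    def test_whole_week_shift_invariance(self, recording):
        series, labels = recording
        m1 = compute_all_metrics(series, labels)
        shifted = EpochSeries(
            series.start_time + pd.Timedelta(days=7),
            series.epoch_seconds,
            series.values,
            series.wear_mask,
        )
        shifted_labels = LabelSeries(
            labels.start_time + pd.Timedelta(days=7),
            labels.epoch_seconds,
            labels.codes,
        )
        m2 = compute_all_metrics(shifted, shifted_labels)
        for k in m1:
            assert m1[k] == pytest.approx(m2[k], nan_ok=True), k

    def test_fast_family_path_matches_registry_values(self):
        """The vectorized MVPA-family shortcut must reproduce the full
        registry computation exactly."""
        from actipat.validation import _mvpa_family_values

        params = ActivityModelParams()
        profiles = generate_cohort(3, 6, seed=7)[:3]
        recordings = {}
        for i, p in enumerate(profiles):
            series, labels = simulate_recording(p, params, None, seed=100 + i)
            recordings[p.id] = (series, labels)
        fast = _mvpa_family_values(recordings)
        for pid, (series, labels) in recordings.items():
            full = compute_all_metrics(series, labels)
            for mid in MVPA_VOLUME_FAMILY:
                assert fast.loc[pid, mid] == pytest.approx(full[mid]), mid
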