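"""Synthetic cohort and activity generator: determinism, marginals,
circadian structure, injected effects, magnitude distributions."""

import numpy as np
import pytest

from actipat.labeling import LabelSeries, SLEEP
from actipat.synthetic import (
    ActivityModelParams,
    ParticipantProfile,
    RAEffect,
    generate_cohort,
    simulate_cohort_labels,
    simulate_labels,
    simulate_magnitudes,
    simulate_recording,
)


class TestGenerateCohort:
    def test_seeded_determinism(self):
        a = generate_cohort(10, 100, seed=1)
        b = generate_cohort(10, 100, seed=1)
        assert a == b

    def test_counts(self):
        profiles = generate_cohort(10, 100, seed=1)
        assert len(profiles) == 110
        assert sum(p.group == "RA" for p in profiles) == 10

    def test_female_fraction_matches_default(self):
        profiles = generate_cohort(1000, 2000, seed=2)
        ra = [p for p in profiles if p.group == "RA"]
        frac = 100.0 * np.mean([p.sex == "female" for p in ra])
        assert abs(frac - 67.0) < 5.0

    def test_age_over_60_fraction(self):
        profiles = generate_cohort(1000, 2000, seed=3)
        ra = [p for p in profiles if p.group == "RA"]
        frac = 100.0 * np.mean([p.age >= 60 for p in ra])
        assert abs(frac - 74.6) < 5.0

    def test_onset_age_invariant(self):
        for p in generate_cohort(300, 600, seed=4):
            if p.group == "RA":
                assert (p.onset == "late") == (p.age_at_diagnosis >= 60)
            else:
                assert p.onset == "none" and p.age_at_diagnosis is None

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 10, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(10, 15, seed=1)  # pool below 2:1

    def test_control_profile_invariant_enforced(self):
        with pytest.raises(ValueError, match="diagnosis"):
            ParticipantProfile(
                "x", "control", 60, "female", 25, 0.0, onset="late",
                age_at_diagnosis=62.0,
            )


class TestSimulateLabels:
    def test_seeded_determinism(self, params):
        p = generate_cohort(1, 2, seed=1)[0]
        a = simulate_labels(p, params, None, seed=11)
        b = simulate_labels(p, params, None, seed=11)
        assert np.array_equal(a.codes, b.codes)

    def test_length_and_grid(self, params):
        p = generate_cohort(1, 2, seed=1)[0]
        out = simulate_labels(p, params, None, seed=11)
        assert out.n_epochs == 7 * 2880
        assert out.epoch_seconds == 30

    def test_sleep_is_nocturnal(self, params):
        p = generate_cohort(1, 2, seed=1)[0]
        out = simulate_labels(p, params, None, seed=12)
        eod = out.epoch_of_day()
        night = (out.codes == SLEEP)[(eod >= 0) & (eod < 720)].mean()
        afternoon = (out.codes == SLEEP)[(eod >= 1440) & (eod < 2160)].mean()
        assert night > afternoon

    def test_effect_requires_ra_profile(self, params):
        ctrl = [p for p in generate_cohort(1, 2, seed=1) if p.group == "control"][0]
        with pytest.raises(ValueError, match="RA"):
            simulate_labels(ctrl, params, RAEffect(mvpa_time_ratio=0.8), seed=1)

    def test_zero_run_length_rejected(self):
        with pytest.raises(ValueError, match="mean_run_minutes"):
            ActivityModelParams(
                mean_run_minutes={
                    "sleep": 45, "sedentary": 12, "light": 4, "MVPA": 0,
                    "walking": 2.5,
                }
            )

    def test_mvpa_time_ratio_halves_mvpa(self, params):
        """Monte-Carlo round trip: a 0.5 entry-rate ratio halves MVPA time."""
        profiles = generate_cohort(200, 400, seed=5)
        ras = [p for p in profiles if p.group == "RA"]
        ctrls = [p for p in profiles if p.group == "control"][:200]
        effect = RAEffect(mvpa_time_ratio=0.5)
        lab_ra = simulate_cohort_labels(ras, params, effect, seed=21)
        lab_ct = simulate_cohort_labels(ctrls, params, None, seed=22)
        mvpa_ra = np.mean([(l.codes == 3).mean() for l in lab_ra])
        mvpa_ct = np.mean([(l.codes == 3).mean() for l in lab_ct])
        assert 0.4 < mvpa_ra / mvpa_ct < 0.6

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            RAEffect(mvpa_time_ratio=0.0)
        with pytest.raises(ValueError):
            RAEffect(morning_delay_minutes=-5)


class TestSimulateMagnitudes:
    def _all_sleep_labels(self, days=7):
        return LabelSeries("2015-03-02", 30, np.zeros(days * 2880, dtype=np.int8))

    def test_sleep_median_recovered(self):
        params = ActivityModelParams(
            magnitude_dist={
                "sleep": (15.0, 1.8), "sedentary": (9.0, 1.9),
                "light": (60.0, 1.15), "MVPA": (180.0, 1.25),
                "walking": (55.0, 1.2),
            },
            nonwear_episodes_per_day=0.0,
            magnitude_frailty_sigma=0.0,
        )
        out = simulate_magnitudes(self._all_sleep_labels(), params, seed=3)
        assert 13.0 <= np.median(out.values) <= 17.0

    def test_degenerate_gsd_gives_median(self):
        params = ActivityModelParams(
            magnitude_dist={
                "sleep": (15.0, 1.0), "sedentary": (9.0, 1.0),
                "light": (60.0, 1.0), "MVPA": (180.0, 1.0), "walking": (55.0, 1.0),
            },
            nonwear_episodes_per_day=0.0,
            magnitude_frailty_sigma=0.0,
        )
        out = simulate_magnitudes(self._all_sleep_labels(days=1), params, seed=4)
        assert np.allclose(out.values, 15.0, atol=1e-4)

    def test_zero_nonwear_rate_all_wear(self, params_no_nonwear):
        out = simulate_magnitudes(
            self._all_sleep_labels(), params_no_nonwear, seed=5
        )
        assert out.wear_mask.all()

    def test_nonwear_label_rejected(self, params):
        labels = LabelSeries("2015-03-02", 30, np.full(2880, 5, dtype=np.int8))
        with pytest.raises(ValueError, match="state set"):
            simulate_magnitudes(labels, params, seed=6)

    def test_recording_reconciles_nonwear(self, params):
        p = generate_cohort(1, 2, seed=9)[0]
        series, labels = simulate_recording(p, params, None, seed=31)
        assert np.array_equal(labels.codes == 5, ~series.wear_mask)


class TestBatchConsistency:
    def test_cohort_labels_deterministic(self, params):
        profiles = generate_cohort(5, 10, seed=6)
        a = simulate_cohort_labels(profiles, params, None, seed=7)
        b = simulate_cohort_labels(profiles, params, None, seed=7)
        assert all(np.array_equal(x.codes, y.codes) for x, y in zip(a, b))

    def test_effect_changes_only_targeted_component(self, params):
        """mvpa_run_ratio shortens MVPA runs but leaves sleep timing alone."""
        from actipat.labeling import run_length_encode

        profiles = [p for p in generate_cohort(150, 300, seed=8) if p.group == "RA"]
        base = simulate_cohort_labels(profiles, params, None, seed=9)
        short = simulate_cohort_labels(
            profiles, params, RAEffect(mvpa_run_ratio=0.5), seed=9
        )

        def mean_mvpa_run(labs):
            lens = []
            for l in labs:
                _, ln, v = run_length_encode(l.codes)
                lens.extend(ln[v == 3])
            return np.mean(lens)

        def sleep_midnight_frac(labs):
            fr = []
            for l in labs:
                eod = l.epoch_of_day()
                fr.append((l.codes == SLEEP)[(eod < 720)].mean())
            return np.mean(fr)

        ratio = mean_mvpa_run(short) / mean_mvpa_run(base)
        assert 0.4 < ratio < 0.65
        assert abs(sleep_midnight_frac(short) - sleep_midnight_frac(base)) < 0.02
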