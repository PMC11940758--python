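"""Screening statistics, ANOVA/ANCOVA, wake-aligned profiles, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from actipat.labeling import LabelSeries, SEDENTARY, consolidate_nights
from actipat.stats import (
    ScreenConfig,
    activity_profiles,
    ancova,
    anova_oneway,
    pca,
    screen_metric,
)
from actipat.synthetic import (
    ActivityModelParams,
    RAEffect,
    generate_cohort,
    simulate_cohort_labels,
)


class TestScreenMetric:
    def test_identical_groups_ratio_one(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 0.2, 200)
        r = screen_metric(x, x.copy())
        assert r.ratio == pytest.approx(1.0)
        assert not r.flagged
        assert r.ci_low <= r.ratio <= r.ci_high

    def test_known_ratio_recovered_and_flagged(self):
        rng = np.random.default_rng(1)
        ctrl = rng.lognormal(0, 0.1, 500)
        ra = rng.lognormal(0, 0.1, 500) * 0.8
        r = screen_metric(ra, ctrl)
        assert 0.78 <= r.ratio <= 0.82
        assert r.flagged

    def test_small_ratio_with_tight_ci_not_flagged(self):
        rng = np.random.default_rng(2)
        ctrl = rng.lognormal(0, 0.01, 2000)
        ra = rng.lognormal(0, 0.01, 2000) * 1.04
        r = screen_metric(ra, ctrl)
        assert r.ci_low > 1.0  # CI excludes 1 ...
        assert not r.flagged  # ... but the 5% magnitude rule fails

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0.2, 0.3, 120)
        b = rng.lognormal(0.0, 0.4, 240)
        fwd = screen_metric(a, b)
        rev = screen_metric(b, a)
        assert fwd.ratio == pytest.approx(1.0 / rev.ratio)
        assert fwd.ci_low == pytest.approx(1.0 / rev.ci_high)
        assert fwd.ci_high == pytest.approx(1.0 / rev.ci_low)
        assert fwd.flagged == rev.flagged

    def test_zero_offset_applied(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        r = screen_metric(a, b)  # offset = half the smallest positive value
        assert np.isfinite(r.ratio) and r.ratio < 1.0

    def test_linear_scale_difference(self):
        rng = np.random.default_rng(4)
        a = rng.normal(14.5, 1.0, 300)
        b = rng.normal(14.0, 1.0, 600)
        r = screen_metric(a, b, ScreenConfig(linear_scale=True))
        assert r.ratio == pytest.approx(0.5, abs=0.25)  # arithmetic difference
        assert r.flagged == (r.ci_low > 0 or r.ci_high < 0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            screen_metric([1.0], [1.0, 2.0])


class TestAnova:
    def test_identical_groups_no_effect(self):
        x = np.concatenate([np.arange(1, 11.0)] * 2)
        g = ["a"] * 10 + ["b"] * 10
        f, p = anova_oneway(x, g)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 0.5, 80)
        g = np.array(["a"] * 40 + ["b"] * 40)
        f, p = anova_oneway(x, g)
        t, pt = sps.ttest_ind(np.log(x[:40]), np.log(x[40:]), equal_var=True)
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(pt)

    def test_underfilled_level_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0], ["a", "a"])


class TestAncova:
    def test_independent_covariate_preserves_anova(self):
        rng = np.random.default_rng(6)
        n = 4000
        g = np.array(["RA"] * (n // 2) + ["ctrl"] * (n // 2))
        cov = rng.choice(["x", "y", "z"], n)
        vals = rng.lognormal(0, 0.3, n) * np.where(g == "RA", 0.9, 1.0)
        _, p_anova = anova_oneway(vals, g)
        _, p_ancova = ancova(vals, g, cov)
        # both should be overwhelmingly significant and similar on z-scale
        z_a = sps.norm.isf(max(p_anova, 1e-300) / 2)
        z_c = sps.norm.isf(max(p_ancova, 1e-300) / 2)
        assert abs(z_a - z_c) < 1.5

    def test_confounded_effect_removed_by_adjustment(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.normal(0, 1, n)
        g = np.where(x > 0, "RA", "ctrl")
        vals = np.exp(0.5 * x + rng.normal(0, 0.2, n))  # effect fully via x
        raw_effect = np.log(
            np.exp(np.log(vals[g == "RA"]).mean())
            / np.exp(np.log(vals[g == "ctrl"]).mean())
        )
        adj_effect, _ = ancova(vals, g, x)
        assert abs(raw_effect) > 0.5
        assert abs(adj_effect) < 0.1

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ancova([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], [5, 5, 5, 5])


def _sedentary_participant(pid, days=2):
    codes = np.full(days * 2880, SEDENTARY, dtype=np.int8)
    return LabelSeries("2015-03-02", 30, codes)


class TestActivityProfiles:
    def test_always_sedentary_curve_is_one(self):
        labels = {
            "a": _sedentary_participant("a"),
            "b": _sedentary_participant("b"),
        }
        getups = {k: [pd.Timestamp("2015-03-02 07:00")] for k in labels}
        groups = {"a": "RA", "b": "control"}
        pm = activity_profiles(labels, getups, groups, horizon_hours=6.0)
        i_sed = pm.labels.index("sedentary")
        for g in ("RA", "control"):
            assert np.allclose(pm.group_probs[g][i_sed], 1.0)
        assert np.allclose(pm.difference, 0.0)

    def test_probabilities_sum_to_one(self):
        params = ActivityModelParams(days=3, nonwear_episodes_per_day=0.0)
        profiles = generate_cohort(5, 10, seed=8)
        labs = simulate_cohort_labels(profiles, params, None, seed=9)
        labels = {p.id: l for p, l in zip(profiles, labs)}
        getups = {
            pid: [w.end for w in consolidate_nights(l)]
            for pid, l in labels.items()
        }
        groups = {p.id: p.group for p in profiles}
        pm = activity_profiles(labels, getups, groups, horizon_hours=10.0)
        for g, probs in pm.group_probs.items():
            has = np.isfinite(probs).all(axis=0)
            assert np.allclose(probs[:, has].sum(axis=0), 1.0, atol=1e-9)

    def test_morning_delay_lowers_early_mvpa(self):
        """Round trip of the morning-delay effect through the profile."""
        params = ActivityModelParams(days=5, nonwear_episodes_per_day=0.0)
        profiles = generate_cohort(25, 50, seed=10)
        ras = [p for p in profiles if p.group == "RA"]
        ctrls = [p for p in profiles if p.group == "control"]
        effect = RAEffect(morning_delay_minutes=90.0)
        lab_ra = simulate_cohort_labels(ras, params, effect, seed=11)
        lab_ct = simulate_cohort_labels(ctrls, params, None, seed=12)
        labels = {p.id: l for p, l in zip(ras + ctrls, lab_ra + lab_ct)}
        getups = {
            pid: [w.end for w in consolidate_nights(l)]
            for pid, l in labels.items()
        }
        groups = {p.id: p.group for p in profiles}
        pm = activity_profiles(labels, getups, groups, horizon_hours=12.0)
        i_mvpa = pm.labels.index("MVPA")
        early = slice(0, int(2 * 3600 / 30))  # first 2 h since wake
        assert np.nanmean(pm.difference[i_mvpa, early]) < 0.0

    def test_empty_group_rejected(self):
        labels = {"a": _sedentary_participant("a")}
        getups = {"a": [pd.Timestamp("2015-03-02 07:00")]}
        with pytest.raises(ValueError, match="group"):
            activity_profiles(labels, getups, {"a": "RA"})


class TestPCA:
    def test_rank_one_case(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal(50)
        m = pd.DataFrame({"a": base, "b": 2.0 * base + 1.0})
        res = pca(m)
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert res.n_components_selected == 1

    def test_uncorrelated_noise_equal_fractions(self):
        rng = np.random.default_rng(12)
        p = 5
        m = pd.DataFrame(rng.standard_normal((4000, p)))
        res = pca(m)
        assert np.allclose(res.variance_fraction, 1.0 / p, atol=0.02)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.standard_normal((60, 8)))
        res = pca(m)
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.standard_normal((80, 6)))
        res = pca(m)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_missing_metric_excluded(self):
        rng = np.random.default_rng(15)
        m = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        m.loc[m.index[3], "c"] = np.nan
        res = pca(m)
        assert res.excluded_for_missingness == ["c"]
        assert "c" not in res.included_metrics

    def test_too_few_metrics_rejected(self):
        rng = np.random.default_rng(16)
        m = pd.DataFrame({"a": rng.standard_normal(30), "b": np.nan})
        with pytest.raises(ValueError, match="at least 2"):
            pca(m)
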