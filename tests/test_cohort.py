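"""Eligibility filters, demographic categorization, 2:1 matching."""

import numpy as np
import pytest

from actipat.cohort import (
    FilterConfig,
    MatchConfig,
    adi_quintile_edges,
    apply_filters,
    categorize,
    match,
)
from actipat.synthetic import ParticipantProfile, generate_cohort


def _profile(pid, group="control", age=60.0, sex="female", bmi=26.0, adi=0.0, **kw):
    return ParticipantProfile(pid, group, age, sex, bmi, adi, **kw)


class TestApplyFilters:
    def test_comorbidity_excluded_and_logged(self):
        profiles = [
            _profile("a", comorbidities=("heart_failure",)),
            _profile("b"),
        ]
        kept, log = apply_filters(profiles)
        assert [p.id for p in kept] == ["b"]
        assert log["comorbidity:heart_failure"] == 1

    def test_rheumatoid_factor_threshold(self):
        above = _profile("a", rheumatoid_factor=25.0)
        below = _profile("b", rheumatoid_factor=15.0)
        untested = _profile("c")
        kept, log = apply_filters([above, below, untested])
        assert [p.id for p in kept] == ["b", "c"]
        assert log["rheumatoid_factor_above_normal"] == 1

    def test_diagnosis_after_recording_excluded(self):
        p = _profile(
            "a", group="RA", diagnosis_source="self_report",
            diagnosis_type="other", onset="early", age_at_diagnosis=50.0,
            diagnosed_after_recording=True,
        )
        kept, log = apply_filters([p])
        assert kept == []
        assert log["diagnosis_after_recording"] == 1

    def test_duplicate_diagnosis_keeps_most_tangible(self):
        p = _profile(
            "a", group="RA", diagnosis_source="self_report",
            diagnosis_type="other", onset="early", age_at_diagnosis=50.0,
            duplicate_diagnosis_sources=("primary_care", "self_report"),
        )
        kept, log = apply_filters([p])
        assert kept[0].diagnosis_source == "primary_care"
        assert log["duplicate_diagnosis_resolved"] == 1

    def test_empty_filter_set_is_identity(self):
        profiles = [
            _profile("a", comorbidities=("stroke",)),
            _profile("b", rheumatoid_factor=99.0),
        ]
        cfg = FilterConfig(
            excluded_comorbidities=(),
            rf_threshold=np.inf,
            exclude_diagnosis_after_recording=False,
            resolve_duplicate_diagnoses=False,
        )
        kept, log = apply_filters(profiles, cfg)
        assert kept == profiles
        assert log == {}


class TestCategorize:
    edges = np.array([-2.0, -1.0, 0.0, 1.0])

    def test_age_bins_five_year_increments(self):
        cfg = MatchConfig()
        sex, age_bin, _, _ = categorize(_profile("a", age=63.0), cfg, self.edges)
        assert age_bin == 3  # [60, 65)
        assert categorize(_profile("b", age=45.0), cfg, self.edges)[1] == 0
        assert categorize(_profile("c", age=80.0), cfg, self.edges)[1] == 6

    def test_bmi_classes(self):
        cfg = MatchConfig()
        assert categorize(_profile("a", bmi=27.0), cfg, self.edges)[2] == 2
        assert categorize(_profile("b", bmi=17.0), cfg, self.edges)[2] == 0
        assert categorize(_profile("c", bmi=41.0), cfg, self.edges)[2] == 4

    def test_adi_quintiles_from_case_edges(self):
        cfg = MatchConfig()
        assert categorize(_profile("a", adi=-5.0), cfg, self.edges)[3] == 0
        assert categorize(_profile("b", adi=5.0), cfg, self.edges)[3] == 4

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            categorize(_profile("a", age=44.0), MatchConfig(), self.edges)

    def test_quintile_edges_are_case_derived(self):
        cases = [_profile(f"c{i}", adi=float(i)) for i in range(100)]
        edges = adi_quintile_edges(cases)
        assert np.allclose(edges, [19.8, 39.6, 59.4, 79.2])


class TestMatch:
    def _exact_pool(self, n_cases, seed=0):
        rng = np.random.default_rng(seed)
        cases, pool = [], []
        for i in range(n_cases):
            kw = dict(
                age=float(rng.uniform(46, 79)),
                sex="female" if rng.random() < 0.5 else "male",
                bmi=float(rng.uniform(19, 39)),
                adi=float(rng.normal(0, 2)),
            )
            cases.append(_profile(f"RA{i}", "RA", **kw))
            pool += [_profile(f"C{i}_{j}", "control", **kw) for j in range(2)]
        return cases, pool

    def test_exact_duplicates_all_matched_without_reuse(self):
        cases, pool = self._exact_pool(30)
        cohort = match(cases, pool, MatchConfig(seed=1))
        assert len(cohort.pairs) == 30
        assert cohort.unmatched_cases == []
        controls = cohort.control_ids
        assert len(controls) == len(set(controls)) == 60

    def test_exact_matching_shares_category(self):
        cases, pool = self._exact_pool(20, seed=3)
        cfg = MatchConfig(seed=2)
        cohort = match(cases, pool, cfg)
        edges = adi_quintile_edges(cases)
        by_id = {p.id: p for p in cases + pool}
        for cid, ctrls in cohort.pairs.items():
            cat = categorize(by_id[cid], cfg, edges)
            for ctrl in ctrls:
                assert categorize(by_id[ctrl], cfg, edges) == cat

    def test_balance_exact_at_distance_zero(self):
        cases, pool = self._exact_pool(25, seed=4)
        cohort = match(cases, pool, MatchConfig(seed=5))
        balance = cohort.balance
        assert (balance.loc["control"] == 2 * balance.loc["RA"]).all()

    def test_insufficient_pool_unmatched(self):
        cases = [_profile("RA0", "RA")]
        pool = [_profile("C0", "control")]
        cohort = match(cases, pool, MatchConfig(seed=1))
        assert cohort.unmatched_cases == ["RA0"]
        assert cohort.pairs == {}

    def test_competition_is_seeded_and_reproducible(self):
        kw = dict(age=60.0, sex="female", bmi=26.0, adi=0.0)
        cases = [_profile("RA0", "RA", **kw), _profile("RA1", "RA", **kw)]
        pool = [
            _profile("C0", "control", **kw),
            _profile("C1", "control", **kw),
            _profile("C2", "control", age=50.0, sex="male", bmi=20.0, adi=3.0),
        ]
        cfg = MatchConfig(seed=11)
        a = match(cases, pool, cfg)
        assert len(a.pairs) == 1  # only one case can take the two exact controls
        assert len(a.unmatched_cases) == 1
        b = match(cases, pool, cfg)
        assert a.pairs == b.pairs and a.unmatched_cases == b.unmatched_cases

    def test_sex_never_crossed_even_with_slack(self):
        cases = [_profile("RA0", "RA", sex="female")]
        pool = [_profile("C0", "control", sex="male"), _profile("C1", "control", sex="male")]
        cohort = match(cases, pool, MatchConfig(seed=1, max_distance=10))
        assert cohort.unmatched_cases == ["RA0"]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            match([_profile("RA0", "RA")], [], MatchConfig())

    def test_generated_cohort_no_control_reuse(self):
        profiles = generate_cohort(40, 400, seed=6)
        cases = [p for p in profiles if p.group == "RA"]
        pool = [p for p in profiles if p.group == "control"]
        cohort = match(cases, pool, MatchConfig(seed=7, max_distance=1))
        controls = cohort.control_ids
        assert len(controls) == len(set(controls))
        assert len(cohort.pairs) + len(cohort.unmatched_cases) == len(cases)
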