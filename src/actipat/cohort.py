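"""Eligibility filtering and 2:1 matched case-control construction.

Cases and controls are matched without replacement on categorized
demographics: sex (hard constraint), 5-year age bins over 45-80, WHO BMI
classes, and area-deprivation quintiles whose edges come from the case
group's empirical distribution. The default caliper is exact-category
matching (distance 0); cases that cannot obtain the full complement of
controls within the caliper are recorded as unmatched.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import ParticipantProfile

__all__ = [
    "FilterConfig",
    "MatchConfig",
    "MatchedCohort",
    "apply_filters",
    "adi_quintile_edges",
    "categorize",
    "match",
]

#: Rheumatoid-factor concentrations above this (IU/mL) exclude a control.
RF_THRESHOLD_IU_ML = 20.0

BMI_EDGES = (18.5, 25.0, 30.0, 40.0)
AGE_MIN, AGE_MAX = 45.0, 80.0

#: "Most tangible" diagnosis source first, for duplicate resolution.
SOURCE_PRIORITY = ("primary_care", "hospital", "self_report")


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion rules applied before matching."""

    excluded_comorbidities: tuple = (
        "heart_failure",
        "respiratory_failure",
        "stroke",
        "thyroiditis",
        "sjogren_syndrome",
    )
    rf_threshold: float = RF_THRESHOLD_IU_ML
    exclude_diagnosis_after_recording: bool = True
    resolve_duplicate_diagnoses: bool = True


@dataclass(frozen=True)
class MatchConfig:
    """Matching design: ratio, category bins, caliper, seed."""

    ratio: int = 2
    max_distance: int = 0  # category steps; 0 = exact matching
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be at least 1")
        if self.max_distance < 0:
            raise ValueError("max_distance must be non-negative")


@dataclass
class MatchedCohort:
    """2:1 (or ratio:1) matched case-control structure."""

    pairs: dict  # case id -> tuple of control ids
    unmatched_cases: list
    balance: pd.DataFrame  # per-variable category frequencies by group

    @property
    def matched_case_ids(self) -> list:
        return list(self.pairs)

    @property
    def control_ids(self) -> list:
        return [cid for ctrls in self.pairs.values() for cid in ctrls]


def apply_filters(
    profiles: Sequence[ParticipantProfile],
    config: Optional[FilterConfig] = None,
) -> tuple:
    """Apply eligibility exclusions; returns (kept profiles, exclusion log).

    Rules: configured comorbidity history excludes anyone; RA diagnosis
    dated after the recording excludes the case; controls with a
    rheumatoid-factor result above the threshold are excluded; duplicate
    RA diagnosis records are resolved (not excluded) by keeping the most
    tangible source: primary care over hospital over self-report.
    """
    config = config or FilterConfig()
    kept = []
    log = Counter()
    for p in profiles:
        bad = [c for c in p.comorbidities if c in config.excluded_comorbidities]
        if bad:
            log[f"comorbidity:{bad[0]}"] += 1
            continue
        if (
            config.exclude_diagnosis_after_recording
            and p.group == "RA"
            and p.diagnosed_after_recording
        ):
            log["diagnosis_after_recording"] += 1
            continue
        if (
            p.group == "control"
            and p.rheumatoid_factor is not None
            and p.rheumatoid_factor > config.rf_threshold
        ):
            log["rheumatoid_factor_above_normal"] += 1
            continue
        if (
            config.resolve_duplicate_diagnoses
            and len(p.duplicate_diagnosis_sources) > 1
        ):
            best = min(
                p.duplicate_diagnosis_sources,
                key=lambda s: SOURCE_PRIORITY.index(s),
            )
            if best != p.diagnosis_source:
                from dataclasses import replace

                p = replace(p, diagnosis_source=best)
            log["duplicate_diagnosis_resolved"] += 1
        kept.append(p)
    return kept, dict(log)


def adi_quintile_edges(cases: Sequence[ParticipantProfile]) -> np.ndarray:
    """Quintile edges of the case group's ADI distribution (4 cuts)."""
    adis = np.array([p.adi for p in cases], float)
    return np.quantile(adis, [0.2, 0.4, 0.6, 0.8])


def categorize(
    profile: ParticipantProfile,
    config: MatchConfig,
    adi_edges: np.ndarray,
) -> tuple:
    """Matching category: (sex, age bin, BMI class, ADI quintile).

    Age bins are 5-year increments over [45, 80]; BMI classes are
    underweight (<18.5), healthy (18.5-25), overweight (25-30), obese
    (30-40), severely obese (>=40); ADI quintile indices come from the
    supplied case-derived edges.
    """
    if not AGE_MIN <= profile.age <= AGE_MAX:
        raise ValueError(
            f"age {profile.age:.1f} outside the matchable range "
            f"[{AGE_MIN:.0f}, {AGE_MAX:.0f}]"
        )
    age_bin = min(int((profile.age - AGE_MIN) // 5), 6)
    bmi_bin = int(np.searchsorted(BMI_EDGES, profile.bmi, side="right"))
    adi_bin = int(np.searchsorted(adi_edges, profile.adi, side="right"))
    return (profile.sex, age_bin, bmi_bin, adi_bin)


def _distance(cat_a: tuple, cat_b: tuple) -> float:
    if cat_a[0] != cat_b[0]:
        return np.inf
    return sum(abs(a - b) for a, b in zip(cat_a[1:], cat_b[1:]))


def _balance_table(
    cases: list, controls: list, config: MatchConfig, adi_edges
) -> pd.DataFrame:
    rows = []
    for group, profs in (("RA", cases), ("control", controls)):
        for p in profs:
            sex, age_bin, bmi_bin, adi_bin = categorize(p, config, adi_edges)
            rows.append(
                {
                    "group": group,
                    "sex": sex,
                    "age_bin": age_bin,
                    "bmi_bin": bmi_bin,
                    "adi_quintile": adi_bin,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    tables = []
    for var in ("sex", "age_bin", "bmi_bin", "adi_quintile"):
        t = pd.crosstab(df["group"], df[var])
        t.columns = [f"{var}={c}" for c in t.columns]
        tables.append(t)
    return pd.concat(tables, axis=1).fillna(0).astype(int)


def match(
    cases: Sequence[ParticipantProfile],
    pool: Sequence[ParticipantProfile],
    config: Optional[MatchConfig] = None,
) -> MatchedCohort:
    """Nearest-neighbor matching without replacement on category tuples.

    Cases are processed in seeded random order; each takes its ``ratio``
    nearest pool controls by category distance (infinite across sexes).
    A case is all-or-nothing: if any of its controls would exceed
    ``max_distance`` it is recorded unmatched and consumes no controls.
    Deterministic given the config seed.
    """
    config = config or MatchConfig()
    if not pool:
        raise ValueError("control pool is empty")
    case_ids = {p.id for p in cases}
    if case_ids & {p.id for p in pool}:
        raise ValueError("pool must be disjoint from cases")
    adi_edges = adi_quintile_edges(cases)
    case_cats = {p.id: categorize(p, config, adi_edges) for p in cases}
    pool_cats = [categorize(p, config, adi_edges) for p in pool]

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(cases))
    available = np.ones(len(pool), dtype=bool)
    pairs = {}
    unmatched = []
    pool_ids = [p.id for p in pool]
    for ci in order:
        case = cases[ci]
        cat = case_cats[case.id]
        dists = np.array(
            [
                _distance(cat, pool_cats[j]) if available[j] else np.inf
                for j in range(len(pool))
            ]
        )
        picked = np.argsort(dists, kind="stable")[: config.ratio]
        if len(picked) < config.ratio or np.any(
            dists[picked] > config.max_distance
        ):
            unmatched.append(case.id)
            continue
        pairs[case.id] = tuple(pool_ids[j] for j in picked)
        available[picked] = False
    # preserve original case order in the output
    pairs = {p.id: pairs[p.id] for p in cases if p.id in pairs}
    matched_cases = [p for p in cases if p.id in pairs]
    used = {cid for ctrls in pairs.values() for cid in ctrls}
    matched_controls = [p for p in pool if p.id in used]
    balance = _balance_table(matched_cases, matched_controls, config, adi_edges)
    return MatchedCohort(pairs=pairs, unmatched_cases=unmatched, balance=balance)
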