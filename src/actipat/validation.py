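"""Self-validation experiments for the analysis pipeline.

Each function runs one structural or statistical check end to end —
registry counts, bout-detector/oracle equivalence, fragmentation
identities, null-screening calibration, injected-effect recovery,
wear-time boundary behavior, exact matching, and profile/PCA sanity —
and returns plain numbers. The test suite asserts on these numbers and
the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bouts import BoutConfig, detect_bouts, oracle_bouts
from .cohort import MatchConfig, match
from .labeling import consolidate_nights
from .metrics import (
    MVPA_VOLUME_FAMILY,
    build_registry,
    compute_all_metrics,
    compute_fragmentation,
)
from .preprocess import EpochSeries, check_validity
from .stats import ScreenConfig, activity_profiles, pca, screen_matrix
from .synthetic import (
    ActivityModelParams,
    ParticipantProfile,
    RAEffect,
    _magnitudes_batch,
    generate_cohort,
    simulate_cohort_labels,
)

MVPA_CUT = 100.0


def registry_counts() -> dict:
    reg = build_registry()
    return {
        "unique_metrics": len(reg),
        "registrations": reg.n_registrations(),
        "total_volume": len(reg.domain_ids("total_volume")),
        "morning": len(reg.domain_ids("morning")),
        "night": len(reg.domain_ids("night")),
        "fragmentation": len(reg.domain_ids("fragmentation")),
    }


# ---------------------------------------------------------------------------
# bout equivalence
# ---------------------------------------------------------------------------


def _random_bout_series(rng: np.random.Generator, max_len: int) -> EpochSeries:
    """Random binary-intensity series with occasional non-wear epochs."""
    n = int(rng.integers(10, max_len + 1))
    p_hi = rng.uniform(0.2, 0.9)
    values = np.where(rng.random(n) < p_hi, 150.0, 20.0)
    wear = rng.random(n) > 0.03
    return EpochSeries("2015-03-02", 30, values, wear)


def bout_oracle_equivalence(
    n_sequences: int = 1000, max_len: int = 500, seed: int = 0
) -> dict:
    """Fast detector vs brute-force oracle on random sequences.

    Cycles break tolerances 0-2 and minimum durations 3-10 minutes.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    for k in range(n_sequences):
        series = _random_bout_series(rng, max_len)
        config = BoutConfig(
            "MVPA",
            min_duration_minutes=float(3 + k % 8),
            break_tolerance_epochs=k % 3,
        )
        fast = detect_bouts(series, config)
        slow = oracle_bouts(series, config)
        if [(b.start_epoch, b.end_epoch) for b in fast] != [
            (b.start_epoch, b.end_epoch) for b in slow
        ]:
            mismatches += 1
    return {
        "n_sequences": n_sequences,
        "n_mismatches": mismatches,
        "agreement_pct": 100.0 * (n_sequences - mismatches) / n_sequences,
    }


# ---------------------------------------------------------------------------
# fragmentation identities
# ---------------------------------------------------------------------------


def fragmentation_identities(seed: int = 0, n_epochs: int = 100_000) -> dict:
    """Hazard identity on a random sequence + hazard/transition-probability
    agreement on censoring-free geometric runs.

    The hazard identity is checked against an independent run scan; the
    geometric check simulates alternating geometric sojourns of ~10 and
    ~4 epochs over ``n_epochs`` epochs.
    """
    rng = np.random.default_rng(seed)
    # arbitrary sequence: hazard must equal 1/mean completed MVPA run
    values = np.where(rng.random(4000) < 0.3, 150.0, 20.0)
    series = EpochSeries("2015-03-02", 30, values)
    _, m = compute_fragmentation(None, series)
    binary = values >= MVPA_CUT
    runs, cur = [], 0
    for i, b in enumerate(binary):
        if b:
            cur += 1
        elif cur:
            runs.append(cur)  # run completed by a non-MVPA epoch
            cur = 0
    # trailing run (cur > 0) is censored: no observed exit
    hazard_by_hand = 1.0 / np.mean(runs)
    identity_gap = abs(m["hazard_mvpa_to_nonmvpa"] - hazard_by_hand)

    # censoring-free geometric runs: alternate MVPA/non-MVPA sojourns
    p_mvpa, p_non = 1 / 4.0, 1 / 10.0
    seq = []
    total = 0
    state = 0
    while total < n_epochs:
        ln = int(rng.geometric(p_mvpa if state else p_non))
        seq.append(np.full(ln, 150.0 if state else 20.0))
        total += ln
        state = 1 - state
    values = np.concatenate(seq)[:n_epochs]
    series = EpochSeries("2015-03-02", 30, values)
    _, m = compute_fragmentation(None, series)
    hz = m["hazard_mvpa_to_nonmvpa"]
    tp = m["tp_mvpa_to_nonmvpa"]
    return {
        "identity_gap": float(identity_gap),
        "hazard_mvpa": float(hz),
        "tp_mvpa": float(tp),
        "relative_gap_pct": float(100.0 * abs(hz - tp) / tp),
        "expected_hazard": p_mvpa,
    }


# ---------------------------------------------------------------------------
# screening calibration and effect recovery
# ---------------------------------------------------------------------------


def _simulate_cohort_recordings(
    n_ra: int,
    n_ctrl: int,
    effect,
    params: ActivityModelParams,
    seed: int,
):
    """Profiles + per-participant (series, labels) for a two-group cohort."""
    profiles = generate_cohort(n_ra, max(n_ctrl, 2 * n_ra), seed)
    profiles = [p for p in profiles if p.group == "RA"][:n_ra] + [
        p for p in profiles if p.group == "control"
    ][:n_ctrl]
    labels = simulate_cohort_labels(profiles, params, effect, seed + 1)
    rng = np.random.default_rng(seed + 2)
    codes = np.stack([l.codes for l in labels])
    values, wear = _magnitudes_batch(codes, params, rng)
    recordings = {}
    for i, p in enumerate(profiles):
        series = EpochSeries(
            labels[i].start_time, params.epoch_seconds, values[i], wear[i]
        )
        recordings[p.id] = (series, labels[i].with_nonwear(wear[i]))
    return profiles, recordings


def screening_calibration(
    seed: int = 0,
    n_ra: int = 300,
    n_ctrl: int = 600,
    n_screens: int = 500,
    n_pools: int = 2,
) -> dict:
    """Null calibration of the ratio screen.

    Effect-free participant pools are simulated and their full metric
    matrices computed; each of ``n_screens`` screens then compares a
    fresh, independently drawn null assignment of 300 "cases" vs 600
    "controls" on one registry metric (rotating through the catalogue).
    Independent group assignments keep the screens nearly independent, so
    under the null the 95% CI should exclude its null value in about 5%
    of screens; the flagged fraction (which adds the 5% magnitude rule)
    can only be smaller or equal.
    """
    from .stats import screen_metric

    params = ActivityModelParams()
    registry = build_registry()
    linear_ids = {d.metric_id for d in registry if d.linear_scale}
    pool_size = n_ra + n_ctrl
    matrices = []
    for k in range(n_pools):
        _, recordings = _simulate_cohort_recordings(
            n_ra, n_ctrl, None, params, seed + 1000 * k
        )
        matrices.append(
            pd.DataFrame.from_dict(
                {
                    pid: compute_all_metrics(series, labels, registry)
                    for pid, (series, labels) in recordings.items()
                },
                orient="index",
                columns=registry.ids,
            ).to_numpy(float)
        )
    rng = np.random.default_rng(seed + 77)
    excluded = np.zeros(n_screens, dtype=bool)
    flagged = np.zeros(n_screens, dtype=bool)
    for i in range(n_screens):
        mat = matrices[i % n_pools]
        col = mat[:, i % len(registry.ids)]
        mid = registry.ids[i % len(registry.ids)]
        perm = rng.permutation(pool_size)
        a = col[perm[:n_ra]]
        b = col[perm[n_ra:]]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            continue  # unscreenable draw; leave as non-excluded
        cfg = ScreenConfig(linear_scale=mid in linear_ids)
        try:
            r = screen_metric(a, b, cfg, metric_id=mid)
        except ValueError:
            continue
        null = 0.0 if r.linear_scale else 1.0
        excluded[i] = r.ci_low > null or r.ci_high < null
        flagged[i] = r.flagged
    return {
        "n_screens": n_screens,
        "n_pools": n_pools,
        "ci_exclusion_pct": float(100.0 * excluded.mean()),
        "flagged_pct": float(100.0 * flagged.mean()),
    }


def _mvpa_family_values(recordings: dict) -> pd.DataFrame:
    """MVPA-volume family metrics, one participant per recording.

    Same definitions as :func:`actipat.metrics.compute_all_metrics`
    (checked by a dedicated test), restricted to the family so that
    replicated experiments stay cheap; bout detection goes through the
    production detector core.
    """
    from .bouts import DEFAULT_MIN_DURATION, _bouts_from_masks

    rows = {}
    for pid, (series, _) in recordings.items():
        epm = series.epoch_seconds / 60.0
        day = series.day_index()
        n_days = int(day[-1]) + 1
        wear = series.wear_mask
        ge100 = (series.values >= MVPA_CUT) & wear
        wear_days = np.unique(day[wear])
        mins = (np.bincount(day[ge100], minlength=n_days) * epm)[wear_days]
        wearsum = wear.sum()
        min_epochs = int(round(DEFAULT_MIN_DURATION["MVPA"] * 60 / series.epoch_seconds))
        bouts = _bouts_from_masks(ge100, ~wear, 1, min_epochs)
        cover = np.zeros(series.n_epochs, dtype=bool)
        for b in bouts:
            cover[b.start_epoch : b.end_epoch + 1] = True
        cover &= wear
        bmins = (np.bincount(day[cover], minlength=n_days) * epm)[wear_days]
        starts = np.array([b.start_epoch for b in bouts], dtype=int)
        cnt = np.bincount(day[starts], minlength=n_days) if starts.size else np.zeros(n_days)
        rows[pid] = {
            "time_ge100_min_daily": mins.mean(),
            "time_ge100_pct": 100.0 * ge100.sum() / wearsum,
            "mvpa_weekly_min": mins.mean() * 7.0,
            "mvpa_most_active_day_min": mins.max(),
            "mvpa_bout_min_daily": bmins.mean(),
            "mvpa_bout_pct": 100.0 * cover.sum() / wearsum,
            "mvpa_bout_count_daily": cnt[wear_days].mean(),
            "mvpa_bout_weekly_min": bmins.mean() * 7.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MVPA_VOLUME_FAMILY))


def effect_recovery(
    seed: int = 0,
    n_replicates: int = 200,
    n_ra: int = 300,
    n_ctrl: int = 600,
    true_ratio: float = 0.8,
) -> dict:
    """Recovery of an injected MVPA-frequency reduction.

    Each replicate simulates a cohort with ``mvpa_time_ratio`` set to the
    true ratio (all other effects neutral), screens the MVPA daily-minutes
    metric and the wider MVPA-volume family, and records whether the CI
    covers the true ratio and what fraction of the family is flagged.
    """
    params = ActivityModelParams()
    effect = RAEffect(mvpa_time_ratio=true_ratio)
    profiles = generate_cohort(n_ra, max(n_ctrl, 2 * n_ra), seed)
    profiles = [p for p in profiles if p.group == "RA"][:n_ra] + [
        p for p in profiles if p.group == "control"
    ][:n_ctrl]
    groups = pd.Series({p.id: p.group for p in profiles})
    covers = []
    family_flagged = []
    ratios = []
    for rep in range(n_replicates):
        rep_seed = seed + 17 + 1000 * rep
        labels = simulate_cohort_labels(profiles, params, effect, rep_seed)
        rng = np.random.default_rng(rep_seed + 1)
        codes = np.stack([l.codes for l in labels])
        values, wear = _magnitudes_batch(codes, params, rng)
        recordings = {
            p.id: (
                EpochSeries(
                    labels[i].start_time, params.epoch_seconds, values[i], wear[i]
                ),
                None,
            )
            for i, p in enumerate(profiles)
        }
        fam = _mvpa_family_values(recordings)
        results = screen_matrix(fam, groups)
        by_id = {r.metric_id: r for r in results}
        r = by_id["time_ge100_min_daily"]
        covers.append(r.ci_low <= true_ratio <= r.ci_high)
        ratios.append(r.ratio)
        family_flagged.append(np.mean([by_id[m].flagged for m in fam.columns]))
    return {
        "n_replicates": n_replicates,
        "true_ratio": true_ratio,
        "coverage_pct": float(100.0 * np.mean(covers)),
        "mean_estimated_ratio": float(np.mean(ratios)),
        "mean_family_flagged_pct": float(100.0 * np.mean(family_flagged)),
        "replicates_family_ge80_pct": float(
            100.0 * np.mean(np.asarray(family_flagged) >= 0.8)
        ),
    }


# ---------------------------------------------------------------------------
# wear-time boundary, matching, profiles + PCA
# ---------------------------------------------------------------------------


def wear_time_boundary(min_hours: float = 72.0) -> dict:
    """Validity decision just below and exactly at the minimum wear time."""
    n = 7 * 2880
    values = np.full(n, 30.0)

    def series_with_wear_hours(h):
        wear = np.zeros(n, dtype=bool)
        wear[: int(round(h * 120))] = True
        return EpochSeries("2015-03-02", 30, values, wear)

    below = check_validity(series_with_wear_hours(71.99), min_hours)
    at = check_validity(series_with_wear_hours(72.0), min_hours)
    return {
        "below_72h_excluded": float(not below.valid),
        "at_72h_included": float(at.valid),
        "below_hours": below.total_wear_hours,
        "at_hours": at.total_wear_hours,
    }


def matching_exact_pool(n_cases: int = 40, seed: int = 0) -> dict:
    """Matching on a pool holding two exact category duplicates per case.

    All cases must match at distance 0 with no control reused, and the
    assignment must reproduce under the same seed.
    """
    rng = np.random.default_rng(seed)
    cases, pool = [], []
    for i in range(n_cases):
        age = float(rng.uniform(46, 79))
        sex = "female" if rng.random() < 0.5 else "male"
        bmi = float(rng.uniform(19, 39))
        adi = float(rng.normal(0, 2))
        cases.append(
            ParticipantProfile(f"RA{i:04d}", "RA", age, sex, bmi, adi)
        )
        for j in range(2):
            pool.append(
                ParticipantProfile(f"C{i:04d}_{j}", "control", age, sex, bmi, adi)
            )
    cfg = MatchConfig(ratio=2, max_distance=0, seed=seed + 5)
    cohort1 = match(cases, pool, cfg)
    cohort2 = match(cases, pool, cfg)
    controls = cohort1.control_ids
    return {
        "n_cases": n_cases,
        "n_matched": len(cohort1.pairs),
        "n_unmatched": len(cohort1.unmatched_cases),
        "controls_unique": float(len(controls) == len(set(controls))),
        "deterministic": float(cohort1.pairs == cohort2.pairs),
    }


def profiles_and_pca(seed: int = 0) -> dict:
    """Profile probability closure and PCA variance normalization."""
    params = ActivityModelParams(days=3)
    profiles, recordings = _simulate_cohort_recordings(8, 16, None, params, seed)
    labels_by_id = {pid: lab for pid, (_, lab) in recordings.items()}
    getups = {
        pid: [w.end for w in consolidate_nights(lab)]
        for pid, lab in labels_by_id.items()
    }
    groups = {p.id: p.group for p in profiles}
    pm = activity_profiles(labels_by_id, getups, groups, horizon_hours=12.0)
    sums = []
    for g, probs in pm.group_probs.items():
        has = np.isfinite(probs).all(axis=0)
        sums.append(probs[:, has].sum(axis=0))
    sums = np.concatenate(sums)
    max_closure_err = float(np.abs(sums - 1.0).max())

    rng = np.random.default_rng(seed + 1)
    base = rng.standard_normal(60)
    rank1 = pd.DataFrame(
        {"a": base, "b": 3.0 * base + 5.0},
        index=[f"p{i}" for i in range(60)],
    )
    res1 = pca(rank1)
    noise = pd.DataFrame(
        rng.standard_normal((80, 6)),
        index=[f"p{i}" for i in range(80)],
        columns=[f"m{j}" for j in range(6)],
    )
    res2 = pca(noise)
    return {
        "profile_max_closure_error": max_closure_err,
        "rank1_first_variance_fraction": float(res1.variance_fraction[0]),
        "variance_fraction_sum": float(res2.variance_fraction.sum()),
    }
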