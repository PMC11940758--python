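"""Physical-activity metric registry and per-participant computation.

145 unique metrics (147 domain registrations) over four domains:

* ``total_volume`` (77) — intensity-binned time, magnitude summaries,
  threshold time, bout time/counts/durations, walking and ambulatory
  metrics, weekly totals.
* ``morning`` (30) — magnitude statistics in windows of 15 min to 4 h
  after the estimated get-up time.
* ``night`` (15) — sleep efficiency, sleep timing, L5/M10, sleep-episode
  durations, movement episodes, rest fragmentation.
* ``fragmentation`` (25) — state-exit hazards, transition probabilities
  and run-duration statistics under two binarizations (sedentary vs
  active at 40 mg; MVPA vs non-MVPA at 100 mg).

Two metrics belong to two domains each ("M10 mean level":
total_volume+night; "MVPA percent of wear time": total_volume+
fragmentation), which is why registrations exceed unique ids by two.

Conventions: time metrics are in minutes, clock-time metrics in hours
since midnight (circularly averaged), percentages in [0, 100]. Intensity
time (bins, thresholds) and label-based metrics count wear epochs only;
magnitude summaries (means, AUC, percentiles, L5/M10, morning windows)
use the imputed series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import labeling
from .bouts import Bout, BoutConfig, detect_bouts, sedentary_complement
from .labeling import (
    LIGHT_CUTPOINT_MG,
    MVPA_CUTPOINT_MG,
    LabelSeries,
    NightWindow,
    ambulatory_bouts,
    consolidate_nights,
    run_length_encode,
)
from .preprocess import EpochSeries, impute_missing

__all__ = [
    "MetricDef",
    "MetricRegistry",
    "FragmentationSummary",
    "build_registry",
    "compute_total_volume",
    "compute_morning",
    "compute_night",
    "compute_fragmentation",
    "compute_all_metrics",
    "compute_metric_matrix",
    "MVPA_VOLUME_FAMILY",
]

DOMAINS = ("total_volume", "morning", "night", "fragmentation")

BIN_EDGES_MG = np.arange(0.0, 440.0, 40.0)  # 0,40,...,400
MORNING_WINDOWS_MIN = (15, 30, 60, 120, 240)
MORNING_STATS = ("mean", "sd", "p95", "auc", "pct_ge040", "mvpa_min")

#: Metrics responding directly to the volume of MVPA; used by the
#: effect-recovery analyses.
MVPA_VOLUME_FAMILY = (
    "time_ge100_min_daily",
    "time_ge100_pct",
    "mvpa_weekly_min",
    "mvpa_most_active_day_min",
    "mvpa_bout_min_daily",
    "mvpa_bout_pct",
    "mvpa_bout_count_daily",
    "mvpa_bout_weekly_min",
)


@dataclass(frozen=True)
class MetricDef:
    """One metric: stable id, owning domain(s), units, scale tag."""

    metric_id: str
    domains: frozenset
    units: str
    description: str = ""
    #: clock-time metrics are screened on the linear (difference) scale
    linear_scale: bool = False
    family: str = ""


class MetricRegistry:
    """Ordered catalogue of metric definitions."""

    def __init__(self, defs: Sequence[MetricDef]):
        self._defs = list(defs)
        ids = [d.metric_id for d in self._defs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate metric_id in registry")
        self._by_id = {d.metric_id: d for d in self._defs}

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs)

    def __getitem__(self, metric_id: str) -> MetricDef:
        return self._by_id[metric_id]

    def __contains__(self, metric_id: str) -> bool:
        return metric_id in self._by_id

    @property
    def ids(self) -> list:
        return [d.metric_id for d in self._defs]

    def domain_ids(self, domain: str) -> list:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        return [d.metric_id for d in self._defs if domain in d.domains]

    def n_registrations(self) -> int:
        return sum(len(d.domains) for d in self._defs)


def build_registry() -> MetricRegistry:
    """The canonical 145-metric catalogue (deterministic)."""
    defs = []

    def add(mid, domains, units, desc="", linear=False, family=""):
        defs.append(
            MetricDef(mid, frozenset(domains), units, desc, linear, family)
        )

    tv = ("total_volume",)
    # intensity bins: daily-mean minutes, percent of wear time, across-day SD
    for lo, hi in zip(BIN_EDGES_MG[:-1], BIN_EDGES_MG[1:]):
        tag = f"{int(lo):03d}_{int(hi):03d}"
        add(f"bin_{tag}_min_daily", tv, "min", f"daily minutes at {int(lo)}-{int(hi)} mg")
        add(f"bin_{tag}_pct", tv, "%", f"percent wear time at {int(lo)}-{int(hi)} mg")
        add(f"bin_{tag}_min_daily_sd", tv, "min", f"across-day SD of daily minutes at {int(lo)}-{int(hi)} mg")
    # overall magnitude summaries
    add("mag_overall_mean", tv, "mg", "overall mean acceleration magnitude")
    add("mag_daily_mean_sd", tv, "mg", "SD across days of daily mean magnitude")
    add("mag_daily_p95_mean", tv, "mg", "mean daily 95th centile of magnitude")
    add("mag_weekday_mean", tv, "mg", "mean magnitude on weekdays")
    add("mag_weekend_mean", tv, "mg", "mean magnitude on weekend days")
    add("mag_daily_auc_mean", tv, "mg*min", "mean daily magnitude area under curve")
    # threshold time
    add("time_ge040_min_daily", tv, "min", "daily minutes >= 40 mg")
    add("time_ge040_pct", tv, "%", "percent wear time >= 40 mg")
    add("time_ge100_min_daily", tv, "min", "daily minutes >= 100 mg (MVPA level)",
        family="mvpa_volume")
    add("time_ge100_pct", ("total_volume", "fragmentation"), "%",
        "MVPA percent of wear time", family="mvpa_volume")
    # bout time / counts / durations / in-bout magnitude
    for cls in ("sed", "active", "mvpa"):
        fam = "mvpa_volume" if cls == "mvpa" else ""
        add(f"{cls}_bout_min_daily", tv, "min", f"daily minutes in {cls} bouts",
            family=fam)
        add(f"{cls}_bout_pct", tv, "%", f"percent wear time in {cls} bouts",
            family=fam)
    for cls in ("active", "mvpa"):
        add(f"{cls}_bout_count_daily", tv, "count/day", f"daily {cls} bout count",
            family="mvpa_volume" if cls == "mvpa" else "")
    for cls in ("sed", "active", "mvpa"):
        add(f"{cls}_bout_duration_mean", tv, "min", f"mean {cls} bout duration")
        add(f"{cls}_bout_duration_sd", tv, "min", f"SD of {cls} bout duration")
    for cls in ("active", "mvpa"):
        add(f"{cls}_bout_mag_daily_mean", tv, "mg", f"daily mean magnitude in {cls} bouts")
        add(f"{cls}_bout_mag_daily_sd", tv, "mg", f"across-day SD of in-{cls}-bout magnitude")
    # in-state magnitude
    for st in ("light", "mvpa", "walking"):
        add(f"{st}_state_mag_daily_mean", tv, "mg", f"daily mean magnitude while labeled {st}")
    # walking time
    add("walking_min_daily", tv, "min", "daily minutes labeled walking")
    add("walking_pct", tv, "%", "percent wear time labeled walking")
    add("walking_min_daily_sd", tv, "min", "across-day SD of daily walking minutes")
    # ambulatory bouts
    for cls, tag in (("2-10 min", "2_10"), ("10-30 min", "10_30"), (">30 min", "gt30")):
        add(f"amb_{tag}_count_daily", tv, "count/day", f"daily count of {cls} walking bouts")
        add(f"amb_{tag}_min_daily", tv, "min", f"daily minutes in {cls} walking bouts")
    # weekly totals
    add("mvpa_weekly_min", tv, "min", "weekly minutes >= 100 mg", family="mvpa_volume")
    add("mvpa_bout_weekly_min", tv, "min", "weekly minutes in MVPA bouts", family="mvpa_volume")
    add("active_bout_weekly_min", tv, "min", "weekly minutes in active bouts")
    add("walking_weekly_min", tv, "min", "weekly minutes labeled walking")
    add("mvpa_most_active_day_min", tv, "min", "MVPA minutes on the most active day",
        family="mvpa_volume")
    add("mvpa_weekday_weekend_ratio", tv, "ratio", "weekday/weekend daily MVPA minutes")
    # M10 level (dual with night)
    add("m10_level", ("total_volume", "night"), "mg", "mean level of the most-active 10 h")

    # morning: window x statistic
    for w in MORNING_WINDOWS_MIN:
        for st in MORNING_STATS:
            units = {
                "mean": "mg", "sd": "mg", "p95": "mg",
                "auc": "mg*min", "pct_ge040": "%", "mvpa_min": "min",
            }[st]
            add(f"morning_{w:03d}m_{st}", ("morning",), units,
                f"{st} of magnitude in the {w} min after getting up")

    nt = ("night",)
    add("sleep_efficiency_mean", nt, "%", "mean nightly sleep efficiency")
    add("sleep_efficiency_sd", nt, "%", "SD of nightly sleep efficiency")
    add("sleep_midpoint_mean", nt, "h", "circular mean sleep midpoint clock time",
        linear=True)
    add("sleep_midpoint_sd", nt, "h", "circular SD of sleep midpoint")
    add("l5_midpoint", nt, "h", "midpoint clock time of least-active 5 h", linear=True)
    add("l5_level", nt, "mg", "mean level of least-active 5 h")
    add("m10_midpoint", nt, "h", "midpoint clock time of most-active 10 h", linear=True)
    add("nocturnal_episode_min_mean", nt, "min", "mean nocturnal sleep-episode duration")
    add("nocturnal_episode_min_sd", nt, "min", "SD of nocturnal sleep-episode duration")
    add("diurnal_episode_min_mean", nt, "min", "mean diurnal sleep-episode duration")
    add("diurnal_episode_min_sd", nt, "min", "SD of diurnal sleep-episode duration")
    add("movement_episodes_per_night_mean", nt, "count", "mean movement episodes per night")
    add("movement_episodes_per_night_sd", nt, "count", "SD of movement episodes per night")
    add("rest_fragmentation_mean", nt, "%/episode", "mean nightly rest fragmentation")

    fr = ("fragmentation",)
    for a, b in (
        ("sed", "active"), ("active", "sed"),
        ("nonmvpa", "mvpa"), ("mvpa", "nonmvpa"),
    ):
        add(f"hazard_{a}_to_{b}", fr, "1/epoch", f"exit hazard {a} -> {b}")
    for a, b in (
        ("sed", "active"), ("active", "sed"),
        ("nonmvpa", "mvpa"), ("mvpa", "nonmvpa"),
    ):
        add(f"tp_{a}_to_{b}", fr, "probability", f"per-epoch transition probability {a} -> {b}")
    for st in ("sed", "active", "mvpa", "nonmvpa"):
        for stat in ("mean", "sd", "median", "p95"):
            add(f"run_{st}_{stat}", fr, "min", f"{stat} of {st} run durations")

    return MetricRegistry(defs)


@dataclass(frozen=True)
class FragmentationSummary:
    """State-switching summaries under the two binarizations."""

    hazard: dict  # e.g. {"sed_to_active": 1/epochs, ...}
    transition_probability: dict
    run_stats: dict  # per state: {"mean","sd","median","p95"} in minutes


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _daily_groups(series: EpochSeries):
    """(day ordinals, day index array, is_weekend per day)."""
    day = series.day_index()
    n_days = int(day[-1]) + 1
    start_weekday = series.start_time.normalize().weekday()
    weekdays = (start_weekday + np.arange(n_days)) % 7
    return day, n_days, weekdays >= 5


def _nanmean(x):
    x = np.asarray(x, float)
    return float(np.mean(x)) if x.size else np.nan


def _nansd(x):
    x = np.asarray(x, float)
    return float(np.std(x, ddof=1)) if x.size >= 2 else np.nan


def _circular_mean_hours(hours: np.ndarray) -> float:
    ang = np.asarray(hours, float) * 2 * np.pi / 24.0
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    return float(np.arctan2(s, c) * 24.0 / (2 * np.pi) % 24.0)


def _circular_sd_hours(hours: np.ndarray) -> float:
    if len(hours) < 2:
        return np.nan
    ang = np.asarray(hours, float) * 2 * np.pi / 24.0
    r = np.hypot(np.sin(ang).mean(), np.cos(ang).mean())
    r = min(r, 1.0)
    if r <= 0:
        return np.nan
    return float(np.sqrt(-2.0 * np.log(r)) * 24.0 / (2 * np.pi))


def _clock_hours(ts: pd.Timestamp) -> float:
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0


# ---------------------------------------------------------------------------
# total volume
# ---------------------------------------------------------------------------


def compute_total_volume(
    series: EpochSeries,
    labels: Optional[LabelSeries],
    bouts_by_class: dict,
    amb: Sequence,
    imputed: Optional[EpochSeries] = None,
) -> dict:
    """Total-volume domain metrics for one participant.

    ``bouts_by_class`` maps "sed"/"active"/"mvpa" to bout lists;
    ``imputed`` is the magnitude series used for magnitude summaries
    (falls back to ``series``).
    """
    out = {}
    imp = imputed if imputed is not None else series
    epm = series.epoch_seconds / 60.0  # minutes per epoch
    day, n_days, is_weekend = _daily_groups(series)
    wear = series.wear_mask
    v = series.values
    if wear.sum() == 0:
        return out

    wear_days = np.unique(day[wear])

    def daily(mask):
        """Minutes per day matching a wear-epoch mask (wear days only)."""
        cnt = np.bincount(day[mask & wear], minlength=n_days)
        return cnt[wear_days] * epm

    wear_per_day = np.bincount(day[wear], minlength=n_days)[wear_days]

    # intensity bins
    binned = np.digitize(v, BIN_EDGES_MG[1:-1], right=False)  # 0..9 then 9 for >=360
    over = v >= BIN_EDGES_MG[-1]
    for k, (lo, hi) in enumerate(zip(BIN_EDGES_MG[:-1], BIN_EDGES_MG[1:])):
        tag = f"{int(lo):03d}_{int(hi):03d}"
        m = (binned == k) & ~over
        mins = daily(m)
        out[f"bin_{tag}_min_daily"] = _nanmean(mins)
        out[f"bin_{tag}_pct"] = float(100.0 * (m & wear).sum() / wear.sum())
        out[f"bin_{tag}_min_daily_sd"] = _nansd(mins)

    # magnitude summaries on the imputed series
    iv = imp.values
    iday = imp.day_index()
    in_days = int(iday[-1]) + 1
    cuts = np.searchsorted(iday, np.arange(in_days + 1))
    day_slices = [slice(cuts[d], cuts[d + 1]) for d in range(in_days)]
    d_mean = np.array([iv[sl].mean() for sl in day_slices])
    d_p95 = np.array([np.percentile(iv[sl], 95) for sl in day_slices])
    d_auc = np.array([iv[sl].sum() * epm for sl in day_slices])
    out["mag_overall_mean"] = float(iv.mean())
    out["mag_daily_mean_sd"] = _nansd(d_mean)
    out["mag_daily_p95_mean"] = _nanmean(d_p95)
    _, _, i_weekend = _daily_groups(imp)
    wk = ~i_weekend[iday]
    out["mag_weekday_mean"] = float(iv[wk].mean()) if wk.any() else np.nan
    out["mag_weekend_mean"] = float(iv[~wk].mean()) if (~wk).any() else np.nan
    out["mag_daily_auc_mean"] = _nanmean(d_auc)

    # threshold time
    ge40 = v >= LIGHT_CUTPOINT_MG
    ge100 = v >= MVPA_CUTPOINT_MG
    mins40, mins100 = daily(ge40), daily(ge100)
    out["time_ge040_min_daily"] = _nanmean(mins40)
    out["time_ge040_pct"] = float(100.0 * (ge40 & wear).sum() / wear.sum())
    out["time_ge100_min_daily"] = _nanmean(mins100)
    out["time_ge100_pct"] = float(100.0 * (ge100 & wear).sum() / wear.sum())

    # bouts
    for cls in ("sed", "active", "mvpa"):
        blist = bouts_by_class.get(cls, [])
        cover = np.zeros(series.n_epochs, dtype=bool)
        for b in blist:
            cover[b.start_epoch : b.end_epoch + 1] = True
        cover &= wear
        mins = daily(cover)
        out[f"{cls}_bout_min_daily"] = _nanmean(mins)
        out[f"{cls}_bout_pct"] = float(100.0 * cover.sum() / wear.sum())
        durs = np.array([b.n_epochs * epm for b in blist])
        out[f"{cls}_bout_duration_mean"] = _nanmean(durs)
        out[f"{cls}_bout_duration_sd"] = _nansd(durs)
        if cls in ("active", "mvpa"):
            starts = np.array([b.start_epoch for b in blist], dtype=int)
            cnt = np.bincount(day[starts], minlength=n_days) if starts.size else np.zeros(n_days)
            out[f"{cls}_bout_count_daily"] = float(cnt[wear_days].mean())
            if cover.any():
                csum = np.bincount(day[cover], weights=v[cover], minlength=n_days)
                ccnt = np.bincount(day[cover], minlength=n_days)
                dmag = [
                    csum[d] / ccnt[d] for d in wear_days if ccnt[d] > 0
                ]
                out[f"{cls}_bout_mag_daily_mean"] = _nanmean(dmag)
                out[f"{cls}_bout_mag_daily_sd"] = _nansd(dmag)
            else:
                out[f"{cls}_bout_mag_daily_mean"] = np.nan
                out[f"{cls}_bout_mag_daily_sd"] = np.nan

    # label-based metrics
    if labels is not None:
        lc = labels.codes
        for st, code in (
            ("light", labeling.LIGHT),
            ("mvpa", labeling.MVPA),
            ("walking", labeling.WALKING),
        ):
            m = (lc == code) & wear
            out[f"{st}_state_mag_daily_mean"] = float(v[m].mean()) if m.any() else np.nan
        walk = (lc == labeling.WALKING) & wear
        wmins = daily(walk)
        out["walking_min_daily"] = _nanmean(wmins)
        out["walking_pct"] = float(100.0 * walk.sum() / wear.sum())
        out["walking_min_daily_sd"] = _nansd(wmins)
        out["walking_weekly_min"] = out["walking_min_daily"] * 7.0
        for cls, tag in (("2-10 min", "2_10"), ("10-30 min", "10_30"), (">30 min", "gt30")):
            sel = [b for b in amb if b.duration_class == cls]
            cnt = np.zeros(n_days)
            mins = np.zeros(n_days)
            for b in sel:
                d = int(day[b.start_epoch])
                cnt[d] += 1
                mins[d] += (b.end_epoch - b.start_epoch) * epm
            out[f"amb_{tag}_count_daily"] = float(cnt[wear_days].mean())
            out[f"amb_{tag}_min_daily"] = float(mins[wear_days].mean())
    else:
        for mid in (
            "light_state_mag_daily_mean", "mvpa_state_mag_daily_mean",
            "walking_state_mag_daily_mean", "walking_min_daily", "walking_pct",
            "walking_min_daily_sd", "walking_weekly_min",
            "amb_2_10_count_daily", "amb_2_10_min_daily",
            "amb_10_30_count_daily", "amb_10_30_min_daily",
            "amb_gt30_count_daily", "amb_gt30_min_daily",
        ):
            out[mid] = np.nan

    # weekly totals and day extremes
    out["mvpa_weekly_min"] = out["time_ge100_min_daily"] * 7.0
    out["mvpa_bout_weekly_min"] = out["mvpa_bout_min_daily"] * 7.0
    out["active_bout_weekly_min"] = out["active_bout_min_daily"] * 7.0
    out["mvpa_most_active_day_min"] = float(mins100.max()) if mins100.size else np.nan
    wkday_mask = ~is_weekend[wear_days]
    wd = mins100[wkday_mask]
    we = mins100[~wkday_mask]
    if wd.size and we.size and we.mean() > 0:
        out["mvpa_weekday_weekend_ratio"] = float(wd.mean() / we.mean())
    else:
        out["mvpa_weekday_weekend_ratio"] = np.nan
    return out


# ---------------------------------------------------------------------------
# morning
# ---------------------------------------------------------------------------


def compute_morning(
    series: EpochSeries,
    getups: Sequence[pd.Timestamp],
    windows_min: Sequence[int] = MORNING_WINDOWS_MIN,
) -> dict:
    """Morning-domain metrics: magnitude statistics after getting up.

    Uses the (imputed) magnitude series; a day is excluded for a window
    length when the window extends past the recording end.
    """
    out = {}
    es = series.epoch_seconds
    t0 = series.start_time
    per_window = {w: [] for w in windows_min}
    for g in getups:
        if g is None:
            continue
        start = int((pd.Timestamp(g) - t0).total_seconds() // es)
        for w in windows_min:
            n = int(w * 60 // es)
            if start < 0 or start + n > series.n_epochs:
                continue
            seg = series.values[start : start + n]
            per_window[w].append(
                {
                    "mean": float(seg.mean()),
                    "sd": float(seg.std(ddof=1)) if seg.size >= 2 else np.nan,
                    "p95": float(np.percentile(seg, 95)),
                    "auc": float(seg.mean() * w),
                    "pct_ge040": float(100.0 * (seg >= LIGHT_CUTPOINT_MG).mean()),
                    "mvpa_min": float((seg >= MVPA_CUTPOINT_MG).sum() * es / 60.0),
                }
            )
    for w in windows_min:
        days = per_window[w]
        for st in MORNING_STATS:
            vals = [d[st] for d in days]
            out[f"morning_{w:03d}m_{st}"] = _nanmean(vals) if vals else np.nan
    return out


# ---------------------------------------------------------------------------
# night
# ---------------------------------------------------------------------------


def _rolling_circular_mean(profile: np.ndarray, window: int) -> np.ndarray:
    """Mean over each wrap-around window of ``window`` bins starting at i."""
    ext = np.concatenate([profile, profile[: window - 1]])
    c = np.concatenate(([0.0], np.cumsum(ext)))
    return (c[window:] - c[:-window]) / window


def compute_night(
    labels: Optional[LabelSeries],
    windows: Sequence[NightWindow],
    series: EpochSeries,
) -> dict:
    """Night-domain metrics: sleep efficiency and timing, L5/M10,
    sleep-episode durations, movement episodes, rest fragmentation."""
    out = {mid: np.nan for mid in (
        "sleep_efficiency_mean", "sleep_efficiency_sd",
        "sleep_midpoint_mean", "sleep_midpoint_sd",
        "nocturnal_episode_min_mean", "nocturnal_episode_min_sd",
        "diurnal_episode_min_mean", "diurnal_episode_min_sd",
        "movement_episodes_per_night_mean", "movement_episodes_per_night_sd",
        "rest_fragmentation_mean",
    )}
    epm = series.epoch_seconds / 60.0

    # L5 / M10 on the across-day average 24-h profile
    epd = series.epochs_per_day
    slot = series.epoch_of_day()
    counts = np.bincount(slot, minlength=epd)
    sums = np.bincount(slot, weights=series.values, minlength=epd)
    if (counts > 0).all() and series.n_epochs >= epd:
        prof = sums / counts
        w5 = int(5 * 3600 // series.epoch_seconds)
        w10 = int(10 * 3600 // series.epoch_seconds)
        r5 = _rolling_circular_mean(prof, w5)
        r10 = _rolling_circular_mean(prof, w10)
        i5, i10 = int(np.argmin(r5)), int(np.argmax(r10))
        hours_per_bin = series.epoch_seconds / 3600.0
        out["l5_midpoint"] = float(((i5 + w5 / 2.0) * hours_per_bin) % 24.0)
        out["l5_level"] = float(r5[i5])
        out["m10_midpoint"] = float(((i10 + w10 / 2.0) * hours_per_bin) % 24.0)
        out["m10_level"] = float(r10[i10])
    else:
        out.update(
            l5_midpoint=np.nan, l5_level=np.nan, m10_midpoint=np.nan, m10_level=np.nan
        )

    if labels is None or not windows:
        return out

    eff, mids, moves, frag = [], [], [], []
    for w in windows:
        n_ep = w.end_epoch - w.start_epoch
        eff.append(100.0 * w.sleep_epochs / n_ep)
        mid = w.start + (w.end - w.start) / 2
        mids.append(_clock_hours(mid))
        moves.append(w.movement_episodes)
        nonsleep_pct = 100.0 * (1.0 - w.sleep_epochs / n_ep)
        frag.append(nonsleep_pct / w.movement_episodes if w.movement_episodes else 0.0)
    out["sleep_efficiency_mean"] = _nanmean(eff)
    out["sleep_efficiency_sd"] = _nansd(eff)
    out["sleep_midpoint_mean"] = _circular_mean_hours(mids)
    out["sleep_midpoint_sd"] = _circular_sd_hours(mids)
    out["movement_episodes_per_night_mean"] = _nanmean(moves)
    out["movement_episodes_per_night_sd"] = _nansd(moves)
    out["rest_fragmentation_mean"] = _nanmean(frag)

    # nocturnal vs diurnal sleep episodes
    in_window = np.zeros(labels.n_epochs, dtype=bool)
    for w in windows:
        in_window[w.start_epoch : w.end_epoch] = True
    starts, lengths, vals = run_length_encode(labels.codes)
    noct, diur = [], []
    for s, ln, vv in zip(starts, lengths, vals):
        if vv != labeling.SLEEP:
            continue
        dur = ln * epm
        # classify by where the episode's midpoint falls
        if in_window[min(s + ln // 2, labels.n_epochs - 1)]:
            noct.append(dur)
        else:
            diur.append(dur)
    out["nocturnal_episode_min_mean"] = _nanmean(noct) if noct else np.nan
    out["nocturnal_episode_min_sd"] = _nansd(noct) if noct else np.nan
    out["diurnal_episode_min_mean"] = _nanmean(diur) if diur else np.nan
    out["diurnal_episode_min_sd"] = _nansd(diur) if diur else np.nan
    return out


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


def _binary_runs(binary: np.ndarray, wear: np.ndarray):
    """Runs of a binary state sequence within contiguous wear segments.

    Returns a list of (state, length_epochs, completed) where ``completed``
    is False for the final run of each wear segment (its exit is censored
    by a non-wear gap or the recording end).
    """
    runs = []
    seg_starts, seg_lengths, seg_vals = run_length_encode(wear.astype(np.int8))
    for s, ln, vv in zip(seg_starts, seg_lengths, seg_vals):
        if vv != 1:
            continue
        rs, rl, rv = run_length_encode(binary[s : s + ln])
        for k in range(len(rs)):
            runs.append((int(rv[k]), int(rl[k]), k < len(rs) - 1))
    return runs


def compute_fragmentation(
    labels: Optional[LabelSeries], series: EpochSeries
) -> tuple:
    """Fragmentation metrics under the 40 mg and 100 mg binarizations.

    Returns ``(FragmentationSummary, metric dict)``. Hazards use completed
    runs only (the last run of each wear segment has no observed exit);
    run-duration statistics use all runs; transition probabilities divide
    observed exits by total epochs in the state.
    """
    epm = series.epoch_seconds / 60.0
    v = series.values
    wear = series.wear_mask
    hazard, tp, run_stats, out = {}, {}, {}, {}

    for hi_name, lo_name, binary in (
        ("active", "sed", v >= LIGHT_CUTPOINT_MG),
        ("mvpa", "nonmvpa", v >= MVPA_CUTPOINT_MG),
    ):
        runs = _binary_runs(binary.astype(np.int8), wear)
        for state, code in ((hi_name, 1), (lo_name, 0)):
            other = lo_name if state == hi_name else hi_name
            key = f"{state}_to_{other}"
            lens = np.array([ln for s, ln, _ in runs if s == code], float)
            completed = np.array(
                [ln for s, ln, comp in runs if s == code and comp], float
            )
            if lens.size == 0:
                hazard[key] = np.nan
                tp[key] = np.nan
                run_stats[state] = dict.fromkeys(("mean", "sd", "median", "p95"), np.nan)
            else:
                # no completed run: the state's exit is never observed
                hazard[key] = (
                    1.0 / completed.mean() if completed.size else np.nan
                )
                tp[key] = (
                    float(completed.size / lens.sum()) if completed.size else np.nan
                )
                mins = lens * epm
                run_stats[state] = {
                    "mean": _nanmean(mins),
                    "sd": _nansd(mins),
                    "median": float(np.median(mins)),
                    "p95": float(np.percentile(mins, 95)),
                }
            out[f"hazard_{key}"] = hazard[key]
            out[f"tp_{key}"] = tp[key]
            for stat in ("mean", "sd", "median", "p95"):
                out[f"run_{state}_{stat}"] = run_stats[state][stat]

    wearsum = wear.sum()
    out["time_ge100_pct"] = (
        float(100.0 * ((v >= MVPA_CUTPOINT_MG) & wear).sum() / wearsum)
        if wearsum
        else np.nan
    )
    return FragmentationSummary(hazard, tp, run_stats), out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def compute_all_metrics(
    series: EpochSeries,
    labels: Optional[LabelSeries] = None,
    registry: Optional[MetricRegistry] = None,
) -> dict:
    """All registry metrics for one participant.

    Derives night windows, get-up times, bouts and ambulatory bouts from
    the inputs, computes the four domains, and returns a dict keyed by the
    registry's unique metric ids (missing values as NaN).
    """
    registry = registry or build_registry()
    try:
        imputed = impute_missing(series)
    except ValueError:
        imputed = series  # a slot never worn: fall back to raw values

    active_bouts = detect_bouts(series, BoutConfig("active"))
    mvpa_bouts = detect_bouts(series, BoutConfig("MVPA"))
    # sedentary bouts: wear time complementary to the (merged) active and
    # MVPA bouts
    covered = np.zeros(series.n_epochs, dtype=bool)
    for b in active_bouts + mvpa_bouts:
        covered[b.start_epoch : b.end_epoch + 1] = True
    merged_starts, merged_lens, merged_vals = run_length_encode(covered.astype(np.int8))
    merged = [
        Bout(int(s), int(s + ln - 1), 1.0)
        for s, ln, vv in zip(merged_starts, merged_lens, merged_vals)
        if vv == 1
    ]
    sed_bouts = sedentary_complement(series, merged)
    bouts_by_class = {"sed": sed_bouts, "active": active_bouts, "mvpa": mvpa_bouts}

    if labels is not None:
        windows = consolidate_nights(labels)
        getups = [w.end for w in windows]
        amb = ambulatory_bouts(labels)
    else:
        windows, getups, amb = [], [], []

    out = {}
    out.update(compute_total_volume(series, labels, bouts_by_class, amb, imputed))
    out.update(compute_morning(imputed, getups))
    out.update(compute_night(labels, windows, imputed))
    _, frag = compute_fragmentation(labels, series)
    out.update(frag)

    result = {mid: out.get(mid, np.nan) for mid in registry.ids}
    return result


def compute_metric_matrix(
    recordings: dict, registry: Optional[MetricRegistry] = None
) -> pd.DataFrame:
    """Participant x metric table.

    ``recordings`` maps participant id to ``(series, labels-or-None)``.
    """
    registry = registry or build_registry()
    rows = {
        pid: compute_all_metrics(series, labels, registry)
        for pid, (series, labels) in recordings.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=registry.ids)
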