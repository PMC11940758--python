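"""Synthetic cohort and actigraphy generator.

Emulates the statistical structure of UK-Biobank-style wrist actigraphy:
7-day recordings on a 30-second epoch grid, circadian-structured activity
states (sleep / sedentary / light / MVPA / walking) generated by a
semi-Markov process, label-conditional log-normal acceleration magnitudes,
non-wear gaps, and a participant table with RA / control demographics.

Disease effects are injected through :class:`RAEffect` knobs — reduced
MVPA frequency, shorter MVPA runs, delayed morning activity, and more
fragmented nocturnal sleep — so that every downstream analysis stage can
be exercised and calibrated without access to the original cohort data.

The activity process: at each state entry, the next state is drawn with
probability proportional to a per-state base weight times a 24-hour
periodic multiplier ``exp(a_s * cos(2*pi*(t - peak_s)/24))``; the sojourn
time is geometric on epochs with mean equal to the state's mean run
length scaled by its (separate, gentler) sojourn multiplier at entry.
Self-transitions are excluded so runs are well defined. Person-level
log-normal frailties on the entry weights and on magnitude level create
between-participant heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labeling import LabelSeries
from .preprocess import EpochSeries

__all__ = [
    "ParticipantProfile",
    "ActivityModelParams",
    "RAEffect",
    "CohortConfig",
    "ALCOHOL_LEVELS",
    "generate_cohort",
    "simulate_labels",
    "simulate_cohort_labels",
    "simulate_magnitudes",
    "simulate_recording",
    "default_ra_effect",
    "profiles_to_frame",
]

STATES = ("sleep", "sedentary", "light", "MVPA", "walking")
N_STATES = len(STATES)

ALCOHOL_LEVELS = (
    "daily",
    "3-4_per_week",
    "1-2_per_week",
    "1-3_per_month",
    "rarely",
    "never",
)
SEASONS = ("spring", "summer", "autumn", "winter")
COMORBIDITIES = (
    "heart_failure",
    "respiratory_failure",
    "stroke",
    "thyroiditis",
    "sjogren_syndrome",
)

#: Age-at-onset boundary between early and late disease onset (years).
LATE_ONSET_AGE = 60.0


@dataclass
class ParticipantProfile:
    """Demographics, covariates and RA descriptors for one participant."""

    id: str
    group: str  # "RA" or "control"
    age: float  # years, 45-80
    sex: str  # "female" / "male"
    bmi: float  # kg/m^2
    adi: float  # area deprivation index (continuous)
    smoking: str = "never"  # ever / never / unknown
    alcohol: str = "never"  # one of ALCOHOL_LEVELS
    chronotype: str = "unknown"  # morning / evening / unknown
    season: str = "spring"
    working: bool = False
    diagnosis_source: str = "none"  # primary_care / hospital / self_report / none
    diagnosis_type: str = "none"  # seropositive / other / none
    onset: str = "none"  # early / late / none
    age_at_diagnosis: Optional[float] = None
    comorbidities: tuple = ()
    rheumatoid_factor: Optional[float] = None  # IU/mL, when tested
    diagnosed_after_recording: bool = False
    duplicate_diagnosis_sources: tuple = ()

    def __post_init__(self) -> None:
        if self.group not in ("RA", "control"):
            raise ValueError("group must be 'RA' or 'control'")
        if self.group == "control":
            if (
                self.diagnosis_source != "none"
                or self.diagnosis_type != "none"
                or self.onset != "none"
                or self.age_at_diagnosis is not None
            ):
                raise ValueError("control profiles must carry no diagnosis fields")
        else:
            if self.age_at_diagnosis is not None:
                late = self.age_at_diagnosis >= LATE_ONSET_AGE
                if (self.onset == "late") != late:
                    raise ValueError(
                        "onset must be 'late' exactly when age_at_diagnosis >= 60"
                    )
        if self.alcohol not in ALCOHOL_LEVELS:
            raise ValueError(f"unknown alcohol level {self.alcohol!r}")


@dataclass(frozen=True)
class RAEffect:
    """Multiplicative disease effects injected into the activity generator.

    Neutral by default (no effect); :func:`default_ra_effect` returns the
    standard disease condition used by the demo pipeline.
    """

    #: multiplies the per-entry probability of starting an MVPA run
    #: (<1 = less MVPA; applied exactly by entry thinning)
    mvpa_time_ratio: float = 1.0
    mvpa_run_ratio: float = 1.0  # scales MVPA mean run length
    morning_delay_minutes: float = 0.0  # ramp-in lag of MVPA/walking after wake
    sleep_interrupt_rate_ratio: float = 1.0  # nocturnal movement-episode rate
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mvpa_time_ratio <= 0 or self.mvpa_run_ratio <= 0:
            raise ValueError("effect ratios must be strictly positive")
        if self.sleep_interrupt_rate_ratio <= 0:
            raise ValueError("sleep_interrupt_rate_ratio must be strictly positive")
        if self.morning_delay_minutes < 0:
            raise ValueError("morning_delay_minutes must be non-negative")


def default_ra_effect(seed: Optional[int] = None) -> RAEffect:
    """Standard RA condition: 20% less MVPA, 15% shorter MVPA runs,
    30-minute morning ramp-in, 30% more nocturnal interruptions."""
    return RAEffect(
        mvpa_time_ratio=0.8,
        mvpa_run_ratio=0.85,
        morning_delay_minutes=30.0,
        sleep_interrupt_rate_ratio=1.3,
        seed=seed,
    )


def _dict_field(d):
    return field(default_factory=lambda: dict(d))


@dataclass
class ActivityModelParams:
    """Parameters of the semi-Markov activity-state generator.

    ``circadian`` maps each state to ``(peak_hour, entry_amplitude,
    sojourn_amplitude)``: entry weights are multiplied by
    ``exp(entry_amplitude * cos(2*pi*(t - peak_hour)/24))`` and sojourn
    means by the analogous (smaller) sojourn term, evaluated at entry.
    """

    state_set: tuple = STATES
    mean_run_minutes: dict = _dict_field(
        {"sleep": 45.0, "sedentary": 12.0, "light": 4.0, "MVPA": 3.0, "walking": 2.5}
    )
    base_entry_weight: dict = _dict_field(
        {"sleep": 0.11, "sedentary": 3.0, "light": 1.5, "MVPA": 0.25, "walking": 0.7}
    )
    circadian: dict = _dict_field(
        {
            "sleep": (3.0, 3.2, 0.8),
            "sedentary": (14.0, 0.3, 0.7),
            "light": (11.0, 0.8, 0.2),
            "MVPA": (11.0, 1.0, 0.2),
            "walking": (13.0, 1.0, 0.2),
        }
    )
    #: per-state log-normal magnitude: (median mg, geometric SD)
    magnitude_dist: dict = _dict_field(
        {
            "sleep": (3.0, 1.8),
            "sedentary": (9.0, 1.9),
            "light": (60.0, 1.15),
            "MVPA": (180.0, 1.25),
            "walking": (55.0, 1.20),
        }
    )
    nonwear_episodes_per_day: float = 0.15
    nonwear_mean_minutes: float = 90.0
    epoch_seconds: int = 30
    days: int = 7
    #: person-level log-normal frailty SD on entry weights, per state
    frailty_sigma: dict = _dict_field(
        {"sleep": 0.10, "sedentary": 0.10, "light": 0.20, "MVPA": 0.30, "walking": 0.30}
    )
    magnitude_frailty_sigma: float = 0.10
    #: reference end of the nocturnal phase, for the morning-delay ramp
    morning_reference_hour: float = 7.0
    #: nocturnal window (start hour, end hour) for the sleep-interrupt effect
    nocturnal_window: tuple = (23.0, 6.0)
    start_date: str = "2015-03-02"  # a Monday, 00:00 local

    def __post_init__(self) -> None:
        if tuple(self.state_set) != STATES:
            raise ValueError(f"state_set must be {STATES}")
        for s in STATES:
            if self.mean_run_minutes[s] <= 0:
                raise ValueError(f"mean_run_minutes[{s!r}] must be strictly positive")
            if self.base_entry_weight[s] <= 0:
                raise ValueError(f"base_entry_weight[{s!r}] must be strictly positive")
            med, gsd = self.magnitude_dist[s]
            if med <= 0 or gsd < 1.0:
                raise ValueError(
                    f"magnitude_dist[{s!r}] needs median > 0 and geometric SD >= 1"
                )
        if self.epoch_seconds <= 0 or 60 % self.epoch_seconds != 0:
            raise ValueError("epoch_seconds must be positive and divide 60")
        if self.days < 1:
            raise ValueError("recording must span at least one day")
        if self.nonwear_episodes_per_day < 0 or self.nonwear_mean_minutes <= 0:
            raise ValueError("non-wear rate/duration must be non-negative/positive")

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_seconds

    @property
    def n_epochs(self) -> int:
        return self.days * self.epochs_per_day


# ---------------------------------------------------------------------------
# Participant table generation
# ---------------------------------------------------------------------------

AGE_BIN_EDGES = np.arange(45.0, 85.0, 5.0)  # 45,50,...,80

# RA age-bin probabilities follow the study population's marginal
# distribution (74.6% aged >= 60); the control pool skews younger.
_RA_AGE_PROBS = np.array([37, 90, 148, 207, 310, 251, 39], float)
_RA_AGE_PROBS /= _RA_AGE_PROBS.sum()
_CTRL_AGE_PROBS = np.array([9, 12, 15, 18, 19, 17, 10], float)
_CTRL_AGE_PROBS /= _CTRL_AGE_PROBS.sum()

_BMI_EDGES = np.array([16.0, 18.5, 25.0, 30.0, 40.0, 45.0])
_RA_BMI_PROBS = np.array([7, 332, 446, 267, 26], float)
_RA_BMI_PROBS /= _RA_BMI_PROBS.sum()
_CTRL_BMI_PROBS = np.array([0.015, 0.36, 0.40, 0.20, 0.025])


@dataclass
class CohortConfig:
    """Distribution settings of the synthetic participant table.

    Defaults follow the RA study population's marginals (67.0% female,
    74.6% aged >= 60, ADI mean -1.48 / SD 2.88, Table-style smoking,
    alcohol, chronotype, season and onset frequencies); the control pool
    is configured with mild imbalances on the post-matching covariates so
    the covariate-adjustment stage has something to adjust for.
    """

    female_frac: dict = _dict_field({"RA": 0.670, "control": 0.56})
    adi_mean: dict = _dict_field({"RA": -1.48, "control": 0.0})
    adi_sd: dict = _dict_field({"RA": 2.88, "control": 3.0})
    smoking_probs: dict = _dict_field(
        {"RA": (0.469, 0.525, 0.006), "control": (0.52, 0.474, 0.006)}
    )  # ever / never / unknown
    alcohol_probs: dict = _dict_field(
        {
            "RA": (0.170, 0.196, 0.248, 0.128, 0.150, 0.108),
            "control": (0.21, 0.24, 0.25, 0.11, 0.11, 0.08),
        }
    )
    chronotype_probs: dict = _dict_field(
        {"RA": (0.543, 0.324, 0.133), "control": (0.58, 0.28, 0.14)}
    )  # morning / evening / unknown
    season_probs: dict = _dict_field(
        {"RA": (0.25, 0.20, 0.35, 0.20), "control": (0.25, 0.27, 0.25, 0.23)}
    )
    working_frac: dict = _dict_field({"RA": 0.35, "control": 0.45})
    seropositive_frac: float = 0.087
    early_onset_frac: float = 0.740
    source_probs: tuple = (0.089, 0.283, 0.628)  # primary care / hospital / self-report
    comorbidity_probs: dict = _dict_field(
        {
            "heart_failure": 0.012,
            "respiratory_failure": 0.003,
            "stroke": 0.009,
            "thyroiditis": 0.002,
            "sjogren_syndrome": 0.008,
        }
    )
    rf_tested_frac: float = 0.30  # controls with a rheumatoid-factor result
    rf_median: float = 6.0  # IU/mL
    rf_gsd: float = 2.0
    diagnosed_after_recording_frac: float = 0.03
    duplicate_diagnosis_frac: float = 0.05


def _draw_categorical(rng, probs, n):
    probs = np.asarray(probs, float)
    return rng.choice(len(probs), size=n, p=probs / probs.sum())


def _draw_ages(rng, probs, n):
    bins = _draw_categorical(rng, probs, n)
    return AGE_BIN_EDGES[bins] + rng.uniform(0.0, 5.0, n)


def _draw_bmi(rng, probs, n):
    bins = _draw_categorical(rng, probs, n)
    lo = _BMI_EDGES[bins]
    hi = _BMI_EDGES[bins + 1]
    return lo + rng.uniform(0.0, 1.0, n) * (hi - lo)


def generate_cohort(
    n_ra: int,
    n_pool: int,
    seed: int,
    config: Optional[CohortConfig] = None,
) -> list:
    """Generate ``n_ra`` RA profiles plus an ``n_pool`` control pool.

    Deterministic given ``seed``. Requires ``n_pool >= 2 * n_ra`` so a
    2:1 matched design is in principle possible.
    """
    if n_ra < 1 or n_pool < 1:
        raise ValueError("participant counts must be positive")
    if n_pool < 2 * n_ra:
        raise ValueError("control pool must hold at least 2 controls per case")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    profiles = []
    for group, n, prefix in (("RA", n_ra, "RA"), ("control", n_pool, "C")):
        age_probs = _RA_AGE_PROBS if group == "RA" else _CTRL_AGE_PROBS
        bmi_probs = _RA_BMI_PROBS if group == "RA" else _CTRL_BMI_PROBS
        ages = np.clip(_draw_ages(rng, age_probs, n), 45.0, 80.0)
        sexes = np.where(
            rng.random(n) < config.female_frac[group], "female", "male"
        )
        bmis = _draw_bmi(rng, bmi_probs, n)
        adis = rng.normal(config.adi_mean[group], config.adi_sd[group], n)
        smoking = _draw_categorical(rng, config.smoking_probs[group], n)
        alcohol = _draw_categorical(rng, config.alcohol_probs[group], n)
        chrono = _draw_categorical(rng, config.chronotype_probs[group], n)
        season = _draw_categorical(rng, config.season_probs[group], n)
        working = rng.random(n) < config.working_frac[group]
        comorb_draws = {
            c: rng.random(n) < p for c, p in config.comorbidity_probs.items()
        }
        for i in range(n):
            kwargs = dict(
                id=f"{prefix}{i + 1:06d}",
                group=group,
                age=float(ages[i]),
                sex=str(sexes[i]),
                bmi=float(bmis[i]),
                adi=float(adis[i]),
                smoking=("ever", "never", "unknown")[smoking[i]],
                alcohol=ALCOHOL_LEVELS[alcohol[i]],
                chronotype=("morning", "evening", "unknown")[chrono[i]],
                season=SEASONS[season[i]],
                working=bool(working[i]),
                comorbidities=tuple(
                    c for c in COMORBIDITIES if comorb_draws[c][i]
                ),
            )
            if group == "RA":
                early = rng.random() < config.early_onset_frac
                age_now = kwargs["age"]
                if early:
                    lo = min(30.0, age_now - 1.0)
                    hi = min(LATE_ONSET_AGE - 0.5, age_now)
                    age_dx = float(rng.uniform(lo, hi))
                    onset = "early"
                else:
                    hi = max(age_now, LATE_ONSET_AGE + 0.5)
                    age_dx = float(rng.uniform(LATE_ONSET_AGE, hi))
                    onset = "late"
                src = ("primary_care", "hospital", "self_report")[
                    _draw_categorical(rng, config.source_probs, 1)[0]
                ]
                dup = ()
                if rng.random() < config.duplicate_diagnosis_frac:
                    other = ("primary_care", "hospital", "self_report")[
                        _draw_categorical(rng, config.source_probs, 1)[0]
                    ]
                    dup = tuple(sorted({src, other}))
                kwargs.update(
                    diagnosis_source=src,
                    diagnosis_type=(
                        "seropositive"
                        if rng.random() < config.seropositive_frac
                        else "other"
                    ),
                    onset=onset,
                    age_at_diagnosis=age_dx,
                    diagnosed_after_recording=bool(
                        rng.random() < config.diagnosed_after_recording_frac
                    ),
                    duplicate_diagnosis_sources=dup,
                )
            else:
                if rng.random() < config.rf_tested_frac:
                    kwargs["rheumatoid_factor"] = float(
                        config.rf_median
                        * np.exp(np.log(config.rf_gsd) * rng.standard_normal())
                    )
            profiles.append(ParticipantProfile(**kwargs))
    return profiles


def profiles_to_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    """Participant table: one row per profile."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "id": p.id,
                "group": p.group,
                "age": p.age,
                "sex": p.sex,
                "bmi": p.bmi,
                "adi": p.adi,
                "smoking": p.smoking,
                "alcohol": p.alcohol,
                "chronotype": p.chronotype,
                "season": p.season,
                "working": p.working,
                "diagnosis_source": p.diagnosis_source,
                "diagnosis_type": p.diagnosis_type,
                "onset": p.onset,
                "age_at_diagnosis": p.age_at_diagnosis,
                "comorbidities": ";".join(p.comorbidities),
                "rheumatoid_factor": p.rheumatoid_factor,
                "diagnosed_after_recording": p.diagnosed_after_recording,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Activity-state simulation
# ---------------------------------------------------------------------------


def _rate_tables(params: ActivityModelParams, effect: Optional[RAEffect]):
    """Per-time-of-day entry-weight and sojourn-mean tables, shape (epd, 5)."""
    epd = params.epochs_per_day
    hours = np.arange(epd) * params.epoch_seconds / 3600.0
    W = np.empty((epd, N_STATES))
    M = np.empty((epd, N_STATES))
    for j, s in enumerate(STATES):
        peak, a_entry, a_sojourn = params.circadian[s]
        phase = np.cos(2 * np.pi * (hours - peak) / 24.0)
        W[:, j] = params.base_entry_weight[s] * np.exp(a_entry * phase)
        mean_epochs = params.mean_run_minutes[s] * 60.0 / params.epoch_seconds
        M[:, j] = mean_epochs * np.exp(a_sojourn * phase)
    if effect is not None:
        j_mvpa = STATES.index("MVPA")
        j_walk = STATES.index("walking")
        if effect.mvpa_time_ratio > 1.0:
            # rate increases are approximated by weight scaling; decreases
            # are applied exactly by entry thinning in the simulation loop
            W[:, j_mvpa] *= effect.mvpa_time_ratio
        M[:, j_mvpa] *= effect.mvpa_run_ratio
        if effect.morning_delay_minutes > 0:
            # ramp MVPA/walking entry rates from 0 to 1 over the delay
            # window after the nocturnal phase ends; unchanged elsewhere
            wake = params.morning_reference_hour
            delay_h = effect.morning_delay_minutes / 60.0
            scale = np.where(
                (hours >= wake) & (hours < wake + delay_h),
                np.clip((hours - wake) / delay_h, 0.0, 1.0),
                1.0,
            )
            W[:, j_mvpa] *= scale
            W[:, j_walk] *= scale
        if effect.sleep_interrupt_rate_ratio != 1.0:
            lo, hi = params.nocturnal_window
            night = (hours >= lo) | (hours < hi)
            for s in ("sedentary", "light"):
                W[night, STATES.index(s)] *= effect.sleep_interrupt_rate_ratio
    return W, M


def _simulate_codes_batch(
    n: int,
    params: ActivityModelParams,
    effect: Optional[RAEffect],
    is_ra: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n`` participants' state codes, shape (n, n_epochs).

    Participants advance one sojourn per iteration in lock-step; per-state
    person frailties on the entry weights are drawn first so that the same
    generator stream always yields the same cohort.
    """
    total = params.n_epochs
    epd = params.epochs_per_day
    sigma = np.array([params.frailty_sigma[s] for s in STATES])
    frailty = np.exp(sigma * rng.standard_normal((n, N_STATES)))
    W_ctrl, M_ctrl = _rate_tables(params, None)
    W_ra, M_ra = _rate_tables(params, effect) if effect is not None else (W_ctrl, M_ctrl)
    is_ra = np.asarray(is_ra, bool)

    cur = np.zeros(n, dtype=np.int64)  # next epoch to fill
    prev = np.full(n, -1, dtype=np.int64)  # previous state, -1 at start
    states_seq = []
    lens_seq = []
    while True:
        active = cur < total
        if not active.any():
            break
        tbin = cur % epd
        W = np.where(is_ra[:, None], W_ra[tbin], W_ctrl[tbin]) * frailty
        # forbid immediate self-transition
        has_prev = prev >= 0
        W[has_prev, prev[has_prev]] = 0.0
        cdf = np.cumsum(W, axis=1)
        u = rng.random(n) * cdf[:, -1]
        state = (u[:, None] >= cdf).sum(axis=1).astype(np.int64)
        if effect is not None and effect.mvpa_time_ratio < 1.0:
            # thin accepted MVPA entries so the entry probability scales
            # by exactly mvpa_time_ratio; rejected entries redraw from
            # the remaining states
            j_mvpa = STATES.index("MVPA")
            u2 = rng.random(n)
            reject = active & is_ra & (state == j_mvpa) & (
                u2 > effect.mvpa_time_ratio
            )
            if reject.any():
                W2 = W[reject].copy()
                W2[:, j_mvpa] = 0.0
                cdf2 = np.cumsum(W2, axis=1)
                u3 = rng.random(int(reject.sum())) * cdf2[:, -1]
                state[reject] = (u3[:, None] >= cdf2).sum(axis=1)
        mean_ep = np.where(
            is_ra, M_ra[tbin, state], M_ctrl[tbin, state]
        )
        p = 1.0 / np.maximum(mean_ep, 1.0)
        length = rng.geometric(p)
        length = np.minimum(length, total - cur)
        length[~active] = 0
        states_seq.append(state)
        lens_seq.append(length)
        prev = np.where(active, state, prev)
        cur = cur + length
    states_arr = np.stack(states_seq, axis=1)  # (n, iters)
    lens_arr = np.stack(lens_seq, axis=1)
    out = np.empty((n, total), dtype=np.int8)
    for i in range(n):
        li = lens_arr[i]
        nz = li > 0
        out[i] = np.repeat(states_arr[i, nz].astype(np.int8), li[nz])
    return out


def simulate_labels(
    profile: ParticipantProfile,
    params: ActivityModelParams,
    effect: Optional[RAEffect],
    seed: int,
) -> LabelSeries:
    """Simulate one participant's activity-state label sequence.

    ``effect`` applies only to RA profiles; passing an effect with a
    control profile is rejected. Deterministic given ``seed``.
    """
    if effect is not None and profile.group != "RA":
        raise ValueError("RA effects apply only to RA profiles")
    rng = np.random.default_rng(seed)
    codes = _simulate_codes_batch(
        1, params, effect, np.array([profile.group == "RA"]), rng
    )[0]
    return LabelSeries(pd.Timestamp(params.start_date), params.epoch_seconds, codes)


def simulate_cohort_labels(
    profiles: Sequence[ParticipantProfile],
    params: ActivityModelParams,
    effect: Optional[RAEffect],
    seed: int,
) -> list:
    """Simulate many participants at once (vectorized; deterministic)."""
    rng = np.random.default_rng(seed)
    is_ra = np.array([p.group == "RA" for p in profiles])
    codes = _simulate_codes_batch(len(profiles), params, effect, is_ra, rng)
    start = pd.Timestamp(params.start_date)
    return [
        LabelSeries(start, params.epoch_seconds, codes[i])
        for i in range(len(profiles))
    ]


def _magnitudes_batch(
    codes: np.ndarray, params: ActivityModelParams, rng: np.random.Generator
):
    """Magnitudes + wear masks for codes of shape (n, n_epochs)."""
    if codes.min() < 0 or codes.max() >= N_STATES:
        raise ValueError("label outside the activity state set")
    n, total = codes.shape
    med = np.array([params.magnitude_dist[s][0] for s in STATES], dtype=np.float32)
    lgsd = np.log([params.magnitude_dist[s][1] for s in STATES]).astype(np.float32)
    mag_frailty = np.exp(
        params.magnitude_frailty_sigma * rng.standard_normal((n, 1))
    ).astype(np.float32)
    # single-precision in-place pipeline: the per-epoch draw is
    # median * exp(log(gsd) * z), scaled by the person's magnitude frailty
    values = rng.standard_normal((n, total), dtype=np.float32)
    values *= np.take(lgsd, codes)
    np.exp(values, out=values)
    values *= np.take(med, codes)
    values *= mag_frailty
    wear = np.ones((n, total), dtype=bool)
    lam = params.nonwear_episodes_per_day * params.days
    if lam > 0:
        n_eps = rng.poisson(lam, size=n)
        for i in range(n):
            for _ in range(n_eps[i]):
                start = rng.integers(0, total)
                dur = max(
                    1,
                    int(
                        rng.exponential(params.nonwear_mean_minutes)
                        * 60
                        / params.epoch_seconds
                    ),
                )
                wear[i, start : start + dur] = False
        # non-worn device resting on a surface: tiny near-constant signal
        nw = ~wear
        values[nw] = np.abs(1.0 + 0.5 * rng.standard_normal(int(nw.sum())))
    return values, wear


def simulate_magnitudes(
    labels: LabelSeries, params: ActivityModelParams, seed: int
) -> EpochSeries:
    """Draw per-epoch magnitudes from the label-conditional log-normals.

    Non-wear episodes (Poisson count, exponential duration) are masked out
    in the returned series; their recorded values emulate a stationary
    unworn device. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    values, wear = _magnitudes_batch(labels.codes[None, :], params, rng)
    return EpochSeries(
        labels.start_time, labels.epoch_seconds, values[0], wear[0]
    )


def simulate_recording(
    profile: ParticipantProfile,
    params: ActivityModelParams,
    effect: Optional[RAEffect],
    seed: int,
):
    """Labels + magnitudes for one participant, non-wear reconciled.

    Returns ``(series, labels)`` where nonwear labels coincide with
    wear_mask=False.
    """
    labels = simulate_labels(profile, params, effect, seed)
    series = simulate_magnitudes(labels, params, seed + 1)
    return series, labels.with_nonwear(series.wear_mask)
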