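"""Per-epoch activity labels and label-derived structures.

The analysis consumes per-epoch activity-state labels (sleep / sedentary /
light / MVPA / walking / nonwear). Labels normally come from an external
human-activity-recognition model; when none are supplied a simple
cutpoint-based fallback labeler is used. From the labels this module
derives consolidated night-time lying-down windows (one per noon-to-noon
night), estimated get-up times, and sustained walking (ambulatory) bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSeries

__all__ = [
    "LABELS",
    "SLEEP",
    "SEDENTARY",
    "LIGHT",
    "MVPA",
    "WALKING",
    "NONWEAR",
    "LabelSeries",
    "NightWindow",
    "AmbulatoryBout",
    "SleepConfig",
    "NightConfig",
    "fallback_labeler",
    "night_spans",
    "consolidate_night",
    "consolidate_nights",
    "getup_time",
    "ambulatory_bouts",
    "run_length_encode",
]

LABELS = ("sleep", "sedentary", "light", "MVPA", "walking", "nonwear")
SLEEP, SEDENTARY, LIGHT, MVPA, WALKING, NONWEAR = range(6)
_LABEL_TO_CODE = {name: i for i, name in enumerate(LABELS)}

#: Intensity cutpoints (mg) shared across the analysis: sedentary <40,
#: light/active 40-<100, MVPA >=100.
LIGHT_CUTPOINT_MG = 40.0
MVPA_CUTPOINT_MG = 100.0


def run_length_encode(codes: np.ndarray):
    """Return (starts, lengths, values) of the maximal constant runs."""
    codes = np.asarray(codes)
    if codes.size == 0:
        return (np.array([], int), np.array([], int), codes)
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    return starts, ends - starts, codes[starts]


@dataclass
class LabelSeries:
    """Per-epoch activity-state labels on an epoch grid.

    ``codes`` holds small integers indexing :data:`LABELS`. Aligned to an
    :class:`~actipat.preprocess.EpochSeries` via matching ``start_time``,
    ``epoch_seconds`` and length; ``nonwear`` labels must coincide with
    wear_mask=False on the paired series.
    """

    start_time: pd.Timestamp
    epoch_seconds: int
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if self.codes.size == 0:
            raise ValueError("label series must be non-empty")
        if self.codes.min() < 0 or self.codes.max() >= len(LABELS):
            raise ValueError("label code outside the label set")

    @classmethod
    def from_strings(cls, start_time, epoch_seconds: int, labels: Sequence[str]):
        try:
            codes = np.array([_LABEL_TO_CODE[l] for l in labels], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"unknown activity label {exc.args[0]!r}") from None
        return cls(start_time, epoch_seconds, codes)

    def to_strings(self) -> list:
        return [LABELS[c] for c in self.codes]

    @property
    def n_epochs(self) -> int:
        return self.codes.size

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_seconds

    def epoch_of_day(self) -> np.ndarray:
        offset = int(
            (self.start_time - self.start_time.normalize()).total_seconds()
            // self.epoch_seconds
        )
        return (offset + np.arange(self.n_epochs)) % self.epochs_per_day

    def time_index(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=f"{self.epoch_seconds}s"
        )

    def with_nonwear(self, wear_mask: np.ndarray) -> "LabelSeries":
        """Return a copy with nonwear set wherever the device was not worn."""
        codes = self.codes.copy()
        codes[~np.asarray(wear_mask, bool)] = NONWEAR
        return LabelSeries(self.start_time, self.epoch_seconds, codes)


@dataclass(frozen=True)
class NightWindow:
    """Consolidated night-time lying-down window for one noon-to-noon night."""

    night_index: int
    start: pd.Timestamp
    end: pd.Timestamp
    sleep_epochs: int
    movement_episodes: int
    #: slice of the window in the parent label series (epoch indices)
    start_epoch: int = field(compare=False, default=0)
    end_epoch: int = field(compare=False, default=0)  # exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("night window must have start < end")
        if self.movement_episodes < 0:
            raise ValueError("movement_episodes must be non-negative")


@dataclass(frozen=True)
class AmbulatoryBout:
    """Sustained walking period with at most one internal break."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_class: str  # "2-10 min", "10-30 min", ">30 min"
    break_seconds_used: float
    start_epoch: int = field(compare=False, default=0)
    end_epoch: int = field(compare=False, default=0)  # exclusive


@dataclass(frozen=True)
class SleepConfig:
    """Fallback-labeler sleep rule: long quiescent sedentary runs."""

    min_minutes: float = 30.0
    max_mg: float = 10.0


@dataclass(frozen=True)
class NightConfig:
    """Night-window expansion rule: grow from the longest sleep run in
    fixed blocks while the adjacent block is at least half sleep."""

    block_minutes: float = 30.0
    min_sleep_fraction: float = 0.5


def fallback_labeler(
    series: EpochSeries,
    cutpoints=(LIGHT_CUTPOINT_MG, MVPA_CUTPOINT_MG),
    sleep_config: SleepConfig = SleepConfig(),
) -> LabelSeries:
    """Threshold-based label fallback when no HAR labels are available.

    Epochs are classed MVPA (>= upper cutpoint), light (>= lower cutpoint)
    or sedentary; sustained quiescent sedentary runs (>= ``min_minutes``
    long with mean magnitude < ``max_mg``) are relabeled sleep; non-wear
    epochs are labeled nonwear. The fallback never emits walking labels.
    """
    lo, hi = cutpoints
    if not lo < hi:
        raise ValueError("cutpoints must be strictly increasing")
    codes = np.full(series.n_epochs, SEDENTARY, dtype=np.int8)
    codes[series.values >= lo] = LIGHT
    codes[series.values >= hi] = MVPA
    codes[~series.wear_mask] = NONWEAR
    min_epochs = int(round(sleep_config.min_minutes * 60 / series.epoch_seconds))
    starts, lengths, vals = run_length_encode(codes)
    for s, ln, v in zip(starts, lengths, vals):
        if v == SEDENTARY and ln >= min_epochs:
            if series.values[s : s + ln].mean() < sleep_config.max_mg:
                codes[s : s + ln] = SLEEP
    return LabelSeries(series.start_time, series.epoch_seconds, codes)


def night_spans(labels: LabelSeries) -> list:
    """Noon-to-noon spans fully contained in the recording.

    Returns ``(night_index, start_epoch, end_epoch)`` triples; the first and
    last partial noon-to-noon days are dropped so a sleep period is never
    truncated by the recording edge.
    """
    epd = labels.epochs_per_day
    half = epd // 2
    offset = int(
        (labels.start_time - labels.start_time.normalize()).total_seconds()
        // labels.epoch_seconds
    )
    # epoch index (relative to recording start) of the first noon boundary
    first_noon = (half - offset) % epd
    spans = []
    night = 0
    s = first_noon
    while s + epd <= labels.n_epochs:
        spans.append((night, s, s + epd))
        night += 1
        s += epd
    return spans


def consolidate_night(
    labels: LabelSeries,
    span: tuple,
    config: NightConfig = NightConfig(),
) -> Optional[NightWindow]:
    """Consolidate one night's lying-down window from its sleep labels.

    The window is initialized at the longest sleep run inside the
    noon-to-noon span and grown outward in fixed blocks (default 30 min)
    while the adjacent block contains at least ``min_sleep_fraction`` sleep
    epochs, stopping when neither edge extends. Returns None when the span
    holds no sleep at all.
    """
    night_index, lo, hi = span
    codes = labels.codes
    starts, lengths, vals = run_length_encode(codes[lo:hi])
    sleep_runs = [(s, ln) for s, ln, v in zip(starts, lengths, vals) if v == SLEEP]
    if not sleep_runs:
        return None
    s, ln = max(sleep_runs, key=lambda r: r[1])
    wstart, wend = lo + s, lo + s + ln  # [wstart, wend) in recording epochs
    block = int(round(config.block_minutes * 60 / labels.epoch_seconds))
    if block < 1:
        raise ValueError("block must cover at least one epoch")
    while True:
        grew = False
        left = max(lo, wstart - block)
        if left < wstart:
            seg = codes[left:wstart]
            if (seg == SLEEP).mean() >= config.min_sleep_fraction:
                wstart = left
                grew = True
        right = min(hi, wend + block)
        if right > wend:
            seg = codes[wend:right]
            if (seg == SLEEP).mean() >= config.min_sleep_fraction:
                wend = right
                grew = True
        if not grew:
            break
    window = codes[wstart:wend]
    sleep_epochs = int((window == SLEEP).sum())
    _, _, wvals = run_length_encode(window)
    movement = int(np.sum(wvals != SLEEP))
    step = pd.Timedelta(seconds=labels.epoch_seconds)
    return NightWindow(
        night_index=night_index,
        start=labels.start_time + wstart * step,
        end=labels.start_time + wend * step,
        sleep_epochs=sleep_epochs,
        movement_episodes=movement,
        start_epoch=int(wstart),
        end_epoch=int(wend),
    )


def consolidate_nights(
    labels: LabelSeries, config: NightConfig = NightConfig()
) -> list:
    """All nights' windows (absent nights skipped, not fatal)."""
    out = []
    for span in night_spans(labels):
        w = consolidate_night(labels, span, config)
        if w is not None:
            out.append(w)
    return out


def getup_time(window: Optional[NightWindow]) -> Optional[pd.Timestamp]:
    """Estimated time of getting up: the end of the consolidated window."""
    return None if window is None else window.end


# Ambulatory-bout break allowances (seconds) by resulting duration class.
_SHORT_BREAK_S = 30.0  # 2-10 min bouts
_LONG_BREAK_S = 60.0  # 10-30 min and >30 min bouts
_MIN_BOUT_MINUTES = 2.0


def _duration_class(minutes: float) -> str:
    if minutes >= 30.0:
        return ">30 min"
    if minutes >= 10.0:
        return "10-30 min"
    return "2-10 min"


def ambulatory_bouts(labels: LabelSeries) -> list:
    """Sustained walking bouts with at most one internal break.

    Maximal walking runs may be merged across a single non-walking gap of
    up to 30 s when the merged bout stays under 10 minutes, or up to 1 min
    when it reaches 10 minutes or longer; merged duration includes the gap.
    Bouts start and end on walking epochs and must last at least 2 minutes.
    """
    es = labels.epoch_seconds
    starts, lengths, vals = run_length_encode(labels.codes)
    runs = [
        (int(s), int(ln)) for s, ln, v in zip(starts, lengths, vals) if v == WALKING
    ]
    min_epochs = int(round(_MIN_BOUT_MINUTES * 60 / es))
    out = []
    step = pd.Timedelta(seconds=es)

    def emit(start_ep: int, end_ep: int, break_epochs: int) -> None:
        n = end_ep - start_ep
        if n < min_epochs:
            return
        minutes = n * es / 60.0
        out.append(
            AmbulatoryBout(
                start=labels.start_time + start_ep * step,
                end=labels.start_time + end_ep * step,
                duration_class=_duration_class(minutes),
                break_seconds_used=break_epochs * es,
                start_epoch=start_ep,
                end_epoch=end_ep,
            )
        )

    i = 0
    while i < len(runs):
        s, ln = runs[i]
        if i + 1 < len(runs):
            s2, ln2 = runs[i + 1]
            gap = s2 - (s + ln)
            merged = ln + gap + ln2
            allowance = _LONG_BREAK_S if merged * es >= 600 else _SHORT_BREAK_S
            if gap * es <= allowance and merged >= min_epochs:
                emit(s, s2 + ln2, gap)
                i += 2
                continue
        emit(s, s + ln, 0)
        i += 1
    return out
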