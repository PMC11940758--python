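"""Epoch-level accelerometer preprocessing.

Converts tri-axial samples to ENMO magnitude, aggregates to a uniform
30-second epoch grid, detects non-wear, imputes missing epochs by
time-of-day means, and enforces the minimum-wear-time validity rule.

All magnitudes are in milligravities (mg). The ENMO convention is the
Euclidean norm of the (x, y, z) acceleration vector minus one gravity
(1000 mg), truncated at zero so that a stationary device reads 0 mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "ValidityReport",
    "enmo",
    "epoch_aggregate",
    "detect_nonwear",
    "impute_missing",
    "check_validity",
]

DEFAULT_EPOCH_SECONDS = 30
#: Non-wear rule: windows of at least this many minutes ...
DEFAULT_NONWEAR_WINDOW_MINUTES = 60
#: ... whose magnitude standard deviation falls below this (mg) are non-wear.
DEFAULT_NONWEAR_SD_MG = 13.0
#: Minimum total wear time (hours) for a recording to enter the analysis.
DEFAULT_MIN_WEAR_HOURS = 72.0


@dataclass
class EpochSeries:
    """Uniform epoch grid of acceleration magnitude for one participant.

    Parameters
    ----------
    start_time
        Timestamp of the first epoch (timezone-naive local time).
    epoch_seconds
        Epoch length in seconds; must be positive and divide 60.
    values
        Magnitude per epoch in mg; finite and non-negative.
    wear_mask
        True where the device was worn.
    imputed_mask
        True where ``values`` was filled in by imputation.
    """

    start_time: pd.Timestamp
    epoch_seconds: int
    values: np.ndarray
    wear_mask: np.ndarray = None
    imputed_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.epoch_seconds <= 0 or 60 % self.epoch_seconds != 0:
            raise ValueError("epoch_seconds must be positive and divide 60")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("magnitude values must be finite")
        if np.any(self.values < 0):
            raise ValueError("magnitude values must be non-negative")
        if self.wear_mask is None:
            self.wear_mask = np.ones(self.values.shape, dtype=bool)
        self.wear_mask = np.asarray(self.wear_mask, dtype=bool)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(self.values.shape, dtype=bool)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.wear_mask.shape != self.values.shape:
            raise ValueError("wear_mask length must match values")
        if self.imputed_mask.shape != self.values.shape:
            raise ValueError("imputed_mask length must match values")

    @property
    def n_epochs(self) -> int:
        return self.values.size

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_seconds

    def time_index(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=f"{self.epoch_seconds}s"
        )

    def epoch_of_day(self) -> np.ndarray:
        """Index of each epoch within its calendar day (0 .. epochs_per_day-1)."""
        offset = (
            self.start_time - self.start_time.normalize()
        ).total_seconds() / self.epoch_seconds
        if offset != int(offset):
            raise ValueError("start_time is not aligned to the epoch grid")
        return (int(offset) + np.arange(self.n_epochs)) % self.epochs_per_day

    def day_index(self) -> np.ndarray:
        """Calendar-day ordinal of each epoch (0 = day of start_time)."""
        offset = int(
            (self.start_time - self.start_time.normalize()).total_seconds()
            // self.epoch_seconds
        )
        return (offset + np.arange(self.n_epochs)) // self.epochs_per_day

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            self.start_time,
            self.epoch_seconds,
            self.values.copy(),
            self.wear_mask.copy(),
            self.imputed_mask.copy(),
        )


@dataclass(frozen=True)
class ValidityReport:
    """Wear-time summary against the minimum-hours validity rule."""

    total_wear_hours: float
    valid: bool
    per_day_wear_hours: tuple


def enmo(x, y, z):
    """Euclidean Norm Minus One magnitude, truncated at zero.

    Inputs are tri-axial acceleration in mg; output is max(0, ||v|| - 1000).
    Accepts scalars or arrays (broadcast elementwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (
        np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))
    ):
        raise ValueError("enmo requires finite inputs")
    out = np.maximum(0.0, np.sqrt(x * x + y * y + z * z) - 1000.0)
    return float(out) if out.ndim == 0 else out


def epoch_aggregate(
    timestamps,
    magnitudes,
    epoch_seconds: int = DEFAULT_EPOCH_SECONDS,
    start_time=None,
) -> EpochSeries:
    """Average magnitude samples onto a uniform epoch grid.

    Each epoch value is the mean of the samples with timestamps in
    ``[t, t + epoch_seconds)``; epochs receiving no samples are marked
    non-wear (value 0).

    Parameters
    ----------
    timestamps
        Sorted sample timestamps (anything ``pd.DatetimeIndex`` accepts).
    magnitudes
        Sample magnitudes in mg, same length as ``timestamps``.
    start_time
        Grid origin; defaults to the first timestamp floored to the epoch.
    """
    ts = pd.DatetimeIndex(timestamps)
    mags = np.asarray(magnitudes, dtype=float)
    if len(ts) != mags.size:
        raise ValueError("timestamps and magnitudes must have equal length")
    if len(ts) == 0:
        raise ValueError("cannot aggregate an empty sample sequence")
    if not ts.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted ascending")
    if start_time is None:
        start_time = ts[0].floor(f"{epoch_seconds}s")
    start_time = pd.Timestamp(start_time)
    idx = ((ts - start_time).total_seconds() // epoch_seconds).astype(int)
    if np.any(idx < 0):
        raise ValueError("samples precede start_time")
    n = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n)
    sums = np.bincount(idx, weights=mags, minlength=n)
    wear = counts > 0
    values = np.zeros(n)
    values[wear] = sums[wear] / counts[wear]
    return EpochSeries(start_time, epoch_seconds, values, wear)


def _rolling_sd(values: np.ndarray, window: int) -> np.ndarray:
    """Population SD over every contiguous window of exactly ``window`` epochs."""
    c1 = np.concatenate(([0.0], np.cumsum(values)))
    c2 = np.concatenate(([0.0], np.cumsum(values**2)))
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = np.maximum(0.0, s2 / window - (s1 / window) ** 2)
    return np.sqrt(var)


def detect_nonwear(
    series: EpochSeries,
    window_minutes: float = DEFAULT_NONWEAR_WINDOW_MINUTES,
    sd_threshold: float = DEFAULT_NONWEAR_SD_MG,
) -> EpochSeries:
    """Flag low-variability stretches as non-wear.

    Every epoch covered by at least one window of ``window_minutes`` whose
    magnitude standard deviation is below ``sd_threshold`` has its wear flag
    cleared. Idempotent; already-non-wear epochs stay non-wear.
    """
    window = int(round(window_minutes * 60 / series.epoch_seconds))
    if window < 1:
        raise ValueError("non-wear window must cover at least one epoch")
    out = series.copy()
    if series.n_epochs < window:
        return out
    sd = _rolling_sd(series.values, window)
    low = sd < sd_threshold
    if not low.any():
        return out
    # Mark all epochs covered by any flagged window via a difference array.
    cover = np.zeros(series.n_epochs + 1, dtype=int)
    starts = np.flatnonzero(low)
    np.add.at(cover, starts, 1)
    np.add.at(cover, starts + window, -1)
    flagged = np.cumsum(cover[:-1]) > 0
    out.wear_mask &= ~flagged
    return out


def impute_missing(series: EpochSeries) -> EpochSeries:
    """Fill non-wear epochs with the same-time-of-day mean over wear epochs.

    The mean is taken across the whole recording at each epoch-of-day slot.
    Raises if some non-wear epoch's slot has no wear data anywhere (the slot
    is named in the error). Wear epochs are never modified.
    """
    out = series.copy()
    missing = ~series.wear_mask
    if not missing.any():
        return out
    slot = series.epoch_of_day()
    nslot = series.epochs_per_day
    wear = series.wear_mask
    counts = np.bincount(slot[wear], minlength=nslot)
    sums = np.bincount(slot[wear], weights=series.values[wear], minlength=nslot)
    needed = np.unique(slot[missing])
    empty = needed[counts[needed] == 0]
    if empty.size:
        sec = int(empty[0]) * series.epoch_seconds
        raise ValueError(
            "no wear data anywhere at time-of-day slot "
            f"{sec // 3600:02d}:{sec % 3600 // 60:02d}:{sec % 60:02d}"
        )
    slot_mean = np.zeros(nslot)
    ok = counts > 0
    slot_mean[ok] = sums[ok] / counts[ok]
    out.values[missing] = slot_mean[slot[missing]]
    out.imputed_mask |= missing
    return out


def check_validity(
    series: EpochSeries, min_hours: float = DEFAULT_MIN_WEAR_HOURS
) -> ValidityReport:
    """Check the total-wear-time validity rule (default 72 h)."""
    hours_per_epoch = series.epoch_seconds / 3600.0
    total = float(series.wear_mask.sum() * hours_per_epoch)
    day = series.day_index()
    per_day = np.bincount(day[series.wear_mask], minlength=int(day[-1]) + 1 if series.n_epochs else 0)
    return ValidityReport(
        total_wear_hours=total,
        valid=total >= min_hours,
        per_day_wear_hours=tuple(per_day * hours_per_epoch),
    )
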