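"""Sustained-activity bout detection.

A bout is a maximal time interval whose boundary epochs satisfy an
intensity predicate, whose internal runs of non-compliant epochs each last
no longer than a break tolerance, and whose total duration reaches a
minimum. The production detector (:func:`detect_bouts`) works on maximal
runs of the compliance mask; :func:`oracle_bouts` re-derives the same set
by forward-scanning every candidate start and is used only as a reference
in tests. Non-wear epochs are non-compliant for every predicate and break
bouts regardless of the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .labeling import LIGHT_CUTPOINT_MG, MVPA_CUTPOINT_MG, run_length_encode
from .preprocess import EpochSeries

__all__ = ["BoutConfig", "Bout", "detect_bouts", "oracle_bouts", "sedentary_complement"]

#: Default minimum durations (minutes) per intensity predicate.
DEFAULT_MIN_DURATION = {"sedentary": 10.0, "active": 10.0, "MVPA": 3.0}

ORACLE_DEFAULT_CAP = 5000


@dataclass(frozen=True)
class BoutConfig:
    """Bout semantics: intensity predicate, minimum duration, break tolerance."""

    predicate: str  # "sedentary" (<40 mg), "active" (40-<100 mg), "MVPA" (>=100 mg)
    min_duration_minutes: Optional[float] = None
    break_tolerance_epochs: int = 1

    def __post_init__(self) -> None:
        if self.predicate not in DEFAULT_MIN_DURATION:
            raise ValueError(f"unknown bout predicate {self.predicate!r}")
        if self.min_duration_minutes is None:
            object.__setattr__(
                self, "min_duration_minutes", DEFAULT_MIN_DURATION[self.predicate]
            )
        if self.min_duration_minutes <= 0:
            raise ValueError("min_duration_minutes must be positive")
        if self.break_tolerance_epochs < 0:
            raise ValueError("break_tolerance_epochs must be non-negative")

    def min_epochs(self, epoch_seconds: int) -> int:
        return int(round(self.min_duration_minutes * 60 / epoch_seconds))


@dataclass(frozen=True)
class Bout:
    """Detected bout over an inclusive epoch index range."""

    start_epoch: int
    end_epoch: int  # inclusive
    compliant_fraction: float

    def __post_init__(self) -> None:
        if self.end_epoch < self.start_epoch:
            raise ValueError("bout end must be >= start")
        if not 0.0 < self.compliant_fraction <= 1.0:
            raise ValueError("compliant_fraction must be in (0, 1]")

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch + 1


def compliance_mask(series: EpochSeries, predicate: str) -> np.ndarray:
    """Epochs satisfying the intensity predicate (non-wear never complies)."""
    v = series.values
    if predicate == "sedentary":
        band = v < LIGHT_CUTPOINT_MG
    elif predicate == "active":
        band = (v >= LIGHT_CUTPOINT_MG) & (v < MVPA_CUTPOINT_MG)
    elif predicate == "MVPA":
        band = v >= MVPA_CUTPOINT_MG
    else:
        raise ValueError(f"unknown bout predicate {predicate!r}")
    return band & series.wear_mask


def _bouts_from_masks(
    compliant: np.ndarray, nonwear: np.ndarray, tol: int, min_epochs: int
) -> list:
    """Maximal-bout extraction from the compliance mask.

    Non-compliant runs longer than ``tol`` (or containing non-wear) split
    the recording into segments; within each segment the unique maximal
    bout is the span from its first to its last compliant epoch.
    """
    n = compliant.size
    if n == 0:
        return []
    starts, lengths, vals = run_length_encode(compliant.astype(np.int8))
    ends = starts + lengths
    nw_cum = np.concatenate(([0], np.cumsum(nonwear)))
    has_nw = (nw_cum[ends] - nw_cum[starts]) > 0
    # blocker runs: non-compliant runs exceeding tolerance or touching non-wear
    is_blocker = (vals == 0) & ((lengths > tol) | has_nw)
    bounds = np.empty(2 * int(is_blocker.sum()) + 2, dtype=np.int64)
    bounds[0] = 0
    bounds[1:-1:2] = starts[is_blocker]
    bounds[2:-1:2] = ends[is_blocker]
    bounds[-1] = n
    out = []
    comp_idx = np.flatnonzero(compliant)
    comp_cum = np.concatenate(([0], np.cumsum(compliant)))
    lo_pos = np.searchsorted(comp_idx, bounds[::2], side="left")
    hi_pos = np.searchsorted(comp_idx, bounds[1::2], side="left")
    for lo, hi in zip(lo_pos, hi_pos):
        if hi <= lo:
            continue
        b0, b1 = int(comp_idx[lo]), int(comp_idx[hi - 1])
        if b1 - b0 + 1 < min_epochs:
            continue
        frac = float((comp_cum[b1 + 1] - comp_cum[b0]) / (b1 - b0 + 1))
        out.append(Bout(b0, b1, frac))
    return out


def detect_bouts(series: EpochSeries, config: BoutConfig) -> list:
    """All maximal bouts of ``config``'s intensity class, sorted, disjoint."""
    if series.n_epochs == 0:
        return []
    compliant = compliance_mask(series, config.predicate)
    return _bouts_from_masks(
        compliant,
        ~series.wear_mask,
        config.break_tolerance_epochs,
        config.min_epochs(series.epoch_seconds),
    )


def _oracle_scan(compliant, nonwear, tol, min_epochs):
    """Forward-scan reference: for every compliant start find the farthest
    compliant end reachable without an internal gap exceeding the
    tolerance, then keep the non-contained intervals."""
    n = compliant.size
    cands_s = []
    cands_e = []
    for i in range(n):
        if not compliant[i]:
            continue
        best_end = i
        gap = 0
        j = i
        while j < n:
            if compliant[j]:
                gap = 0
                best_end = j
            else:
                if nonwear[j]:
                    break
                gap += 1
                if gap > tol:
                    break
            j += 1
        if best_end - i + 1 >= min_epochs:
            cands_s.append(i)
            cands_e.append(best_end)
    # drop intervals contained in an earlier (longer-reaching) one
    keep_s = []
    keep_e = []
    max_e = -1
    for s, e in zip(cands_s, cands_e):
        if e > max_e:
            keep_s.append(s)
            keep_e.append(e)
            max_e = e
    return keep_s, keep_e


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _oracle_scan_fast = njit(cache=False)(_oracle_scan)
except Exception:  # pragma: no cover
    _oracle_scan_fast = None


def oracle_bouts(
    series: EpochSeries, config: BoutConfig, cap: int = ORACLE_DEFAULT_CAP
) -> list:
    """Brute-force reference bout detector (tests only; capped length)."""
    if series.n_epochs > cap:
        raise ValueError(f"oracle_bouts input exceeds cap of {cap} epochs")
    if series.n_epochs == 0:
        return []
    compliant = compliance_mask(series, config.predicate)
    nonwear = ~series.wear_mask
    tol = config.break_tolerance_epochs
    min_epochs = config.min_epochs(series.epoch_seconds)
    if _oracle_scan_fast is not None:
        ss, ee = _oracle_scan_fast(compliant, nonwear, tol, min_epochs)
    else:
        ss, ee = _oracle_scan(compliant, nonwear, tol, min_epochs)
    return [
        Bout(int(s), int(e), float(compliant[s : e + 1].mean()))
        for s, e in zip(ss, ee)
    ]


def sedentary_complement(series: EpochSeries, active_bouts: list) -> list:
    """Wear-time intervals not covered by any active bout.

    The paper-style sedentary-bout definition: the complement of the
    active bouts within wear time, as maximal intervals.
    """
    covered = np.zeros(series.n_epochs, dtype=bool)
    last_end = -1
    for b in sorted(active_bouts, key=lambda b: b.start_epoch):
        if b.start_epoch <= last_end:
            raise ValueError("active bouts must be disjoint")
        covered[b.start_epoch : b.end_epoch + 1] = True
        last_end = b.end_epoch
    free = series.wear_mask & ~covered
    starts, lengths, vals = run_length_encode(free.astype(np.int8))
    return [
        Bout(int(s), int(s + ln - 1), 1.0)
        for s, ln, v in zip(starts, lengths, vals)
        if v == 1
    ]
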