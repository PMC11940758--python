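"""Group screening, covariate adjustment, activity profiles and PCA.

The screening statistic is a geometric-mean ratio: metric values are
log-transformed within each group and the RA/control ratio is
``exp(mean_log_RA - mean_log_ctrl)`` with a Welch (unequal-variance) 95%
interval exponentiated around it. A metric is flagged as potentially
differentiating when the ratio deviates from 1 by more than 5% and the
interval excludes 1. Clock-time metrics (sleep midpoint, L5/M10 timing)
are screened on the linear scale with an arithmetic-difference interval,
since ratios of clock times are not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import labeling
from .labeling import LabelSeries

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "ProfileMatrix",
    "PCAResult",
    "screen_metric",
    "screen_matrix",
    "anova_oneway",
    "ancova",
    "activity_profiles",
    "pca",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Screening settings: flag threshold, CI level, zero handling."""

    min_relative_difference: float = 0.05
    ci_level: float = 0.95
    #: offset added before log when zeros occur; None = half the smallest
    #: positive observed value (per metric)
    zero_offset: Optional[float] = None
    linear_scale: bool = False


@dataclass
class ScreenResult:
    """Per-metric screening outcome.

    On the ratio scale ``ratio`` is the RA/control geometric-mean ratio;
    on the linear scale it holds the arithmetic difference (and the CI is
    a difference interval around 0 rather than a ratio interval around 1).
    """

    metric_id: str
    ratio: float
    ci_low: float
    ci_high: float
    flagged: bool
    n_ra: int
    n_ctrl: int
    linear_scale: bool = False
    anova_p: Optional[float] = None
    ancova_p: dict = field(default_factory=dict)


def _welch_ci(a: np.ndarray, b: np.ndarray, level: float):
    """(mean(a)-mean(b), lo, hi) by the Welch t-interval."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0:
        return diff, diff, diff
    se = np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = sps.t.ppf(0.5 + level / 2.0, df)
    return diff, diff - t * se, diff + t * se


def _log_with_offset(values: np.ndarray, offset: Optional[float]) -> np.ndarray:
    if np.any(values < 0):
        raise ValueError("ratio-scale screening requires non-negative values")
    if np.any(values == 0):
        if offset is None:
            pos = values[values > 0]
            if pos.size == 0:
                raise ValueError("cannot log-transform an all-zero metric")
            offset = 0.5 * pos.min()
        values = values + offset
    return np.log(values)


def screen_metric(
    values_ra,
    values_ctrl,
    config: ScreenConfig = ScreenConfig(),
    metric_id: str = "",
) -> ScreenResult:
    """Ratio (or linear-difference) screen of one metric between groups."""
    a = np.asarray(values_ra, float)
    b = np.asarray(values_ctrl, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if config.linear_scale:
        diff, lo, hi = _welch_ci(a, b, config.ci_level)
        flagged = bool(lo > 0 or hi < 0)
        return ScreenResult(
            metric_id, float(diff), float(lo), float(hi), flagged,
            a.size, b.size, linear_scale=True,
        )
    pooled_offset = config.zero_offset
    if pooled_offset is None and (np.any(a == 0) or np.any(b == 0)):
        pos = np.concatenate([a[a > 0], b[b > 0]])
        if pos.size == 0:
            raise ValueError("cannot log-transform an all-zero metric")
        pooled_offset = 0.5 * pos.min()
    la = _log_with_offset(a, pooled_offset)
    lb = _log_with_offset(b, pooled_offset)
    diff, lo, hi = _welch_ci(la, lb, config.ci_level)
    ratio = float(np.exp(diff))
    ci_low, ci_high = float(np.exp(lo)), float(np.exp(hi))
    flagged = bool(
        abs(ratio - 1.0) > config.min_relative_difference
        and (ci_low > 1.0 or ci_high < 1.0)
    )
    return ScreenResult(metric_id, ratio, ci_low, ci_high, flagged, a.size, b.size)


def screen_matrix(
    matrix: pd.DataFrame,
    groups: pd.Series,
    linear_ids: Sequence[str] = (),
    config: ScreenConfig = ScreenConfig(),
) -> list:
    """Screen every metric column of a participant x metric table.

    ``groups`` maps participant id to "RA"/"control". Metrics with fewer
    than 2 non-missing values in either group are skipped.
    """
    groups = groups.loc[matrix.index]
    is_ra = (groups == "RA").to_numpy()
    results = []
    for mid in matrix.columns:
        col = matrix[mid].to_numpy(float)
        a, b = col[is_ra], col[~is_ra]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            continue
        cfg = config
        if mid in linear_ids:
            cfg = ScreenConfig(
                config.min_relative_difference, config.ci_level,
                config.zero_offset, linear_scale=True,
            )
        try:
            results.append(screen_metric(a, b, cfg, metric_id=mid))
        except ValueError:
            continue  # unscreenable (e.g. all-zero) metric
    return results


def anova_oneway(values, factor) -> tuple:
    """One-way ANOVA of log-transformed values across factor levels.

    Returns ``(F, p)``. Supports any categorical factor (group, diagnosis
    source, diagnosis type, onset); every level must hold at least 2
    values.
    """
    values = np.asarray(values, float)
    factor = np.asarray(factor)
    ok = np.isfinite(values)
    values, factor = values[ok], factor[ok]
    levels = np.unique(factor)
    if levels.size < 2:
        raise ValueError("ANOVA requires at least 2 factor levels")
    logged = _log_with_offset(values, None)
    groups = [logged[factor == lv] for lv in levels]
    if any(g.size < 2 for g in groups):
        raise ValueError("every factor level needs at least 2 values")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def ancova(values, group, covariate) -> tuple:
    """Group effect on log values adjusted for one covariate.

    Fits ``log(value) ~ group + covariate`` by OLS (categorical
    covariates enter as indicator contrasts) and returns the adjusted
    group effect (log scale) and its p-value.
    """
    import statsmodels.formula.api as smf

    values = np.asarray(values, float)
    group = np.asarray(group)
    covariate = np.asarray(covariate)
    ok = np.isfinite(values)
    values, group, covariate = values[ok], group[ok], covariate[ok]
    if np.unique(covariate).size < 2:
        raise ValueError("covariate is constant")
    if np.unique(group).size != 2:
        raise ValueError("group must have exactly 2 levels")
    df = pd.DataFrame(
        {
            "y": _log_with_offset(values, None),
            "g": group,
            "x": covariate,
        }
    )
    cov_term = "x" if np.issubdtype(covariate.dtype, np.number) else "C(x)"
    model = smf.ols(f"y ~ C(g) + {cov_term}", data=df).fit()
    term = [c for c in model.params.index if c.startswith("C(g)")][0]
    return float(model.params[term]), float(model.pvalues[term])


# ---------------------------------------------------------------------------
# wake-aligned activity profiles
# ---------------------------------------------------------------------------

PROFILE_LABELS = ("sleep", "sedentary", "light", "MVPA")


@dataclass
class ProfileMatrix:
    """Group-average label-probability curves vs time since wake-up."""

    time_hours: np.ndarray  # bin centers, hours since get-up
    labels: tuple
    group_probs: dict  # group -> array (n_labels, n_bins)
    difference: np.ndarray  # RA - control, (n_labels, n_bins)
    n_participants: dict


def _participant_profile(
    labels: LabelSeries, getups: Sequence[pd.Timestamp], horizon_epochs: int
):
    """Counts (n_labels, bins) and totals (bins,) aligned to wake-ups."""
    n_lab = len(PROFILE_LABELS)
    counts = np.zeros((n_lab, horizon_epochs))
    totals = np.zeros(horizon_epochs)
    codes = labels.codes
    es = labels.epoch_seconds
    t0 = labels.start_time
    # walking counts toward MVPA in the 4-class profile
    remap = {
        labeling.SLEEP: 0,
        labeling.SEDENTARY: 1,
        labeling.LIGHT: 2,
        labeling.MVPA: 3,
        labeling.WALKING: 3,
    }
    for g in getups:
        if g is None:
            continue
        start = int((pd.Timestamp(g) - t0).total_seconds() // es)
        end = min(start + horizon_epochs, labels.n_epochs)
        if start < 0 or start >= labels.n_epochs:
            continue
        seg = codes[start:end]
        for code, row in remap.items():
            m = seg == code
            counts[row, : m.size] += m
        totals[: seg.size] += seg != labeling.NONWEAR
    return counts, totals


def activity_profiles(
    labels_by_id: dict,
    getups_by_id: dict,
    groups: dict,
    horizon_hours: float = 24.0,
    include_ids: Optional[Sequence[str]] = None,
) -> ProfileMatrix:
    """Population-average activity profiles aligned to time since wake-up.

    Per participant, label indicators are averaged across that
    participant's days; participants are then averaged within group.
    ``groups`` maps participant id to "RA"/"control"; ``include_ids``
    optionally restricts to a subgroup (e.g. non-working morning
    chronotypes). Non-wear time does not contribute.
    """
    ids = list(labels_by_id)
    if include_ids is not None:
        include = set(include_ids)
        ids = [i for i in ids if i in include]
    by_group = {"RA": [], "control": []}
    first = labels_by_id[ids[0]] if ids else None
    if first is None:
        raise ValueError("no participants to profile")
    horizon = int(horizon_hours * 3600 // first.epoch_seconds)
    for pid in ids:
        counts, totals = _participant_profile(
            labels_by_id[pid], getups_by_id.get(pid, []), horizon
        )
        if totals.sum() == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = counts / totals
        by_group[groups[pid]].append((probs, totals > 0))
    for g, members in by_group.items():
        if not members:
            raise ValueError(f"no usable participants in group {g!r}")
    group_probs = {}
    n_participants = {}
    for g, members in by_group.items():
        acc = np.zeros((len(PROFILE_LABELS), horizon))
        denom = np.zeros(horizon)
        for probs, has in members:
            acc[:, has] += probs[:, has]
            denom += has
        with np.errstate(invalid="ignore", divide="ignore"):
            group_probs[g] = acc / denom
        n_participants[g] = len(members)
    time_hours = (np.arange(horizon) + 0.5) * first.epoch_seconds / 3600.0
    return ProfileMatrix(
        time_hours=time_hours,
        labels=PROFILE_LABELS,
        group_probs=group_probs,
        difference=group_probs["RA"] - group_probs["control"],
        n_participants=n_participants,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Standardized PCA of the metric matrix."""

    included_metrics: list
    excluded_for_missingness: list
    excluded_constant: list
    loadings: pd.DataFrame  # metric x component, columns orthonormal
    variance_fraction: np.ndarray
    scores: pd.DataFrame  # participant x component
    n_components_selected: int


def pca(
    matrix: pd.DataFrame, cumulative_variance: float = 0.70
) -> PCAResult:
    """PCA of centered, unit-variance metrics; complete metrics only.

    Metrics with any missing value are dropped (recorded); metrics with
    zero variance cannot be standardized and are dropped too. The number
    of selected components is the smallest reaching the cumulative
    variance threshold (default 70%).
    """
    from sklearn.decomposition import PCA as SkPCA

    missing = [c for c in matrix.columns if matrix[c].isna().any()]
    kept = matrix.drop(columns=missing)
    sd = kept.std(ddof=0)
    constant = [c for c in kept.columns if sd[c] == 0]
    kept = kept.drop(columns=constant)
    if kept.shape[1] < 2:
        raise ValueError("PCA requires at least 2 complete metrics")
    if kept.shape[0] < 3:
        raise ValueError("PCA requires at least 3 participants")
    X = (kept - kept.mean()) / kept.std(ddof=0)
    model = SkPCA(n_components=min(X.shape))
    scores = model.fit_transform(X.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(model.n_components_)]
    vf = model.explained_variance_ratio_
    n_sel = int(np.searchsorted(np.cumsum(vf), cumulative_variance) + 1)
    n_sel = min(n_sel, len(vf))
    return PCAResult(
        included_metrics=list(kept.columns),
        excluded_for_missingness=missing,
        excluded_constant=constant,
        loadings=pd.DataFrame(
            model.components_.T, index=kept.columns, columns=comp_names
        ),
        variance_fraction=vf,
        scores=pd.DataFrame(scores, index=kept.index, columns=comp_names),
        n_components_selected=n_sel,
    )
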