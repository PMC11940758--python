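"""End-to-end pipeline: simulate -> preprocess -> label -> metrics ->
match -> screen -> profiles -> PCA, with file interfaces and a manifest.

The interchange format is an epoch-level CSV (one recording per
participant) with columns ``participant_id, timestamp, enmo_mg, wear``
and optionally ``label``; raw device files are out of scope. All stages
are driven by a :class:`RunConfig` that round-trips losslessly through
YAML/JSON, and a fixed config + seed reproduces every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import MatchConfig, apply_filters, match
from .labeling import LABELS, LabelSeries, consolidate_nights, fallback_labeler
from .metrics import build_registry, compute_all_metrics
from .preprocess import EpochSeries, check_validity, detect_nonwear
from .stats import ScreenConfig, activity_profiles, anova_oneway, ancova, pca, screen_matrix
from .synthetic import (
    ActivityModelParams,
    RAEffect,
    default_ra_effect,
    generate_cohort,
    profiles_to_frame,
    simulate_cohort_labels,
    simulate_magnitudes,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "read_epoch_csv", "write_epoch_csv"]

log = logging.getLogger("actipat")

STAGES = ("simulate", "preprocess", "label", "metrics", "match", "screen", "profiles", "pca")

ANCOVA_COVARIATES = ("smoking", "alcohol", "chronotype", "season", "working")


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Reproducible pipeline configuration (lossless YAML round-trip)."""

    seed: int = 0
    out_dir: str = "results/run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulation
    n_ra: int = 50
    n_pool: int = 200
    days: int = 7
    ra_effect: dict = field(
        default_factory=lambda: dataclasses.asdict(default_ra_effect())
    )
    write_epochs_csv: bool = False
    # external inputs (used when simulate is off)
    participants_csv: Optional[str] = None
    epochs_csv: Optional[str] = None
    # preprocessing
    min_wear_hours: float = 72.0
    apply_nonwear_detection: bool = False
    # matching / screening / pca
    match_ratio: int = 2
    match_max_distance: int = 0
    min_relative_difference: float = 0.05
    pca_cumulative_variance: float = 0.70

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# epoch CSV interchange
# ---------------------------------------------------------------------------


def write_epoch_csv(recordings: dict, path) -> None:
    """Write ``{participant_id: (EpochSeries, LabelSeries-or-None)}``.

    Columns: participant_id, timestamp (ISO-8601), enmo_mg, wear (0/1)
    and, when any labels are present, label.
    """
    frames = []
    any_labels = any(lab is not None for _, lab in recordings.values())
    for pid, (series, labels) in recordings.items():
        df = pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp": series.time_index().strftime("%Y-%m-%dT%H:%M:%S"),
                "enmo_mg": np.round(series.values, 3),
                "wear": series.wear_mask.astype(int),
            }
        )
        if any_labels:
            df["label"] = labels.to_strings() if labels is not None else ""
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epoch_csv(path) -> dict:
    """Read an epoch CSV back into per-participant series and labels.

    Rejects non-uniform epoch spacing (naming the offending timestamp)
    and unknown labels (naming the CSV line numbers).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "timestamp", "enmo_mg", "wear"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    has_labels = "label" in df.columns
    if has_labels:
        lab = df["label"].fillna("")
        bad = ~lab.isin(LABELS) & (lab != "")
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(
                f"unknown activity labels at CSV lines {lines}"
            )
    out = {}
    for pid, g in df.groupby("participant_id", sort=False):
        ts = pd.to_datetime(g["timestamp"])
        deltas = ts.diff().dropna().dt.total_seconds()
        if len(deltas) == 0:
            raise ValueError(f"participant {pid}: recording too short")
        step = deltas.iloc[0]
        bad = deltas[deltas != step]
        if len(bad):
            when = ts.iloc[int(bad.index[0] - g.index[0])]
            raise ValueError(
                f"participant {pid}: non-uniform epoch spacing at {when}"
            )
        series = EpochSeries(
            ts.iloc[0], int(step), g["enmo_mg"].to_numpy(float),
            g["wear"].to_numpy(int).astype(bool),
        )
        labels = None
        if has_labels and (g["label"].fillna("") != "").all():
            labels = LabelSeries.from_strings(
                ts.iloc[0], int(step), g["label"].tolist()
            )
        out[pid] = (series, labels)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; write tables and a manifest.

    Returns a dict of in-memory artifacts (profiles, recordings, metric
    matrix, matched cohort, screen results, PCA). Identical config and
    seed produce identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    art: dict = {}
    stages = config.stages

    if stages.get("simulate", False):
        log.info("simulate: %d RA + %d pool", config.n_ra, config.n_pool)
        profiles = generate_cohort(config.n_ra, config.n_pool, config.seed)
        profiles, exclusion_log = apply_filters(profiles)
        params = ActivityModelParams(days=config.days)
        effect = RAEffect(**config.ra_effect)
        labels = simulate_cohort_labels(profiles, params, effect, config.seed + 1)
        recordings = {}
        rng = np.random.default_rng(config.seed + 2)
        for p, lab in zip(profiles, labels):
            series = simulate_magnitudes(lab, params, int(rng.integers(2**31)))
            recordings[p.id] = (series, lab.with_nonwear(series.wear_mask))
        art["profiles"] = profiles
        art["exclusion_log"] = exclusion_log
        art["recordings"] = recordings
        profiles_to_frame(profiles).to_csv(out_dir / "participants.csv", index=False)
        if config.write_epochs_csv:
            write_epoch_csv(recordings, out_dir / "epochs.csv")
    else:
        if not config.epochs_csv or not config.participants_csv:
            raise StageError(
                "simulate",
                "simulation disabled but participants_csv/epochs_csv not set",
            )
        for name in ("participants_csv", "epochs_csv"):
            p = getattr(config, name)
            if not Path(p).exists():
                raise StageError("simulate", f"input path does not exist: {p}")
        pdf = pd.read_csv(config.participants_csv)
        art["participants_frame"] = pdf
        art["recordings"] = read_epoch_csv(config.epochs_csv)
        art["profiles"] = None

    if stages.get("preprocess", False):
        kept = {}
        for pid, (series, labels) in art["recordings"].items():
            if config.apply_nonwear_detection:
                series = detect_nonwear(series)
                if labels is not None:
                    labels = labels.with_nonwear(series.wear_mask)
            report = check_validity(series, config.min_wear_hours)
            if report.valid:
                kept[pid] = (series, labels)
        log.info("preprocess: %d/%d recordings valid", len(kept), len(art["recordings"]))
        if not kept:
            raise StageError("preprocess", "no recording meets the wear-time minimum")
        art["recordings"] = kept

    if stages.get("label", False):
        labeled = {}
        for pid, (series, labels) in art["recordings"].items():
            if labels is None:  # fallback when no HAR labels were supplied
                labels = fallback_labeler(series)
            labeled[pid] = (series, labels)
        art["recordings"] = labeled

    if stages.get("metrics", False):
        registry = build_registry()
        rows = {
            pid: compute_all_metrics(series, labels, registry)
            for pid, (series, labels) in art["recordings"].items()
        }
        matrix = pd.DataFrame.from_dict(rows, orient="index", columns=registry.ids)
        matrix.index.name = "participant_id"
        art["metric_matrix"] = matrix
        art["registry"] = registry
        matrix.to_csv(out_dir / "metric_matrix.csv")
        log.info("metrics: %d participants x %d metrics", *matrix.shape)

    if stages.get("match", False):
        if art.get("profiles") is None:
            raise StageError("match", "matching requires simulated profiles")
        valid_ids = set(art["recordings"])
        cases = [p for p in art["profiles"] if p.group == "RA" and p.id in valid_ids]
        pool = [p for p in art["profiles"] if p.group == "control" and p.id in valid_ids]
        cohort = match(
            cases,
            pool,
            MatchConfig(
                ratio=config.match_ratio,
                max_distance=config.match_max_distance,
                seed=config.seed + 3,
            ),
        )
        art["cohort"] = cohort
        matched = set(cohort.matched_case_ids) | set(cohort.control_ids)
        art["matched_ids"] = matched
        pd.Series(
            {cid: ";".join(ctrls) for cid, ctrls in cohort.pairs.items()},
            name="controls",
        ).rename_axis("case_id").to_csv(out_dir / "matched_pairs.csv")
        log.info(
            "match: %d/%d cases matched %d:1",
            len(cohort.pairs), len(cases), config.match_ratio,
        )

    if stages.get("screen", False):
        if "metric_matrix" not in art:
            raise StageError("screen", "screening requires the metrics stage")
        matrix = art["metric_matrix"]
        if "matched_ids" in art:
            matrix = matrix.loc[[i for i in matrix.index if i in art["matched_ids"]]]
        prof_by_id = {p.id: p for p in art["profiles"] or []}
        groups = pd.Series(
            {pid: prof_by_id[pid].group for pid in matrix.index}, name="group"
        )
        registry = art["registry"]
        linear_ids = [d.metric_id for d in registry if d.linear_scale]
        results = screen_matrix(
            matrix, groups,
            linear_ids=linear_ids,
            config=ScreenConfig(min_relative_difference=config.min_relative_difference),
        )
        is_ra = (groups == "RA").to_numpy()
        rows = []
        for r in results:
            col = matrix[r.metric_id].to_numpy(float)
            try:
                _, r.anova_p = anova_oneway(col, np.where(is_ra, "RA", "control"))
            except ValueError:
                r.anova_p = np.nan
            if r.flagged and not r.linear_scale:
                for cov in ANCOVA_COVARIATES:
                    covv = np.array([getattr(prof_by_id[pid], cov) for pid in matrix.index])
                    try:
                        _, p_adj = ancova(col, np.where(is_ra, "RA", "control"), covv)
                    except ValueError:
                        p_adj = np.nan
                    r.ancova_p[cov] = p_adj
            rows.append(
                {
                    "metric_id": r.metric_id,
                    "ratio": r.ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "flagged": r.flagged,
                    "linear_scale": r.linear_scale,
                    "n_ra": r.n_ra,
                    "n_ctrl": r.n_ctrl,
                    "anova_p": r.anova_p,
                    **{f"ancova_p_{c}": r.ancova_p.get(c, np.nan) for c in ANCOVA_COVARIATES},
                }
            )
        screen_df = pd.DataFrame(rows)
        art["screen_results"] = results
        art["screen_frame"] = screen_df
        screen_df.to_csv(out_dir / "screen_results.csv", index=False)
        log.info("screen: %d metrics screened, %d flagged",
                 len(screen_df), int(screen_df["flagged"].sum()))

    if stages.get("profiles", False):
        if art.get("profiles") is None:
            raise StageError("profiles", "profiles require simulated participants")
        ids = art.get("matched_ids", set(art["recordings"]))
        labels_by_id = {
            pid: lab for pid, (_, lab) in art["recordings"].items()
            if pid in ids and lab is not None
        }
        getups_by_id = {
            pid: [w.end for w in consolidate_nights(lab)]
            for pid, lab in labels_by_id.items()
        }
        groups = {p.id: p.group for p in art["profiles"]}
        pm = activity_profiles(labels_by_id, getups_by_id, groups)
        art["profile_matrix"] = pm
        rows = {"hours_since_wake": pm.time_hours}
        for g, probs in pm.group_probs.items():
            for i, lab in enumerate(pm.labels):
                rows[f"{g}_{lab}"] = probs[i]
        pd.DataFrame(rows).to_csv(out_dir / "activity_profiles.csv", index=False)

    if stages.get("pca", False):
        if "screen_frame" not in art:
            raise StageError("pca", "PCA requires the screening stage")
        flagged_ids = art["screen_frame"].query("flagged")["metric_id"].tolist()
        matrix = art["metric_matrix"]
        if "matched_ids" in art:
            matrix = matrix.loc[[i for i in matrix.index if i in art["matched_ids"]]]
        if len(flagged_ids) >= 2:
            result = pca(matrix[flagged_ids], config.pca_cumulative_variance)
            art["pca"] = result
            result.loadings.to_csv(out_dir / "pca_loadings.csv")
            result.scores.to_csv(out_dir / "pca_scores.csv")
            pd.Series(result.variance_fraction, name="variance_fraction").to_csv(
                out_dir / "pca_variance.csv", index_label="component"
            )
        else:
            log.info("pca: fewer than 2 flagged metrics, skipped")
            art["pca"] = None

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "actipat": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_participants": len(art.get("recordings", {})),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    art["manifest"] = manifest
    return art
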