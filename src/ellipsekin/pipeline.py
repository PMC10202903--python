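"""End-to-end orchestration: recording analysis, cohort summaries, and the
statistical report.

Stage order is fixed: zero-phase low-pass filter, finite-difference
kinematics, centroid-angle cycle segmentation, exclusion of the first and
two last cycles, per-cycle feature extraction, per-recording summary, then
cohort statistics (ART ANOVA on means and CVs, cross-hand accuracy and
precision correlations per speed, Steiger comparisons of the per-speed
correlations).
"""

from __future__ import annotations

import datetime
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnalysisConfig, Trajectory, TrajectoryError, ValidationError
from .features import FEATURE_COLUMNS, analyze_cycle
from .preprocessing import (
    estimate_derivatives,
    exclude_cycles,
    lowpass_filter,
    segment_cycles,
)
from .stats import (
    STAT_PARAMETERS,
    ConditionSummary,
    art_anova,
    correlation_accuracy,
    correlation_precision,
    steiger_test,
    summarize_condition,
    tukey_hsd,
)

__all__ = [
    "RunManifest",
    "analyze_recording",
    "analyze_cohort",
    "summarize_cohort",
    "run_statistics",
]

logger = logging.getLogger(__name__)

SPEEDS = ("S", "N", "F")
HANDS = ("D", "ND")
CONDITIONS = [f"{h}-{s}" for h in HANDS for s in SPEEDS]


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, seed, inputs, stage counts."""

    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    started: str = field(default_factory=lambda: datetime.datetime.now().isoformat())
    software: str = "ellipsekin 0.1.0"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def analyze_recording(traj: Trajectory, config: AnalysisConfig | None = None
                      ) -> tuple[pd.DataFrame, ConditionSummary]:
    """Run the full single-recording pipeline.

    Returns the per-cycle feature table (one row per retained cycle, columns
    subject_id/hand/speed/cycle_index plus the parameter set) and the
    per-recording :class:`ConditionSummary` (mean, SD, CV per parameter).
    """
    config = config or AnalysisConfig()
    label = traj.label()
    try:
        filtered = lowpass_filter(traj, cutoff=config.filter_cutoff,
                                  order=config.filter_order)
        profile = estimate_derivatives(filtered)
        cycles = segment_cycles(filtered, profile)
        retained = exclude_cycles(cycles, rule=config.exclusion,
                                  min_cycles=config.min_cycles_after_exclusion)
        template = config.template_for_hand(traj.hand)
        rows = []
        for cyc in retained:
            feats = analyze_cycle(filtered, profile, cyc, template, config)
            row = {"subject_id": traj.subject_id, "hand": traj.hand.value,
                   "speed": traj.speed.value, "cycle_index": cyc.cycle_index}
            row.update(feats.as_dict())
            rows.append(row)
    except TrajectoryError as exc:
        raise type(exc)(f"recording {label}: {exc}") from exc
    features = pd.DataFrame(rows, columns=list(
        ("subject_id", "hand", "speed", "cycle_index") + tuple(FEATURE_COLUMNS)))
    summary = summarize_condition(features)
    return features, summary


def analyze_cohort(trajectories, config: AnalysisConfig | None = None,
                   on_error: str = "skip"
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every recording of a cohort.

    Returns the concatenated per-cycle feature table and the long-form
    summary table (one row per recording x parameter). Failing recordings
    are skipped with a logged reason (``on_error='raise'`` propagates).
    """
    config = config or AnalysisConfig()
    feature_tables = []
    summary_tables = []
    n_failed = 0
    for traj in trajectories:
        try:
            features, summary = analyze_recording(traj, config)
        except TrajectoryError as exc:
            if on_error == "raise":
                raise
            n_failed += 1
            logger.warning("skipping recording %s: %s", traj.label(), exc)
            continue
        feature_tables.append(features)
        summary_tables.append(summary.to_frame())
    if not feature_tables:
        raise ValidationError("no recording could be analyzed")
    if n_failed:
        logger.warning("%d recording(s) skipped", n_failed)
    return (pd.concat(feature_tables, ignore_index=True),
            pd.concat(summary_tables, ignore_index=True))


def summarize_cohort(summaries: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Across-subject condition grid: parameter x condition means and SDs.

    Returns ``{"mean": ..., "sd": ...}`` DataFrames with the twelve
    parameters as rows and the six hand-speed conditions (D-S ... ND-F) as
    columns. Missing conditions yield NaN columns (nonfatal)."""
    grids = {}
    for stat in ("mean", "sd"):
        grid = pd.DataFrame(index=STAT_PARAMETERS, columns=CONDITIONS, dtype=float)
        for hand, speed in itertools.product(HANDS, SPEEDS):
            sub = summaries[(summaries["hand"] == hand)
                            & (summaries["speed"] == speed)]
            if sub.empty:
                continue
            per_param = sub.groupby("parameter")["mean"]
            agg = per_param.mean() if stat == "mean" else per_param.std(ddof=1)
            for param in STAT_PARAMETERS:
                if param in agg.index:
                    grid.loc[param, f"{hand}-{speed}"] = agg[param]
        grids[stat] = grid
    return grids


def _complete_subjects(summaries: pd.DataFrame) -> pd.DataFrame:
    """Drop subjects missing any of the six conditions (listwise)."""
    cond_counts = (summaries[["subject_id", "hand", "speed"]]
                   .drop_duplicates()
                   .groupby("subject_id").size())
    complete = cond_counts[cond_counts == 6].index
    dropped = cond_counts.index.difference(complete)
    if len(dropped):
        logger.warning("dropping %d incomplete subject(s): %s",
                       len(dropped), ", ".join(map(str, dropped)))
    return summaries[summaries["subject_id"].isin(complete)]


def run_statistics(summaries: pd.DataFrame, parameters=None,
                   alpha: float = 0.05, adjust: str | None = None) -> dict:
    """The full statistical report over a cohort's condition summaries.

    For each parameter: ART ANOVA of the per-recording means and of the CVs
    (effects hand, speed, hand x speed; Tukey HSD on the speed ranks when
    the speed effect is significant), cross-hand accuracy and precision
    correlations at each speed, and Steiger comparisons of the three
    per-speed correlations pairwise. Subjects incomplete in any condition
    are dropped listwise. ``adjust='holm'`` additionally reports
    family-wise adjusted ANOVA p-values across the parameter family per
    effect (off by default: each parameter is tested separately).
    """
    parameters = list(parameters or STAT_PARAMETERS)
    summaries = _complete_subjects(summaries)
    n_subjects = summaries["subject_id"].nunique()
    if n_subjects < 3:
        raise ValidationError(f"too few subjects for statistics ({n_subjects} < 3)")

    report: dict = {"n_subjects": n_subjects, "alpha": alpha, "parameters": {}}
    for param in parameters:
        sub = summaries[summaries["parameter"] == param]
        entry: dict = {}
        for value_col, key in (("mean", "anova_mean"), ("cv", "anova_cv")):
            obs = sub.rename(columns={value_col: "value"})[
                ["subject_id", "hand", "speed", "value"]]
            if obs["value"].isna().any():
                entry[key] = None
                continue
            results = art_anova(obs, response="value")
            entry[key] = [r.__dict__ for r in results]
            speed_res = next(r for r in results if r.effect == "speed")
            if key == "anova_mean" and speed_res.p < alpha:
                from .stats import align_rank_transform

                art = align_rank_transform(obs, response="value")
                entry["tukey_speed_mean"] = tukey_hsd(
                    art, "speed", "rank_speed").to_dict("records")
        for kind, func in (("accuracy", correlation_accuracy),
                           ("precision", correlation_precision)):
            per_speed = {}
            for speed in SPEEDS:
                try:
                    res = func(sub, param, speed)
                    per_speed[speed] = res.__dict__
                except ValidationError as exc:
                    per_speed[speed] = {"error": str(exc)}
            entry[f"correlation_{kind}"] = per_speed
            entry[f"steiger_{kind}"] = _steiger_between_speeds(
                sub, param, value_col="mean" if kind == "accuracy" else "cv")
        report["parameters"][param] = entry
    if adjust == "holm":
        _apply_holm(report, parameters)
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r} (use 'holm')")
    return report


def _apply_holm(report: dict, parameters: list) -> None:
    from .stats import holm_adjust

    for key in ("anova_mean", "anova_cv"):
        for effect_idx in range(3):
            ps, slots = [], []
            for param in parameters:
                entry = report["parameters"][param].get(key)
                if entry is None:
                    continue
                ps.append(entry[effect_idx]["p"])
                slots.append(entry[effect_idx])
            for slot, p_adj in zip(slots, holm_adjust(ps)):
                slot["p_holm"] = float(p_adj)


def _steiger_between_speeds(sub: pd.DataFrame, parameter: str,
                            value_col: str) -> dict:
    """Pairwise Steiger comparisons of the cross-hand correlation between
    speeds. Each speed contributes the (D, ND) variable pair; the four
    cross-speed cross-hand correlations are computed from the same
    subjects."""
    vectors = {}
    for speed in SPEEDS:
        pivot = sub[sub["speed"] == speed].pivot_table(
            index="subject_id", columns="hand", values=value_col, aggfunc="first")
        if "D" in pivot.columns and "ND" in pivot.columns:
            vectors[speed] = pivot[["D", "ND"]].dropna()
    out = {}
    for s1, s2 in itertools.combinations(SPEEDS, 2):
        if s1 not in vectors or s2 not in vectors:
            out[f"{s1}-{s2}"] = {"error": "missing speed"}
            continue
        joined = vectors[s1].join(vectors[s2], lsuffix="_1", rsuffix="_2").dropna()
        n = len(joined)
        if n < 4:
            out[f"{s1}-{s2}"] = {"error": f"too few subjects ({n})"}
            continue
        arr = joined.to_numpy(float)  # columns: D1, ND1, D2, ND2
        if np.any(arr.std(axis=0) == 0):
            out[f"{s1}-{s2}"] = {"error": "zero variance"}
            continue
        corr = np.corrcoef(arr, rowvar=False)
        # j,k = (D,ND) at speed 1; h,m = (D,ND) at speed 2
        r_jk, r_hm = corr[0, 1], corr[2, 3]
        cross = (corr[0, 2], corr[0, 3], corr[1, 2], corr[1, 3])
        try:
            res = steiger_test(r_jk, r_hm, cross, n)
            out[f"{s1}-{s2}"] = {"r_1": float(r_jk), "r_2": float(r_hm),
                                 "Z": res.Z, "p": res.p, "n": n}
        except ValidationError as exc:
            out[f"{s1}-{s2}"] = {"error": str(exc)}
    return out

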