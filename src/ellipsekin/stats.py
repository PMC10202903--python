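"""Variability and inferential statistics for cycle-feature tables.

Implements the statistical layer of the drawing-movement analysis:

* intra-trial variability as the coefficient of variation (CV) of each
  parameter over the retained cycles of one recording;
* cross-hand *accuracy* correlations (Pearson r between subjects'
  dominant- and non-dominant-hand parameter means at a given speed) and
  *precision* correlations (the same on per-subject CVs);
* Steiger's Z for comparing two dependent Pearson correlations that share
  subjects (e.g. the cross-hand correlation at slow vs fast speed), in the
  non-overlapping-variables form with the overlapping form selectable;
* the Aligned Rank Transform (ART) factorial ANOVA for the 2 (hand) x 3
  (speed) within-subject design, with subject entered as an additive
  blocking factor, Tukey HSD post hocs on the ranked responses, and partial
  eta squared as the effect size.

For a balanced complete cohort of n subjects with one observation per
subject x hand x speed cell, the error degrees of freedom are
N - 1 - df_hand - df_speed - df_interaction - (n - 1); with n = 40 that is
240 - 1 - 1 - 2 - 2 - 39 = 195.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError
from .features import FEATURE_COLUMNS

__all__ = [
    "STAT_PARAMETERS",
    "ConditionSummary",
    "AnovaResult",
    "CorrelationResult",
    "SteigerResult",
    "coefficient_of_variation",
    "summarize_condition",
    "correlation_accuracy",
    "correlation_precision",
    "steiger_test",
    "align_rank_transform",
    "art_anova",
    "tukey_hsd",
    "holm_adjust",
]

# The twelve tabulated parameters (rotation_angle is reported but, being
# sign-carrying, has no meaningful CV and is excluded from the statistics).
STAT_PARAMETERS = [c for c in FEATURE_COLUMNS if c != "rotation_angle"]

_META_COLS = ("subject_id", "hand", "speed", "cycle_index")


@dataclass
class ConditionSummary:
    """Per-recording (subject x hand x speed) summary: a long-form table with
    one row per parameter carrying mean, SD, and CV over retained cycles."""

    subject_id: str
    hand: str
    speed: str
    n_cycles: int
    table: pd.DataFrame  # columns: parameter, mean, sd, cv

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "subject_id", self.subject_id)
        out.insert(1, "hand", self.hand)
        out.insert(2, "speed", self.speed)
        out["n_cycles"] = self.n_cycles
        return out


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class SteigerResult:
    Z: float
    p: float


def coefficient_of_variation(values) -> float:
    """Sample CV: SD (n-1 denominator) over mean, for positive-mean data."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValidationError("CV needs >= 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValidationError(f"CV undefined for non-positive mean ({mean:.4g})")
    return float(values.std(ddof=1) / mean)


def summarize_condition(features: pd.DataFrame) -> ConditionSummary:
    """Summarize the retained cycles of one recording.

    ``features`` holds one row per cycle with the parameter columns plus
    subject/hand/speed labels; at least two cycles are required. CV is set
    to NaN for parameters with non-positive mean.
    """
    if len(features) < 2:
        raise ValidationError(
            f"summary needs >= 2 retained cycles, got {len(features)}"
        )
    for col in ("subject_id", "hand", "speed"):
        if features[col].nunique() != 1:
            raise ValidationError(f"features table mixes multiple {col} values")
    rows = []
    for param in FEATURE_COLUMNS:
        vals = features[param].to_numpy(float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = sd / mean if mean > 0 else float("nan")
        rows.append({"parameter": param, "mean": mean, "sd": sd, "cv": cv})
    return ConditionSummary(
        subject_id=str(features["subject_id"].iloc[0]),
        hand=str(features["hand"].iloc[0]),
        speed=str(features["speed"].iloc[0]),
        n_cycles=int(len(features)),
        table=pd.DataFrame(rows),
    )


def _paired_vectors(summaries: pd.DataFrame, parameter: str, speed: str,
                    value_col: str) -> tuple[np.ndarray, np.ndarray, list]:
    sub = summaries[(summaries["parameter"] == parameter)
                    & (summaries["speed"] == speed)]
    pivot = sub.pivot_table(index="subject_id", columns="hand",
                            values=value_col, aggfunc="first")
    if "D" not in pivot.columns or "ND" not in pivot.columns:
        raise ValidationError(f"missing a hand for parameter {parameter} at speed {speed}")
    pivot = pivot.dropna(subset=["D", "ND"])
    if len(pivot) < 3:
        raise ValidationError(
            f"need >= 3 subjects with both hands, got {len(pivot)}"
        )
    return pivot["D"].to_numpy(float), pivot["ND"].to_numpy(float), list(pivot.index)


def _pearson(d: np.ndarray, nd: np.ndarray) -> CorrelationResult:
    if np.std(d) == 0 or np.std(nd) == 0:
        raise ValidationError("undefined correlation: zero variance in one hand")
    res = sps.pearsonr(d, nd)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(d.size))


def correlation_accuracy(summaries: pd.DataFrame, parameter: str,
                         speed: str) -> CorrelationResult:
    """Cross-hand accuracy: Pearson r between subjects' D- and ND-hand
    parameter *means* at one speed."""
    d, nd, _ = _paired_vectors(summaries, parameter, speed, "mean")
    return _pearson(d, nd)


def correlation_precision(summaries: pd.DataFrame, parameter: str,
                          speed: str) -> CorrelationResult:
    """Cross-hand precision: Pearson r between subjects' D- and ND-hand
    parameter *CVs* at one speed (an index of shared intra-trial
    variability)."""
    d, nd, _ = _paired_vectors(summaries, parameter, speed, "cv")
    return _pearson(d, nd)


def _check_psd(r_jk, r_hm, cross):
    r_jh, r_jm, r_kh, r_km = cross
    corr = np.array([
        [1.0, r_jk, r_jh, r_jm],
        [r_jk, 1.0, r_kh, r_km],
        [r_jh, r_kh, 1.0, r_hm],
        [r_jm, r_km, r_hm, 1.0],
    ])
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-8:
        raise ValidationError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )


def steiger_test(r_jk: float, r_hm: float, cross_correlations, n: int,
                 overlapping: bool = False) -> SteigerResult:
    """Steiger's Z for the difference of two dependent Pearson correlations.

    Non-overlapping form (default): variables (j, k) and (h, m) share no
    member but are measured on the same n subjects;
    ``cross_correlations`` supplies (r_jh, r_jm, r_kh, r_km). The two
    correlations are Fisher-z transformed, their covariance estimated with
    the Pearson-Filon expression evaluated at the pooled correlation
    (Steiger's Z-bar-star), and the difference referred to a standard
    normal (two-sided p). With all cross-correlations zero this reduces to
    Z = (z_jk - z_hm) / sqrt(2/(n-3)).

    Overlapping form (``overlapping=True``): the correlations share variable
    j (r_jk vs r_jh); pass the single correlation r_kh as
    ``cross_correlations`` (scalar or length-1 sequence).
    """
    if n < 4:
        raise ValidationError("Steiger test needs n >= 4")
    rbar = 0.5 * (r_jk + r_hm)
    if overlapping:
        r_kh = float(np.atleast_1d(cross_correlations)[0])
        _check_psd_overlap = np.array([
            [1.0, r_jk, r_hm],
            [r_jk, 1.0, r_kh],
            [r_hm, r_kh, 1.0],
        ])
        if np.linalg.eigvalsh(_check_psd_overlap).min() < -1e-8:
            raise ValidationError("correlation matrix is not positive semi-definite")
        psi = r_kh * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
            1.0 - 2.0 * rbar**2 - r_kh**2)
        cov = psi / (1.0 - rbar**2) ** 2
    else:
        cross = tuple(float(c) for c in cross_correlations)
        if len(cross) != 4:
            raise ValidationError(
                "non-overlapping Steiger needs the 4 cross-correlations "
                "(r_jh, r_jm, r_kh, r_km)"
            )
        _check_psd(r_jk, r_hm, cross)
        r_jh, r_jm, r_kh, r_km = cross
        # Pearson-Filon covariance term at the pooled correlation
        psi = (0.5 * rbar * rbar * (r_jh**2 + r_jm**2 + r_kh**2 + r_km**2)
               + r_jh * r_km + r_jm * r_kh
               - (rbar * r_jh * r_jm + rbar * r_kh * r_km
                  + rbar * r_jh * r_kh + rbar * r_jm * r_km))
        cov = psi / (1.0 - rbar**2) ** 2
    z1 = math.atanh(r_jk)
    z2 = math.atanh(r_hm)
    denom = math.sqrt(max(2.0 - 2.0 * cov, 1e-12) / (n - 3))
    Z = (z1 - z2) / denom
    p = 2.0 * sps.norm.sf(abs(Z))
    return SteigerResult(Z=float(Z), p=float(p))


def _require_layout(obs: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in (response, "hand", "speed", "subject_id"):
        if col not in obs.columns:
            raise ValidationError(f"observations table missing column {col}")
    if obs["hand"].nunique() < 2:
        raise ValidationError("factor hand needs >= 2 levels")
    if obs["speed"].nunique() < 2:
        raise ValidationError("factor speed needs >= 2 levels")
    counts = obs.groupby(["subject_id", "hand", "speed"]).size()
    if counts.max() != counts.min():
        raise ValidationError("unbalanced layout: unequal cell sizes")
    full = obs["subject_id"].nunique() * obs["hand"].nunique() * obs["speed"].nunique()
    if len(counts) != full:
        raise ValidationError("incomplete layout: missing subject x hand x speed cells")
    return obs


def _effect_estimates(obs: pd.DataFrame, response: str) -> dict[str, np.ndarray]:
    """Least-squares estimates of the additive-blocking factorial model on a
    balanced layout, as per-observation arrays."""
    y = obs[response].to_numpy(float)
    grand = y.mean()
    hand_eff = obs.groupby("hand")[response].transform("mean").to_numpy() - grand
    speed_eff = obs.groupby("speed")[response].transform("mean").to_numpy() - grand
    cell = obs.groupby(["hand", "speed"])[response].transform("mean").to_numpy()
    inter_eff = cell - grand - hand_eff - speed_eff
    subj_eff = obs.groupby("subject_id")[response].transform("mean").to_numpy() - grand
    fitted = grand + hand_eff + speed_eff + inter_eff + subj_eff
    return {
        "grand": grand,
        "hand": hand_eff,
        "speed": speed_eff,
        "hand:speed": inter_eff,
        "subject": subj_eff,
        "residual": y - fitted,
    }


def align_rank_transform(observations: pd.DataFrame, response: str = "value"
                         ) -> pd.DataFrame:
    """Aligned-and-ranked responses for the hand, speed, and hand x speed
    effects of a balanced two-factor within-subject layout.

    For each effect, the response is aligned by stripping every estimated
    component of the additive-blocking factorial model except that effect
    (aligned = residual + effect estimate), then midranked over all
    observations. Returns a copy of the table with ``aligned_<effect>`` and
    ``rank_<effect>`` columns for effects hand, speed, hand_speed.
    """
    obs = _require_layout(observations, response).copy()
    est = _effect_estimates(obs, response)
    out = obs.copy()
    for effect, col in (("hand", "hand"), ("speed", "speed"),
                        ("hand:speed", "hand_speed")):
        aligned = est["residual"] + est[effect]
        out[f"aligned_{col}"] = aligned
        out[f"rank_{col}"] = sps.rankdata(aligned, method="average")
    return out


def _balanced_anova_table(obs: pd.DataFrame, response: str) -> dict:
    """Sums of squares of the balanced factorial + subject-blocking model."""
    y = obs[response].to_numpy(float)
    est = _effect_estimates(obs, response)
    ss = {k: float(np.sum(est[k] ** 2)) for k in
          ("hand", "speed", "hand:speed", "subject", "residual")}
    n_hand = obs["hand"].nunique()
    n_speed = obs["speed"].nunique()
    n_subj = obs["subject_id"].nunique()
    N = len(obs)
    dfs = {
        "hand": n_hand - 1,
        "speed": n_speed - 1,
        "hand:speed": (n_hand - 1) * (n_speed - 1),
        "subject": n_subj - 1,
    }
    df_err = N - 1 - sum(dfs.values())
    return {"ss": ss, "dfs": dfs, "df_err": df_err, "ss_total": float(np.sum((y - y.mean()) ** 2))}


def art_anova(observations: pd.DataFrame, response: str = "value"
              ) -> list[AnovaResult]:
    """Aligned Rank Transform ANOVA for the hand x speed within-subject design.

    Each effect (hand, speed, hand x speed) is tested by a fixed-effects
    factorial ANOVA on that effect's aligned ranks, with subject as an
    additive blocking factor; partial eta squared is
    SS_effect / (SS_effect + SS_error). With all responses tied the ranks
    are degenerate and F is reported as NaN with ``degenerate=True``.
    """
    art = align_rank_transform(observations, response)
    results = []
    for effect, col in (("hand", "hand"), ("speed", "speed"),
                        ("hand:speed", "hand_speed")):
        tab = _balanced_anova_table(art, f"rank_{col}")
        ss_eff = tab["ss"][effect]
        ss_err = tab["ss"]["residual"]
        df_num = tab["dfs"][effect]
        df_den = tab["df_err"]
        if tab["ss_total"] < 1e-12 or ss_err < 1e-12:
            results.append(AnovaResult(effect=effect, F=float("nan"),
                                       df_num=df_num, df_den=df_den,
                                       p=float("nan"), partial_eta_sq=float("nan"),
                                       degenerate=True))
            continue
        F = (ss_eff / df_num) / (ss_err / df_den)
        p = float(sps.f.sf(F, df_num, df_den))
        eta = ss_eff / (ss_eff + ss_err)
        results.append(AnovaResult(effect=effect, F=float(F), df_num=df_num,
                                   df_den=df_den, p=p, partial_eta_sq=float(eta)))
    return results


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down family-wise adjustment of a p-value family.

    NaNs pass through unadjusted. Off by default everywhere (the factorial
    analyses test each parameter separately); callers opt in per family.
    """
    p = np.asarray(pvalues, float)
    adj = np.full_like(p, np.nan)
    idx = np.flatnonzero(~np.isnan(p))
    if idx.size == 0:
        return adj
    order = idx[np.argsort(p[idx])]
    m = order.size
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def tukey_hsd(observations: pd.DataFrame, factor: str, response: str
              ) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of one factor's levels on ``response``
    (typically that effect's aligned ranks). Returns one row per level pair
    with the studentized-range family-wise adjusted p-value."""
    levels = sorted(observations[factor].unique())
    if len(levels) < 2:
        raise ValidationError(f"factor {factor} needs >= 2 levels")
    groups = [observations.loc[observations[factor] == lv, response].to_numpy(float)
              for lv in levels]
    res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        rows.append({
            "level_a": levels[i],
            "level_b": levels[j],
            "statistic": float(res.statistic[i, j]),
            "p_adj": float(min(1.0, res.pvalue[i, j])),
        })
    return pd.DataFrame(rows)
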