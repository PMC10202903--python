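"""Reading and writing trajectory tables and analysis configurations.

Trajectory files are plain comma-separated text with a ``t,x,y`` header and
``#``-prefixed metadata lines (subject, hand, speed, sample rate, units), so
fixtures stay diff-able. Positions are stored in cm; a ``# units: mm`` header
triggers conversion on read. Configurations are YAML (or JSON, a YAML subset)
documents with the :class:`~ellipsekin.core.AnalysisConfig` schema.
"""

from __future__ import annotations

import io as _stdio
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AnalysisConfig,
    FormatError,
    Hand,
    Speed,
    TemplateSpec,
    Trajectory,
    ValidationError,
)

__all__ = ["read_trajectory_table", "write_trajectory_table", "load_config", "save_config"]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("t", "x", "y")


def read_trajectory_table(
    path,
    subject_id: str | None = None,
    hand: str | None = None,
    speed: str | None = None,
    sample_rate: float | None = None,
) -> Trajectory:
    """Read a trajectory from a delimited text file.

    Metadata given as keyword arguments overrides metadata found in the
    file's ``# key: value`` comment lines. Raises :class:`FormatError` for
    missing columns and :class:`ValidationError` for invariant violations
    (e.g. non-monotone time stamps). If sample gaps exceed the uniformity
    tolerance the trajectory is linearly resampled to a uniform grid and a
    warning is logged.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
            elif stripped:
                data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    try:
        frame = pd.read_csv(_stdio.StringIO("".join(data_lines)))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unparseable table ({exc})") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in _REQUIRED_COLUMNS:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise FormatError(f"{path}: column {col} is not numeric")

    t = frame["t"].to_numpy(float)
    x = frame["x"].to_numpy(float)
    y = frame["y"].to_numpy(float)

    units = meta.get("units", "cm").lower()
    if units == "mm":
        x = x / 10.0
        y = y / 10.0
    elif units != "cm":
        raise FormatError(f"{path}: unsupported units {units!r} (cm or mm)")

    dt = np.diff(t)
    if t.size >= 2 and np.any(dt <= 0):
        idx = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ValidationError(
            f"{path}: t must be strictly increasing; violation at row {idx}"
        )

    sr = sample_rate
    if sr is None and "sample_rate" in meta:
        sr = float(meta["sample_rate"])
    if sr is None:
        sr = 1.0 / float(np.median(dt)) if t.size >= 2 else 200.0

    kwargs = dict(
        subject_id=subject_id or meta.get("subject", "anon"),
        hand=hand or meta.get("hand", "D"),
        speed=speed or meta.get("speed", "N"),
        sample_rate=float(sr),
    )
    nominal = 1.0 / float(sr)
    if t.size >= 2 and np.any(np.abs(dt - nominal) > Trajectory.GAP_TOLERANCE * nominal):
        logger.warning(
            "%s: non-uniform sampling beyond tolerance; resampling to %.6g Hz",
            path, sr,
        )
        t_uniform = t[0] + np.arange(round((t[-1] - t[0]) * sr) + 1) * nominal
        x = np.interp(t_uniform, t, x)
        y = np.interp(t_uniform, t, y)
        t = t_uniform
    return Trajectory(t=t, x=x, y=y, **kwargs)


def write_trajectory_table(traj: Trajectory, path) -> None:
    """Write a trajectory as ``#``-commented metadata plus a t,x,y CSV body."""
    traj.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject: {traj.subject_id}\n")
        fh.write(f"# hand: {traj.hand.value}\n")
        fh.write(f"# speed: {traj.speed.value}\n")
        fh.write(f"# sample_rate: {traj.sample_rate:.10g}\n")
        fh.write("# units: cm\n")
        fh.write("t,x,y\n")
        for ti, xi, yi in zip(traj.t, traj.x, traj.y):
            fh.write(f"{ti:.10f},{xi:.10f},{yi:.10f}\n")


def _template_from_mapping(doc: dict, hand_default: str = "D") -> TemplateSpec:
    return TemplateSpec(
        a=float(doc.get("a", 8.0)),
        b=float(doc.get("b", 2.0)),
        rotation=float(doc.get("rotation", 45.0 if hand_default == "D" else -45.0)),
        center=tuple(doc.get("center", (0.0, 0.0))),
        direction=doc.get("direction", "CCW" if hand_default == "D" else "CW"),
    )


def load_config(path=None, text: str | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML/JSON document.

    Unspecified fields take the documented defaults; an empty document yields
    the default configuration. Out-of-range values raise
    :class:`ValidationError` naming the offending field.
    """
    if text is None:
        if path is None:
            doc = {}
        else:
            with open(path, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise FormatError("config document must be a mapping")

    known = {
        "filter_cutoff", "filter_order", "exclusion",
        "min_cycles_after_exclusion", "speed_epsilon", "curvature_epsilon",
        "seed", "template",
    }
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"unknown config field(s): {', '.join(sorted(unknown))}")

    kwargs = {}
    for field_name in ("filter_cutoff", "speed_epsilon", "curvature_epsilon"):
        if field_name in doc:
            try:
                kwargs[field_name] = float(doc[field_name])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"config field {field_name} is not numeric") from exc
    for field_name in ("filter_order", "min_cycles_after_exclusion", "seed"):
        if field_name in doc:
            kwargs[field_name] = int(doc[field_name])
    if "exclusion" in doc:
        pair = doc["exclusion"]
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise ValidationError("config field exclusion must be a [n_first, n_last] pair")
        kwargs["exclusion"] = (int(pair[0]), int(pair[1]))
    if "template" in doc:
        if not isinstance(doc["template"], dict):
            raise ValidationError("config field template must be a mapping")
        kwargs["template"] = _template_from_mapping(doc["template"])
    try:
        return AnalysisConfig(**kwargs)
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(str(exc)) from exc


def save_config(config: AnalysisConfig, path) -> None:
    """Serialize a config back to YAML (used by run manifests)."""
    doc = {
        "filter_cutoff": config.filter_cutoff,
        "filter_order": config.filter_order,
        "exclusion": list(config.exclusion),
        "min_cycles_after_exclusion": config.min_cycles_after_exclusion,
        "speed_epsilon": config.speed_epsilon,
        "curvature_epsilon": config.curvature_epsilon,
        "seed": config.seed,
        "template": {
            "a": config.template.a,
            "b": config.template.b,
            "rotation": config.template.rotation,
            "center": list(config.template.center),
            "direction": config.template.direction.value,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
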