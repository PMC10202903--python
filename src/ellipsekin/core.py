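"""Core data model: trajectories, templates, and the analysis configuration.

Positions are in centimetres and time in seconds throughout the package;
angles are degrees counterclockwise from the +x axis, reported in (-90, 90]
(an ellipse axis has no sign). These conventions follow the standard way
drawing-kinematics results are tabulated (cm, cm/s, s, degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Hand",
    "Speed",
    "Direction",
    "TrajectoryError",
    "ValidationError",
    "FormatError",
    "FitError",
    "TooFewCyclesError",
    "DegenerateCycleError",
    "Trajectory",
    "TemplateSpec",
    "AnalysisConfig",
    "DEFAULT_TEMPLATE_A",
    "DEFAULT_TEMPLATE_B",
]

# Template ellipse traced in the task: 8 x 2 cm semi-axes (eccentricity 0.968),
# major axis at +45 deg for the dominant (right) hand, -45 deg for the
# non-dominant (left) hand.
DEFAULT_TEMPLATE_A = 8.0
DEFAULT_TEMPLATE_B = 2.0


class Hand(str, Enum):
    """Performing hand: dominant or non-dominant."""

    D = "D"
    ND = "ND"


class Speed(str, Enum):
    """Instructed pace relative to the spontaneous (normal) pace."""

    S = "S"  # slow
    N = "N"  # normal / spontaneous
    F = "F"  # fast


class Direction(str, Enum):
    """Tracing direction. The protocol uses CCW for the right (dominant) hand
    and CW for the left (non-dominant) hand."""

    CCW = "CCW"
    CW = "CW"


class TrajectoryError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(TrajectoryError):
    """An input violates a documented invariant."""


class FormatError(TrajectoryError):
    """A file does not conform to the expected layout."""


class FitError(TrajectoryError):
    """A model fit failed (degenerate ellipse, uninformative regression...)."""


class TooFewCyclesError(TrajectoryError):
    """Fewer cycles remain than the analysis requires."""


class DegenerateCycleError(TrajectoryError):
    """A cycle has no usable samples (all masked)."""


def _as_enum(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value))
    except ValueError as exc:
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValidationError(
            f"invalid {enum_cls.__name__} {value!r}; expected one of {allowed}"
        ) from exc


@dataclass
class Trajectory:
    """A time-stamped 2D pen trajectory for one recording.

    Parameters
    ----------
    t, x, y
        Sample times (s) and pen positions (cm). ``t`` must be strictly
        increasing and close to uniform (gaps within 10% of ``1/sample_rate``).
    subject_id
        Opaque subject label.
    hand, speed
        Condition labels (dominant/non-dominant hand; slow/normal/fast pace).
    sample_rate
        Nominal sampling rate in Hz (tablets record at ~200 samples/s).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    subject_id: str = "anon"
    hand: Hand = Hand.D
    speed: Speed = Speed.N
    sample_rate: float = 200.0

    # gap tolerance relative to the nominal sampling interval
    GAP_TOLERANCE: float = field(default=0.10, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hand = _as_enum(self.hand, Hand)
        self.speed = _as_enum(self.speed, Speed)
        self.validate()

    def validate(self) -> None:
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValidationError("t, x, y must have identical shapes")
        if self.t.ndim != 1:
            raise ValidationError("samples must be one-dimensional arrays")
        if self.n_samples < 4:
            raise ValidationError(
                f"trajectory needs >= 4 samples, got {self.n_samples}"
            )
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                idx = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValidationError(f"non-finite {name} at sample {idx}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            idx = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValidationError(
                f"t must be strictly increasing; violation at sample {idx}"
            )
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        nominal = 1.0 / self.sample_rate
        if np.any(np.abs(dt - nominal) > self.GAP_TOLERANCE * nominal):
            idx = int(
                np.flatnonzero(np.abs(dt - nominal) > self.GAP_TOLERANCE * nominal)[0]
            ) + 1
            raise ValidationError(
                f"sample gap at index {idx} deviates more than "
                f"{self.GAP_TOLERANCE:.0%} from 1/sample_rate; resample first "
                "(ellipsekin.preprocessing.resample_uniform)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def positions(self) -> np.ndarray:
        """(n, 2) array of x, y positions."""
        return np.column_stack([self.x, self.y])

    def with_positions(self, x: np.ndarray, y: np.ndarray) -> "Trajectory":
        """Copy of this trajectory with replaced positions (same times/labels)."""
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float))

    def label(self) -> str:
        return f"{self.subject_id}/{self.hand.value}/{self.speed.value}"


@dataclass
class TemplateSpec:
    """The template ellipse subjects trace.

    ``rotation`` is the major-axis inclination in degrees CCW from horizontal,
    constrained to (-90, 90]; ``direction`` is the tracing direction.
    """

    a: float = DEFAULT_TEMPLATE_A
    b: float = DEFAULT_TEMPLATE_B
    rotation: float = 45.0
    center: tuple[float, float] = (0.0, 0.0)
    direction: Direction = Direction.CCW

    def __post_init__(self) -> None:
        self.direction = _as_enum(self.direction, Direction)
        if not (self.a >= self.b > 0):
            raise ValidationError(f"template requires a >= b > 0, got a={self.a}, b={self.b}")
        if not (-90.0 < self.rotation <= 90.0):
            raise ValidationError(
                f"template rotation must lie in (-90, 90], got {self.rotation}"
            )

    @property
    def eccentricity(self) -> float:
        from .features import eccentricity_from_axes

        return eccentricity_from_axes(self.a, self.b)

    @property
    def perimeter(self) -> float:
        from .features import ellipse_perimeter

        return ellipse_perimeter(self.a, self.b)

    @classmethod
    def for_hand(cls, hand: Hand | str, a: float = DEFAULT_TEMPLATE_A,
                 b: float = DEFAULT_TEMPLATE_B) -> "TemplateSpec":
        """Template as presented to each hand: +45 deg / CCW for the dominant
        (right) hand, -45 deg / CW for the non-dominant (left) hand."""
        hand = _as_enum(hand, Hand)
        if hand is Hand.D:
            return cls(a=a, b=b, rotation=45.0, direction=Direction.CCW)
        return cls(a=a, b=b, rotation=-45.0, direction=Direction.CW)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the analysis pipeline.

    Defaults encode the study's processing choices: zero-phase Butterworth
    low-pass (7 Hz cutoff, order 2), exclusion of the first and the two last
    cycles of each ten-cycle recording, and small positive floors below which
    speed/curvature samples are masked before log-domain fitting.
    """

    filter_cutoff: float = 7.0
    filter_order: int = 2
    exclusion: tuple[int, int] = (1, 2)
    min_cycles_after_exclusion: int = 2
    speed_epsilon: float = 1e-6
    curvature_epsilon: float = 1e-6
    seed: int = 0
    template: TemplateSpec = field(default_factory=TemplateSpec)

    def __post_init__(self) -> None:
        if self.filter_cutoff <= 0:
            raise ValidationError(
                f"filter_cutoff must be positive, got {self.filter_cutoff}"
            )
        if int(self.filter_order) < 1:
            raise ValidationError("filter_order must be >= 1")
        self.filter_order = int(self.filter_order)
        n_first, n_last = self.exclusion
        if n_first < 0 or n_last < 0:
            raise ValidationError("exclusion counts must be >= 0")
        self.exclusion = (int(n_first), int(n_last))
        if self.min_cycles_after_exclusion < 2:
            raise ValidationError("min_cycles_after_exclusion must be >= 2")
        if self.speed_epsilon <= 0 or self.curvature_epsilon <= 0:
            raise ValidationError("epsilon floors must be positive")

    def template_for_hand(self, hand: Hand | str) -> TemplateSpec:
        """The template with the rotation/direction convention for ``hand``,
        keeping this config's semi-axes."""
        return TemplateSpec.for_hand(hand, a=self.template.a, b=self.template.b)
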