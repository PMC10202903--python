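"""Synthetic elliptical-drawing trajectories with a controlled speed-curvature
power law.

The generator family emulates the tablet task the analysis targets: subjects
trace an 8 x 2 cm template ellipse (rotated +/-45 deg) for ten continuous
cycles at three paces around a spontaneous one, dominant hand tracing
counterclockwise and non-dominant clockwise. Tangential speed along the
ellipse follows v = k * R^beta (equivalently, angular velocity V = K * C^(1-beta));
the harmonic ellipse x = a*cos(w*t), y = b*sin(w*t) is the exact beta = 1/3
member of that family and serves as the analytic anchor.

Cohorts add the between/within-subject structure the statistics assume:
subject-idiosyncratic pace and vigor shared across hands with a high
cross-hand correlation, a reduced eccentricity for the non-dominant hand,
per-cycle multiplicative jitter and additive positional sensor noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    Direction,
    Hand,
    Speed,
    Trajectory,
    ValidationError,
    _as_enum,
    DEFAULT_TEMPLATE_A,
    DEFAULT_TEMPLATE_B,
)

__all__ = [
    "CycleSpec",
    "RecordingSpec",
    "CohortSpec",
    "generate_harmonic_cycle",
    "generate_power_law_cycle",
    "generate_recording",
    "draw_cohort_parameters",
    "generate_cohort",
]

# parameter-grid resolution for arbitrary-beta arc-length integration
_PHI_STEPS = 8192


@dataclass
class CycleSpec:
    """One elliptical cycle: geometry, power-law exponent, and period."""

    a: float = DEFAULT_TEMPLATE_A
    b: float = DEFAULT_TEMPLATE_B
    beta: float = 1.0 / 3.0
    duration: float = 1.66
    rotation: float = 45.0
    center: tuple[float, float] = (0.0, 0.0)
    direction: Direction = Direction.CCW
    phase0: float = 0.0

    def __post_init__(self) -> None:
        self.direction = _as_enum(self.direction, Direction)
        if not (self.a >= self.b > 0):
            raise ValidationError(f"cycle requires a >= b > 0, got a={self.a}, b={self.b}")
        if not (0.0 < self.beta < 1.0):
            raise ValidationError(f"beta must lie in (0, 1), got {self.beta}")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")


@dataclass
class RecordingSpec:
    """A continuous multi-cycle recording: base cycle plus noise structure."""

    cycle: CycleSpec = field(default_factory=CycleSpec)
    n_cycles: int = 10
    jitter_cv: float = 0.035
    noise_sd: float = 0.02
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if self.jitter_cv < 0 or self.noise_sd < 0:
            raise ValidationError("jitter_cv and noise_sd must be >= 0")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")


@dataclass
class CohortSpec:
    """A full simulated cohort: n_subjects x 2 hands x 3 speeds recordings.

    ``speed_duration_multipliers`` scale each subject's spontaneous cycle
    period for the slow/normal/fast conditions; ``nd_eccentricity_shift`` is
    added to the aspect ratio b/a for the non-dominant hand (rounder
    ellipses); subject pace and vigor are log-normal across subjects and
    correlated across hands at ``cross_hand_correlation``.
    """

    n_subjects: int = 40
    speed_duration_multipliers: dict = field(
        default_factory=lambda: {"S": 2.2, "N": 1.0, "F": 0.63}
    )
    nd_eccentricity_shift: float = 0.015
    subject_duration_dist: tuple[float, float] = (1.66, 0.3)  # (median s, log-SD)
    subject_vigor_dist: tuple[float, float] = (1.0, 0.1)  # size scale (median, log-SD)
    subject_beta_dist: tuple[float, float] = (1.0 / 3.0, 0.01)  # (mean, SD)
    cross_hand_correlation: float = 0.9
    recording: RecordingSpec = field(default_factory=RecordingSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for key in ("S", "N", "F"):
            if key not in self.speed_duration_multipliers:
                raise ValidationError(f"speed_duration_multipliers missing {key}")
            if self.speed_duration_multipliers[key] <= 0:
                raise ValidationError("speed multipliers must be positive")
        if not (0.0 <= self.cross_hand_correlation <= 1.0):
            raise ValidationError("cross_hand_correlation must lie in [0, 1]")


def _rotation_matrix(rotation_deg: float) -> np.ndarray:
    th = math.radians(rotation_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


def _place(xl: np.ndarray, yl: np.ndarray, rotation: float,
           center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    rot = _rotation_matrix(rotation)
    xy = rot @ np.vstack([xl, yl])
    return xy[0] + center[0], xy[1] + center[1]


def generate_harmonic_cycle(
    a: float = DEFAULT_TEMPLATE_A,
    b: float = DEFAULT_TEMPLATE_B,
    frequency: float = 1.0,
    rotation: float = 0.0,
    direction: Direction | str = Direction.CCW,
    phase0: float = 0.0,
    sample_rate: float = 200.0,
    n_cycles: int = 1,
    center: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Noise-free harmonic ellipse: x = a*cos(2*pi*f*t + phi0),
    y = +/- b*sin(2*pi*f*t + phi0), rotated and translated.

    This is the exact beta = 1/3 trajectory (peak tangential speed
    2*pi*f*a); the final sample closes the last cycle at t = n_cycles/f.
    """
    direction = _as_enum(direction, Direction)
    if frequency <= 0:
        raise ValidationError("frequency must be positive")
    if sample_rate < 4 * frequency:
        raise ValidationError(
            f"sample_rate {sample_rate} Hz under-samples a {frequency} Hz cycle "
            "(need >= 4x)"
        )
    n = int(round(n_cycles * sample_rate / frequency))
    t = np.arange(n + 1) / sample_rate
    sign = 1.0 if direction is Direction.CCW else -1.0
    phase = 2 * math.pi * frequency * t + phase0
    xl = a * np.cos(phase)
    yl = sign * b * np.sin(phase)
    x, y = _place(xl, yl, rotation, center)
    return Trajectory(t=t, x=x, y=y, sample_rate=sample_rate)


def _power_law_phase_law(spec: CycleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Time as a function of ellipse parameter phi over one revolution.

    Along r(phi) = (a*cos(phi), b*sin(phi)) the speed profile
    v(phi) = k * R(phi)^beta gives dt/dphi = |r'(phi)| / v(phi); k is set so
    that one revolution takes ``spec.duration``. Returns (phi_grid, t_of_phi)
    with t normalized to end exactly at spec.duration.
    """
    a, b, beta = spec.a, spec.b, spec.beta
    phi = spec.phase0 + np.linspace(0.0, 2 * math.pi, _PHI_STEPS + 1)
    g = np.sqrt(a**2 * np.sin(phi) ** 2 + b**2 * np.cos(phi) ** 2)  # |r'(phi)|
    # radius of curvature R(phi) = g^3 / (a*b)
    R = g**3 / (a * b)
    integrand = g / R**beta  # proportional to dt/dphi
    from scipy.integrate import cumulative_trapezoid

    t_of_phi = cumulative_trapezoid(integrand, phi, initial=0.0)
    t_of_phi *= spec.duration / t_of_phi[-1]
    return phi, t_of_phi


def generate_power_law_cycle(spec: CycleSpec, sample_rate: float = 200.0) -> Trajectory:
    """One noise-free cycle whose tangential speed obeys v = k * R^beta.

    Implemented by integrating dphi/dt = v(phi)/|r'(phi)| on a fine parameter
    grid and resampling to ``sample_rate`` by interpolation; the speed
    constant k is fixed by the requested cycle period. For beta = 1/3 the
    result coincides with :func:`generate_harmonic_cycle`. The final sample
    closes the cycle at t = duration.
    """
    if sample_rate <= 0:
        raise ValidationError("sample_rate must be positive")
    if sample_rate * spec.duration < 4:
        raise ValidationError("sample_rate too low for the requested cycle duration")
    phi_grid, t_grid = _power_law_phase_law(spec)
    # snap the period onto the sample grid (sub-sample adjustment) so the
    # trajectory is exactly uniformly sampled and the cycle closes on a sample
    n = int(round(spec.duration * sample_rate))
    t_grid = t_grid * (n / sample_rate / spec.duration)
    t = np.arange(n + 1) / sample_rate
    phi = np.interp(t, t_grid, phi_grid)
    # closure check: interpolation must recover the full revolution
    if abs(phi[-1] - phi_grid[-1]) > 1e-6 * 2 * math.pi:
        raise ValidationError("cycle integration failed to close the revolution")
    sign = 1.0 if spec.direction is Direction.CCW else -1.0
    xl = spec.a * np.cos(phi)
    yl = sign * spec.b * np.sin(phi)
    x, y = _place(xl, yl, spec.rotation, spec.center)
    return Trajectory(t=t, x=x, y=y, sample_rate=sample_rate)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative mean-1 log-normal jitter with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_recording(spec: RecordingSpec, seed: int | np.random.Generator = 0,
                       subject_id: str = "anon", hand: Hand | str = Hand.D,
                       speed: Speed | str = Speed.N) -> Trajectory:
    """A continuous multi-cycle recording with per-cycle jitter and sensor noise.

    Cycle period and semi-axes are jittered by independent mean-1 log-normal
    factors of coefficient of variation ``jitter_cv``; isotropic Gaussian
    positional noise of SD ``noise_sd`` cm is added. Deterministic for a
    fixed seed. Successive cycles are joined continuously in position.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = spec.cycle
    dur_f = _lognormal_factors(rng, spec.jitter_cv, spec.n_cycles)
    a_f = _lognormal_factors(rng, spec.jitter_cv, spec.n_cycles)
    b_f = _lognormal_factors(rng, spec.jitter_cv, spec.n_cycles)

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    n_total = 0
    end_point = None
    for i in range(spec.n_cycles):
        a_i = base.a * a_f[i]
        b_i = base.b * b_f[i]
        cyc = replace(base, a=max(a_i, b_i), b=min(a_i, b_i),
                      duration=base.duration * dur_f[i])
        traj = generate_power_law_cycle(cyc, sample_rate=spec.sample_rate)
        x, y = traj.x.copy(), traj.y.copy()
        if end_point is not None:
            # translate so this cycle starts where the previous one ended
            x += end_point[0] - x[0]
            y += end_point[1] - y[0]
        end_point = (x[-1], y[-1])
        last = i == spec.n_cycles - 1
        stop = None if last else -1  # drop duplicated join sample
        xs.append(x[:stop])
        ys.append(y[:stop])
        n_total += x.size - (0 if last else 1)

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.arange(x.size) / spec.sample_rate
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, x.size)
        y = y + rng.normal(0.0, spec.noise_sd, y.size)
    return Trajectory(t=t, x=x, y=y, subject_id=subject_id, hand=hand,
                      speed=speed, sample_rate=spec.sample_rate)


def _correlated_lognormal_pair(rng: np.random.Generator, median: float,
                               log_sd: float, rho: float, n: int) -> np.ndarray:
    """(n, 2) log-normal draws with cross-column correlation rho (shared
    latent + independent noise in log space)."""
    shared = rng.normal(0.0, 1.0, n)
    eps = rng.normal(0.0, 1.0, (n, 2))
    z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * eps
    return median * np.exp(log_sd * z)


def draw_cohort_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-recording generating parameters of a cohort.

    One row per subject x hand x speed with the true cycle duration,
    semi-axes, beta, rotation, direction, and a per-recording child seed.
    Subject-level duration and vigor (size scale) are shared across hands at
    the target cross-hand correlation; the non-dominant hand's aspect ratio
    b/a is increased by ``nd_eccentricity_shift`` (rounder ellipses).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    dur_med, dur_lsd = spec.subject_duration_dist
    vig_med, vig_lsd = spec.subject_vigor_dist
    beta_mean, beta_sd = spec.subject_beta_dist
    rho = spec.cross_hand_correlation

    durations = _correlated_lognormal_pair(rng, dur_med, dur_lsd, rho, n)  # (n, 2) D/ND
    vigors = _correlated_lognormal_pair(rng, vig_med, vig_lsd, rho, n)
    betas = np.clip(rng.normal(beta_mean, beta_sd, n), 0.05, 0.95)

    seeds = np.random.SeedSequence(spec.seed).spawn(n * 6)
    rows = []
    k = 0
    for i in range(n):
        subject = f"S{i + 1:03d}"
        for hi, hand in enumerate((Hand.D, Hand.ND)):
            scale = vigors[i, hi]
            a = DEFAULT_TEMPLATE_A * scale
            ar = DEFAULT_TEMPLATE_B / DEFAULT_TEMPLATE_A
            if hand is Hand.ND:
                ar = ar + spec.nd_eccentricity_shift
            b = a * ar
            rotation = 45.0 if hand is Hand.D else -45.0
            direction = Direction.CCW if hand is Hand.D else Direction.CW
            for sp in (Speed.S, Speed.N, Speed.F):
                duration = durations[i, hi] * spec.speed_duration_multipliers[sp.value]
                rows.append({
                    "subject_id": subject,
                    "hand": hand.value,
                    "speed": sp.value,
                    "duration": duration,
                    "a": a,
                    "b": b,
                    "beta": betas[i],
                    "rotation": rotation,
                    "direction": direction.value,
                    "child_seed": int(seeds[k].generate_state(1)[0] % (2**31)),
                })
                k += 1
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> tuple[list[Trajectory], pd.DataFrame]:
    """Generate all recordings of a cohort plus the ground-truth table.

    Returns ``n_subjects * 2 * 3`` trajectories (one per subject x hand x
    speed) and the table of true generating parameters for recovery tests.
    """
    truth = draw_cohort_parameters(spec)
    trajectories = []
    for row in truth.itertuples(index=False):
        cyc = CycleSpec(
            a=row.a, b=row.b, beta=row.beta, duration=row.duration,
            rotation=row.rotation, direction=row.direction,
        )
        rec = replace(spec.recording, cycle=cyc)
        trajectories.append(
            generate_recording(rec, seed=int(row.child_seed),
                               subject_id=row.subject_id, hand=row.hand,
                               speed=row.speed)
        )
    return trajectories, truth
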