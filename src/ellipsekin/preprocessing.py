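"""Filtering, differentiation, and cycle segmentation of pen trajectories.

The processing order is fixed: zero-phase low-pass filtering of the position
samples, finite-difference kinematics, segmentation of the continuous tracing
into single elliptical revolutions by centroid-angle accumulation, then
exclusion of the warm-up/wind-down cycles (first one and last two by
default, leaving seven of a ten-cycle recording).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Trajectory, TooFewCyclesError, ValidationError

__all__ = [
    "KinematicProfile",
    "Cycle",
    "lowpass_filter",
    "estimate_derivatives",
    "segment_cycles",
    "exclude_cycles",
    "resample_uniform",
]

MIN_CYCLE_SAMPLES = 16


@dataclass
class KinematicProfile:
    """Per-sample kinematics aligned with a trajectory: velocity (cm/s),
    acceleration (cm/s^2), and tangential speed (cm/s)."""

    vx: np.ndarray
    vy: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    speed: np.ndarray

    def __len__(self) -> int:
        return int(self.speed.size)


@dataclass(frozen=True)
class Cycle:
    """One elliptical revolution as a half-open sample range [start, end)."""

    start: int
    end: int
    cycle_index: int

    def __post_init__(self) -> None:
        if self.end - self.start < MIN_CYCLE_SAMPLES:
            raise ValidationError(
                f"cycle {self.cycle_index} spans only {self.end - self.start} "
                f"samples (< {MIN_CYCLE_SAMPLES})"
            )

    def slice(self, closed: bool = False) -> slice:
        """Index slice; ``closed=True`` includes the boundary sample that
        starts the next cycle (closing the revolution)."""
        return slice(self.start, self.end + 1 if closed else self.end)


def resample_uniform(traj: Trajectory) -> Trajectory:
    """Linearly resample onto a uniform grid at the nominal sample rate."""
    dt = 1.0 / traj.sample_rate
    t = traj.t[0] + np.arange(round(traj.duration * traj.sample_rate) + 1) * dt
    x = np.interp(t, traj.t, traj.x)
    y = np.interp(t, traj.t, traj.y)
    return Trajectory(t=t, x=x, y=y, subject_id=traj.subject_id, hand=traj.hand,
                      speed=traj.speed, sample_rate=traj.sample_rate)


def lowpass_filter(traj: Trajectory, cutoff: float = 7.0, order: int = 2) -> Trajectory:
    """Zero-phase (forward-backward) Butterworth low-pass of x and y.

    Forward-backward application (``scipy.signal.filtfilt``) cancels the
    phase response, so a passband component comes through with zero lag;
    the effective magnitude response is the squared one-pass response.
    """
    nyquist = traj.sample_rate / 2.0
    if not (0.0 < cutoff < nyquist):
        raise ValidationError(
            f"cutoff must lie in (0, {nyquist}) Hz for sample_rate "
            f"{traj.sample_rate} Hz; got {cutoff}"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=traj.sample_rate, output="sos")
    x = signal.sosfiltfilt(sos, traj.x)
    y = signal.sosfiltfilt(sos, traj.y)
    return traj.with_positions(x, y)


def estimate_derivatives(traj: Trajectory) -> KinematicProfile:
    """Finite-difference kinematics: central differences on interior samples,
    one-sided at the ends; tangential speed is the Euclidean velocity norm."""
    if traj.n_samples < 3:
        raise ValidationError("need >= 3 samples to differentiate")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    ax = np.gradient(vx, traj.t)
    ay = np.gradient(vy, traj.t)
    speed = np.hypot(vx, vy)
    return KinematicProfile(vx=vx, vy=vy, ax=ax, ay=ay, speed=speed)


def segment_cycles(traj: Trajectory, profile: KinematicProfile | None = None
                   ) -> list[Cycle]:
    """Split a continuous tracing into single revolutions about its centroid.

    The unwrapped centroid angle theta(t) = atan2(y - y_mean, x - x_mean) is
    accumulated as total swept angle |d theta|; a cycle boundary is placed at
    the sample nearest each crossing of a multiple of 2*pi. Works for both
    tracing directions; a trailing partial revolution is discarded.
    """
    theta = np.unwrap(np.arctan2(traj.y - traj.y.mean(), traj.x - traj.x.mean()))
    swept = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(theta)))])
    # a revolution that closes within half a sample step counts as complete
    tol = 0.5 * float(np.median(np.abs(np.diff(theta))))
    n_revolutions = int(np.floor((swept[-1] + tol) / (2 * np.pi)))
    if n_revolutions < 1:
        raise ValidationError(
            f"no complete cycle: total angular excursion {swept[-1]:.3f} rad < 2*pi"
        )
    boundaries = [0]
    for k in range(1, n_revolutions + 1):
        idx = int(np.argmin(np.abs(swept - 2 * np.pi * k)))
        boundaries.append(idx)
    cycles = []
    for i in range(n_revolutions):
        start, end = boundaries[i], boundaries[i + 1]
        if end <= start:
            continue
        cycles.append(Cycle(start=start, end=end, cycle_index=len(cycles)))
    return cycles


def exclude_cycles(cycles: list[Cycle], rule: tuple[int, int] = (1, 2),
                   min_cycles: int = 2) -> list[Cycle]:
    """Drop the first ``rule[0]`` and last ``rule[1]`` cycles (warm-up and
    wind-down); ten recorded cycles leave seven under the default rule.

    Raises :class:`TooFewCyclesError` if fewer than ``min_cycles`` remain.
    """
    n_first, n_last = rule
    if n_first < 0 or n_last < 0:
        raise ValidationError("exclusion counts must be >= 0")
    kept = cycles[n_first: len(cycles) - n_last if n_last else None]
    if len(kept) < min_cycles:
        raise TooFewCyclesError(
            f"too few cycles: {len(cycles)} segmented, {len(kept)} retained "
            f"after dropping first {n_first} and last {n_last}; "
            f"need >= {min_cycles}"
        )
    return kept
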