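"""Per-cycle geometric, kinematic, and speed-curvature power-law features.

For each retained elliptical cycle the module computes the standard
descriptor set: an ellipse fitted to the samples by direct least squares
(center, semi-axes, orientation), eccentricity e = sqrt(1 - (b/a)^2), drawn
perimeter and size relative to the template, cycle duration, peak and mean
tangential velocity, and the power-law triple (beta, velocity gain factor K,
log-log correlation) from the regression of angular velocity on curvature:

    V(t) = K * C(t)^(1 - beta)

Curvature is estimated from the first and second derivatives of the sampled
path, C = |vx*ay - vy*ax| / v^3, which converges on densely sampled smooth
curves; angular velocity is V = v * C. The log-log regression of V on C has
slope 1 - beta, so beta = 1 - slope and K = exp(intercept) (natural logs;
beta and the correlation are base-invariant). For elliptic harmonic motion
beta = 1/3 exactly and K = 2*pi*f*(a*b)^(1/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy import special, stats

from .core import (
    AnalysisConfig,
    DegenerateCycleError,
    FitError,
    TemplateSpec,
    Trajectory,
    ValidationError,
)
from .preprocessing import Cycle, KinematicProfile

__all__ = [
    "EllipseFit",
    "CurvatureProfile",
    "PowerLawFit",
    "CycleFeatures",
    "FEATURE_COLUMNS",
    "eccentricity_from_axes",
    "ellipse_perimeter",
    "fit_ellipse",
    "geometry_features",
    "kinematic_features",
    "curvature_profile",
    "fit_power_law",
    "analyze_cycle",
]

# Table-style parameter order used by all feature tables and reports.
FEATURE_COLUMNS = [
    "max_v",
    "mean_v",
    "duration",
    "beta",
    "K",
    "corr_coef",
    "eccentricity",
    "semi_major",
    "semi_minor",
    "aspect_ratio",
    "perimeter",
    "relative_size",
    "rotation_angle",
]


def eccentricity_from_axes(a: float, b: float) -> float:
    """e = sqrt(1 - (b/a)^2) for semi-axes a >= b > 0."""
    if not (a >= b > 0):
        raise ValidationError(f"eccentricity needs a >= b > 0, got a={a}, b={b}")
    return math.sqrt(1.0 - (b / a) ** 2)


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter 4*a*E(e^2) via the complete elliptic integral
    of the second kind (8 x 2 cm template: 34.3137 cm)."""
    if not (a >= b > 0):
        raise ValidationError(f"perimeter needs a >= b > 0, got a={a}, b={b}")
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * float(special.ellipe(m))


@dataclass
class EllipseFit:
    """Geometric parameters of a direct least-squares ellipse fit."""

    center: tuple[float, float]
    a: float  # semi-major, cm
    b: float  # semi-minor, cm
    orientation: float  # degrees CCW from +x, in (-90, 90]
    rms_residual: float  # cm, RMS algebraic-normalized residual

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise FitError(f"fit produced invalid axes a={self.a}, b={self.b}")


@dataclass
class CurvatureProfile:
    """Per-sample curvature C (1/cm), radius R = 1/C (cm), and angular
    velocity V = v*C (rad/s), with a validity mask excluding samples where
    speed or curvature falls below its epsilon floor."""

    C: np.ndarray
    R: np.ndarray
    V_ang: np.ndarray
    valid: np.ndarray  # boolean mask


@dataclass
class PowerLawFit:
    """Result of the log-log regression of angular velocity on curvature."""

    beta: float
    K: float
    corr_coef: float
    n_points: int


@dataclass
class CycleFeatures:
    """The per-cycle parameter set: kinematics, power law, geometry."""

    duration: float
    max_v: float
    mean_v: float
    beta: float
    K: float
    corr_coef: float
    eccentricity: float
    semi_major: float
    semi_minor: float
    aspect_ratio: float
    perimeter: float
    relative_size: float
    rotation_angle: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def _normalize_orientation(deg: float) -> float:
    """Fold an axis orientation into (-90, 90]."""
    deg = (deg + 90.0) % 180.0 - 90.0
    if deg == -90.0:
        deg = 90.0
    return deg


def fit_ellipse(x: np.ndarray, y: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (numerically stable formulation).

    Solves the constrained conic least-squares problem whose solution is
    guaranteed to be an ellipse, using the partitioned generalized
    eigenproblem of Halir & Flusser; data are centered/scaled first for
    conditioning. Raises :class:`FitError` for degenerate inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 6:
        raise FitError(f"ellipse fit needs >= 6 points, got {x.size}")
    mx, my = x.mean(), y.mean()
    scale = max(np.abs(x - mx).max(), np.abs(y - my).max())
    if scale <= 0 or not np.isfinite(scale):
        raise FitError("degenerate point set (zero extent)")
    xs = (x - mx) / scale
    ys = (y - my) / scale

    D1 = np.column_stack([xs * xs, xs * ys, ys * ys])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate (collinear?) point set") from exc
    M = S1 + S2 @ T
    # apply inverse constraint matrix C1^-1 for the constraint 4AC - B^2 = 1
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    eigval = np.real(eigval)
    eigvec = np.real(eigvec)
    # the ellipse solution satisfies 4AC - B^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    candidates = np.flatnonzero((cond > 0) & np.isfinite(eigval))
    if candidates.size == 0:
        raise FitError("no elliptical solution (points may be collinear)")
    a1 = eigvec[:, candidates[0]]
    coeffs = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F in scaled frame
    A, B, C, D, E, F = coeffs

    # conic -> geometric in the scaled frame
    Mq = np.array([[A, B / 2.0], [B / 2.0, C]])
    try:
        cx, cy = np.linalg.solve(2.0 * Mq, [-D, -E])
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate conic (no unique center)") from exc
    F0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    lam, vecs = np.linalg.eigh(Mq)
    axes_sq = -F0 / lam
    if np.any(axes_sq <= 0):
        raise FitError("conic is not a real ellipse")
    semi = np.sqrt(axes_sq)  # aligned with eigvecs of lam
    major_idx = int(np.argmax(semi))
    a_fit = float(semi[major_idx]) * scale
    b_fit = float(semi[1 - major_idx]) * scale
    if math.isclose(a_fit, b_fit, rel_tol=1e-9):
        orientation = 0.0  # circle: orientation undefined, report 0
    else:
        v_major = vecs[:, major_idx]
        orientation = _normalize_orientation(math.degrees(math.atan2(v_major[1], v_major[0])))
    center = (float(cx * scale + mx), float(cy * scale + my))

    # RMS of the gradient-normalized algebraic residual (approx. geometric, cm)
    gx = 2 * A * xs + B * ys + D
    gy = B * xs + 2 * C * ys + E
    alg = A * xs * xs + B * xs * ys + C * ys * ys + D * xs + E * ys + F
    grad = np.hypot(gx, gy)
    grad[grad == 0] = np.inf
    rms = float(np.sqrt(np.mean((alg / grad) ** 2))) * scale
    return EllipseFit(center=center, a=a_fit, b=b_fit,
                      orientation=orientation, rms_residual=rms)


def geometry_features(fit: EllipseFit, x: np.ndarray, y: np.ndarray,
                      template: TemplateSpec) -> dict:
    """Geometric descriptors of one drawn cycle.

    Eccentricity comes from the fitted semi-axes; the perimeter is the
    polyline arc length of the cycle's samples; relative size is that
    perimeter over the template's exact (elliptic-integral) perimeter.
    """
    perimeter = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    return {
        "eccentricity": eccentricity_from_axes(fit.a, fit.b),
        "semi_major": fit.a,
        "semi_minor": fit.b,
        "aspect_ratio": fit.b / fit.a,
        "perimeter": perimeter,
        "relative_size": perimeter / ellipse_perimeter(template.a, template.b),
        "rotation_angle": fit.orientation,
    }


def kinematic_features(t: np.ndarray, speed: np.ndarray) -> dict:
    """Cycle duration, peak tangential velocity (vigor), and time-averaged
    tangential velocity (trapezoidal, so a closing sample is not
    double-counted)."""
    if t.size < 2:
        raise ValidationError("kinematic features need >= 2 samples")
    return {
        "duration": float(t[-1] - t[0]),
        "max_v": float(np.max(speed)),
        "mean_v": float(np.trapezoid(speed, t) / (t[-1] - t[0])),
    }


def curvature_profile(profile: KinematicProfile, speed_epsilon: float = 1e-6,
                      curvature_epsilon: float = 1e-6,
                      edge_exclude: int = 2) -> CurvatureProfile:
    """Curvature, radius of curvature, and angular velocity per sample.

    C = |vx*ay - vy*ax| / v^3; samples with near-zero speed or curvature are
    masked out (they are undefined or uninformative in the log domain), as
    are ``edge_exclude`` samples at either end, whose second derivatives
    rest on one-sided differences and are unreliable.
    """
    v = profile.speed
    cross = np.abs(profile.vx * profile.ay - profile.vy * profile.ax)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(v > 0, cross / np.maximum(v, 1e-300) ** 3, np.nan)
    valid = np.isfinite(C) & (v >= speed_epsilon) & (C >= curvature_epsilon)
    if edge_exclude > 0:
        valid[:edge_exclude] = False
        valid[-edge_exclude:] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(valid, 1.0 / C, np.nan)
    V_ang = np.where(valid, v * C, np.nan)
    if not np.any(valid):
        raise DegenerateCycleError("all samples masked in curvature profile")
    return CurvatureProfile(C=C, R=R, V_ang=V_ang, valid=valid)


def fit_power_law(curv: CurvatureProfile, min_points: int = 10,
                  min_log_spread: float = 1e-3) -> PowerLawFit:
    """Fit V = K * C^(1-beta) by OLS of ln(V) on ln(C) over valid samples.

    The regression slope s gives beta = 1 - s; K = exp(intercept);
    ``corr_coef`` is the Pearson r of the same log-log point cloud. A
    near-constant curvature (a circle) leaves the slope unidentified and
    raises :class:`FitError`.
    """
    mask = curv.valid
    n = int(np.count_nonzero(mask))
    if n < min_points:
        raise FitError(f"power-law fit needs >= {min_points} valid samples, got {n}")
    logC = np.log(curv.C[mask])
    logV = np.log(curv.V_ang[mask])
    if logC.max() - logC.min() < min_log_spread:
        raise FitError(
            "uninformative curvature range: log-curvature spread "
            f"{logC.max() - logC.min():.2e} < {min_log_spread:.0e} (near-circle)"
        )
    res = stats.linregress(logC, logV)
    return PowerLawFit(beta=1.0 - float(res.slope), K=float(np.exp(res.intercept)),
                       corr_coef=float(res.rvalue), n_points=n)


def analyze_cycle(traj: Trajectory, profile: KinematicProfile, cycle: Cycle,
                  template: TemplateSpec, config: AnalysisConfig | None = None
                  ) -> CycleFeatures:
    """Assemble the full per-cycle feature record for one segmented cycle."""
    config = config or AnalysisConfig()
    sl = cycle.slice(closed=True)
    t = traj.t[sl]
    x = traj.x[sl]
    y = traj.y[sl]
    sub = KinematicProfile(vx=profile.vx[sl], vy=profile.vy[sl],
                           ax=profile.ax[sl], ay=profile.ay[sl],
                           speed=profile.speed[sl])
    try:
        fit = fit_ellipse(x, y)
        geom = geometry_features(fit, x, y, template)
        kin = kinematic_features(t, sub.speed)
        curv = curvature_profile(sub, speed_epsilon=config.speed_epsilon,
                                 curvature_epsilon=config.curvature_epsilon)
        power = fit_power_law(curv)
    except (FitError, DegenerateCycleError, ValidationError) as exc:
        raise type(exc)(f"cycle {cycle.cycle_index}: {exc}") from exc
    return CycleFeatures(
        duration=kin["duration"], max_v=kin["max_v"], mean_v=kin["mean_v"],
        beta=power.beta, K=power.K, corr_coef=power.corr_coef,
        eccentricity=geom["eccentricity"], semi_major=geom["semi_major"],
        semi_minor=geom["semi_minor"], aspect_ratio=geom["aspect_ratio"],
        perimeter=geom["perimeter"], relative_size=geom["relative_size"],
        rotation_angle=geom["rotation_angle"],
    )
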