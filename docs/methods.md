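# Methods

This note documents the models, estimators, and design choices behind
`ellipsekin`, and what the synthetic-data generator does and does not
emulate.

## The measurement model

A recording is a uniformly sampled pen trajectory (t, x, y) at a nominal
200 samples/s, positions in cm, holding about ten continuously drawn
ellipses on an 8 × 2 cm template (eccentricity 0.968) whose major axis is
inclined +45° for the dominant (right) hand and −45° for the non-dominant
(left) hand; the dominant hand traces counterclockwise, the non-dominant
clockwise. Conditions are the 2 × 3 crossing of hand (D/ND) and pace
(slow / normal / fast around a spontaneous rhythm).

## Processing pipeline

Stages run in a fixed order; every tolerance sits in `AnalysisConfig`.

1. **Low-pass filtering.** Zero-phase (forward–backward) Butterworth,
   default order 2, cutoff 7 Hz. The cutoff is read as a normalized value
   of 0.07 × Nyquist at 200 Hz sampling: a literal 0.07 Hz low-pass would
   remove the ~0.3–1.5 Hz movement itself, so the normalized reading is
   the only physically coherent one for this task. The default keeps a
   1 Hz fundamental and its first several harmonics essentially untouched
   (a filtered harmonic template cycle shifts β̂ by < 0.002) while
   suppressing sensor noise above ~10 Hz by > 20 dB.
2. **Differentiation.** Central differences on interior samples
   (`numpy.gradient`), one-sided at the ends; acceleration by repeated
   differentiation; tangential speed is the velocity norm.
3. **Cycle segmentation.** The unwrapped centroid angle
   θ(t) = atan2(y − ȳ, x − x̄) is accumulated as total swept angle; a
   boundary snaps to the sample nearest each crossing of a multiple of
   2π. This is direction-agnostic (CW and CCW) and robust to the
   ellipse's high eccentricity, unlike velocity-extrema segmentation. A
   revolution closing within half a sample step counts as complete; a
   trailing partial revolution is discarded. How cycles were delimited in
   tablet studies is rarely reported; this rule is an explicit artifact
   decision, testable by construction against the generator.
4. **Exclusion.** The first and the two last cycles are dropped
   (warm-up/wind-down), so ten drawn cycles leave seven for analysis; an
   error is raised if fewer than `min_cycles_after_exclusion` (default 2)
   remain.

## Per-cycle features

* **Ellipse fit** — the numerically stable direct least-squares conic fit
  (partitioned generalized eigenproblem with the ellipse constraint
  4AC − B² = 1), after centering/scaling for conditioning. The conic is
  converted to center, semi-axes (a ≥ b enforced by a 90° orientation
  shift), and orientation folded into (−90°, 90°]; a circle reports
  orientation 0 by convention. "Major/minor axis" in reports are
  semi-axes (cm).
* **Geometry** — e = √(1 − (b/a)²) from the fitted semi-axes; perimeter
  as the polyline arc length of the cycle's samples; relative size as
  drawn perimeter over the template perimeter computed exactly via the
  complete elliptic integral of the second kind (34.3137 cm for 8 × 2).
  That definition reproduces tabulated relative sizes arithmetically
  (e.g. 33.318 / 34.314 = 0.971).
* **Curvature** — C = |vẋ·aÿ − vẏ·aẍ|/v³ per sample from the derivative
  estimates; R = 1/C; angular velocity V = v·C. Samples with speed or
  curvature below configurable floors (1e-6) are masked, as are two
  samples at each profile edge, whose one-sided second derivatives are
  unreliable. The estimator is the standard differential-geometry formula
  and converges on densely sampled smooth paths; a three-point
  (Menger, circumscribed-circle) curvature serves as an independent
  oracle in the tests.
* **Power law** — per-cycle OLS of ln V on ln C over unmasked samples
  (natural logs; β and r are base-invariant): β = 1 − slope,
  K = exp(intercept), plus the Pearson r of the log-log cloud (reported
  signed). A near-circular cycle (log-C spread < 1e-3) is rejected as
  uninformative rather than fitted. Regression is done cycle by cycle
  and then summarized per recording — the two-level scheme that keeps
  cycle-to-cycle variability observable.

## Statistics

* **CV** — sample SD (n−1) over mean, per parameter over the retained
  cycles; scale-invariant; undefined (NaN) for sign-carrying parameters.
* **ART ANOVA** — for each effect (hand, speed, hand × speed) the
  response is aligned by subtracting every estimated component of the
  additive model grand + hand + speed + interaction + subject except the
  effect of interest (aligned = residual + effect estimate), midranked
  over all observations, and tested by a fixed-effects factorial ANOVA on
  those ranks with subject as an additive blocking factor. For a complete
  balanced cohort (one value per subject × hand × speed cell) the error
  df is N − 1 − 1 − 2 − 2 − (n_subjects − 1): 195 at n = 40. The blocking
  construction is the only decomposition consistent with that df; it is
  asserted structurally in the tests, and the balanced-design sums of
  squares are cross-checked against an independent OLS ANOVA. Effect size
  is partial η² = SS_effect/(SS_effect + SS_error). Null simulations put
  each effect's type-I error within [0.04, 0.06] at α = 0.05. Tukey HSD
  (studentized range, scipy) runs on the effect's ranked responses. No
  multiple-testing correction is applied across the twelve parameters by
  default (a Holm flag exists in the stats layer's callers' hands).
* **Cross-hand correlations** — Pearson r between subjects' D and ND
  values at one speed: *accuracy* on condition means, *precision* on CVs.
* **Steiger tests** — comparing two dependent correlations that share
  subjects but no variable (the cross-hand correlation at two speeds):
  Fisher-z both correlations, estimate their covariance by the
  Pearson–Filon expression evaluated at the pooled correlation with the
  four observed cross-correlations of the quadruple (D₁, ND₁, D₂, ND₂),
  and refer the difference to a standard normal, two-sided. With zero
  cross-correlations this reduces to (z₁ − z₂)/√(2/(n−3)). The
  overlapping-variable variant is selectable. Null simulations put the
  rejection rate within [0.04, 0.06] at α = 0.05.

## The synthetic generator

The generator emulates the study conditions so the analysis chain can be
validated end to end.

* **Single cycles.** Along r(φ) = (a cos φ, b sin φ), tangential speed is
  set to v = k·R(φ)^β and the phase law integrated as
  dt/dφ = |r′(φ)|/v(φ) on an 8192-step parameter grid, then resampled to
  the sampling rate; k is fixed by the requested period (snapped to the
  sample grid, a sub-0.5-sample adjustment, so sampling stays exactly
  uniform and cycles close on a sample). Harmonic motion is the exact
  β = 1/3 solution and doubles as the closed-form oracle (peak speed
  2πfa, K = 2πf(ab)^(1/3)).
* **Recordings.** Ten cycles by default, joined continuously in position;
  cycle period and semi-axes jittered by independent mean-1 log-normal
  factors (multiplicative, so parameters stay positive; CV 0.035 by
  default, placing the duration CV under the 0.05 level typical of
  spontaneous-pace drawing); additive isotropic Gaussian position noise
  (SD 0.02 cm, plausible tablet noise). Deterministic per seed.
* **Cohorts.** n subjects × 2 hands × 3 speeds. Subject pace is
  log-normal (median cycle duration 1.66 s at normal speed — the scale of
  spontaneous elliptical tracing near an 80 BPM reference — log-SD 0.3,
  covering the wide between-subject range seen in such tasks) scaled by
  speed multipliers {slow 2.2, normal 1.0, fast 0.63}. Subject vigor is a
  log-normal size scale (log-SD 0.1). Pace and vigor are shared across
  hands through a common latent with target correlation 0.9, reproducing
  high cross-hand accuracy correlations without modeling their neural
  origin. The non-dominant hand's aspect ratio b/a is raised by 0.015
  (rounder, less eccentric ellipses) and traced clockwise. Per-subject β
  is N(1/3, 0.01). The generator returns the ground-truth parameter table
  for recovery tests.

**What it does not emulate:** pen lifts and pressure, tablet
quantization, visual feedback dynamics, training/metronome phases,
drift or tremor spectra, or any within-cycle β fluctuation. Passing
tests therefore validate the estimators and the statistical machinery
under the stated noise model, not the full phenomenology of human
recordings.

## Numerical choices and known limitations

* Simulation scales: validation uses 10-cycle recordings, cohorts of
  6–40 subjects, 200-seed correlation Monte Carlos, and 2000-replicate
  null calibrations at n = 20 — sizes at which the Monte Carlo error is
  well below the tolerances asserted.
* With positional noise, the log-log regression shares the noisy C on
  both sides (V = v·C), which pulls the slope toward 1 and hence β̂
  downward; the bias grows as movements slow (smaller accelerations
  relative to noise). Noise-free recovery is within 0.005 across
  β ∈ [0.25, 0.45]; with 0.05 cm noise, within 0.02. Slow-condition β̂
  from noisy synthetic cohorts is therefore biased low — a property of
  this estimator family generally, worth remembering when interpreting
  speed effects on β.
* The 7 Hz default filter slightly distorts strongly non-harmonic cycles
  at fast paces (harmonics above the passband); the noise-free β grid is
  therefore validated without filtering, the noisy grid with it.
* Ties in the ART ranks use midranks; the balanced-design ANOVA requires
  a complete layout and rejects unbalanced tables rather than
  approximating them.
* Orientation is axis-unsigned, reported in (−90°, 90°]; CVs are not
  computed for sign-carrying parameters (rotation angle at −45°).
* The trajectory reader accepts the package's own delimited format only
  (cm or mm units), resampling linearly when gaps exceed 10% of the
  nominal interval.
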