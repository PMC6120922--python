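"""Domain types for the inactivation-attention analyses.

The study design these types describe: a focal, reversible inactivation
(muscimol) of an oculomotor structure (superior colliculus, SC, or frontal
eye field, FEF) creates a "scotoma" — a retinotopically confined region of
visual space where saccades are slower to start and slower in flight.  The
same sessions measure covert attention with a two-patch motion-change
detection task.  Each session is summarised by two numbers:

* the saccade latency asymmetry (mean latency into the affected patch minus
  mean latency into the unaffected patch, in ms), and
* the change in detection-rate asymmetry (how much the out-minus-in hit-rate
  difference grew from the pre-injection to the injection epoch, in
  percentage points).

Coordinates are visual degrees with the origin at fixation; x > 0 points
into the affected (contralesional) hemifield, y > 0 is up.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np


class Structure(str, Enum):
    SC = "SC"
    FEF = "FEF"
    SHAM = "SHAM"


class Epoch(str, Enum):
    BEFORE = "before"
    DURING = "during"


class ChangeSide(str, Enum):
    IN = "in"      # affected hemifield
    OUT = "out"    # unaffected hemifield
    NONE = "none"  # catch trial, no motion-direction change


class ValidationError(ValueError):
    """A record violated a schema or domain invariant."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class SessionSummary:
    """One inactivation (or sham) experiment, i.e. one table row.

    Hit rates are proportions in [0, 1]; ``delta_det_asym_pct`` is in
    percentage points.  When all four hit rates are present they must be
    consistent with the detection-asymmetry statistic to within 0.05
    percentage points.
    """

    session_id: str
    structure: Structure
    subject: str
    latency_asym_ms: float
    delta_det_asym_pct: float
    scotoma_area_deg2: float
    overlap_pct: float
    center_dist_deg: float
    scotoma_center: Tuple[float, float]
    injection_ul: float
    hit_in_before: Optional[float] = None
    hit_out_before: Optional[float] = None
    hit_in_during: Optional[float] = None
    hit_out_during: Optional[float] = None
    velocity_asym_degps: Optional[float] = None
    significant_deficit: Optional[int] = None

    def __post_init__(self) -> None:
        self.structure = Structure(self.structure)
        rates = (self.hit_in_before, self.hit_out_before,
                 self.hit_in_during, self.hit_out_during)
        for name, r in zip(("hit_in_before", "hit_out_before",
                            "hit_in_during", "hit_out_during"), rates):
            if r is not None:
                _check(0.0 <= r <= 1.0,
                       f"{self.session_id}: {name}={r} outside [0, 1]")
        _check(0.0 <= self.overlap_pct <= 100.0,
               f"{self.session_id}: overlap_pct={self.overlap_pct} outside [0, 100]")
        _check(self.scotoma_area_deg2 >= 0.0,
               f"{self.session_id}: negative scotoma area")
        _check(self.center_dist_deg >= 0.0,
               f"{self.session_id}: negative center distance")
        _check(self.injection_ul > 0.0,
               f"{self.session_id}: injection volume must be positive")
        if self.significant_deficit is not None:
            _check(self.significant_deficit in (0, 1),
                   f"{self.session_id}: significant_deficit must be 0 or 1")
        if all(r is not None for r in rates):
            from .asymmetry import delta_detection_rate_asymmetry
            expected = delta_detection_rate_asymmetry(
                self.hit_in_before, self.hit_out_before,
                self.hit_in_during, self.hit_out_during)
            _check(abs(expected - self.delta_det_asym_pct) <= 0.05,
                   f"{self.session_id}: delta_det_asym_pct={self.delta_det_asym_pct} "
                   f"inconsistent with hit rates (expected {expected:.3f})")


@dataclass
class AttentionTrial:
    """One change-detection trial of the covert attention task."""

    session_id: str
    epoch: Epoch
    change_side: ChangeSide
    change_magnitude_deg: float
    delay_s: float
    responded: bool
    valid: bool
    reaction_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.epoch = Epoch(self.epoch)
        self.change_side = ChangeSide(self.change_side)
        if self.change_side is ChangeSide.NONE:
            _check(self.change_magnitude_deg == 0.0,
                   "catch trial must have zero change magnitude")
        else:
            _check(self.change_magnitude_deg >= 0.0,
                   "change magnitude must be non-negative")
        _check(1.0 <= self.delay_s <= 3.0,
               f"delay_s={self.delay_s} outside the 1-3 s task window")
        if self.valid and self.responded:
            _check(self.reaction_time_s is not None
                   and 0.3 <= self.reaction_time_s <= 0.8,
                   "a valid response must fall in the 300-800 ms window")


@dataclass
class SaccadeRecord:
    """One visually guided saccade from the delayed-saccade mapping task."""

    session_id: str
    epoch: Epoch
    target: Tuple[float, float]
    endpoint: Tuple[float, float]
    latency_ms: float
    peak_velocity_degps: float

    def __post_init__(self) -> None:
        self.epoch = Epoch(self.epoch)
        _check(self.latency_ms > 0.0, "latency must be positive")
        _check(self.peak_velocity_degps > 0.0, "peak velocity must be positive")


@dataclass
class PatchGeometry:
    """A circular motion-patch aperture (radius 3 deg by task design)."""

    center: Tuple[float, float]
    radius_deg: float = 3.0
    side: ChangeSide = ChangeSide.IN

    def __post_init__(self) -> None:
        _check(self.radius_deg > 0.0, "patch radius must be positive")
        self.side = ChangeSide(self.side)
        _check(self.side is not ChangeSide.NONE, "patch side must be in or out")

    def contains(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = np.hypot(xy[:, 0] - self.center[0], xy[:, 1] - self.center[1])
        return d <= self.radius_deg

    def mirror(self) -> "PatchGeometry":
        """The mirror-symmetric patch in the opposite hemifield."""
        other = ChangeSide.OUT if self.side is ChangeSide.IN else ChangeSide.IN
        return PatchGeometry((-self.center[0], self.center[1]),
                             self.radius_deg, other)


def patch_pair(eccentricity_deg: float = 9.0,
               radius_deg: float = 3.0) -> Tuple[PatchGeometry, PatchGeometry]:
    """Mirror-symmetric (in, out) patches on the horizontal meridian."""
    inp = PatchGeometry((eccentricity_deg, 0.0), radius_deg, ChangeSide.IN)
    return inp, inp.mirror()


@dataclass
class Scotoma:
    """The mapped saccadic deficit region of one inactivation."""

    significant_targets: Sequence[Tuple[float, float]]
    area_deg2: float
    centroid: Optional[Tuple[float, float]]
    overlap_pct: float
    center_dist_deg: Optional[float]
    alpha: float
    p_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check(self.area_deg2 >= 0.0, "scotoma area must be non-negative")
        _check(0.0 <= self.overlap_pct <= 100.0, "overlap_pct outside [0, 100]")
        _check((self.area_deg2 == 0.0) == (len(self.significant_targets) == 0),
               "area and significant-target count disagree on emptiness")


@dataclass
class PsychometricFit:
    """Four-parameter cumulative-Gaussian fit of hit rate vs change size.

    ``guess`` is the lower asymptote (response bias / false-alarm floor),
    ``lapse`` the complement of the upper asymptote.  The threshold is the
    change magnitude at 75 % of the signal-driven range, i.e.
    ``mu + sigma * Phi^{-1}(0.75)`` — by construction independent of the
    guess and lapse parameters.
    """

    mu_deg: float
    sigma_deg: float
    guess: float
    lapse: float
    threshold_deg: float
    n_trials: int
    loglik: float
    threshold_ci95: Optional[Tuple[float, float]] = None
    boundary_constrained: bool = False

    def __post_init__(self) -> None:
        _check(self.sigma_deg > 0.0, "sigma must be positive")
        _check(0.0 <= self.guess <= 0.5 and 0.0 <= self.lapse <= 0.5,
               "guess and lapse must lie in [0, 0.5]")
        _check(self.guess + self.lapse < 1.0, "guess + lapse must be < 1")


@dataclass
class RegressionResult:
    """Orthogonal-regression summary of the saccade/attention coupling."""

    slope: float
    intercept: float
    slope_se_jackknife: float
    r_squared: float
    n: int
    through_origin: bool = True
    r_squared_origin: Optional[float] = None

    def __post_init__(self) -> None:
        _check(self.n >= 3, "regression needs at least 3 sessions")
        _check(self.slope_se_jackknife >= 0.0, "SE must be non-negative")
        _check(0.0 <= self.r_squared <= 1.0, "r_squared outside [0, 1]")

    @property
    def dof(self) -> int:
        return self.n - 1


@dataclass
class LogisticPosterior:
    """Laplace posterior of a Bayesian logistic dose-response fit.

    ``w_map`` is (intercept, slope) in raw predictor units; ``laplace_cov``
    the Gaussian posterior covariance (inverse Hessian at the MAP).
    """

    w_map: np.ndarray
    laplace_cov: np.ndarray
    prior_sd: float
    n: int
    x_mean: float = 0.0
    x_scale: float = 1.0

    def __post_init__(self) -> None:
        self.w_map = np.asarray(self.w_map, dtype=float)
        self.laplace_cov = np.asarray(self.laplace_cov, dtype=float)
        _check(self.w_map.shape == (2,), "w_map must be (intercept, slope)")
        _check(self.laplace_cov.shape == (2, 2), "covariance must be 2x2")
        _check(np.allclose(self.laplace_cov, self.laplace_cov.T, atol=1e-10),
               "covariance must be symmetric")
        _check(np.all(np.linalg.eigvalsh(self.laplace_cov) >= -1e-12),
               "covariance must be positive semi-definite")
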