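"""Coupling analysis: orthogonal regression of the change in detection-rate
asymmetry on the saccade asymmetry, with jackknife slope errors, a bootstrap
slope comparison between structures, and binned group tests.

The line is fit by total least squares — minimising perpendicular distances
in raw units (percentage points on y, ms or deg/s on x) — and, by default,
constrained through the origin: a session with no saccade deficit is
predicted to have no attention deficit, which is what the sham-control
sessions clustered at (0, 0) show.  Through the origin the slope is the
major-axis eigenvector of the uncentered second-moment matrix; the centered
(free-intercept) variant uses the covariance matrix and is available with
``through_origin=False``.  This through-origin convention is the one that
reproduces the published per-structure slopes from the packaged session
tables; the centered variant gives materially different values on the same
data (see docs/methods.md).
"""
from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import RegressionResult


def _as_xy(points) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(points, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    return a[:, 0], a[:, 1]


def tls_slope(x: np.ndarray, y: np.ndarray, through_origin: bool = True) -> float:
    """Total-least-squares slope (scalar), vectorised over leading axes.

    For stacked resamples, ``x`` and ``y`` may be (B, n); a (B,) slope
    vector is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not through_origin:
        x = x - x.mean(axis=-1, keepdims=True)
        y = y - y.mean(axis=-1, keepdims=True)
    sxx = np.sum(x * x, axis=-1)
    syy = np.sum(y * y, axis=-1)
    sxy = np.sum(x * y, axis=-1)
    if np.any(sxx == 0):
        raise ValueError("zero variance in x: slope undefined")
    # major-axis eigenvector of [[sxx, sxy], [sxy, syy]]
    disc = np.sqrt((syy - sxx) ** 2 + 4.0 * sxy ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxy != 0.0, (syy - sxx + disc) / (2.0 * sxy),
                         np.where(syy > sxx, np.inf, 0.0))
    return slope if slope.ndim else float(slope)


def orthogonal_regression(points, through_origin: bool = True) -> RegressionResult:
    """Fit the coupling line and summarise it.

    ``r_squared`` is the squared Pearson correlation of x and y (a
    goodness-of-association convention, independent of the fitted line);
    ``r_squared_origin`` is 1 - SSR/sum(y^2) of the through-origin fit.
    """
    x, y = _as_xy(points)
    n = len(x)
    if n < 3:
        raise ValueError("orthogonal regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    slope = tls_slope(x, y, through_origin)
    intercept = 0.0 if through_origin else float(y.mean() - slope * x.mean())
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2) if np.ptp(y) > 0 else 1.0
    res0 = y - tls_slope(x, y, through_origin=True) * x
    r2_origin = float(1.0 - np.sum(res0 ** 2) / np.sum(y ** 2)) if np.any(y) else 1.0
    se = jackknife_slope_se(points, through_origin) if n >= 4 else 0.0
    return RegressionResult(slope=float(slope), intercept=intercept,
                            slope_se_jackknife=se, r_squared=min(r2, 1.0),
                            n=n, through_origin=through_origin,
                            r_squared_origin=r2_origin)


def jackknife_slope_se(points, through_origin: bool = True) -> float:
    """Leave-one-out standard error of the TLS slope."""
    x, y = _as_xy(points)
    n = len(x)
    if n < 4:
        raise ValueError("jackknife needs n >= 4")
    idx = np.arange(n)
    loo = np.stack([np.delete(idx, i) for i in range(n)])  # (n, n-1)
    theta = tls_slope(x[loo], y[loo], through_origin)
    if not np.all(np.isfinite(theta)):
        raise ValueError("a leave-one-out fit is degenerate")
    return float(np.sqrt((n - 1) / n * np.sum((theta - theta.mean()) ** 2)))


def bootstrap_slopes(points, n_boot: int, rng: np.random.Generator,
                     through_origin: bool = True) -> np.ndarray:
    """TLS slopes of ``n_boot`` session-level resamples (with replacement)."""
    x, y = _as_xy(points)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    slopes = tls_slope(x[idx], y[idx], through_origin)
    ok = np.isfinite(slopes)
    return slopes[ok]


def bootstrap_slope_compare(points_a, points_b, n_boot: int = 1000,
                            seed: int = 0, through_origin: bool = True):
    """Rank-sum comparison of bootstrap slope distributions of two groups.

    Sessions are resampled jointly (each draw keeps its (x, y) pair), the
    TLS slope is refit per resample, and the two B-length slope
    distributions are compared with a two-sided Wilcoxon rank-sum test.
    Returns ``(p_value, slopes_a, slopes_b)``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    sa = bootstrap_slopes(points_a, n_boot, rng, through_origin)
    sb = bootstrap_slopes(points_b, n_boot, rng, through_origin)
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError("all bootstrap fits degenerate in one group")
    p = float(stats.ranksums(sa, sb).pvalue)
    return p, sa, sb


def binned_group_compare(group_a, group_b, bin_width: float,
                         alpha: float = 0.05, min_per_group: int = 2):
    """Per-bin rank-sum tests of y between two groups of (x, y) points.

    Bins tile the x axis from 0 in steps of ``bin_width`` over the pooled
    observed range.  Bins with fewer than ``min_per_group`` points in either
    group are reported as not testable (``p_value`` None).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    xa, ya = _as_xy(group_a)
    xb, yb = _as_xy(group_b)
    lo = min(0.0, xa.min(), xb.min())
    hi = max(xa.max(), xb.max())
    start = np.floor(lo / bin_width) * bin_width
    edges = np.arange(start, hi + bin_width, bin_width)
    out = []
    for left in edges:
        right = left + bin_width
        in_a = ya[(xa >= left) & (xa < right)]
        in_b = yb[(xb >= left) & (xb < right)]
        if len(in_a) == 0 and len(in_b) == 0:
            continue
        row = {"bin": (float(left), float(right)),
               "n_a": len(in_a), "n_b": len(in_b),
               "median_a": float(np.median(in_a)) if len(in_a) else None,
               "median_b": float(np.median(in_b)) if len(in_b) else None,
               "p_value": None, "significant": False}
        if len(in_a) >= min_per_group and len(in_b) >= min_per_group:
            p = float(stats.ranksums(in_a, in_b).pvalue)
            row["p_value"] = p
            row["significant"] = p < alpha
        out.append(row)
    return out


def session_points(sessions: Sequence, metric: str = "latency") -> np.ndarray:
    """(x, y) pairs for the coupling regression from session summaries."""
    if metric == "latency":
        xs = [s.latency_asym_ms for s in sessions]
    elif metric == "velocity":
        xs = [s.velocity_asym_degps for s in sessions]
        if any(v is None for v in xs):
            raise ValueError("velocity asymmetry missing for some sessions")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ys = [s.delta_det_asym_pct for s in sessions]
    return np.column_stack([xs, ys])
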