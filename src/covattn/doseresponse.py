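"""Probability of an attention deficit as a function of the saccade deficit.

Each session's attention outcome is first classified as significant or not:
the four hit rates (in/out x before/during) are bootstrap-resampled
(parametric binomial at the observed rate, B = 100), the change in
detection-rate asymmetry is recomputed per resample, and the session is
called a deficit when the observed change sits further from zero than
Phi^{-1}(1 - alpha/2) resampling standard deviations (alpha = 0.001, which
absorbs the multiple sessions tested).  Basing the decision on the spread
of the resampled distribution keeps the false-positive rate at the nominal
level; a bare sign test on the resampled values would reduce to
|z| > 0.43 and flag most null sessions (see docs/methods.md).
The binary outcomes are then regressed on the
saccade asymmetry with a Bayesian logistic model

    p(y = 1 | x, W) = sigm(w0 + w1 * x)

under independent zero-mean Gaussian priors (SD 10 on the standardized
scale).  The posterior is approximated by a Laplace Gaussian at the MAP
(inverse Hessian covariance) and the posterior predictive curve and its
95 % band by Monte-Carlo sampling of W.  The midpoint — the saccade
asymmetry at which a detection deficit becomes more likely than not — is
the x where the median predictive curve crosses 0.5.
"""
from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .datatypes import LogisticPosterior
from .regression import bootstrap_slopes


def classify_session_significance(counts, n_boot: int = 100,
                                  alpha: float = 0.001, seed: int = 0):
    """Classify one session's attention outcome as deficit (1) or not (0).

    ``counts`` maps the four cells ``("in"|"out", "before"|"during")`` to
    ``(hits, change_trials)``.  Returns ``(y, p_value, resampled_deltas)``.
    """
    cells = [("in", "before"), ("out", "before"), ("in", "during"), ("out", "during")]
    rates, ns = {}, {}
    for cell in cells:
        if cell not in counts:
            raise ValueError(f"missing cell {cell}")
        hits, n = counts[cell]
        if n <= 0:
            raise ValueError(f"cell {cell} has no change trials")
        if not 0 <= hits <= n:
            raise ValueError(f"cell {cell}: hits outside [0, n]")
        rates[cell], ns[cell] = hits / n, n
    rng = np.random.default_rng(seed)
    resampled = {cell: rng.binomial(ns[cell], rates[cell], n_boot) / ns[cell]
                 for cell in cells}
    deltas = 100.0 * ((resampled[("out", "during")] - resampled[("in", "during")])
                      - (resampled[("out", "before")] - resampled[("in", "before")]))
    observed = 100.0 * ((rates[("out", "during")] - rates[("in", "during")])
                        - (rates[("out", "before")] - rates[("in", "before")]))
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:  # cells at rate exactly 0 or 1: degenerate but defined
        p = 1.0 if observed == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(observed) / sd))
    return int(p < alpha), p, deltas


def _map_and_hessian(x_std, y, prior_sd, w0):
    """Newton iterations for the MAP of the standardized-scale weights."""
    X = np.column_stack([np.ones_like(x_std), x_std])
    prior_prec = np.eye(2) / prior_sd ** 2
    w = np.asarray(w0, dtype=float)
    for _ in range(100):
        eta = X @ w
        p = expit(eta)
        grad = X.T @ (y - p) - prior_prec @ w
        H = X.T @ (X * (p * (1 - p))[:, None]) + prior_prec
        step = np.linalg.solve(H, grad)
        w = w + step
        if np.linalg.norm(grad) < 1e-8:
            return w, H
    raise RuntimeError(
        f"logistic MAP did not converge in 100 Newton iterations "
        f"(final gradient norm {np.linalg.norm(grad):.3g})")


def fit_bayesian_logistic(x: Sequence[float], y: Sequence[int],
                          prior_sd: float = 10.0) -> LogisticPosterior:
    """MAP + Laplace posterior of the logistic dose-response.

    The predictor is centered and scaled by its SD for the fit (the prior is
    placed on that scale); the returned weights and covariance are
    transformed back to raw predictor units.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need n >= 5 paired observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary")
    mean, scale = float(x.mean()), float(x.std())
    if scale == 0:
        raise ValueError("x has zero variance")
    x_std = (x - mean) / scale
    w_std, H = _map_and_hessian(x_std, y, prior_sd, np.zeros(2))
    cov_std = np.linalg.inv(H)
    # raw = A @ std with A = [[1, -mean/scale], [0, 1/scale]]
    A = np.array([[1.0, -mean / scale], [0.0, 1.0 / scale]])
    w_raw = A @ w_std
    cov_raw = A @ cov_std @ A.T
    cov_raw = 0.5 * (cov_raw + cov_raw.T)
    return LogisticPosterior(w_map=w_raw, laplace_cov=cov_raw,
                             prior_sd=prior_sd, n=len(x),
                             x_mean=mean, x_scale=scale)


def posterior_predictive(post: LogisticPosterior, xgrid: Sequence[float],
                         n_samples: int = 10_000, seed: int = 0) -> np.ndarray:
    """Median and 95 % band of p(y=1 | x) over ``xgrid``.

    Returns an array of rows ``(x, median, lo95, hi95)``.
    """
    xgrid = np.asarray(xgrid, dtype=float)
    eigvals = np.linalg.eigvalsh(post.laplace_cov)
    if np.any(eigvals < -1e-10):
        raise ValueError("posterior covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    if np.allclose(post.laplace_cov, 0.0):
        W = np.tile(post.w_map, (n_samples, 1))
    else:
        W = rng.multivariate_normal(post.w_map, post.laplace_cov, size=n_samples,
                                    method="eigh")
    eta = W[:, 0][:, None] + np.outer(W[:, 1], xgrid)
    P = expit(eta)
    med = np.median(P, axis=0)
    lo = np.percentile(P, 2.5, axis=0)
    hi = np.percentile(P, 97.5, axis=0)
    return np.column_stack([xgrid, med, lo, hi])


def predictive_midpoint(post: LogisticPosterior, xgrid: Sequence[float] | None = None,
                        n_samples: int = 10_000, seed: int = 0) -> float:
    """x at which the posterior-median predictive probability equals 0.5.

    For a point-mass posterior this reduces to ``-w0 / w1``.
    """
    if xgrid is None:
        half = 4.0 * abs(post.x_scale) + abs(post.x_mean)
        xgrid = np.linspace(post.x_mean - half, post.x_mean + half, 201)
    grid = posterior_predictive(post, xgrid, n_samples, seed)
    med = grid[:, 1] - 0.5
    sign_change = np.flatnonzero(np.diff(np.signbit(med)))
    if len(sign_change) == 0:
        raise ValueError("median predictive curve does not cross 0.5 on the grid")
    i = int(sign_change[0])

    def f(xv):
        return posterior_predictive(post, [xv], n_samples, seed)[0, 1] - 0.5

    return float(optimize.brentq(f, grid[i, 0], grid[i + 1, 0], xtol=1e-3))


def subsample_control(sc_points, fef_points, n_iter: int = 1000,
                      n_sub: int = 23, n_boot: int = 1000, seed: int = 0,
                      alpha: float = 0.05, through_origin: bool = True):
    """Sample-size-matched control for the slope comparison.

    Each iteration draws ``n_sub`` of the SC sessions without replacement,
    bootstrap-resamples TLS slopes for the subsample and for the full FEF
    group (B = ``n_boot`` each), and counts the iteration as significant
    when the two-sided rank-sum p < alpha with the SC median slope larger.
    Returns a dict with the significant count and the slope-ratio
    distribution (median SC slope / median FEF slope per iteration).
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    sc = np.asarray(sc_points, dtype=float)
    fef = np.asarray(fef_points, dtype=float)
    if n_sub > len(sc):
        raise ValueError("n_sub exceeds the number of SC sessions")
    rng = np.random.default_rng(seed)
    n_sig = 0
    ratios = np.empty(n_iter)
    for it in range(n_iter):
        take = rng.choice(len(sc), size=n_sub, replace=False)
        s_sc = bootstrap_slopes(sc[take], n_boot, rng, through_origin)
        s_fef = bootstrap_slopes(fef, n_boot, rng, through_origin)
        p = stats.ranksums(s_sc, s_fef).pvalue
        med_sc, med_fef = np.median(s_sc), np.median(s_fef)
        if p < alpha and med_sc > med_fef:
            n_sig += 1
        ratios[it] = med_sc / med_fef if med_fef != 0 else np.nan
    return {"n_iter": n_iter, "n_sub": n_sub,
            "n_significant_sc_greater": n_sig,
            "slope_ratio_mean": float(np.nanmean(ratios)),
            "slope_ratio_sd": float(np.nanstd(ratios))}
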