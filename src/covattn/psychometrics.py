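"""Four-parameter cumulative-Gaussian psychometric fitting.

The hit probability for a motion-direction change of magnitude ``x`` is

    p(hit | x) = guess + (1 - guess - lapse) * Phi((x - mu) / sigma)

where ``guess`` is the lower asymptote (response bias / false-alarm floor)
and ``lapse`` the complement of the upper asymptote.  The detection
threshold is defined at 75 % of the signal-driven range — the Gaussian part
with bias and lapses stripped — i.e. ``mu + sigma * Phi^{-1}(0.75)``, so a
change in threshold reflects a change in sensitivity, not in bias.

Parameters are maximum-likelihood estimates under a Bernoulli likelihood,
found by bounded L-BFGS-B from five deterministic multi-starts (mu seeded
at data quantiles); the best log-likelihood wins, ties broken toward the
smallest sigma.  Confidence intervals come from a stratified nonparametric
bootstrap (resampling trials within each stimulus level).
"""
from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .datatypes import PsychometricFit

#: Phi^{-1}(0.75): the 75 %-of-range point sits this many sigmas above mu.
Z75 = float(stats.norm.ppf(0.75))

_EPS = 1e-9


class FitError(RuntimeError):
    """The psychometric likelihood cannot be maximised on these data."""


def _unpack(trials) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(trials, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("trials must be (magnitude_deg, responded) pairs")
    return a[:, 0], a[:, 1].astype(bool)


def hit_probability(x, mu: float, sigma: float, guess: float, lapse: float):
    return guess + (1.0 - guess - lapse) * stats.norm.cdf((np.asarray(x, float) - mu) / sigma)


def _neg_loglik(params, x, r):
    mu, sigma, guess, lapse = params
    p = np.clip(hit_probability(x, mu, sigma, guess, lapse), _EPS, 1 - _EPS)
    return -(np.sum(np.log(p[r])) + np.sum(np.log1p(-p[~r])))


def fit_psychometric(trials, max_asymptote: float = 0.5) -> PsychometricFit:
    """Maximum-likelihood 4-parameter fit of (magnitude, responded) pairs."""
    x, r = _unpack(trials)
    levels = np.unique(x[x > 0])
    if len(levels) < 2:
        raise FitError("need >= 2 distinct nonzero stimulus levels")
    if r.all() or (~r).all():
        raise FitError("degenerate data: all trials hit (or all missed); "
                       "the psychometric location is unidentified")

    span = float(levels.max() - levels.min()) or 1.0
    lo = np.array([levels.min() - span, 1e-3, 0.0, 0.0])
    hi = np.array([levels.max() + span, 10.0 * span, max_asymptote, max_asymptote])
    bounds = list(zip(lo, hi))

    best = None
    for q in (0.1, 0.3, 0.5, 0.7, 0.9):
        start = np.array([float(np.quantile(levels, q)), span / 2.0, 0.05, 0.02])
        res = optimize.minimize(_neg_loglik, start, args=(x, r),
                                method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        if (best is None or res.fun < best.fun - 1e-9
                or (abs(res.fun - best.fun) <= 1e-9 and res.x[1] < best.x[1])):
            best = res
    if best is None:
        raise FitError("optimizer failed from every start")

    mu, sigma, guess, lapse = best.x
    if guess + lapse >= 1.0:  # numerically possible only at the joint bound
        raise FitError("asymptotes collapsed: guess + lapse >= 1")
    on_bound = bool(np.any(np.isclose(best.x, lo, atol=1e-6)
                           | np.isclose(best.x, hi, atol=1e-6)))
    return PsychometricFit(mu_deg=float(mu), sigma_deg=float(sigma),
                           guess=float(guess), lapse=float(lapse),
                           threshold_deg=float(mu + sigma * Z75),
                           n_trials=len(x), loglik=float(-best.fun),
                           boundary_constrained=on_bound)


def threshold(fit: PsychometricFit) -> float:
    """Change magnitude at 75 % of the signal-driven range (deg)."""
    return fit.mu_deg + fit.sigma_deg * Z75


def bootstrap_thresholds(trials, n_boot: int = 1000, seed: int = 0):
    """Stratified bootstrap distribution of the threshold, with a 95 % CI.

    Trials are resampled with replacement within each stimulus level
    (method-of-constant-stimuli design: per-level n is fixed).  Returns
    ``(thresholds, (lo, hi), n_failed)``; resamples whose refit fails are
    dropped and counted, with a warning recorded when more than 20 % fail.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    x, r = _unpack(trials)
    fit_psychometric(trials)  # must succeed on the full data
    rng = np.random.default_rng(seed)
    level_idx = [np.flatnonzero(x == lv) for lv in np.unique(x)]
    out, failed = [], 0
    for _ in range(n_boot):
        take = np.concatenate([idx[rng.integers(0, len(idx), len(idx))]
                               for idx in level_idx])
        try:
            out.append(fit_psychometric(np.column_stack([x[take], r[take]])).threshold_deg)
        except FitError:
            failed += 1
    if not out:
        raise FitError("every bootstrap refit failed")
    thresholds = np.asarray(out)
    ci = (float(np.percentile(thresholds, 2.5)),
          float(np.percentile(thresholds, 97.5)))
    if failed > 0.2 * n_boot:
        import warnings
        warnings.warn(f"{failed}/{n_boot} bootstrap refits failed",
                      RuntimeWarning, stacklevel=2)
    return thresholds, ci, failed


def compare_threshold_distributions(dist_a: Sequence[float],
                                    dist_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two bootstrap
    threshold distributions (midrank convention for ties).

    Note this inherits the anti-conservative character of rank tests on
    resampled distributions: the effective sample size is the bootstrap
    count, not the trial count.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty threshold distribution")
    return float(stats.ranksums(a, b).pvalue)
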