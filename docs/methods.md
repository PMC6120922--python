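# Methods notes

## Session statistics

A session contributes one point to every population analysis:

* **Saccade latency asymmetry** (ms): mean injection-epoch latency of
  visually guided saccades whose *target* falls inside the affected motion
  patch, minus the mean for the mirror-symmetric unaffected patch. Only
  the two patch discs count; the rest of the mapping grid is used for the
  scotoma, not for this statistic. Peak-velocity asymmetry is the same
  construction with the sign flipped (out − in), so positive always means
  impairment.
* **Δ detection-rate asymmetry** (percentage points):
  `100·[(out_during − in_during) − (out_before − in_before)]` over the four
  hit rates of the change-detection task. Hit = change-present trial with
  a joystick release inside the 300–800 ms validity window. The statistic
  is antisymmetric under in/out relabelling and invariant to adding a
  common constant to all four rates; both are property-tested.

## Scotoma mapping

A mapping-grid target belongs to the scotoma when its injection-epoch
latencies stochastically exceed its pre-injection latencies (one-sided
Wilcoxon rank-sum, default α = 0.05, exposed as a parameter; the baseline
is the same target before injection, not the opposite hemifield). The
region is the raw union of significant grid tiles — deliberately not
fitted or smoothed, so area is tile count × grid-cell area and can only
take discrete values. The centroid is the unweighted mean of the
during-epoch saccade endpoints at significant targets. Overlap with the
affected patch is a seeded Monte-Carlo estimate (default 100 000 points,
accurate to ~±0.2 percentage points); exact circle–polygon intersection
was rejected as needless complexity for a union of axis-aligned tiles.

## Coupling regression

Both session statistics are noisy estimates, so the coupling line is fit
by total least squares (perpendicular distances, raw units: percentage
points on y, ms or deg/s on x), i.e. the major-axis eigenvector of the
second-moment matrix. Two conventions exist:

* **through the origin** (default): uncentered second moments. The
  scientific argument: a session with no saccade deficit has, in
  expectation, no attention deficit — sham sessions cluster at (0, 0) —
  so the line is anchored there and the slope is a pure coupling gain.
* **centered** (free intercept): covariance matrix, `through_origin=False`.

The distinction matters on the bundled tables: the through-origin fit
gives 0.323 (SC) and 0.083 (FEF) — reproducing the published estimates
0.31 ± 0.03 and 0.08 ± 0.03 — whereas the centered fit gives 0.26 and
0.22. Indeed no centered errors-in-variables fit can reach 0.08 on the FEF
table: for any error-variance ratio the slope is pinned between the two
ordinary regressions, [0.21, 0.53]. The published slopes are therefore
only consistent with the through-origin reading, which this package adopts
as its default convention.

Slope uncertainty is the leave-one-out jackknife,
`SE² = (n−1)/n · Σ(θ₋ᵢ − θ̄)²`, and `dof = n − 1`. Slopes between
structures are compared by resampling sessions with replacement within
each group (jointly in x and y — the only statistically defensible
reading), refitting B = 1000 slopes per group, and applying a two-sided
Wilcoxon rank-sum test to the two slope distributions. This test inherits
the anti-conservative character of rank tests on bootstrap distributions
(its effective n is B); on the bundled tables the separation is so large
that the verdict is unambiguous, and the sample-size-matched subsampling
control (draw 23 of the 46 SC sessions without replacement, 1000 times)
flags SC > FEF in essentially every iteration.

Two r² conventions are reported side by side, because neither published
value is recoverable from the published per-session tables: `r_squared`
is the squared Pearson correlation (0.39 SC, 0.40 FEF on the tables) and
`r_squared_origin` is 1 − SSR/Σy² of the through-origin fit (0.80 SC,
0.39 FEF). The tables support a strong, roughly proportional coupling but
not the printed R² of 0.83/0.70; users comparing against the published
figures should rely on the slopes and their SEs, which do reproduce.

### Degenerate inputs and tie-breaks

Zero x-variance or n < 3 is an error; collinear data give jackknife SE 0.
When the cross-moment is exactly zero the slope is 0 if x carries more
variance and ±∞ (reported as a degenerate resample and dropped from
bootstrap distributions) otherwise. On a sham-like cloud centred at the
origin with more y- than x-variance, the through-origin TLS major axis is
close to vertical and its jackknife SE is comparably enormous — the
correct reading is "slope unconstrained", and the tests assert exactly
the 0-in-±2SE property rather than a point value.

## Psychometric model

Hit probability for a change of magnitude x (deg of motion direction):

    p(x) = guess + (1 − guess − lapse) · Φ((x − μ)/σ)

with guess and lapse bounded in [0, 0.5] (standard identifiability
choice). The threshold is defined at 75 % of the signal-driven range,
`μ + σ·Φ⁻¹(0.75) = μ + 0.6745σ`, which strips response bias and lapses
from threshold comparisons by construction. Fitting is maximum likelihood
(Bernoulli) by bounded L-BFGS-B from five deterministic starts with μ
seeded at the 10/30/50/70/90 % quantiles of the stimulus levels — the
4-parameter likelihood is multimodal — keeping the best log-likelihood and
breaking ties toward the smaller σ. Data with all hits or all misses are
rejected as unidentifiable. Threshold CIs use a stratified nonparametric
bootstrap (resampling within stimulus level, mirroring the
method-of-constant-stimuli design; default B = 1000), and before/during
threshold distributions are compared by a two-sided rank-sum test — again
knowingly anti-conservative, matching the procedure being modelled.

## Deficit classification and dose–response

Each session's four hit rates are resampled parametrically (binomial at
the observed rate, B = 100 — rates and counts are all a summary table
offers), and the asymmetry change is recomputed per resample. The session
is classified a deficit when the observed change lies further than
Φ⁻¹(1 − α/2) resampling SDs from zero (α = 0.001, absorbing the number of
sessions tested). A bare sign test on the resampled values was considered
and rejected: counting resample signs reduces to |z| > 0.43 at this α and
would flag roughly two-thirds of null sessions, while the bootstrap-SE
rule holds the false-positive rate at the nominal ~0.1 % (verified on 500
simulated sham sessions). The strictness has a visible consequence: weak
couplings (FEF-like, ~0.08) at realistic trial counts rarely produce
classifiable deficits, so their dose–response is weakly constrained.

The binary outcomes feed a logistic regression
`p(y=1|x) = sigm(w₀ + w₁x)` with independent zero-mean Gaussian priors
(SD 10 on the centered/SD-scaled predictor — required for separable data;
coefficients are reported back in raw units). The MAP is found by Newton
iterations to gradient norm < 1e-8; the Laplace covariance is the inverse
Hessian at the MAP; the posterior predictive median and 95 % band come
from 10 000 Gaussian weight draws; and the midpoint (x at median p = 0.5)
is root-found to 1e-3. The logistic link is used throughout; a probit
alternative was deliberately left out of scope.

## Synthetic-data generator

The generator emulates the study's two tasks with known ground truth:

* **Saccade task**: an 8×6 target grid spanning ±20° × ±12°, 8 saccades
  per target per epoch; latencies N(175, 15²) ms, peak velocities
  N(550, 40²) °/s, endpoints = target + isotropic 0.5° noise. The scotoma
  is a hard disc (default radius 4° centred on the affected patch);
  injection-epoch saccades into it gain `latency_penalty_ms` and lose
  `5 °/s` of peak velocity per ms of penalty. A graded spatial profile is
  deliberately out of scope.
* **Attention task**: change present on 66 % of trials, side uniform,
  1–3 s delay, 160 change trials per side per epoch, single near-threshold
  change magnitude (μ + 0.6745σ of the generating psychometric function,
  defaults μ = 14°, σ = 6°, guess = 0.08, lapse = 0.03, chosen to put the
  printed 15–22° threshold range and ~75 % operating point in a realistic
  regime); catch trials respond at the guess rate. The during-epoch
  in-side μ is shifted so that the *expected* asymmetry change equals
  `coupling_slope × latency_penalty` (defaults 0.31 SC-like, 0.08
  FEF-like) — the linkage is deterministic so recovery tests are sharp,
  with noise entering only through finite trials.
* **Cohorts**: per-session penalties uniform on (0, 130) ms, matching the
  observed latency-asymmetry range; summaries are *measured* from the
  generated trials by the analysis modules, never copied from the
  generator. One root seed; per-session streams split via SeedSequence.

What the generator does not emulate — and hence what passing recovery
tests do not establish about real data: motion-energy stimulus dynamics,
reaction-time distributions beyond the validity window, drift in
behavioural state across a session, spatially graded muscimol spread, or
between-subject differences. Recovery results certify the estimators, not
the biology.

## Problem sizes in the test suite

The suite calibrates stochastic properties at sizes chosen to keep the
whole run in a few minutes while leaving comfortable statistical margins:
100 generate-and-refit psychometric replicates (200 trials/level), 15
simulated cohorts of 46 sessions for coupling recovery, 500 sham sessions
for classifier calibration, 50 random instances against the brute-force
perpendicular-distance oracle, 100 synthetic cohorts (n = 69) for
predictive-band coverage, and the full 3-seed × 1000-iteration subsampling
control on the bundled tables.

## Known limitations

* The bundled tables carry the printed scotoma areas unchanged, including
  cases where the display edge may have truncated them.
* Pearson r² of the bundled analysis columns (~0.39) does not match the
  published 0.83/0.70 under any convention tried; see the regression notes.
* The classifier is stricter than the resampling rule described in the
  source study; sessions with modest deficits that the study counted as
  significant may be classified 0 here.
* Velocity-based analyses run only on data that carry peak velocities
  (synthetic cohorts); the bundled tables tabulate latency asymmetries
  only.
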