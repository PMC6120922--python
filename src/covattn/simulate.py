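"""Synthetic session generator with known ground truth.

The generator emulates the two behavioural tasks of a reversible-
inactivation experiment:

* a delayed visually guided saccade task probing a grid of targets, where
  the injection epoch adds a latency penalty (and a proportional peak-
  velocity loss) to saccades aimed inside a hard-disc scotoma; and
* a two-patch motion-change detection task, where the injection epoch
  degrades sensitivity for changes in the affected ("in") patch.

The attention deficit is tied to the saccade deficit deterministically:
the during-epoch "in"-side psychometric mean is shifted so that the
*expected* change in detection-rate asymmetry equals
``coupling_slope * latency_penalty_ms``.  Noise enters only through the
finite number of trials, which keeps parameter-recovery experiments sharp.

Defaults mirror the task statistics of the study being modelled: changes on
66 % of trials after a 1-3 s delay, responses valid in a 300-800 ms window,
16 deg motion-direction SD, 3-deg-radius patches at 9 deg eccentricity,
~175 ms baseline latencies, and per-session latency penalties spanning
0-130 ms (the observed latency-asymmetry range).  Coupling defaults are
0.31 pct-points/ms for SC-like and 0.08 for FEF-like inactivations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .asymmetry import (saccade_asymmetry, session_delta_asymmetry,
                        session_hit_rates, map_scotoma)
from .datatypes import (AttentionTrial, ChangeSide, Epoch, PatchGeometry,
                        SaccadeRecord, SessionSummary, Structure, patch_pair)

_COUPLING_DEFAULTS = {Structure.SC: 0.31, Structure.FEF: 0.08,
                      Structure.SHAM: 0.0}


@dataclass
class PsychParams:
    """Generating psychometric parameters for one side."""
    mu_deg: float = 14.0
    sigma_deg: float = 6.0
    guess: float = 0.08
    lapse: float = 0.03

    def __post_init__(self):
        if not (0 <= self.guess <= 1 and 0 <= self.lapse <= 1
                and self.guess + self.lapse < 1):
            raise ValueError("need guess, lapse in [0, 1] with guess + lapse < 1")

    def hit_rate(self, x: float) -> float:
        return self.guess + (1 - self.guess - self.lapse) * stats.norm.cdf(
            (x - self.mu_deg) / self.sigma_deg)


def _default_grid() -> List[Tuple[float, float]]:
    xs = np.linspace(-20.0, 20.0, 8)
    ys = np.linspace(-12.0, 12.0, 6)
    return [(float(x), float(y)) for x in xs for y in ys]


@dataclass
class SimConfig:
    structure: Structure = Structure.SC
    n_sessions: int = 46
    trials_per_epoch_per_side: int = 160
    saccade_targets: Sequence[Tuple[float, float]] = field(default_factory=_default_grid)
    saccades_per_target_per_epoch: int = 8
    patch_eccentricity_deg: float = 9.0
    patch_radius_deg: float = 3.0
    p_change: float = 0.66
    direction_sd_deg: float = 16.0
    baseline_latency_ms: float = 175.0
    latency_noise_sd_ms: float = 15.0
    baseline_velocity_degps: float = 550.0
    velocity_noise_sd_degps: float = 40.0
    scotoma_center: Optional[Tuple[float, float]] = None  # default: in-patch center
    scotoma_radius_deg: float = 4.0
    latency_penalty_ms: float = 60.0
    max_penalty_ms: float = 130.0        # cohort penalties drawn U(0, max)
    coupling_slope: Optional[float] = None  # default by structure
    velocity_penalty_per_ms: float = 5.0
    psychometric: Dict[str, PsychParams] = field(
        default_factory=lambda: {"in": PsychParams(), "out": PsychParams()})
    endpoint_noise_sd_deg: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.structure = Structure(self.structure)
        if self.n_sessions <= 0:
            raise ValueError("n_sessions must be positive")
        if not 0.0 <= self.p_change <= 1.0:
            raise ValueError("p_change must be a probability")
        if self.latency_penalty_ms < 0 or self.velocity_penalty_per_ms < 0:
            raise ValueError("penalties must be non-negative")
        if len(self.saccade_targets) == 0:
            raise ValueError("saccade target grid is empty")
        if self.coupling_slope is None:
            self.coupling_slope = _COUPLING_DEFAULTS[self.structure]
        if self.scotoma_center is None:
            self.scotoma_center = (self.patch_eccentricity_deg, 0.0)
        if self.structure is Structure.SHAM:
            self.latency_penalty_ms = 0.0
            self.coupling_slope = 0.0

    @property
    def patches(self) -> Tuple[PatchGeometry, PatchGeometry]:
        return patch_pair(self.patch_eccentricity_deg, self.patch_radius_deg)


def session_seeds(config: SimConfig) -> np.ndarray:
    """Per-session seeds split deterministically from the root seed."""
    return np.random.SeedSequence(config.seed).generate_state(config.n_sessions)


def simulate_saccade_session(config: SimConfig, session_seed: int,
                             session_id: str = "sim") -> List[SaccadeRecord]:
    """Saccade-mapping records for one session (both epochs)."""
    rng = np.random.default_rng(session_seed)
    cx, cy = config.scotoma_center
    records: List[SaccadeRecord] = []
    for target in config.saccade_targets:
        in_scotoma = (np.hypot(target[0] - cx, target[1] - cy)
                      <= config.scotoma_radius_deg)
        for epoch in (Epoch.BEFORE, Epoch.DURING):
            affected = in_scotoma and epoch is Epoch.DURING
            lat_mu = config.baseline_latency_ms + (
                config.latency_penalty_ms if affected else 0.0)
            vel_mu = config.baseline_velocity_degps - (
                config.velocity_penalty_per_ms * config.latency_penalty_ms
                if affected else 0.0)
            n = config.saccades_per_target_per_epoch
            lat = np.maximum(rng.normal(lat_mu, config.latency_noise_sd_ms, n), 50.0)
            vel = np.maximum(rng.normal(vel_mu, config.velocity_noise_sd_degps, n), 50.0)
            end = np.asarray(target) + rng.normal(0.0, config.endpoint_noise_sd_deg,
                                                  (n, 2))
            records.extend(
                SaccadeRecord(session_id=session_id, epoch=epoch,
                              target=target,
                              endpoint=(float(end[k, 0]), float(end[k, 1])),
                              latency_ms=float(lat[k]),
                              peak_velocity_degps=float(vel[k]))
                for k in range(n))
    return records


def _during_in_params(config: SimConfig, x0: float) -> PsychParams:
    """Shift the in-side psychometric mean so that the expected change in
    detection-rate asymmetry equals coupling_slope * latency_penalty."""
    base = config.psychometric["in"]
    target_drop = config.coupling_slope * config.latency_penalty_ms / 100.0
    rate = base.hit_rate(x0) - target_drop
    lo = base.guess + 1e-4
    hi = 1.0 - base.lapse - 1e-4
    rate = float(np.clip(rate, lo, hi))
    z = stats.norm.ppf((rate - base.guess) / (1.0 - base.guess - base.lapse))
    return replace(base, mu_deg=x0 - z * base.sigma_deg)


def change_magnitude(config: SimConfig) -> float:
    """The single near-threshold change level used in cohort sessions."""
    p = config.psychometric["in"]
    return p.mu_deg + p.sigma_deg * float(stats.norm.ppf(0.75))


def simulate_attention_session(config: SimConfig, session_seed: int,
                               session_id: str = "sim",
                               magnitudes: Optional[Sequence[float]] = None,
                               ) -> List[AttentionTrial]:
    """Change-detection trials for one session (both epochs).

    By default every change trial uses the single near-threshold magnitude
    (the usual cohort design); pass ``magnitudes`` for a multi-level,
    psychometric-curve session.
    """
    for p in config.psychometric.values():
        if p.guess + p.lapse >= 1:
            raise ValueError("guess + lapse must be < 1")
    rng = np.random.default_rng(session_seed)
    x0 = change_magnitude(config)
    levels = list(magnitudes) if magnitudes is not None else [x0]
    params = {
        (ChangeSide.IN, Epoch.BEFORE): config.psychometric["in"],
        (ChangeSide.OUT, Epoch.BEFORE): config.psychometric["out"],
        (ChangeSide.IN, Epoch.DURING): _during_in_params(config, x0),
        (ChangeSide.OUT, Epoch.DURING): config.psychometric["out"],
    }
    n_change = config.trials_per_epoch_per_side
    trials: List[AttentionTrial] = []
    for epoch in (Epoch.BEFORE, Epoch.DURING):
        for side in (ChangeSide.IN, ChangeSide.OUT):
            pp = params[(side, epoch)]
            for k in range(n_change):
                x = levels[k % len(levels)]
                hit = rng.random() < pp.hit_rate(x)
                trials.append(AttentionTrial(
                    session_id=session_id, epoch=epoch, change_side=side,
                    change_magnitude_deg=float(x),
                    delay_s=float(rng.uniform(1.0, 3.0)),
                    responded=hit, valid=True,
                    reaction_time_s=float(rng.uniform(0.35, 0.75)) if hit else None))
        # catch trials keep the change-present fraction at p_change
        if config.p_change > 0:
            n_catch = int(round(2 * n_change * (1 - config.p_change)
                                / config.p_change))
        else:
            n_catch = 2 * n_change
        guess = config.psychometric["in"].guess
        for _ in range(n_catch):
            fa = rng.random() < guess
            trials.append(AttentionTrial(
                session_id=session_id, epoch=epoch, change_side=ChangeSide.NONE,
                change_magnitude_deg=0.0,
                delay_s=float(rng.uniform(1.0, 3.0)),
                responded=fa, valid=not fa, reaction_time_s=None))
    return trials


def simulate_cohort(config: SimConfig, include_scotoma: bool = True):
    """Simulate a cohort of sessions and summarise them.

    Per-session latency penalties are drawn uniformly on
    ``(0, max_penalty_ms)`` (all zero for SHAM).  Summary statistics are
    computed by the analysis modules from the generated trial-level data —
    they are measured, not copied from the generator.  Returns
    ``(summaries, attention_trials, saccade_records, truth)`` where
    ``truth`` holds each session's generating penalty.
    """
    seeds = session_seeds(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777]).generate_state(1)[0])
    prefix = config.structure.value
    summaries: List[SessionSummary] = []
    all_trials: List[AttentionTrial] = []
    all_saccades: List[SaccadeRecord] = []
    truth = []
    patches = config.patches
    for i in range(config.n_sessions):
        penalty = (0.0 if config.structure is Structure.SHAM
                   else float(rng.uniform(0.0, config.max_penalty_ms)))
        cfg_i = replace(config, latency_penalty_ms=penalty)
        sid = f"{prefix}-sim-{i + 1:03d}"
        sac = simulate_saccade_session(cfg_i, seeds[i], sid)
        att = simulate_attention_session(cfg_i, seeds[i] + 1, sid)
        lat_asym = saccade_asymmetry(sac, patches, "latency")
        vel_asym = saccade_asymmetry(sac, patches, "velocity")
        rates, _ = session_hit_rates(att)
        delta = session_delta_asymmetry(att)
        if include_scotoma:
            before = [r for r in sac if r.epoch is Epoch.BEFORE]
            during = [r for r in sac if r.epoch is Epoch.DURING]
            sco = map_scotoma(before, during, patches[0], n_mc=20_000,
                              mc_seed=int(seeds[i]))
            area, ov = sco.area_deg2, sco.overlap_pct
            dist = sco.center_dist_deg if sco.center_dist_deg is not None else 0.0
            center = sco.centroid if sco.centroid is not None else (0.0, 0.0)
        else:
            area, ov, dist, center = 0.0, 0.0, 0.0, (0.0, 0.0)
        summaries.append(SessionSummary(
            session_id=sid, structure=config.structure, subject="sim",
            hit_in_before=rates[(ChangeSide.IN, Epoch.BEFORE)],
            hit_out_before=rates[(ChangeSide.OUT, Epoch.BEFORE)],
            hit_in_during=rates[(ChangeSide.IN, Epoch.DURING)],
            hit_out_during=rates[(ChangeSide.OUT, Epoch.DURING)],
            latency_asym_ms=lat_asym, velocity_asym_degps=vel_asym,
            delta_det_asym_pct=delta, scotoma_area_deg2=area,
            overlap_pct=ov, center_dist_deg=dist,
            scotoma_center=(float(center[0]), float(center[1])),
            injection_ul=0.5 if config.structure is Structure.SC else 2.0))
        all_trials.extend(att)
        all_saccades.extend(sac)
        truth.append({"session_id": sid, "latency_penalty_ms": penalty,
                      "coupling_slope": config.coupling_slope})
    return summaries, all_trials, all_saccades, truth
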