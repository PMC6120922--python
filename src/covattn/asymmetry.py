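"""Session-level behavioural statistics and scotoma mapping.

Two headline statistics condense each experiment to one number per task:

* detection:  ``100 * [(out_during - in_during) - (out_before - in_before)]``
  — the change, from the pre-injection epoch to the injection epoch, in the
  out-minus-in hit-rate difference, in percentage points.  Positive values
  mean the asymmetry grew in favour of changes outside the affected region.
* saccades:  mean latency into the affected ("in") patch minus mean latency
  into the unaffected ("out") patch, in ms.  For peak velocity the sign is
  flipped (out minus in) so that positive always indicates impairment.

The scotoma is mapped target-by-target from the visually guided saccade
task: a target is part of the scotoma when its injection-epoch latencies
are significantly longer than its pre-injection latencies (one-sided
rank-sum).  The mapped region is the raw union of significant grid tiles —
not fitted or smoothed.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import (AttentionTrial, ChangeSide, Epoch, PatchGeometry,
                        SaccadeRecord, Scotoma)


def delta_detection_rate_asymmetry(in_before: float, out_before: float,
                                   in_during: float, out_during: float) -> float:
    """Change in detection-rate asymmetry, in percentage points."""
    for name, p in (("in_before", in_before), ("out_before", out_before),
                    ("in_during", in_during), ("out_during", out_during)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} is not a proportion in [0, 1]")
    return 100.0 * ((out_during - in_during) - (out_before - in_before))


def saccade_asymmetry(records: Sequence[SaccadeRecord],
                      patches: Tuple[PatchGeometry, PatchGeometry],
                      metric: str = "latency") -> float:
    """Lateralised saccade impairment from injection-epoch records.

    Only saccades whose *target* falls inside one of the two task patches
    are considered.  ``metric`` is ``"latency"`` (in minus out, ms) or
    ``"velocity"`` (out minus in, deg/s); both are signed so that positive
    values indicate impairment of the affected side.
    """
    if metric not in ("latency", "velocity"):
        raise ValueError(f"unknown metric {metric!r}")
    by_side: Dict[ChangeSide, List[float]] = {ChangeSide.IN: [], ChangeSide.OUT: []}
    patch_map = {p.side: p for p in patches}
    if set(patch_map) != {ChangeSide.IN, ChangeSide.OUT}:
        raise ValueError("need one 'in' patch and one 'out' patch")
    for rec in records:
        if rec.epoch is not Epoch.DURING:
            continue
        for side, patch in patch_map.items():
            if patch.contains(rec.target)[0]:
                by_side[side].append(rec.latency_ms if metric == "latency"
                                     else rec.peak_velocity_degps)
    for side in (ChangeSide.IN, ChangeSide.OUT):
        if not by_side[side]:
            raise ValueError(f"no injection-epoch saccades into the "
                             f"{side.value!r} patch")
    mean_in = float(np.mean(by_side[ChangeSide.IN]))
    mean_out = float(np.mean(by_side[ChangeSide.OUT]))
    return mean_in - mean_out if metric == "latency" else mean_out - mean_in


def _group_by_target(records: Iterable[SaccadeRecord]):
    grouped: Dict[Tuple[float, float], List[SaccadeRecord]] = defaultdict(list)
    for rec in records:
        grouped[rec.target].append(rec)
    return grouped


def map_scotoma(before: Sequence[SaccadeRecord],
                during: Sequence[SaccadeRecord],
                patch: PatchGeometry,
                alpha: float = 0.05,
                tile_area_deg2: float | None = None,
                n_mc: int = 100_000,
                mc_seed: int = 0) -> Scotoma:
    """Map the saccadic deficit region from before/during latency samples.

    A grid target is significant when its during-epoch latencies exceed the
    before-epoch latencies at that target (one-sided rank-sum, p < alpha).
    Area is significant-tile count times the grid-cell area; the centroid is
    the unweighted mean of the during-epoch endpoints of significant
    targets.  Overlap with the affected task patch is estimated by Monte
    Carlo sampling of the patch disc against the union of significant tiles.
    """
    g_before = _group_by_target(before)
    g_during = _group_by_target(during)
    if set(g_before) != set(g_during):
        raise ValueError("before and during epochs use different target grids")
    targets = sorted(g_before)
    if not targets:
        raise ValueError("no saccade records")

    xs = np.unique([t[0] for t in targets])
    ys = np.unique([t[1] for t in targets])
    if tile_area_deg2 is None:
        dx = float(np.min(np.diff(xs))) if len(xs) > 1 else 1.0
        dy = float(np.min(np.diff(ys))) if len(ys) > 1 else 1.0
        tile_area_deg2 = dx * dy
    else:
        dx = dy = float(np.sqrt(tile_area_deg2))

    pvals: Dict[Tuple[float, float], float] = {}
    significant: List[Tuple[float, float]] = []
    sig_endpoints: List[Tuple[float, float]] = []
    for t in targets:
        lat_b = [r.latency_ms for r in g_before[t]]
        lat_d = [r.latency_ms for r in g_during[t]]
        if len(lat_b) < 3 or len(lat_d) < 3:
            raise ValueError(f"target {t}: need >= 3 saccades per epoch")
        p = stats.mannwhitneyu(lat_d, lat_b, alternative="greater").pvalue
        pvals[t] = float(p)
        if p < alpha:
            significant.append(t)
            sig_endpoints.extend(r.endpoint for r in g_during[t])

    area = len(significant) * tile_area_deg2
    if significant:
        centroid = tuple(np.mean(np.asarray(sig_endpoints, dtype=float), axis=0))
        center_dist = float(np.hypot(centroid[0] - patch.center[0],
                                     centroid[1] - patch.center[1]))
        overlap = _mc_overlap_pct(significant, dx, dy, patch, n_mc, mc_seed)
    else:
        centroid, center_dist, overlap = None, None, 0.0
    return Scotoma(significant_targets=significant, area_deg2=area,
                   centroid=centroid, overlap_pct=overlap,
                   center_dist_deg=center_dist, alpha=alpha, p_values=pvals)


def _mc_overlap_pct(significant, dx, dy, patch, n_mc, seed) -> float:
    rng = np.random.default_rng(seed)
    r = patch.radius_deg * np.sqrt(rng.random(n_mc))
    th = rng.random(n_mc) * 2.0 * np.pi
    px = patch.center[0] + r * np.cos(th)
    py = patch.center[1] + r * np.sin(th)
    inside = np.zeros(n_mc, dtype=bool)
    for (tx, ty) in significant:
        inside |= (np.abs(px - tx) <= dx / 2.0) & (np.abs(py - ty) <= dy / 2.0)
    return 100.0 * float(np.mean(inside))


def session_hit_rates(trials: Sequence[AttentionTrial]):
    """Hit rate and change-trial count per (side, epoch) cell.

    Returns ``(rates, counts)`` where each is a dict keyed by
    ``(side, epoch)`` over in/out x before/during.  A hit is a change-present
    trial answered with a valid (in-window) joystick release.
    """
    hits: Dict[Tuple[ChangeSide, Epoch], int] = defaultdict(int)
    totals: Dict[Tuple[ChangeSide, Epoch], int] = defaultdict(int)
    for tr in trials:
        if tr.change_side is ChangeSide.NONE:
            continue
        key = (tr.change_side, tr.epoch)
        totals[key] += 1
        if tr.responded and tr.valid:
            hits[key] += 1
    rates, counts = {}, {}
    empty = []
    for side in (ChangeSide.IN, ChangeSide.OUT):
        for epoch in (Epoch.BEFORE, Epoch.DURING):
            key = (side, epoch)
            if totals[key] == 0:
                empty.append(f"{side.value}/{epoch.value}")
                continue
            rates[key] = hits[key] / totals[key]
            counts[key] = totals[key]
    if empty:
        raise ValueError("no change-present trials in cell(s): " + ", ".join(empty))
    return rates, counts


def session_delta_asymmetry(trials: Sequence[AttentionTrial]) -> float:
    """Detection-asymmetry statistic computed directly from trials (pct pts)."""
    rates, _ = session_hit_rates(trials)
    return delta_detection_rate_asymmetry(
        rates[(ChangeSide.IN, Epoch.BEFORE)],
        rates[(ChangeSide.OUT, Epoch.BEFORE)],
        rates[(ChangeSide.IN, Epoch.DURING)],
        rates[(ChangeSide.OUT, Epoch.DURING)])
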