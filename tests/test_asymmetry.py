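"""Detection/saccade asymmetry statistics and scotoma mapping."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covattn import (ChangeSide, Epoch, PatchGeometry, SaccadeRecord,
                     AttentionTrial, delta_detection_rate_asymmetry,
                     map_scotoma, saccade_asymmetry, session_hit_rates,
                     patch_pair)
from tests.conftest import make_saccade

rates = st.floats(0.0, 1.0)


class TestDeltaDetection:
    def test_hand_arithmetic(self):
        assert delta_detection_rate_asymmetry(0.7, 0.7, 0.4, 0.7) == pytest.approx(30.0)

    @given(p=rates)
    @settings(max_examples=30, deadline=None)
    def test_null_when_all_equal(self, p):
        assert delta_detection_rate_asymmetry(p, p, p, p) == pytest.approx(0.0)

    @given(a=rates, b=rates, c=rates, d=rates)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_under_label_swap(self, a, b, c, d):
        fwd = delta_detection_rate_asymmetry(a, b, c, d)
        rev = delta_detection_rate_asymmetry(b, a, d, c)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    @given(a=st.floats(0, 0.5), b=st.floats(0, 0.5), c=st.floats(0, 0.5),
           d=st.floats(0, 0.5), shift=st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_common_shift(self, a, b, c, d, shift):
        base = delta_detection_rate_asymmetry(a, b, c, d)
        shifted = delta_detection_rate_asymmetry(a + shift, b + shift,
                                                 c + shift, d + shift)
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_rejects_non_proportions(self):
        with pytest.raises(ValueError, match="in_during"):
            delta_detection_rate_asymmetry(0.5, 0.5, 1.7, 0.5)


class TestSaccadeAsymmetry:
    def test_example_session_latencies(self, patches):
        recs = [make_saccade(259.0, target=(9.0, 0.0)),
                make_saccade(175.0, target=(-9.0, 0.0))]
        assert saccade_asymmetry(recs, patches, "latency") == pytest.approx(84.0)

    def test_identical_samples_give_zero(self, patches):
        recs = [make_saccade(200.0, target=(9.0, 0.0)),
                make_saccade(200.0, target=(-9.0, 0.0))]
        assert saccade_asymmetry(recs, patches, "latency") == pytest.approx(0.0)

    def test_velocity_sign_convention(self, patches):
        recs = [make_saccade(200.0, velocity=400.0, target=(9.0, 0.0)),
                make_saccade(200.0, velocity=500.0, target=(-9.0, 0.0))]
        # slower saccades into the affected patch => positive impairment
        assert saccade_asymmetry(recs, patches, "velocity") == pytest.approx(100.0)

    def test_translation_invariance(self, patches, rng):
        base = [make_saccade(float(l), target=(9.0, 0.0))
                for l in rng.normal(250, 10, 20)]
        base += [make_saccade(float(l), target=(-9.0, 0.0))
                 for l in rng.normal(180, 10, 20)]
        a0 = saccade_asymmetry(base, patches, "latency")
        shifted = [make_saccade(r.latency_ms + 37.0, target=r.target)
                   for r in base]
        assert saccade_asymmetry(shifted, patches, "latency") == pytest.approx(a0)

    def test_empty_patch_named_in_error(self, patches):
        recs = [make_saccade(200.0, target=(9.0, 0.0))]
        with pytest.raises(ValueError, match="'out'"):
            saccade_asymmetry(recs, patches, "latency")

    def test_targets_outside_patches_ignored(self, patches):
        recs = [make_saccade(900.0, target=(0.0, 12.0)),
                make_saccade(259.0, target=(9.0, 0.0)),
                make_saccade(175.0, target=(-9.0, 0.0))]
        assert saccade_asymmetry(recs, patches, "latency") == pytest.approx(84.0)


def _grid_session(rng, targets, n=8, shift_at=None, shift_ms=0.0):
    before, during = [], []
    for t in targets:
        for epoch, bucket in ((Epoch.BEFORE, before), (Epoch.DURING, during)):
            extra = shift_ms if (epoch is Epoch.DURING and t == shift_at) else 0.0
            for _ in range(n):
                lat = float(rng.normal(175 + extra, 15))
                end = (t[0] + float(rng.normal(0, 0.3)),
                       t[1] + float(rng.normal(0, 0.3)))
                bucket.append(make_saccade(lat, target=t, epoch=epoch,
                                           endpoint=end))
    return before, during


class TestScotomaMapping:
    targets = [(x, y) for x in (4.0, 9.0, 14.0) for y in (-4.0, 0.0, 4.0)]

    def test_null_session_maps_empty(self, rng, patches):
        before, during = _grid_session(rng, self.targets)
        sco = map_scotoma(before, during, patches[0])
        # identical generating distributions: expect no (or chance-level) hits
        assert sco.area_deg2 <= 2 * 16.0  # at most one false-positive tile or so
        if not sco.significant_targets:
            assert sco.centroid is None and sco.overlap_pct == 0.0

    def test_injected_deficit_detected(self, patches):
        hits, false_pos = 0, 0
        n_runs = 60
        for k in range(n_runs):
            r = np.random.default_rng(1000 + k)
            before, during = _grid_session(r, self.targets,
                                           shift_at=(9.0, 0.0), shift_ms=80.0)
            sco = map_scotoma(before, during, patches[0])
            if (9.0, 0.0) in sco.significant_targets:
                hits += 1
            false_pos += len([t for t in sco.significant_targets
                              if t != (9.0, 0.0)])
        assert hits >= 0.9 * n_runs
        # 8 null targets per run at alpha=0.05
        assert false_pos <= 2 * 0.05 * 8 * n_runs

    def test_centroid_is_mean_of_significant_endpoints(self, patches):
        t = (9.0, 0.0)
        before = [make_saccade(175.0 + i, target=t, epoch=Epoch.BEFORE,
                               endpoint=t) for i in range(4)]
        during = [make_saccade(400.0 + i, target=t, epoch=Epoch.DURING,
                               endpoint=e)
                  for i, e in enumerate([(10, 0), (12, 2), (14, 1), (12, 1)])]
        sco = map_scotoma(before, during, patches[0], tile_area_deg2=16.0)
        assert sco.significant_targets == [t]
        assert sco.centroid == pytest.approx((12.0, 1.0))
        assert sco.area_deg2 == pytest.approx(16.0)
        assert sco.center_dist_deg == pytest.approx(np.hypot(12 - 9, 1 - 0))

    def test_area_nondecreasing_in_alpha(self, rng, patches):
        before, during = _grid_session(rng, self.targets,
                                       shift_at=(9.0, 0.0), shift_ms=40.0)
        areas = [map_scotoma(before, during, patches[0], alpha=a).area_deg2
                 for a in (1e-9, 0.001, 0.05, 0.2, 0.5)]
        assert areas[0] == 0.0
        assert all(a1 <= a2 for a1, a2 in zip(areas, areas[1:]))

    def test_overlap_approaches_full_coverage(self, rng, patches):
        # large deficit over every tile covering the in-patch
        before, during = [], []
        for t in self.targets:
            b, d = _grid_session(rng, [t], n=10, shift_at=t, shift_ms=200.0)
            before += b
            during += d
        sco = map_scotoma(before, during, patches[0])
        assert sco.overlap_pct > 95.0

    def test_mismatched_grids_rejected(self, rng, patches):
        before, _ = _grid_session(rng, self.targets)
        _, during = _grid_session(rng, self.targets[:-1])
        with pytest.raises(ValueError, match="grid"):
            map_scotoma(before, during, patches[0])


def _trial(side, epoch, hit):
    return AttentionTrial(session_id="s", epoch=epoch, change_side=side,
                          change_magnitude_deg=15.0, delay_s=2.0,
                          responded=hit, valid=True,
                          reaction_time_s=0.5 if hit else None)


class TestSessionHitRates:
    def test_uniform_cells(self):
        trials = []
        for side in (ChangeSide.IN, ChangeSide.OUT):
            for epoch in (Epoch.BEFORE, Epoch.DURING):
                trials += [_trial(side, epoch, True)] * 10
                trials += [_trial(side, epoch, False)] * 10
        rates, counts = session_hit_rates(trials)
        assert all(r == pytest.approx(0.5) for r in rates.values())
        assert all(c == 20 for c in counts.values())

    def test_empty_cell_listed(self):
        trials = [_trial(ChangeSide.IN, Epoch.BEFORE, True)]
        with pytest.raises(ValueError, match="out/before"):
            session_hit_rates(trials)

    def test_recovers_generating_rates(self, rng):
        gen = {(ChangeSide.IN, Epoch.BEFORE): 0.8,
               (ChangeSide.OUT, Epoch.BEFORE): 0.8,
               (ChangeSide.IN, Epoch.DURING): 0.5,
               (ChangeSide.OUT, Epoch.DURING): 0.8}
        n = 160
        trials = [_trial(side, epoch, bool(rng.random() < p))
                  for (side, epoch), p in gen.items() for _ in range(n)]
        rates, _ = session_hit_rates(trials)
        for key, p in gen.items():
            # binomial 95% bound
            half = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(rates[key] - p) < 2 * half
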