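import numpy as np
import pytest

from covattn import (ChangeSide, Epoch, PatchGeometry, SaccadeRecord,
                     patch_pair)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def patches():
    return patch_pair(9.0, 3.0)


def make_saccade(latency, velocity=500.0, target=(9.0, 0.0),
                 epoch=Epoch.DURING, session="s1", endpoint=None):
    return SaccadeRecord(session_id=session, epoch=epoch, target=target,
                         endpoint=endpoint or target, latency_ms=latency,
                         peak_velocity_degps=velocity)


@pytest.fixture
def make_patch_saccades():
    """Build injection-epoch records with given latencies per patch."""
    def _build(in_latencies, out_latencies, metric_values=None):
        recs = []
        for lat in in_latencies:
            recs.append(make_saccade(lat, target=(9.0, 0.0)))
        for lat in out_latencies:
            recs.append(make_saccade(lat, target=(-9.0, 0.0)))
        return recs
    return _build


def psychometric_trials(rng, mu, sigma, guess, lapse, levels, n_per_level):
    """Bernoulli draws from the 4-parameter cumulative-Gaussian model."""
    from scipy.stats import norm
    xs, rs = [], []
    for lv in levels:
        p = guess + (1 - guess - lapse) * norm.cdf((lv - mu) / sigma)
        hits = rng.random(n_per_level) < p
        xs.extend([lv] * n_per_level)
        rs.extend(hits.tolist())
    return np.column_stack([xs, rs])
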