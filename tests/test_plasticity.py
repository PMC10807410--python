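"""Unit tests for STDP updates, traces and the prune-and-rewire sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plastinet.plasticity import (
    PlasticityConfig,
    RewireSaturationError,
    decay_traces,
    pair_protocol,
    prune_and_rewire,
    sample_presynaptic_by_distance,
    stdp_on_post_spike,
    stdp_on_pre_arrival,
)
from plastinet.topology import Network

CFG = PlasticityConfig()


class TestTraces:
    def test_decay_matches_exponential(self):
        """Ten Euler decays over 5 ms approximate e^{-1/2} within 2%."""
        s = 1.0
        for _ in range(10):
            s = decay_traces(s, dt=0.5, tau=10.0)
        assert s == pytest.approx(np.exp(-0.5), rel=0.02)

    def test_zero_stays_zero(self):
        assert decay_traces(0.0, 0.5) == 0.0

    def test_two_spikes_one_step_apart(self):
        # +1, one decay, +1  ->  1 + (1 - dt/tau)
        s = 0.0
        s += 1.0
        s = decay_traces(s, dt=0.5, tau=10.0)
        s += 1.0
        assert s == pytest.approx(1.0 + (1.0 - 0.05))


class TestSTDPUpdates:
    def test_potentiation_example(self):
        w = stdp_on_post_spike(0.3, s_pre=0.6065, cfg=CFG)
        assert w - 0.3 == pytest.approx(0.001 * 0.7 * 0.6065, rel=1e-12)

    def test_potentiation_saturates_at_one(self):
        assert stdp_on_post_spike(1.0, s_pre=5.0, cfg=CFG) == 1.0

    def test_no_potentiation_without_pre_trace(self):
        assert stdp_on_post_spike(0.3, s_pre=0.0, cfg=CFG) == 0.3

    def test_depression_example(self):
        w = stdp_on_pre_arrival(0.3, s_post=1.0, cfg=CFG)
        assert w - 0.3 == pytest.approx(-0.001 * 5 * 0.3, rel=1e-12)

    def test_depression_vanishes_at_zero(self):
        assert stdp_on_pre_arrival(0.0, s_post=3.0, cfg=CFG) == 0.0
        assert stdp_on_pre_arrival(0.3, s_post=0.0, cfg=CFG) == 0.3

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_weight_stays_bounded(self, seed):
        """Under arbitrary spike trains the weight remains in [0, 1]."""
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.uniform(0, 2000, 40))
        post = np.sort(rng.uniform(0, 2000, 40))
        _, ws = pair_protocol(pre, post, CFG, w0=rng.uniform(0, 1), record=True)
        assert np.all(ws >= 0.0) and np.all(ws <= 1.0)


class TestPairing:
    def test_pre_before_post_potentiates(self):
        """100 pairings at +5 ms lag strictly increase the weight."""
        base = np.arange(100) * 1000.0
        w = pair_protocol(base, base + 5.0, CFG, w0=0.3)
        assert w > 0.3

    def test_post_before_pre_depresses(self):
        base = np.arange(100) * 1000.0
        w = pair_protocol(base + 5.0, base, CFG, w0=0.3)
        assert w < 0.3

    def test_depression_outweighs_potentiation_at_balance_weight(self):
        """At w = 1/(1+alpha) symmetric pairings leave w nearly unchanged."""
        w_star = 1.0 / (1.0 + CFG.alpha)
        base = np.arange(50) * 1000.0
        up = pair_protocol(base, base + 5.0, CFG, w0=w_star) - w_star
        down = pair_protocol(base + 5.0, base, CFG, w0=w_star) - w_star
        # potentiation gain (1-w) lambda and depression alpha lambda w are equal at w*
        assert up == pytest.approx(-down, rel=0.15)


def _toy_net(weights, multiplicity="single"):
    """Five neurons on a line, synapses 0->1, 1->2, 2->3, 3->4."""
    pos = np.column_stack([50.0 + 50.0 * np.arange(5), np.full(5, 50.0)])
    m = len(weights)
    return Network(
        pos=pos,
        excitatory=np.ones(5, dtype=bool),
        substrate=(400.0, 100.0),
        pre=np.arange(m),
        post=np.arange(m) + 1,
        w=np.array(weights, dtype=float),
        delay_ms=np.full(m, 1.0),
        multiplicity=multiplicity,
    )


class TestPruneAndRewire:
    def test_nothing_happens_above_threshold(self, rng):
        net = _toy_net([0.3, 0.3, 0.3, 0.3])
        log = prune_and_rewire(net, CFG, t=10.0, rng=rng)
        assert log == []
        assert np.array_equal(net.pre, np.arange(4))

    def test_weak_synapse_removed_after_lifetime(self, rng):
        """w = 0.04 < w_min for exactly t_w seconds -> replaced by exactly
        one newborn edge with weight w_new."""
        cfg = PlasticityConfig(w_min=0.05, t_w=5.0, w_new=0.1)
        net = _toy_net([0.04, 0.3, 0.3, 0.3])
        assert prune_and_rewire(net, cfg, t=10.0, rng=rng) == []  # marked weak
        log = prune_and_rewire(net, cfg, t=15.0, rng=rng)  # 5 s later: pruned
        events = [e["event"] for e in log]
        assert events == ["removed", "created"]
        assert log[0]["pre_id"] == 0 and log[0]["post_id"] == 1
        assert log[1]["weight"] == 0.1
        assert net.n_synapses == 4
        assert net.w[0] == 0.1 and net.x[0] == 1.0 and net.y[0] == 0.0
        assert np.isnan(net.weak_since[0]) and net.birth_time[0] == 15.0

    def test_recovered_weight_is_never_pruned(self, rng):
        cfg = PlasticityConfig(w_min=0.05, t_w=5.0, w_new=0.1)
        net = _toy_net([0.04, 0.3, 0.3, 0.3])
        prune_and_rewire(net, cfg, t=0.0, rng=rng)
        net.w[0] = 0.2  # recovers above threshold before t_w elapses
        prune_and_rewire(net, cfg, t=4.0, rng=rng)
        net.w[0] = 0.04  # weak again: the clock must restart
        assert prune_and_rewire(net, cfg, t=6.0, rng=rng) == []
        assert prune_and_rewire(net, cfg, t=10.0, rng=rng) == []
        assert prune_and_rewire(net, cfg, t=11.0, rng=rng) != []

    def test_count_conserved_and_no_duplicates_in_single_mode(self):
        rng = np.random.default_rng(0)
        cfg = PlasticityConfig(w_min=0.5, t_w=1.0, w_new=0.6)  # aggressive churn
        net = _toy_net([0.3, 0.3, 0.3, 0.3])
        for t in range(1, 30):
            net.w[net.w < 0.5] = 0.3  # keep recycling
            prune_and_rewire(net, cfg, t=float(t), rng=rng)
            assert net.n_synapses == 4
            pairs = list(zip(net.pre.tolist(), net.post.tolist()))
            assert len(set(pairs)) == 4, "duplicate pair in single mode"
            assert all(p != q for p, q in pairs), "self-loop created"

    def test_exhausted_attempt_budget_raises(self):
        """When every sampled candidate duplicates an existing pair within
        the attempt budget, the sweep reports saturation."""
        pos = np.array([[50.0, 50.0], [100.0, 50.0]])
        net = Network(
            pos=pos,
            excitatory=np.array([True, True]),
            substrate=(150.0, 100.0),
            pre=np.array([0, 1]),
            post=np.array([1, 0]),
            w=np.array([0.01, 0.3]),
            delay_ms=np.array([1.0, 1.0]),
        )
        # budget of one draw; the first candidate (post=0, pre=1) collides
        # with the surviving synapse 1 -> 0
        cfg = PlasticityConfig(w_min=0.05, t_w=1.0, w_new=0.1, max_rewire_attempts=1)
        prune_and_rewire(net, cfg, t=0.0, rng=np.random.default_rng(1))
        with pytest.raises(RewireSaturationError):
            prune_and_rewire(net, cfg, t=2.0, rng=np.random.default_rng(1))


class TestDistanceSampling:
    def test_equal_distances_are_uniform(self, rng):
        """Equidistant candidates are selected uniformly (chi-squared)."""
        post = np.array([0.0, 0.0])
        cand = np.array([[10.0, 0.0], [-10.0, 0.0], [0.0, 10.0], [0.0, -10.0]])
        draws = [
            sample_presynaptic_by_distance(post, cand, sigma=20.0, rng=rng)
            for _ in range(10_000)
        ]
        counts = np.bincount(draws, minlength=4)
        assert stats.chisquare(counts).pvalue > 1e-4

    def test_frequencies_match_gaussian_weights(self, rng):
        post = np.array([0.0, 0.0])
        cand = np.array([[10.0, 0.0], [30.0, 0.0], [60.0, 0.0], [90.0, 0.0]])
        sigma = 40.0
        n = 50_000
        draws = np.array(
            [sample_presynaptic_by_distance(post, cand, sigma, rng) for _ in range(n)]
        )
        counts = np.bincount(draws, minlength=4)
        d2 = np.sum(cand**2, axis=1)
        p = np.exp(-d2 / (2 * sigma**2))
        p /= p.sum()
        for k in range(4):
            se = np.sqrt(n * p[k] * (1 - p[k]))
            assert abs(counts[k] - n * p[k]) < 3 * se

    def test_nearby_candidate_dominates(self, rng):
        post = np.array([0.0, 0.0])
        cand = np.array([[1.0, 0.0], [1e4, 0.0]])
        draws = {sample_presynaptic_by_distance(post, cand, 50.0, rng) for _ in range(200)}
        assert draws == {0}

    def test_empty_admissible_set_raises(self, rng):
        with pytest.raises(ValueError):
            sample_presynaptic_by_distance(
                np.zeros(2), np.array([[1.0, 0.0]]), 10.0, rng, exclusions={0}
            )
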