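"""Integration tests of the simulation loop: determinism, resumability,
equivalence with the documented per-component update rules, and the basic
stimulated-line behaviour."""

import numpy as np
import pytest

from plastinet import engine
from plastinet.core_dynamics import NeuronParams, SimulationConfig, StimulusProtocol
from plastinet.plasticity import PlasticityConfig, decay_traces, stdp_on_post_spike, stdp_on_pre_arrival
from plastinet.synapses import DelayBuffer, SynapseParams, TMState, step_synapse_tm
from plastinet.topology import SnapshotFormatError, build_line_1d, build_random_planar


def test_zero_duration_returns_initial_snapshot_only(two_neuron_net):
    run = engine.run(two_neuron_net, sim=SimulationConfig(seed=0), duration=0.0)
    assert len(run.spike_neuron) == 0
    assert run.change_log == []
    assert len(run.snapshots) == 1
    assert run.snapshots[0].t_s == 0.0


def test_constant_drive_is_deterministic(two_neuron_net):
    # a pulse as wide as its period is a constant suprathreshold current
    stim = StimulusProtocol(target_neuron_ids=(0,), frequency=10.0, pulse_width=100.0, amplitude=10.0)
    sim = SimulationConfig(seed=1, noise_sd=0.0)
    a = engine.run(two_neuron_net, sim=sim, stimulus=stim, duration=1.0)
    b = engine.run(two_neuron_net, sim=sim, stimulus=stim, duration=1.0)
    assert len(a.spike_neuron) > 5
    np.testing.assert_array_equal(a.spike_neuron, b.spike_neuron)
    np.testing.assert_array_equal(a.spike_time_ms, b.spike_time_ms)
    assert np.all(a.spike_time_ms % 0.5 == 0.0)


def test_identical_seeds_give_identical_spike_logs():
    net = build_random_planar(n=20, substrate=(200.0, 200.0), k_out=4, rng=11)
    plast = PlasticityConfig()
    runs = [
        engine.run(net, sim=SimulationConfig(seed=42), plasticity=plast, duration=3.0)
        for _ in range(2)
    ]
    h = [hash((tuple(r.spike_neuron), tuple(r.spike_time_ms))) for r in runs]
    assert h[0] == h[1]
    assert runs[0].network.to_json() == runs[1].network.to_json()


def test_engine_matches_composed_module_operations(two_neuron_net):
    """The fused simulation kernel reproduces the documented per-component
    updates (transmitter pools, traces, STDP, delays, neuron step) applied
    in the contracted phase order."""
    net = two_neuron_net
    stim = StimulusProtocol(target_neuron_ids=(0,), frequency=10.0, pulse_width=3.0, amplitude=40.0)
    sim = SimulationConfig(seed=0, noise_sd=0.0)
    pcfg = PlasticityConfig(rewiring_enabled=False)
    steps = 2000  # 1 s
    run = engine.run(net, sim=sim, stimulus=stim, plasticity=pcfg, duration=1.0)

    # reference: plain composition of the module-level operations
    nparams = NeuronParams()
    sparams = SynapseParams()
    dt = 0.5
    from plastinet.core_dynamics import NeuronState, step_neuron

    states = [NeuronState(pos=tuple(net.pos[i])) for i in range(2)]
    tm = TMState()
    w = float(net.w[0])
    s_pre = 0.0
    s_post = np.zeros(2)
    buf = DelayBuffer(1, 20)
    delay_steps = int(round(net.delay_ms[0] / dt))
    spikes = []
    for k in range(steps):
        arrived = bool(buf.pop(k)[0])
        tm = step_synapse_tm(tm, sparams, dt, spike_arrived=arrived)
        if arrived:
            w = float(stdp_on_pre_arrival(w, s_post[net.post[0]], pcfg))
        I = [0.0, nparams.g(True) * w * tm.y]
        spiked = []
        for i in range(2):
            I_tot = I[i] + stim.amplitude_at(k * dt, i)
            states[i], fired = step_neuron(states[i], nparams, I_tot, dt, t_ms=k * dt)
            if fired:
                spiked.append(i)
                spikes.append((i, k * dt))
        if 1 in spiked:
            w = float(stdp_on_post_spike(w, s_pre, pcfg))
        if 0 in spiked:
            buf.schedule(np.array([0]), np.array([delay_steps]), k)
        if arrived:
            s_pre += 1.0
        for i in spiked:
            s_post[i] += 1.0
        s_pre = decay_traces(s_pre, dt, pcfg.tau_trace)
        s_post = decay_traces(s_post, dt, pcfg.tau_trace)

    ref_spikes = np.array([t for _, t in spikes])
    np.testing.assert_array_equal(run.spike_time_ms, ref_spikes)
    fin = run.network
    assert fin.w[0] == pytest.approx(w, abs=1e-9)
    assert fin.x[0] == pytest.approx(tm.x, abs=1e-9)
    assert fin.y[0] == pytest.approx(tm.y, abs=1e-9)
    assert fin.u_star[0] == pytest.approx(tm.u_star, abs=1e-9)
    assert fin.s_pre[0] == pytest.approx(s_pre, abs=1e-9)
    assert fin.v[0] == pytest.approx(states[0].v, abs=1e-9)
    assert fin.v[1] == pytest.approx(states[1].v, abs=1e-9)


class TestSnapshots:
    def test_save_load_save_identical_bytes(self, tmp_path, two_neuron_net):
        run = engine.run(two_neuron_net, sim=SimulationConfig(seed=3), duration=0.5)
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        engine.save_snapshot(run.snapshots[0], p1)
        engine.save_snapshot(engine.load_snapshot(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_field_is_named(self, tmp_path, two_neuron_net):
        import json

        run = engine.run(two_neuron_net, sim=SimulationConfig(seed=3), duration=0.1)
        path = tmp_path / "snap.json"
        engine.save_snapshot(run.snapshots[0], path)
        data = json.loads(path.read_text())
        del data["network"]["neurons"][0]["u"]
        path.write_text(json.dumps(data))
        with pytest.raises(SnapshotFormatError, match=r"neurons\[0\]\.u"):
            engine.load_snapshot(path)

    def test_resume_equals_uninterrupted_run(self, tmp_path):
        """Split 10 s = 5 s + snapshot + 5 s reproduces the one-shot run
        exactly (spikes, weights, full state)."""
        net = build_random_planar(n=15, substrate=(200.0, 200.0), k_out=4, rng=21)
        plast = PlasticityConfig(w_min=0.3, t_w=2.0, w_new=0.35)  # ensure rewiring happens
        stim = StimulusProtocol(target_neuron_ids=(0,))
        sim = SimulationConfig(seed=9)

        full = engine.run(net, sim=sim, stimulus=stim, plasticity=plast,
                          duration=10.0, snapshot_every=5.0)
        first = engine.run(net, sim=sim, stimulus=stim, plasticity=plast,
                           duration=5.0, snapshot_every=5.0)
        path = tmp_path / "mid.json"
        engine.save_snapshot(first.snapshots[-1], path)
        second = engine.run(net, sim=sim, stimulus=stim, plasticity=plast,
                            duration=5.0, resume_from=engine.load_snapshot(path))

        assert full.network.to_json() == second.network.to_json()
        mask = full.spike_time_ms >= 5000.0
        np.testing.assert_array_equal(full.spike_neuron[mask], second.spike_neuron)
        np.testing.assert_array_equal(full.spike_time_ms[mask], second.spike_time_ms)


def test_neuron_relabelling_only_relabels_spikes():
    """Permuting neuron indices (carrying their noise keys) permutes the
    spike log without changing any spike times."""
    net = build_random_planar(n=10, substrate=(200.0, 200.0), k_out=3, rng=2)
    sim = SimulationConfig(seed=5)
    base = engine.run(net, sim=sim, duration=2.0)

    perm = np.random.default_rng(0).permutation(10)  # new index of old neuron i
    pnet = net.copy()
    inv = np.argsort(perm)
    pnet.pos = net.pos[inv]
    pnet.excitatory = net.excitatory[inv]
    pnet.noise_key = net.noise_key[inv]
    pnet.v, pnet.u = net.v[inv], net.u[inv]
    pnet.s_post, pnet.last_spike_ms = net.s_post[inv], net.last_spike_ms[inv]
    pnet.pre = perm[net.pre]
    pnet.post = perm[net.post]
    permuted = engine.run(pnet, sim=sim, duration=2.0)

    # within a step the log is ordered by neuron index, so compare as sets
    base_events = sorted(zip(base.spike_time_ms, perm[base.spike_neuron]))
    perm_events = sorted(zip(permuted.spike_time_ms, permuted.spike_neuron))
    assert base_events == perm_events


def test_numerical_blowup_aborts_with_last_good_snapshot(two_neuron_net):
    stim = StimulusProtocol(target_neuron_ids=(0,), amplitude=1e12)
    with pytest.raises(engine.NumericalBlowupError) as err:
        engine.run(two_neuron_net, sim=SimulationConfig(seed=0, noise_sd=0.0),
                   stimulus=stim, duration=1.0)
    assert err.value.snapshot is not None
    assert err.value.snapshot.t_s == 0.0


def test_spike_raster_csv(tmp_path, two_neuron_net):
    stim = StimulusProtocol(target_neuron_ids=(0,))
    run = engine.run(two_neuron_net, sim=SimulationConfig(seed=0, noise_sd=0.0),
                     stimulus=stim, duration=1.0)
    path = tmp_path / "spikes.csv"
    run.save_spikes(path)
    header = path.read_text().splitlines()[0]
    assert header == "neuron_id,time_ms"
    assert len(path.read_text().splitlines()) == len(run.spike_neuron) + 1


def test_stimulated_line_drives_outward_activity_field():
    """20 s of centre stimulation makes the activity-field vectors point
    away from the centre on both sides of the line."""
    net = build_line_1d(9)
    stim = StimulusProtocol(target_neuron_ids=(4,))
    run = engine.run(net, sim=SimulationConfig(seed=1), stimulus=stim,
                     plasticity=PlasticityConfig(rewiring_enabled=False), duration=20.0)
    from plastinet.vector_fields import activity_field

    f = activity_field(run.network, grid_n=21)
    centre = net.pos[4]
    vec = f.vectors
    nz = np.linalg.norm(vec, axis=2) > 1e-9
    assert nz.sum() > 5
    outward = f.cell_centres() - centre
    dots = np.sum(vec * outward, axis=2)[nz]
    assert np.mean(dots > 0) > 0.8


def test_performance_smoke_medium_network():
    """A 100-neuron, 20 s run with plasticity completes promptly."""
    net = build_random_planar(n=100, substrate=(400.0, 400.0), k_out=8, rng=31)
    run = engine.run(net, sim=SimulationConfig(seed=1), plasticity=PlasticityConfig(), duration=20.0)
    assert len(run.spike_neuron) > 0
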