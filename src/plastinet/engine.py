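"""Fixed-step simulation loop tying neurons, synapses and plasticity together.

One forward-Euler step of ``dt`` (default 0.5 ms) applies, in this fixed
order:

1. pop delayed presynaptic spike arrivals from the ring buffer;
2. transmitter-pool relaxation; on arrivals, facilitation + release and
   STDP depression (using the current postsynaptic trace);
3. synaptic currents I_i = sum_j g_j w_ij y_ij;
4. neuron Euler step with noise/stimulation and after-spike resets;
5. on spikes: STDP potentiation and activity-trace increments (using the
   presynaptic traces before this step's own increments), then trace
   increments (+1) and scheduling of the emitted spikes into the delay
   buffer;
6. decay of all spike and activity traces;
7. every ``rewire_period`` of simulated time, the structural sweep;
8. user callbacks / snapshots.

Noise is generated with counter-based (Philox) streams keyed by
``(seed, neuron noise_key)`` and indexed by step number, so a run is a pure
function of (network, configs, seed): results are bit-identical across
repeats, invariant to neuron relabelling (up to the relabelling), and a run
resumed from a snapshot continues exactly as an uninterrupted one.

Internally all times are integer step counts; seconds and milliseconds
appear only at the interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .core_dynamics import NeuronParams, SimulationConfig, StimulusProtocol
from .plasticity import PlasticityConfig, prune_and_rewire
from .synapses import SynapseParams
from .topology import Network, SnapshotFormatError

__all__ = [
    "EngineSnapshot",
    "SimulationRun",
    "NumericalBlowupError",
    "run",
    "save_snapshot",
    "load_snapshot",
]

_REWIRE_STREAM = 0x5E11


class NumericalBlowupError(RuntimeError):
    """Integration diverged; carries the last good snapshot."""

    def __init__(self, message: str, t_s: float, snapshot: "EngineSnapshot | None"):
        super().__init__(message)
        self.t_s = t_s
        self.snapshot = snapshot


@dataclass
class EngineSnapshot:
    """Full simulation state at one instant: network + in-flight spikes.

    ``pending`` lists (synapse_index, offset_steps) pairs for spikes that
    have been emitted but not yet delivered, so resuming is exact.
    """

    t_s: float
    network: Network
    pending: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SimulationRun:
    """Result of one simulation: final network, logs and snapshots."""

    network: Network
    spike_neuron: np.ndarray
    spike_time_ms: np.ndarray
    change_log: list[dict]
    snapshots: list[EngineSnapshot]
    sim: SimulationConfig
    plasticity: PlasticityConfig | None
    stimulus: StimulusProtocol | None

    def spikes_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.spike_neuron, "time_ms": self.spike_time_ms})

    def save_spikes(self, path) -> None:
        """Spike raster CSV: one row per spike, times at dt resolution."""
        self.spikes_dataframe().to_csv(path, index=False)

    def save_change_log(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.change_log, columns=["t_s", "event", "pre_id", "post_id", "weight"]
        ).to_csv(path, index=False)


# --------------------------------------------------------------------- kernel


def _advance_impl(
    steps,
    step0,
    dt,
    v,
    u,
    s_post,
    last_spike_ms,
    a,
    b,
    c,
    d,
    noise,
    stim_amp,
    stim_mask,
    pre,
    post,
    w,
    x,
    y,
    z,
    u_star,
    s_pre,
    l_act,
    delay_steps,
    plastic,
    g_syn,
    buf,
    eff_ptr,
    eff_idx,
    aff_ptr,
    aff_idx,
    inv_tau_I,
    inv_tau_rec,
    inv_tau_facil,
    release_inc,
    lam,
    alpha,
    inv_tau_trace,
    inv_tau_l,
    stdp_on,
    spike_neuron,
    spike_step,
):
    """Advance the whole network ``steps`` steps.  Returns (n_spikes, status);
    status is -1 on success or the step index at which a non-finite membrane
    potential appeared."""
    n = v.shape[0]
    m = w.shape[0]
    L = buf.shape[0]
    I_acc = np.zeros(n)
    arrived = np.empty(m, dtype=np.int64)
    spiked = np.empty(n, dtype=np.int64)
    kd_tr = 1.0 - dt * inv_tau_trace
    kd_l = 1.0 - dt * inv_tau_l
    count = 0
    cap = spike_neuron.shape[0]
    for kstep in range(steps):
        ptr = (step0 + kstep) % L
        # --- phases 1-2: arrivals, transmitter pools, depression
        na = 0
        for s in range(m):
            yy = y[s]
            zz = z[s]
            y[s] = yy - dt * yy * inv_tau_I
            z[s] = zz + dt * (yy * inv_tau_I - zz * inv_tau_rec)
            x[s] = x[s] + dt * zz * inv_tau_rec
            u_star[s] = u_star[s] - dt * u_star[s] * inv_tau_facil
            if buf[ptr, s]:
                buf[ptr, s] = False
                arrived[na] = s
                na += 1
                us = u_star[s] + release_inc * (1.0 - u_star[s])
                u_star[s] = us
                delta = us * x[s]
                x[s] -= delta
                y[s] += delta
                if stdp_on and plastic[s]:
                    wv = w[s] - lam * alpha * w[s] * s_post[post[s]]
                    if wv < 0.0:
                        wv = 0.0
                    elif wv > 1.0:
                        wv = 1.0
                    w[s] = wv
        # --- phase 3: synaptic currents
        for i in range(n):
            I_acc[i] = 0.0
        for s in range(m):
            I_acc[post[s]] += g_syn[s] * w[s] * y[s]
        # --- phase 4: neuron update and resets
        nspk = 0
        status = -1
        for i in range(n):
            I = noise[kstep, i] + I_acc[i]
            if stim_mask[i]:
                I += stim_amp[kstep]
            vv = v[i]
            uu = u[i]
            vn = vv + dt * (0.04 * vv * vv + 5.0 * vv + 140.0 - uu + I)
            un = uu + dt * (a * (b * vv - uu))
            if not (vn > -1e9 and vn < 1e9):
                status = step0 + kstep
                vn = vv
                un = uu
            if vn >= 30.0:
                spiked[nspk] = i
                nspk += 1
                v[i] = c
                u[i] = un + d
                last_spike_ms[i] = (step0 + kstep) * dt
                if count < cap:
                    spike_neuron[count] = i
                    spike_step[count] = step0 + kstep
                    count += 1
            else:
                v[i] = vn
                u[i] = un
        if status >= 0:
            return count, status
        # --- phase 5: potentiation, activity traces, increments, scheduling
        for si in range(nspk):
            i = spiked[si]
            for p in range(aff_ptr[i], aff_ptr[i + 1]):
                s = aff_idx[p]
                if stdp_on and plastic[s]:
                    wv = w[s] + lam * (1.0 - w[s]) * s_pre[s]
                    if wv > 1.0:
                        wv = 1.0
                    w[s] = wv
                l_act[s] += s_pre[s]
            for p in range(eff_ptr[i], eff_ptr[i + 1]):
                s = eff_idx[p]
                buf[(step0 + kstep + delay_steps[s]) % L, s] = True
        for q in range(na):
            s_pre[arrived[q]] += 1.0
        for si in range(nspk):
            s_post[spiked[si]] += 1.0
        # --- phase 6: trace decay
        for i in range(n):
            s_post[i] *= kd_tr
        for s in range(m):
            s_pre[s] *= kd_tr
            l_act[s] *= kd_l
    return count, -1


try:  # pragma: no cover - exercised implicitly by every engine test
    from numba import njit

    _advance = njit(cache=True)(_advance_impl)
except ImportError:  # pragma: no cover
    _advance = _advance_impl


# ----------------------------------------------------------------- noise/stim


def _neuron_noise(seed: int, noise_key: np.ndarray, step0: int, steps: int, sd: float) -> np.ndarray:
    """Per-neuron Gaussian noise for steps [step0, step0+steps).

    Each neuron owns a Philox counter-based stream keyed by (seed, its
    noise_key); the draw for step t is obtained by inverse-CDF transform of
    the t-th uniform of that stream, so the value depends only on
    (seed, key, t).
    """
    n = len(noise_key)
    out = np.empty((steps, n))
    if sd == 0.0 or steps == 0:
        out.fill(0.0)
        return out
    # Philox.advance(k) skips k counter blocks of four 64-bit draws, and a
    # fresh generator starts at a block boundary: pad to the exact step.
    pad = step0 % 4
    for i in range(n):
        bg = np.random.Philox(key=(int(seed) << 32) + int(noise_key[i]))
        bg.advance(step0 // 4)
        uni = np.random.Generator(bg).random(pad + steps)[pad:]
        np.clip(uni, 1e-300, 1.0 - 1e-16, out=uni)
        out[:, i] = ndtri(uni) * sd
    return out


def _csr(index_of: np.ndarray, n: int):
    order = np.argsort(index_of, kind="stable").astype(np.int64)
    counts = np.bincount(index_of, minlength=n)
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, order


# ----------------------------------------------------------------------- run


def run(
    network: Network,
    sim: SimulationConfig | None = None,
    stimulus: StimulusProtocol | None = None,
    plasticity: PlasticityConfig | None = None,
    synapse_params: SynapseParams | None = None,
    neuron_params: NeuronParams | None = None,
    duration: float | None = None,
    snapshot_every: float | None = None,
    callbacks: list | None = None,
    resume_from: "EngineSnapshot | None" = None,
) -> SimulationRun:
    """Simulate ``network`` for ``duration`` seconds (modifies a copy).

    ``plasticity=None`` disables both STDP and rewiring.  ``snapshot_every``
    records full state snapshots (the initial state at the resume time is
    always included).  ``callbacks`` is a list of ``(every_s, fn)`` pairs;
    ``fn(t_s, network)`` is invoked at multiples of ``every_s``.  Raises
    :class:`NumericalBlowupError` carrying the last good snapshot if the
    membrane potential diverges.
    """
    sim = sim or SimulationConfig()
    synapse_params = synapse_params or SynapseParams()
    neuron_params = neuron_params or NeuronParams()
    callbacks = list(callbacks or [])
    dt = sim.dt
    if duration is None:
        duration = sim.duration
    if duration < 0:
        raise ValueError("duration must be >= 0")

    net = (resume_from.network if resume_from is not None else network).copy()
    t0_s = resume_from.t_s if resume_from is not None else 0.0
    step0 = int(round(t0_s * 1000.0 / dt))
    total_steps = int(round(duration * 1000.0 / dt))

    n = net.n_neurons
    m = net.n_synapses
    W, H = net.substrate
    max_delay_ms = math.hypot(W, H) / sim.conduction_velocity + dt
    L = max(int(math.ceil(max_delay_ms / dt)) + 2, 2)
    buf = np.zeros((L, m), dtype=bool)
    if resume_from is not None:
        for s_idx, offset in resume_from.pending:
            if offset < 1 or offset >= L:
                raise SnapshotFormatError(f"pending[{s_idx}] offset {offset} outside buffer horizon")
            buf[(step0 + offset) % L, s_idx] = True

    delay_steps = np.round(net.delay_ms / dt).astype(np.int64)
    if np.any(np.abs(delay_steps * dt - net.delay_ms) > 1e-9):
        raise ValueError("synaptic delays must be integer multiples of dt")
    if np.any(delay_steps < 1):
        raise ValueError("synaptic delays must be at least one step")
    if np.any(delay_steps >= L):
        raise ValueError("a synaptic delay exceeds the buffer horizon")

    stim_mask = np.zeros(n, dtype=bool)
    if stimulus is not None:
        stim_mask[list(stimulus.target_neuron_ids)] = True

    stdp_on = plasticity is not None and plasticity.stdp_enabled
    rewiring_on = plasticity is not None and plasticity.rewiring_enabled
    pcfg = plasticity or PlasticityConfig()
    # STDP and rewiring act on excitatory synapses only
    plastic = net.excitatory[net.pre].copy()
    g_syn = np.where(
        net.excitatory[net.pre], neuron_params.g_excitatory, neuron_params.g_inhibitory
    ).astype(float)

    rewire_steps = int(round(pcfg.rewire_period * 1000.0 / dt)) if rewiring_on else 0
    snap_steps = int(round(snapshot_every * 1000.0 / dt)) if snapshot_every else 0
    if snapshot_every and snap_steps == 0:
        raise ValueError("snapshot_every is below one step")
    cb_steps = [max(int(round(ev * 1000.0 / dt)), 1) for ev, _ in callbacks]

    def make_snapshot(t_step: int) -> EngineSnapshot:
        pending = []
        for row in range(L):
            offset = (row - t_step) % L
            if offset == 0:
                continue
            for s_idx in np.nonzero(buf[row])[0]:
                pending.append((int(s_idx), int(offset)))
        pending.sort()
        return EngineSnapshot(t_s=t_step * dt / 1000.0, network=net.copy(), pending=pending)

    snapshots = [make_snapshot(step0)]
    spike_parts_n: list[np.ndarray] = []
    spike_parts_t: list[np.ndarray] = []
    change_log: list[dict] = []

    aff_ptr, aff_idx = _csr(net.post, n)
    eff_ptr, eff_idx = _csr(net.pre, n)

    # results are invariant to chunk splitting (noise and stimulation are
    # pure functions of the step index); the cap only bounds buffer memory
    max_chunk_steps = max(1, int(4_000_000 / max(n, 1)))
    t_step = step0
    end_step = step0 + total_steps
    while t_step < end_step:
        boundaries = [end_step, t_step + max_chunk_steps]
        if rewire_steps:
            boundaries.append(((t_step // rewire_steps) + 1) * rewire_steps)
        if snap_steps:
            boundaries.append(((t_step // snap_steps) + 1) * snap_steps)
        for ev in cb_steps:
            boundaries.append(((t_step // ev) + 1) * ev)
        next_stop = min(b for b in boundaries if b > t_step)
        chunk = min(next_stop, end_step) - t_step

        noise = _neuron_noise(sim.seed, net.noise_key, t_step, chunk, sim.noise_sd)
        if stimulus is not None:
            stim_amp = stimulus.amplitude_trace(t_step, chunk, dt)
        else:
            stim_amp = np.zeros(chunk)
        cap = max(n * chunk, 1)
        spike_neuron = np.empty(cap, dtype=np.int64)
        spike_step = np.empty(cap, dtype=np.int64)
        cnt, status = _advance(
            chunk,
            t_step,
            dt,
            net.v,
            net.u,
            net.s_post,
            net.last_spike_ms,
            neuron_params.a,
            neuron_params.b,
            neuron_params.c,
            neuron_params.d,
            noise,
            stim_amp,
            stim_mask,
            net.pre,
            net.post,
            net.w,
            net.x,
            net.y,
            net.z,
            net.u_star,
            net.s_pre,
            net.l_act,
            delay_steps,
            plastic,
            g_syn,
            buf,
            eff_ptr,
            eff_idx,
            aff_ptr,
            aff_idx,
            1.0 / synapse_params.tau_I,
            1.0 / synapse_params.tau_rec,
            1.0 / synapse_params.tau_facil,
            synapse_params.release_increment,
            pcfg.lambda_rate,
            pcfg.alpha,
            1.0 / pcfg.tau_trace,
            1.0 / pcfg.tau_l,
            stdp_on,
            spike_neuron,
            spike_step,
        )
        if status >= 0:
            raise NumericalBlowupError(
                f"membrane potential diverged at t = {status * dt / 1000.0:.4f} s; "
                "reduce dt or input currents",
                t_s=status * dt / 1000.0,
                snapshot=snapshots[-1],
            )
        if sim.record_spikes and cnt:
            spike_parts_n.append(spike_neuron[:cnt].copy())
            spike_parts_t.append(spike_step[:cnt].copy())
        t_step += chunk
        t_s = t_step * dt / 1000.0

        if rewire_steps and t_step % rewire_steps == 0 and t_step > step0:
            event_index = t_step // rewire_steps
            rng = np.random.default_rng(
                np.random.SeedSequence((int(sim.seed), _REWIRE_STREAM, int(event_index)))
            )
            changes = prune_and_rewire(
                net, pcfg, t_s, rng, conduction_velocity=sim.conduction_velocity, dt=dt
            )
            if changes:
                change_log.extend(changes)
                # refresh derived per-synapse arrays and drop in-flight spikes
                # of replaced slots (their birth_time was just set to t_s)
                slots = np.nonzero(net.birth_time == t_s)[0]
                for s_idx in slots:
                    buf[:, s_idx] = False
                delay_steps = np.round(net.delay_ms / dt).astype(np.int64)
                plastic = net.excitatory[net.pre].copy()
                g_syn = np.where(
                    net.excitatory[net.pre],
                    neuron_params.g_excitatory,
                    neuron_params.g_inhibitory,
                ).astype(float)
                aff_ptr, aff_idx = _csr(net.post, n)
                eff_ptr, eff_idx = _csr(net.pre, n)

        if snap_steps and t_step % snap_steps == 0 and t_step > step0:
            snapshots.append(make_snapshot(t_step))
        for (ev_s, fn), ev in zip(callbacks, cb_steps):
            if t_step % ev == 0 and t_step > step0:
                fn(t_s, net)

    if spike_parts_n:
        spike_neuron_all = np.concatenate(spike_parts_n)
        spike_time_all = np.concatenate(spike_parts_t) * dt
    else:
        spike_neuron_all = np.empty(0, dtype=np.int64)
        spike_time_all = np.empty(0)
    return SimulationRun(
        network=net,
        spike_neuron=spike_neuron_all,
        spike_time_ms=spike_time_all,
        change_log=change_log,
        snapshots=snapshots,
        sim=sim,
        plasticity=plasticity,
        stimulus=stimulus,
    )


# ------------------------------------------------------------------ snapshots


def save_snapshot(snapshot: EngineSnapshot, path) -> None:
    """Serialize a full simulation snapshot to JSON (exact round-trip)."""
    data = {
        "format": "plastinet-snapshot",
        "version": 1,
        "t_s": float(snapshot.t_s),
        "network": snapshot.network.to_dict(),
        "pending": [[int(a), int(b)] for a, b in snapshot.pending],
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(data, sort_keys=True, separators=(",", ":")))


def load_snapshot(path) -> EngineSnapshot:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("format", "t_s", "network", "pending"):
        if key not in data:
            raise SnapshotFormatError(f"missing required field '{key}'")
    if data["format"] != "plastinet-snapshot":
        raise SnapshotFormatError(f"unrecognized format '{data['format']}'")
    return EngineSnapshot(
        t_s=float(data["t_s"]),
        network=Network.from_dict(data["network"]),
        pending=[(int(a), int(b)) for a, b in data["pending"]],
    )
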