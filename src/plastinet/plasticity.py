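"""Long-term plasticity (multiplicative STDP) and structural rewiring.

STDP with local trace variables: each neuron carries a postsynaptic trace
``s_i`` and each synapse a presynaptic trace ``s_j``; both are incremented
by 1 on the corresponding (delayed, for the presynaptic side) spike and
decay with time constant ``tau_trace``.  Weight updates are event driven,

    on a postsynaptic spike:      w <- w + lambda (1 - w) s_j
    on a presynaptic arrival:     w <- w - lambda alpha w s_i

so potentiation vanishes as w -> 1 and depression as w -> 0 (multiplicative
soft bounds).  For uncorrelated pre/post firing the drift balances at
w* = 1/(1 + alpha).

Structural rewiring: every ``rewire_period`` seconds all weights are
checked; a synapse whose weight has stayed below ``w_min`` for at least
``t_w`` seconds is removed and replaced by a newborn synapse with weight
``w_new`` whose postsynaptic neuron is uniform random and whose
presynaptic neuron is drawn with the distance-dependent Gaussian weight
exp(-d^2/2 sigma^2).  The synapse count is therefore conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .topology import Network, delay_from_distance

__all__ = [
    "PlasticityConfig",
    "RewireSaturationError",
    "decay_traces",
    "stdp_on_post_spike",
    "stdp_on_pre_arrival",
    "sample_presynaptic_by_distance",
    "prune_and_rewire",
    "pair_protocol",
]


@dataclass
class PlasticityConfig:
    """Parameters of the STDP rule and the rewiring algorithm.

    lambda_rate : learning rate of the multiplicative STDP rule.
    alpha : asymmetry (depression/potentiation ratio); the uncorrelated
        balance point is 1/(1+alpha).
    tau_trace : decay time (ms) of the local spike traces.
    w_min, t_w, w_new : pruning threshold, lifetime of a weak connection
        (s), and weight of newborn connections.
    rewire_period : interval (s) between structural checks.
    sigma : Gaussian length scale for presynaptic rebirth sampling; when
        None the network's own sigma is used.
    """

    lambda_rate: float = 0.001
    alpha: float = 5.0
    tau_trace: float = 10.0
    w_min: float = 0.05
    t_w: float = 5.0
    w_new: float = 0.1
    rewire_period: float = 1.0
    rewiring_enabled: bool = True
    stdp_enabled: bool = True
    sigma: float | None = None
    tau_l: float = 1000.0
    max_rewire_attempts: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.w_min < 1:
            raise ValueError("w_min must be in (0, 1)")
        if not 0 < self.w_new < 1:
            raise ValueError("w_new must be in (0, 1)")
        if self.t_w <= 0:
            raise ValueError("t_w must be positive")
        if self.rewire_period <= 0:
            raise ValueError("rewire_period must be positive")
        if self.tau_trace <= 0 or self.tau_l <= 0:
            raise ValueError("trace time constants must be positive")


class RewireSaturationError(RuntimeError):
    """No admissible (pre, post) pair was found within the attempt budget."""


def decay_traces(traces: np.ndarray | float, dt: float, tau: float = 10.0) -> np.ndarray | float:
    """One Euler decay step of spike traces: s <- s (1 - dt/tau)."""
    return traces * (1.0 - dt / tau)


def stdp_on_post_spike(w: np.ndarray | float, s_pre: np.ndarray | float, cfg: PlasticityConfig):
    """Potentiation at a postsynaptic spike: w + lambda (1-w) s_j, clipped to [0, 1]."""
    return np.clip(w + cfg.lambda_rate * (1.0 - w) * s_pre, 0.0, 1.0)


def stdp_on_pre_arrival(w: np.ndarray | float, s_post: np.ndarray | float, cfg: PlasticityConfig):
    """Depression at a delayed presynaptic arrival: w - lambda alpha w s_i, clipped."""
    return np.clip(w - cfg.lambda_rate * cfg.alpha * w * s_post, 0.0, 1.0)


def sample_presynaptic_by_distance(
    post_pos: np.ndarray,
    candidate_pos: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    candidate_ids: np.ndarray | None = None,
    exclusions: set[int] | None = None,
) -> int:
    """Draw one presynaptic neuron with probability ~ exp(-d^2/2 sigma^2).

    ``d`` is the distance from each candidate to ``post_pos``.  Candidates
    listed in ``exclusions`` (by id) are inadmissible; an empty admissible
    set raises ``ValueError``.
    """
    candidate_pos = np.asarray(candidate_pos, dtype=float)
    if candidate_ids is None:
        candidate_ids = np.arange(len(candidate_pos))
    candidate_ids = np.asarray(candidate_ids)
    if exclusions:
        keep = ~np.isin(candidate_ids, list(exclusions))
        candidate_pos = candidate_pos[keep]
        candidate_ids = candidate_ids[keep]
    if len(candidate_ids) == 0:
        raise ValueError("no admissible presynaptic candidate")
    d2 = np.sum((candidate_pos - np.asarray(post_pos, dtype=float)) ** 2, axis=1)
    logw = -(d2 - d2.min()) / (2.0 * sigma * sigma)
    p = np.exp(logw)
    p /= p.sum()
    return int(candidate_ids[rng.choice(len(candidate_ids), p=p)])


def prune_and_rewire(
    net: Network,
    cfg: PlasticityConfig,
    t: float,
    rng: np.random.Generator,
    conduction_velocity: float = 50.0,
    dt: float = 0.5,
) -> list[dict]:
    """One structural-plasticity sweep at simulation time ``t`` (seconds).

    Updates the weak-since bookkeeping of every synapse, removes synapses
    that have been weak for at least ``t_w`` seconds, and replaces each
    removal in place by a newborn connection (so the synapse count is
    conserved).  The postsynaptic neuron of a newborn connection is uniform
    random; the presynaptic neuron is drawn with the Gaussian distance
    weight.  In single-connection mode a candidate that duplicates an
    existing pair triggers a full redraw, up to ``max_rewire_attempts``.

    Returns the change log: a list of dicts with keys
    ``t_s, event, pre_id, post_id, weight`` (event is 'removed' or
    'created'), in the order the events were applied.  The network is
    modified in place.
    """
    sigma = cfg.sigma if cfg.sigma is not None else net.sigma
    weak = net.w < cfg.w_min
    newly_weak = weak & np.isnan(net.weak_since)
    net.weak_since[newly_weak] = t
    net.weak_since[~weak] = np.nan
    prune = weak & ((t - net.weak_since) >= cfg.t_w)
    changes: list[dict] = []
    if not np.any(prune):
        return changes

    n = net.n_neurons
    existing = net.existing_pairs() if net.multiplicity == "single" else set()
    for idx in np.nonzero(prune)[0]:
        changes.append(
            {
                "t_s": t,
                "event": "removed",
                "pre_id": int(net.pre[idx]),
                "post_id": int(net.post[idx]),
                "weight": float(net.w[idx]),
            }
        )
        if net.multiplicity == "single":
            existing.discard((int(net.pre[idx]), int(net.post[idx])))
        for _ in range(cfg.max_rewire_attempts):
            post = int(rng.integers(n))
            pre = sample_presynaptic_by_distance(
                net.pos[post], net.pos, sigma, rng, exclusions={post}
            )
            if net.multiplicity == "single" and (pre, post) in existing:
                continue
            break
        else:
            raise RewireSaturationError(
                f"no admissible (pre, post) pair found in {cfg.max_rewire_attempts} "
                f"attempts at t={t} s (network saturated)"
            )
        dist = float(np.linalg.norm(net.pos[post] - net.pos[pre]))
        net.replace_synapse(
            int(idx), pre, post, cfg.w_new, delay_from_distance(dist, conduction_velocity, dt), t_s=t
        )
        if net.multiplicity == "single":
            existing.add((pre, post))
        changes.append(
            {"t_s": t, "event": "created", "pre_id": pre, "post_id": post, "weight": cfg.w_new}
        )
    return changes


def pair_protocol(
    pre_arrival_ms: np.ndarray,
    post_spike_ms: np.ndarray,
    cfg: PlasticityConfig,
    dt: float = 0.5,
    w0: float = 0.5,
    record: bool = False,
):
    """Evolve one synapse's weight under imposed pre/post spike trains.

    ``pre_arrival_ms`` are the times at which the presynaptic spike reaches
    the synapse (i.e. already including the axonal delay); ``post_spike_ms``
    are the postsynaptic spike times.  Times are snapped to the integration
    grid.  The update ordering per step matches the simulation engine:
    depression on arrival is applied before potentiation on a coincident
    postsynaptic spike, trace increments happen at the end of the step, and
    traces decay once per step.  Trace decay between events is applied in
    closed form, (1 - dt/tau)^k, which reproduces the per-step Euler loop
    exactly.

    Returns the final weight, or (times_ms, weights) arrays when ``record``.
    """
    pre_steps = np.unique(np.round(np.asarray(pre_arrival_ms, dtype=float) / dt).astype(np.int64))
    post_steps = np.unique(np.round(np.asarray(post_spike_ms, dtype=float) / dt).astype(np.int64))
    events = np.union1d(pre_steps, post_steps)
    pre_set = set(pre_steps.tolist())
    post_set = set(post_steps.tolist())
    decay = 1.0 - dt / cfg.tau_trace
    s_pre = 0.0
    s_post = 0.0
    w = float(w0)
    last = None
    ts, ws = [], []
    for k in events.tolist():
        if last is not None:
            f = decay ** (k - last)
            s_pre *= f
            s_post *= f
        is_arr = k in pre_set
        is_spk = k in post_set
        if is_arr:
            w = float(stdp_on_pre_arrival(w, s_post, cfg))
        if is_spk:
            w = float(stdp_on_post_spike(w, s_pre, cfg))
        # end-of-step increments (pre-increment trace values were used above)
        if is_arr:
            s_pre += 1.0
        if is_spk:
            s_post += 1.0
        last = k
        if record:
            ts.append(k * dt)
            ws.append(w)
    if record:
        return np.array(ts), np.array(ws)
    return w
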