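"""Short-term synaptic plasticity and delayed spike propagation.

Each synapse carries a Tsodyks-Markram neurotransmitter model: fractions
``x`` (restored), ``y`` (active) and ``z`` (inactivated) with x+y+z = 1,
plus a facilitating release fraction ``u*``.  Between presynaptic spikes

    dy/dt = -y/tau_I          (active -> inactivated)
    dz/dt =  y/tau_I - z/tau_rec
    dx/dt =  z/tau_rec        (inactivated -> restored)
    du*/dt = -u*/tau_facil

and when a presynaptic spike arrives (after the axonal delay) the release
fraction facilitates first, u* <- u* + 0.5 (1 - u*), then a quantum
delta = u* x is released: x <- x - delta, y <- y + delta.

The postsynaptic current is the weighted sum g_j w_ij y_ij over afferent
synapses, with g signed by the presynaptic cell type.

Default time constants (tau_I = 10 ms, tau_rec = 50 ms, tau_facil =
1000 ms) put the synapse in a regime showing depression under
high-frequency drive and facilitation near 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "TMState",
    "step_synapse_tm",
    "synaptic_current",
    "synaptic_currents",
    "DelayBuffer",
    "DelayBufferOverflow",
]


@dataclass(frozen=True)
class SynapseParams:
    """Time constants (ms) and release increment of the transmitter model."""

    tau_I: float = 10.0
    tau_rec: float = 50.0
    tau_facil: float = 1000.0
    release_increment: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_I", "tau_rec", "tau_facil"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.release_increment <= 1.0:
            raise ValueError("release_increment must be in (0, 1]")


@dataclass
class TMState:
    """Neurotransmitter pools of one synapse (x + y + z = 1)."""

    x: float = 1.0
    y: float = 0.0
    z: float = 0.0
    u_star: float = 0.0


def step_synapse_tm(
    state: TMState,
    params: SynapseParams,
    dt: float,
    spike_arrived: bool = False,
) -> TMState:
    """Advance the transmitter pools of one synapse by one Euler step.

    The continuous relaxation is integrated first; if a (delayed)
    presynaptic spike arrives during this step, facilitation of ``u*``
    precedes the release event.  The conservation x + y + z = 1 holds by
    construction up to round-off.
    """
    x, y, z, us = state.x, state.y, state.z, state.u_star
    x_new = x + dt * (z / params.tau_rec)
    y_new = y + dt * (-y / params.tau_I)
    z_new = z + dt * (y / params.tau_I - z / params.tau_rec)
    us_new = us + dt * (-us / params.tau_facil)
    if spike_arrived:
        us_new = us_new + params.release_increment * (1.0 - us_new)
        delta = us_new * x_new
        x_new -= delta
        y_new += delta
    return TMState(x=x_new, y=y_new, z=z_new, u_star=us_new)


def synaptic_current(g: np.ndarray | float, w: np.ndarray | float, y: np.ndarray | float) -> float:
    """Current onto one postsynaptic neuron: sum_j g_j w_ij y_ij.

    ``g``, ``w`` and ``y`` are aligned arrays over the afferent synapses of
    that neuron (scalars for a single synapse); an empty set gives 0.
    """
    return float(np.sum(np.asarray(g, dtype=float) * np.asarray(w, dtype=float) * np.asarray(y, dtype=float)))


def synaptic_currents(
    post: np.ndarray,
    g_pre: np.ndarray,
    w: np.ndarray,
    y: np.ndarray,
    n_neurons: int,
) -> np.ndarray:
    """Synaptic current for every neuron of a network at once."""
    if len(post) == 0:
        return np.zeros(n_neurons)
    return np.bincount(post, weights=g_pre * w * y, minlength=n_neurons)


class DelayBufferOverflow(RuntimeError):
    """A spike was scheduled beyond the ring buffer horizon."""


class DelayBuffer:
    """Ring buffer delivering presynaptic spikes after integer-step delays.

    A spike emitted by neuron j at step t is applied to synapse (i, j) at
    step t + delay_steps exactly: no event is lost or duplicated.  The
    buffer spans ``max_delay_steps`` steps; scheduling past that horizon
    raises :class:`DelayBufferOverflow`.
    """

    def __init__(self, n_synapses: int, max_delay_steps: int):
        if max_delay_steps < 1:
            raise ValueError("max_delay_steps must be >= 1")
        self.length = int(max_delay_steps) + 1
        self.buf = np.zeros((self.length, n_synapses), dtype=bool)

    def schedule(self, syn_indices: np.ndarray, delay_steps: np.ndarray, t_step: int) -> None:
        delay_steps = np.asarray(delay_steps)
        if np.any(delay_steps < 1):
            raise ValueError("delays must be at least one step")
        if np.any(delay_steps >= self.length):
            raise DelayBufferOverflow(
                f"delay of {int(delay_steps.max())} steps exceeds buffer horizon "
                f"of {self.length - 1} steps"
            )
        self.buf[(t_step + delay_steps) % self.length, syn_indices] = True

    def pop(self, t_step: int) -> np.ndarray:
        """Arrival flags per synapse for step ``t_step`` (cleared on read)."""
        row = t_step % self.length
        arrived = self.buf[row].copy()
        self.buf[row] = False
        return arrived

    def clear_synapse(self, syn_index: int) -> None:
        """Drop pending arrivals of one synapse (used when it is rewired)."""
        self.buf[:, syn_index] = False
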