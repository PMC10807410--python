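"""Izhikevich point-neuron dynamics with reset, noise, and pulse stimulation.

The membrane potential ``v`` (mV) and recovery variable ``u`` of each neuron
follow the two-variable quadratic model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I(t)
    du/dt = a (b v - u)

with the after-spike reset ``v <- c``, ``u <- u + d`` whenever ``v`` reaches
the +30 mV spike peak.  With the regular-spiking parameter set used
throughout this package (a=0.02, b=0.2, c=-65, d=8) the resting state
(v, u) = (-70, -14) is a stable fixed point and sustained input produces
regular spiking.

The total input current is the sum of three terms: uncorrelated Gaussian
noise (drawn independently per neuron per integration step with standard
deviation ``D``), the synaptic current, and an optional pulsed stimulation
current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "V_PEAK",
    "NeuronParams",
    "NeuronState",
    "SimulationConfig",
    "StimulusProtocol",
    "step_neuron",
    "stimulus_current",
    "external_current",
]

#: Spike-peak threshold (mV) at which the after-spike reset is applied.
V_PEAK = 30.0


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters plus the synaptic transformation coefficient.

    ``g`` converts the synaptic output signal (active neurotransmitter
    fraction) into a current; it is positive for excitatory and negative
    for inhibitory presynaptic neurons.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    g_excitatory: float = 20.0
    g_inhibitory: float = -20.0

    def g(self, excitatory: bool) -> float:
        return self.g_excitatory if excitatory else self.g_inhibitory


@dataclass
class NeuronState:
    """State of one point neuron.

    ``s_post`` is the postsynaptic spike trace used by the timing-dependent
    plasticity rule (it is incremented by 1 at each spike of this neuron and
    decays with time constant ``tau_trace``).  ``last_spike_ms`` is ``None``
    until the neuron has fired.
    """

    v: float = -70.0
    u: float = -14.0
    pos: tuple[float, float] = (0.0, 0.0)
    excitatory: bool = True
    s_post: float = 0.0
    last_spike_ms: float | None = None


@dataclass
class SimulationConfig:
    """Global integration settings.

    dt : forward-Euler time step in ms (default 0.5 ms).
    duration : total simulated time in seconds.
    noise_sd : standard deviation D of the per-step Gaussian noise current.
    conduction_velocity : axonal conduction speed (um/ms) used to turn
        connection lengths into spike-arrival delays.
    """

    dt: float = 0.5
    duration: float = 1.0
    noise_sd: float = 5.5
    seed: int = 0
    record_spikes: bool = True
    conduction_velocity: float = 50.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


@dataclass
class StimulusProtocol:
    """Pulsed current stimulation of a set of target neurons.

    Pulses of ``pulse_width`` ms at ``frequency`` Hz are delivered between
    ``start`` and ``stop`` (seconds).  The default amplitude of 40 (arb.
    current units) is comfortably suprathreshold ("sufficient to excite"):
    a noise-free resting regular-spiking neuron fires on every pulse.
    """

    target_neuron_ids: tuple[int, ...] = ()
    frequency: float = 10.0
    pulse_width: float = 3.0
    amplitude: float = 40.0
    start: float = 0.0
    stop: float = math.inf

    def __post_init__(self) -> None:
        self.target_neuron_ids = tuple(int(i) for i in self.target_neuron_ids)
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency

    def pulse_active(self, t_ms: float) -> bool:
        """True when a stimulation pulse is on at time ``t_ms``."""
        start_ms = self.start * 1000.0
        stop_ms = self.stop * 1000.0
        if t_ms < start_ms or t_ms >= stop_ms:
            return False
        return (t_ms - start_ms) % self.period_ms < self.pulse_width

    def amplitude_at(self, t_ms: float, neuron_id: int) -> float:
        if neuron_id not in self.target_neuron_ids:
            return 0.0
        return self.amplitude if self.pulse_active(t_ms) else 0.0

    def amplitude_trace(self, step0: int, n_steps: int, dt: float) -> np.ndarray:
        """Pulse amplitude for target neurons at each of ``n_steps`` steps."""
        t_ms = (step0 + np.arange(n_steps)) * dt
        start_ms = self.start * 1000.0
        stop_ms = self.stop * 1000.0
        active = (t_ms >= start_ms) & (t_ms < stop_ms)
        phase = np.mod(t_ms - start_ms, self.period_ms)
        return np.where(active & (phase < self.pulse_width), self.amplitude, 0.0)


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    I_total: float,
    dt: float,
    t_ms: float | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one forward-Euler step of ``dt`` ms.

    Returns the updated state and a flag indicating whether the neuron
    reached the +30 mV spike peak during this step (in which case the reset
    ``v <- c``, ``u <- u + d`` has been applied and the spike time recorded).

    Raises ``FloatingPointError`` on non-finite state or input, signalling
    numerical blow-up: the caller must reduce dt or the input current.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(I_total)):
        raise FloatingPointError(
            f"non-finite neuron state or input (v={state.v}, u={state.u}, I={I_total})"
        )
    v, u = state.v, state.u
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I_total)
    u_new = u + dt * (params.a * (params.b * v - u))
    if not (math.isfinite(v_new) and math.isfinite(u_new)):
        raise FloatingPointError("neuron integration diverged; reduce dt or inputs")
    spiked = v_new >= V_PEAK
    if spiked:
        v_new = params.c
        u_new = u_new + params.d
    out = replace(
        state,
        v=v_new,
        u=u_new,
        last_spike_ms=(t_ms if (spiked and t_ms is not None) else state.last_spike_ms),
    )
    return out, bool(spiked)


def stimulus_current(t_ms: float, stim: StimulusProtocol | None, neuron_id: int) -> float:
    """Pulsed stimulation current for one neuron at time ``t_ms``."""
    if stim is None:
        return 0.0
    return stim.amplitude_at(t_ms, neuron_id)


def external_current(
    t_ms: float,
    stim: StimulusProtocol | None,
    rng: np.random.Generator,
    noise_sd: float,
    I_syn: float,
    neuron_id: int = 0,
) -> float:
    """Total external current: noise + synaptic + stimulation.

    The noise term is one Gaussian draw of standard deviation ``noise_sd``
    (one draw per neuron per step; it enters the Euler update as a current).
    """
    xi = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return xi + I_syn + stimulus_current(t_ms, stim, neuron_id)
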