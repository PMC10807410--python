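"""Ready-made experiment configurations.

Each preset returns ``(network, sim_config, stimulus, plasticity_config)``
for one of the reference scenarios:

* ``line-stim``: 1-D line with bidirectional nearest-neighbour synapses
  (w = 0.3), centre neuron stimulated at 10 Hz; rewiring with
  w_min = 0.05, t_w = 5 s, w_new = 0.1.
* ``radial-stim``: concentric rings with radial and tangential synapses,
  centre stimulated; rewiring with w_min = 0.2, t_w = 5 s, w_new = 0.05.
* ``planar-stim``: random planar culture-like network with one stimulated
  neuron near the centre; rewiring with w_min = 0.05, t_w = 100 s,
  w_new = 0.1.
* ``planar-spontaneous``: the same planar network driven by noise only;
  rewiring with w_min = 0.05, t_w = 5 s, w_new = 0.06.
"""

from __future__ import annotations

import numpy as np

from .core_dynamics import SimulationConfig, StimulusProtocol
from .plasticity import PlasticityConfig
from .topology import Network, build_line_1d, build_radial_2d, build_random_planar

__all__ = ["PRESETS", "make_preset"]


def _line(seed: int, n: int = 21, **kw):
    net = build_line_1d(n=n)
    sim = SimulationConfig(seed=seed, **kw)
    stim = StimulusProtocol(target_neuron_ids=(n // 2,))
    plast = PlasticityConfig(w_min=0.05, t_w=5.0, w_new=0.1)
    return net, sim, stim, plast


def _radial(seed: int, rings: int = 3, spokes: int = 8, **kw):
    net = build_radial_2d(rings=rings, spokes=spokes)
    sim = SimulationConfig(seed=seed, **kw)
    stim = StimulusProtocol(target_neuron_ids=(0,))
    plast = PlasticityConfig(w_min=0.2, t_w=5.0, w_new=0.05)
    return net, sim, stim, plast


def _planar_stim(seed: int, n: int = 200, **kw):
    net = build_random_planar(n=n, substrate=(500.0, 500.0), rng=seed)
    sim = SimulationConfig(seed=seed, **kw)
    centre = np.array(net.substrate) / 2.0
    target = int(np.argmin(np.linalg.norm(net.pos - centre, axis=1)))
    stim = StimulusProtocol(target_neuron_ids=(target,))
    plast = PlasticityConfig(w_min=0.05, t_w=100.0, w_new=0.1)
    return net, sim, stim, plast


def _planar_spont(seed: int, n: int = 200, **kw):
    net = build_random_planar(n=n, substrate=(500.0, 500.0), rng=seed)
    sim = SimulationConfig(seed=seed, **kw)
    plast = PlasticityConfig(w_min=0.05, t_w=5.0, w_new=0.06)
    return net, sim, None, plast


PRESETS = {
    "line-stim": _line,
    "radial-stim": _radial,
    "planar-stim": _planar_stim,
    "planar-spontaneous": _planar_spont,
}


def make_preset(name: str, seed: int = 0, **kwargs):
    """Build (network, sim, stimulus, plasticity) for a named preset."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return factory(seed, **kwargs)
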