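"""Wiring, weight and activity vector fields on an N x N grid.

Every synapse from presynaptic position p_j to postsynaptic position p_i
defines a connection vector

    c_ij = l_ij (p_i - p_j) / ||p_i - p_j||

anchored on the segment [p_j, p_i].  The substrate is divided into an
N x N grid of closed rectangular cells; the field value of cell (k, m) is
the sum of the connection vectors of all synapses whose segment has a
non-empty intersection with that cell (each synapse contributes its full
vector to every crossed cell).  Antiparallel connections through the same
cell cancel.

The magnitude l_ij depends on the field kind:

* wiring  : l_ij = 1 for every existing synapse (anatomical connectome),
* weight  : l_ij = w_ij (synaptic connectome),
* activity: l_ij follows dl/dt = s_j delta(t - t_sp_i) - l/tau_l, i.e. it
  integrates presynaptic trace values at postsynaptic spike times and
  relaxes with tau_l (functional connectome).

Cell rectangles are closed sets: a segment that only touches a cell
boundary (or corner) is counted for every adjacent cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .topology import Network

__all__ = [
    "VectorField",
    "connection_vector",
    "cells_crossed",
    "accumulate_field",
    "wiring_lengths",
    "weight_lengths",
    "activity_lengths",
    "step_activity_lengths",
    "wiring_field",
    "weight_field",
    "activity_field",
    "field_to_csv",
    "field_from_csv",
    "quiver_plot",
]


@dataclass
class VectorField:
    """N x N grid of resultant 2-D vectors.

    ``vectors[k, m]`` is the resultant of cell (k, m), with k the column
    index along x and m the row index along y; cell (0, 0) touches the
    substrate origin corner.
    """

    vectors: np.ndarray
    kind: str
    substrate: tuple[float, float]
    grid_n: int
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (self.grid_n, self.grid_n, 2):
            raise ValueError(
                f"vectors must have shape ({self.grid_n}, {self.grid_n}, 2), "
                f"got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vector field entries must be finite")

    def cell_centres(self) -> np.ndarray:
        """(N, N, 2) array of cell-centre coordinates."""
        W, H = self.substrate
        N = self.grid_n
        cx = (np.arange(N) + 0.5) * (W / N)
        cy = (np.arange(N) + 0.5) * (H / N)
        out = np.empty((N, N, 2))
        out[..., 0] = cx[:, None]
        out[..., 1] = cy[None, :]
        return out

    def __neg__(self) -> "VectorField":
        return VectorField(-self.vectors, self.kind, self.substrate, self.grid_n, self.timestamp)


def connection_vector(pre_pos, post_pos, l: float) -> np.ndarray:
    """Vector of magnitude ``l`` pointing from the pre to the post neuron."""
    pre_pos = np.asarray(pre_pos, dtype=float)
    post_pos = np.asarray(post_pos, dtype=float)
    diff = post_pos - pre_pos
    norm = float(np.linalg.norm(diff))
    if norm == 0.0:
        raise ValueError("pre and post positions coincide; direction undefined")
    return (l / norm) * diff


def _cells_crossed_one(p0: np.ndarray, p1: np.ndarray, grid_n: int, substrate) -> list[tuple[int, int]]:
    """Closed-rectangle segment/cell intersection by interval clipping.

    For each candidate cell the segment parameter interval [0, 1] is
    clipped against the cell's closed slab on each axis; the intersection
    is non-empty iff t_enter <= t_exit (equality = boundary touch, which
    counts for every adjacent cell).
    """
    W, H = substrate
    cw = W / grid_n
    ch = H / grid_n
    # candidate index ranges from the bounding box, padded by one cell to
    # cover exact boundary touches
    k_lo = max(int(math.floor(min(p0[0], p1[0]) / cw)) - 1, 0)
    k_hi = min(int(math.floor(max(p0[0], p1[0]) / cw)) + 1, grid_n - 1)
    m_lo = max(int(math.floor(min(p0[1], p1[1]) / ch)) - 1, 0)
    m_hi = min(int(math.floor(max(p0[1], p1[1]) / ch)) + 1, grid_n - 1)
    d = p1 - p0
    out = []
    for k in range(k_lo, k_hi + 1):
        x0, x1 = k * cw, (k + 1) * cw
        for m in range(m_lo, m_hi + 1):
            y0, y1 = m * ch, (m + 1) * ch
            t_enter, t_exit = 0.0, 1.0
            ok = True
            for lo, hi, o, dd in ((x0, x1, p0[0], d[0]), (y0, y1, p0[1], d[1])):
                if dd == 0.0:
                    if o < lo or o > hi:
                        ok = False
                        break
                else:
                    ta = (lo - o) / dd
                    tb = (hi - o) / dd
                    if ta > tb:
                        ta, tb = tb, ta
                    t_enter = max(t_enter, ta)
                    t_exit = min(t_exit, tb)
            if ok and t_enter <= t_exit:
                out.append((k, m))
    return out


def cells_crossed(p0, p1, grid_n: int, substrate) -> set[tuple[int, int]]:
    """Grid cells whose closed rectangle intersects the segment [p0, p1]."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    return set(_cells_crossed_one(p0, p1, grid_n, substrate))


def accumulate_field(
    net: Network,
    lengths: np.ndarray,
    grid_n: int = 20,
    kind: str = "custom",
    timestamp: float = 0.0,
) -> VectorField:
    """Sum connection vectors into the cells their segments cross.

    ``lengths`` gives l_ij per synapse; synapses with l_ij = 0 contribute a
    zero vector and are skipped.  The result is linear in the synapse set.
    """
    lengths = np.asarray(lengths, dtype=float)
    if len(lengths) != net.n_synapses:
        raise ValueError("lengths must be defined for every synapse")
    vectors = np.zeros((grid_n, grid_n, 2))
    for j in range(net.n_synapses):
        l = lengths[j]
        if l == 0.0:
            continue
        p_pre = net.pos[net.pre[j]]
        p_post = net.pos[net.post[j]]
        c = connection_vector(p_pre, p_post, l)
        for k, m in _cells_crossed_one(p_pre, p_post, grid_n, net.substrate):
            vectors[k, m] += c
    return VectorField(vectors, kind, tuple(net.substrate), grid_n, timestamp)


def wiring_lengths(net: Network) -> np.ndarray:
    """l_ij = 1 for every existing synapse (anatomical connectome)."""
    return np.ones(net.n_synapses)


def weight_lengths(net: Network) -> np.ndarray:
    """l_ij = current synaptic weight (synaptic connectome)."""
    return net.w.copy()


def activity_lengths(net: Network) -> np.ndarray:
    """Current activity traces l_ij (functional connectome)."""
    return net.l_act.copy()


def step_activity_lengths(
    l: np.ndarray,
    post_spiked: np.ndarray,
    s_pre: np.ndarray,
    post: np.ndarray,
    dt: float,
    tau_l: float = 1000.0,
) -> np.ndarray:
    """One update of the activity traces.

    Every trace decays by (1 - dt/tau_l); synapses whose postsynaptic
    neuron spiked this step gain their current presynaptic trace value,
    l_ij <- l_ij + s_j.  A postsynaptic spike with a silent presynaptic
    partner (s_j = 0) therefore leaves the trace unchanged.
    """
    l = np.asarray(l, dtype=float) * (1.0 - dt / tau_l)
    fired = np.asarray(post_spiked, dtype=bool)[np.asarray(post)]
    return l + np.where(fired, np.asarray(s_pre, dtype=float), 0.0)


def wiring_field(net: Network, grid_n: int = 20, timestamp: float = 0.0) -> VectorField:
    return accumulate_field(net, wiring_lengths(net), grid_n, "wiring", timestamp)


def weight_field(net: Network, grid_n: int = 20, timestamp: float = 0.0) -> VectorField:
    return accumulate_field(net, weight_lengths(net), grid_n, "weight", timestamp)


def activity_field(net: Network, grid_n: int = 20, timestamp: float = 0.0) -> VectorField:
    return accumulate_field(net, activity_lengths(net), grid_n, "activity", timestamp)


FIELD_BUILDERS = {"wiring": wiring_field, "weight": weight_field, "activity": activity_field}


def field_to_csv(f: VectorField, path) -> None:
    """Write a field as CSV ``k,m,cx,cy`` (row-major) plus a JSON sidecar."""
    import pandas as pd

    N = f.grid_n
    kk, mm = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    pd.DataFrame(
        {
            "k": kk.ravel(),
            "m": mm.ravel(),
            "cx": f.vectors[..., 0].ravel(),
            "cy": f.vectors[..., 1].ravel(),
        }
    ).to_csv(path, index=False)
    sidecar = {
        "kind": f.kind,
        "grid_n": f.grid_n,
        "timestamp_s": f.timestamp,
        "substrate": list(f.substrate),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True)


def field_from_csv(path) -> VectorField:
    import pandas as pd

    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    N = int(meta["grid_n"])
    vectors = np.zeros((N, N, 2))
    vectors[df["k"], df["m"], 0] = df["cx"]
    vectors[df["k"], df["m"], 1] = df["cy"]
    return VectorField(vectors, meta["kind"], tuple(meta["substrate"]), N, meta["timestamp_s"])


def quiver_plot(f: VectorField, ax=None, **kwargs):
    """Minimal quiver rendering of a field (plotting is not part of the
    computational surface; scaling/normalization is left to matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centres = f.cell_centres()
    ax.quiver(
        centres[..., 0], centres[..., 1], f.vectors[..., 0], f.vectors[..., 1], **kwargs
    )
    ax.set_xlim(0, f.substrate[0])
    ax.set_ylim(0, f.substrate[1])
    ax.set_aspect("equal")
    return ax
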