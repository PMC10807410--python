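"""Network container and builders for the three substrate architectures.

A :class:`Network` stores neurons and directed synapses as flat arrays
(struct-of-arrays), which is what the simulation engine iterates over.
Builders are provided for

* a 1-D line of neurons with bidirectional nearest-neighbour synapses,
* a radial 2-D circuit (concentric rings around a centre, with radial and
  tangential connections), and
* a random planar network in which neurons are scattered uniformly over a
  rectangular substrate and wired with a distance-dependent Gaussian rule:
  the probability of selecting a presynaptic partner at distance d is
  proportional to exp(-d^2 / 2 sigma^2).

``calibrate_sigma`` chooses sigma numerically so that the expected length
of a sampled connection matches a target (50 um in the reference
configuration).  Because the Gaussian acts as a selection weight over the
discrete realized positions, the expected length depends on local density,
so a closed form for sigma does not exist.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Network",
    "SnapshotFormatError",
    "delay_from_distance",
    "build_line_1d",
    "build_radial_2d",
    "build_random_planar",
    "calibrate_sigma",
    "expected_connection_length",
]

_SIGN = {True: "exc", False: "inh"}


class SnapshotFormatError(ValueError):
    """A serialized network is malformed; the message names the first offending field."""


def delay_from_distance(distance_um: np.ndarray | float, conduction_velocity: float = 50.0, dt: float = 0.5) -> np.ndarray | float:
    """Axonal delay (ms): distance / velocity, rounded up to a multiple of dt.

    Delays are proportional to connection length and never shorter than one
    integration step.
    """
    d = np.asarray(distance_um, dtype=float)
    delay = np.ceil(d / conduction_velocity / dt) * dt
    delay = np.maximum(delay, dt)
    return float(delay) if np.isscalar(distance_um) or d.ndim == 0 else delay


@dataclass
class Network:
    """Neurons, synapses and substrate geometry of one spiking network.

    Neuron arrays have length ``n_neurons``; synapse arrays have length
    ``n_synapses``.  ``noise_key`` gives each neuron a persistent identity
    in the noise stream so that relabelling neurons permutes, rather than
    scrambles, their noise histories.  ``weak_since`` is the simulation
    time (s) at which a synapse's weight was first observed below the
    pruning threshold, or NaN while it is not weak.
    """

    pos: np.ndarray
    excitatory: np.ndarray
    substrate: tuple[float, float]
    pre: np.ndarray
    post: np.ndarray
    w: np.ndarray
    delay_ms: np.ndarray
    multiplicity: str = "single"
    sigma: float = 50.0
    noise_key: np.ndarray | None = None
    # neuron state
    v: np.ndarray | None = None
    u: np.ndarray | None = None
    s_post: np.ndarray | None = None
    last_spike_ms: np.ndarray | None = None
    # synapse state
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    z: np.ndarray | None = None
    u_star: np.ndarray | None = None
    s_pre: np.ndarray | None = None
    l_act: np.ndarray | None = None
    weak_since: np.ndarray | None = None
    birth_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.pos)
        m = len(self.pre)
        self.pos = np.asarray(self.pos, dtype=float).reshape(n, 2)
        self.excitatory = np.asarray(self.excitatory, dtype=bool)
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float)
        self.delay_ms = np.asarray(self.delay_ms, dtype=float)
        if self.multiplicity not in ("single", "multiple"):
            raise ValueError("multiplicity must be 'single' or 'multiple'")
        if self.noise_key is None:
            self.noise_key = np.arange(n, dtype=np.uint32)
        else:
            self.noise_key = np.asarray(self.noise_key, dtype=np.uint32)
        defaults = {
            "v": np.full(n, -70.0),
            "u": np.full(n, -14.0),
            "s_post": np.zeros(n),
            "last_spike_ms": np.full(n, -np.inf),
            "x": np.ones(m),
            "y": np.zeros(m),
            "z": np.zeros(m),
            "u_star": np.zeros(m),
            "s_pre": np.zeros(m),
            "l_act": np.zeros(m),
            "weak_since": np.full(m, np.nan),
            "birth_time": np.zeros(m),
        }
        for name, default in defaults.items():
            cur = getattr(self, name)
            if cur is None:
                setattr(self, name, default)
            else:
                setattr(self, name, np.asarray(cur, dtype=float))

    # ------------------------------------------------------------------ basic
    @property
    def n_neurons(self) -> int:
        return len(self.pos)

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def lengths(self) -> np.ndarray:
        """Euclidean length (um) of every synapse."""
        return np.linalg.norm(self.pos[self.post] - self.pos[self.pre], axis=1)

    def copy(self) -> "Network":
        return Network(
            pos=self.pos.copy(),
            excitatory=self.excitatory.copy(),
            substrate=tuple(self.substrate),
            pre=self.pre.copy(),
            post=self.post.copy(),
            w=self.w.copy(),
            delay_ms=self.delay_ms.copy(),
            multiplicity=self.multiplicity,
            sigma=self.sigma,
            noise_key=self.noise_key.copy(),
            v=self.v.copy(),
            u=self.u.copy(),
            s_post=self.s_post.copy(),
            last_spike_ms=self.last_spike_ms.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            z=self.z.copy(),
            u_star=self.u_star.copy(),
            s_pre=self.s_pre.copy(),
            l_act=self.l_act.copy(),
            weak_since=self.weak_since.copy(),
            birth_time=self.birth_time.copy(),
        )

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on the first violation."""
        W, H = self.substrate
        if np.any(self.pos[:, 0] < 0) or np.any(self.pos[:, 0] > W) or np.any(
            self.pos[:, 1] < 0
        ) or np.any(self.pos[:, 1] > H):
            raise ValueError("neuron positions must lie inside the substrate")
        if np.any(self.pre == self.post):
            raise ValueError("self-loop synapse found")
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("synaptic weights must lie in [0, 1]")
        if self.multiplicity == "single":
            pairs = set(zip(self.pre.tolist(), self.post.tolist()))
            if len(pairs) != self.n_synapses:
                raise ValueError("duplicate (pre, post) pair in single-connection mode")
        if np.any(np.abs(self.x + self.y + self.z - 1.0) > 1e-6):
            raise ValueError("transmitter pools must satisfy x + y + z = 1")

    def existing_pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.pre.tolist(), self.post.tolist()))

    def replace_synapse(
        self,
        index: int,
        pre: int,
        post: int,
        w: float,
        delay_ms: float,
        t_s: float = 0.0,
    ) -> None:
        """Overwrite synapse ``index`` with a newborn connection (fresh state)."""
        self.pre[index] = pre
        self.post[index] = post
        self.w[index] = w
        self.delay_ms[index] = delay_ms
        self.x[index] = 1.0
        self.y[index] = 0.0
        self.z[index] = 0.0
        self.u_star[index] = 0.0
        self.s_pre[index] = 0.0
        self.l_act[index] = 0.0
        self.weak_since[index] = np.nan
        self.birth_time[index] = t_s

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        def opt(val: float) -> float | None:
            return None if not math.isfinite(val) else float(val)

        neurons = [
            {
                "id": i,
                "x": float(self.pos[i, 0]),
                "y": float(self.pos[i, 1]),
                "sign": _SIGN[bool(self.excitatory[i])],
                "noise_key": int(self.noise_key[i]),
                "v": float(self.v[i]),
                "u": float(self.u[i]),
                "s_post": float(self.s_post[i]),
                "last_spike_ms": opt(self.last_spike_ms[i]),
            }
            for i in range(self.n_neurons)
        ]
        synapses = [
            {
                "pre": int(self.pre[j]),
                "post": int(self.post[j]),
                "w": float(self.w[j]),
                "delay_ms": float(self.delay_ms[j]),
                "x": float(self.x[j]),
                "y": float(self.y[j]),
                "z": float(self.z[j]),
                "u_star": float(self.u_star[j]),
                "s_pre": float(self.s_pre[j]),
                "l": float(self.l_act[j]),
                "weak_since_s": None if math.isnan(self.weak_since[j]) else float(self.weak_since[j]),
                "birth_s": float(self.birth_time[j]),
            }
            for j in range(self.n_synapses)
        ]
        return {
            "format": "plastinet-network",
            "version": 1,
            "substrate": [float(self.substrate[0]), float(self.substrate[1])],
            "multiplicity": self.multiplicity,
            "sigma": float(self.sigma),
            "neurons": neurons,
            "synapses": synapses,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Network":
        for key in ("format", "substrate", "multiplicity", "sigma", "neurons", "synapses"):
            if key not in data:
                raise SnapshotFormatError(f"missing required field '{key}'")
        if data["format"] != "plastinet-network":
            raise SnapshotFormatError(f"unrecognized format '{data['format']}'")

        def req(record: dict, name: str, where: str):
            if name not in record:
                raise SnapshotFormatError(f"missing required field '{where}.{name}'")
            return record[name]

        neurons = data["neurons"]
        synapses = data["synapses"]
        n, m = len(neurons), len(synapses)
        pos = np.zeros((n, 2))
        exc = np.zeros(n, dtype=bool)
        keys = np.zeros(n, dtype=np.uint32)
        v = np.zeros(n)
        u = np.zeros(n)
        s_post = np.zeros(n)
        last = np.full(n, -np.inf)
        for i, rec in enumerate(neurons):
            where = f"neurons[{i}]"
            pos[i] = (req(rec, "x", where), req(rec, "y", where))
            sign = req(rec, "sign", where)
            if sign not in ("exc", "inh"):
                raise SnapshotFormatError(f"invalid value for '{where}.sign': {sign!r}")
            exc[i] = sign == "exc"
            keys[i] = req(rec, "noise_key", where)
            v[i] = req(rec, "v", where)
            u[i] = req(rec, "u", where)
            s_post[i] = req(rec, "s_post", where)
            ls = req(rec, "last_spike_ms", where)
            last[i] = -np.inf if ls is None else ls
        cols = {name: np.zeros(m) for name in ("w", "delay_ms", "x", "y", "z", "u_star", "s_pre", "l", "birth_s")}
        pre = np.zeros(m, dtype=np.int64)
        post = np.zeros(m, dtype=np.int64)
        weak = np.full(m, np.nan)
        for j, rec in enumerate(synapses):
            where = f"synapses[{j}]"
            pre[j] = req(rec, "pre", where)
            post[j] = req(rec, "post", where)
            for name in cols:
                cols[name][j] = req(rec, name, where)
            ws = req(rec, "weak_since_s", where)
            weak[j] = np.nan if ws is None else ws
        return cls(
            pos=pos,
            excitatory=exc,
            substrate=tuple(data["substrate"]),
            pre=pre,
            post=post,
            w=cols["w"],
            delay_ms=cols["delay_ms"],
            multiplicity=data["multiplicity"],
            sigma=float(data["sigma"]),
            noise_key=keys,
            v=v,
            u=u,
            s_post=s_post,
            last_spike_ms=last,
            x=cols["x"],
            y=cols["y"],
            z=cols["z"],
            u_star=cols["u_star"],
            s_pre=cols["s_pre"],
            l_act=cols["l"],
            weak_since=weak,
            birth_time=cols["birth_s"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "Network":
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Network":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def edge_list(self):
        """Edge list as a pandas DataFrame: pre, post, weight, length_um."""
        import pandas as pd

        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "weight": self.w,
                "length_um": self.lengths(),
            }
        )


# ---------------------------------------------------------------------- builders

def build_line_1d(
    n: int,
    spacing: float = 50.0,
    w0: float = 0.3,
    margin: float = 50.0,
    conduction_velocity: float = 50.0,
    dt: float = 0.5,
    sigma: float = 50.0,
) -> Network:
    """Line of ``n`` neurons with bidirectional nearest-neighbour synapses.

    All initial weights are ``w0`` (default 0.3).  The substrate is a thin
    rectangle with ``margin`` free space around the line so that rewired
    connections remain inside it.
    """
    if n < 2:
        raise ValueError("a line network needs at least 2 neurons")
    width = spacing * (n - 1) + 2 * margin
    height = 2 * margin
    xs = margin + spacing * np.arange(n)
    pos = np.column_stack([xs, np.full(n, margin)])
    pre, post = [], []
    for i in range(n - 1):
        pre += [i, i + 1]
        post += [i + 1, i]
    pre = np.array(pre, dtype=np.int64)
    post = np.array(post, dtype=np.int64)
    d = np.linalg.norm(pos[post] - pos[pre], axis=1)
    return Network(
        pos=pos,
        excitatory=np.ones(n, dtype=bool),
        substrate=(width, height),
        pre=pre,
        post=post,
        w=np.full(len(pre), float(w0)),
        delay_ms=delay_from_distance(d, conduction_velocity, dt),
        sigma=sigma,
    )


def build_radial_2d(
    rings: int,
    spokes: int,
    ring_spacing: float = 50.0,
    w0: float = 0.3,
    margin: float = 50.0,
    conduction_velocity: float = 50.0,
    dt: float = 0.5,
    sigma: float = 50.0,
) -> Network:
    """Concentric rings of neurons around a central neuron.

    Bidirectional radial synapses run along each spoke between adjacent
    rings (and between the centre and the first ring); bidirectional
    tangential synapses connect neighbours around each ring.  The centre
    neuron has no tangential synapses.
    """
    if rings < 1:
        raise ValueError("need at least one ring")
    if spokes < 3:
        raise ValueError("need at least three spokes")
    radius = rings * ring_spacing
    size = 2 * (radius + margin)
    centre = np.array([size / 2.0, size / 2.0])
    pos = [centre]
    for r in range(1, rings + 1):
        for s in range(spokes):
            theta = 2 * math.pi * s / spokes
            pos.append(centre + r * ring_spacing * np.array([math.cos(theta), math.sin(theta)]))
    pos = np.array(pos)

    def node(r: int, s: int) -> int:
        # r = 0 is the centre
        return 0 if r == 0 else 1 + (r - 1) * spokes + (s % spokes)

    pre, post = [], []
    for r in range(1, rings + 1):
        for s in range(spokes):
            inner = node(r - 1, s)
            outer = node(r, s)
            pre += [inner, outer]
            post += [outer, inner]
    for r in range(1, rings + 1):
        for s in range(spokes):
            a = node(r, s)
            b = node(r, s + 1)
            pre += [a, b]
            post += [b, a]
    pre = np.array(pre, dtype=np.int64)
    post = np.array(post, dtype=np.int64)
    d = np.linalg.norm(pos[post] - pos[pre], axis=1)
    return Network(
        pos=pos,
        excitatory=np.ones(len(pos), dtype=bool),
        substrate=(size, size),
        pre=pre,
        post=post,
        w=np.full(len(pre), float(w0)),
        delay_ms=delay_from_distance(d, conduction_velocity, dt),
        sigma=sigma,
    )


def _distance_weights(d: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian selection weights exp(-d^2/2 sigma^2), underflow-protected."""
    d2 = d * d
    shift = np.min(d2[np.isfinite(d2)]) if d2.size else 0.0
    return np.exp(-(d2 - shift) / (2.0 * sigma * sigma))


def expected_connection_length(positions: np.ndarray, sigma: float) -> float:
    """Expected length of one sampled connection given realized positions.

    The postsynaptic neuron is uniform over all neurons; the presynaptic
    neuron is drawn among the others with weight exp(-d^2/2 sigma^2).
    Computed by exact summation over all ordered pairs.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    diff = positions[None, :, :] - positions[:, None, :]
    d = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(d, np.inf)
    total = 0.0
    for i in range(n):
        row = np.where(np.isfinite(d[i]), d[i], 0.0)
        wgt = _distance_weights(d[i], sigma)
        wgt[i] = 0.0
        total += float(np.sum(row * wgt) / np.sum(wgt))
    return total / n


def calibrate_sigma(
    positions: np.ndarray,
    mean_length_target: float,
    rng: np.random.Generator | None = None,
    rtol: float = 0.02,
    sigma_max_factor: float = 10.0,
) -> float:
    """Find sigma so that the expected connection length equals the target.

    The expectation is monotone increasing in sigma, so a bracketing root
    find suffices.  A target at or above the mean pairwise distance is
    unreachable (the sigma -> infinity limit); it is capped with a warning.
    A target below the sigma -> 0 limit (the mean nearest-neighbour
    distance) raises ``ValueError``.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        raise ValueError("need at least two positions")
    diff = positions[None, :, :] - positions[:, None, :]
    d = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(d, np.inf)
    nn_mean = float(np.mean(np.min(d, axis=1)))
    finite = d[np.isfinite(d)]
    pair_mean = float(np.mean(finite))
    d_max = float(np.max(finite))
    if n == 2:
        warnings.warn("only two positions: any sigma reproduces their separation")
        return float(d_max)
    if mean_length_target < nn_mean * (1 - rtol):
        raise ValueError(
            f"target length {mean_length_target} is below the minimum achievable "
            f"(mean nearest-neighbour distance {nn_mean:.3g})"
        )
    sigma_cap = sigma_max_factor * d_max
    if mean_length_target >= pair_mean * (1 - rtol):
        warnings.warn(
            f"target length {mean_length_target} is at or above the sigma->inf limit "
            f"({pair_mean:.3g}); returning capped sigma"
        )
        if mean_length_target > pair_mean * (1 + rtol):
            raise ValueError(
                f"target length {mean_length_target} exceeds the maximum achievable "
                f"(mean pairwise distance {pair_mean:.3g})"
            )
        return sigma_cap

    lo = max(nn_mean / 100.0, 1e-6)
    hi = sigma_cap

    def f(sig: float) -> float:
        return expected_connection_length(positions, sig) - mean_length_target

    # widen the lower bracket if needed
    while f(lo) > 0 and lo > 1e-12:
        lo /= 10.0
    sigma = float(brentq(f, lo, hi, xtol=1e-6, rtol=1e-4))
    return sigma


def build_random_planar(
    n: int,
    substrate: tuple[float, float] = (500.0, 500.0),
    mean_length_target: float = 50.0,
    k_out: float = 10.0,
    w0_dist: tuple[float, float] = (0.2, 0.4),
    rng: np.random.Generator | int | None = None,
    multiplicity: str = "single",
    inhibitory_fraction: float = 0.0,
    conduction_velocity: float = 50.0,
    dt: float = 0.5,
    sigma: float | None = None,
) -> Network:
    """Random planar network with distance-dependent Gaussian wiring.

    ``n`` neurons are placed uniformly at random on the substrate, then
    ``round(n * k_out)`` directed synapses are created: for each, the
    postsynaptic neuron is uniform and the presynaptic neuron is drawn with
    weight exp(-d^2/2 sigma^2) (no self-connections; in single mode no
    duplicated pair).  ``sigma`` defaults to the value calibrated so the
    mean connection length matches ``mean_length_target``.  Initial weights
    are uniform on ``w0_dist``.
    """
    if n < 2:
        raise ValueError("need at least 2 neurons")
    rng = np.random.default_rng(rng)
    W, H = substrate
    if min(W, H) < 4 * mean_length_target:
        warnings.warn("substrate is small relative to the target connection length; boundary effects may dominate")
    pos = np.column_stack([rng.uniform(0, W, n), rng.uniform(0, H, n)])
    exc = np.ones(n, dtype=bool)
    n_inh = int(round(inhibitory_fraction * n))
    if n_inh:
        exc[rng.choice(n, size=n_inh, replace=False)] = False
    if sigma is None:
        sigma = calibrate_sigma(pos, mean_length_target)

    diff = pos[None, :, :] - pos[:, None, :]
    dmat = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dmat, np.inf)
    weight_rows = np.empty((n, n))
    for i in range(n):
        wgt = _distance_weights(dmat[i], sigma)
        wgt[i] = 0.0
        weight_rows[i] = wgt / wgt.sum()

    m = int(round(n * k_out))
    if multiplicity == "single" and m > n * (n - 1):
        raise ValueError("requested more synapses than distinct ordered pairs")
    pre = np.empty(m, dtype=np.int64)
    post = np.empty(m, dtype=np.int64)
    existing: set[tuple[int, int]] = set()
    ids = np.arange(n)
    for j in range(m):
        for _ in range(1000):
            p = int(rng.integers(n))
            q = int(rng.choice(ids, p=weight_rows[p]))
            if multiplicity == "single" and (q, p) in existing:
                continue
            break
        else:
            raise RuntimeError("could not place a new synapse: network saturated")
        pre[j] = q
        post[j] = p
        existing.add((q, p))
    d = np.linalg.norm(pos[post] - pos[pre], axis=1)
    lo, hi = w0_dist
    return Network(
        pos=pos,
        excitatory=exc,
        substrate=substrate,
        pre=pre,
        post=post,
        w=rng.uniform(lo, hi, m),
        delay_ms=delay_from_distance(d, conduction_velocity, dt),
        multiplicity=multiplicity,
        sigma=float(sigma),
    )
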