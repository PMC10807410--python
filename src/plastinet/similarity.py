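"""Cosine similarity of vector fields and the long-run stability protocol.

Two fields I and II on the same grid are compared cell by cell,

    s_km = (C_km^I . C_km^II) / (||C_km^I|| ||C_km^II||),

and summarized by the mean S over cells.  S = 1 means the orientation
patterns coincide; S = -1 means they are opposite.  The per-cell cosine is
undefined when either vector is zero; two policies handle this:

* ``valid`` (default): average only over cells where both vectors are
  nonzero and report their count;
* ``literal``: undefined cells contribute 0 and the sum is divided by N^2.

The stability protocol runs one simulation, snapshots the network state at
regular intervals, builds the chosen field for each snapshot and fills the
matrix of pairwise similarities; its off-diagonal mean is the network
stabilization measure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .vector_fields import FIELD_BUILDERS, VectorField

__all__ = [
    "SimilarityResult",
    "StabilityReport",
    "cell_cosine",
    "field_similarity",
    "stability_protocol",
    "stability_from_networks",
    "parameter_sweep",
]


@dataclass
class SimilarityResult:
    """Per-cell cosines (NaN where undefined) and their mean S."""

    per_cell: np.ndarray
    S: float
    n_valid_cells: int
    handling_policy: str


@dataclass
class StabilityReport:
    """Pairwise similarity of snapshot fields along one simulation."""

    snapshot_times: np.ndarray
    pairwise_S: np.ndarray
    mean_S: float
    field_kind: str
    policy: str
    config: dict = field(default_factory=dict)

    def pairs_dataframe(self):
        """Tidy table of off-diagonal pairs: t1_s, t2_s, S."""
        import pandas as pd

        rows = []
        k = len(self.snapshot_times)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "t1_s": self.snapshot_times[i],
                        "t2_s": self.snapshot_times[j],
                        "S": self.pairwise_S[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def consecutive_S(self) -> np.ndarray:
        return np.array([self.pairwise_S[i, i + 1] for i in range(len(self.snapshot_times) - 1)])

    def save(self, csv_path, json_path=None) -> None:
        self.pairs_dataframe().to_csv(csv_path, index=False)
        if json_path is not None:
            summary = {
                "mean_S": self.mean_S,
                "n_snapshots": int(len(self.snapshot_times)),
                "policy": self.policy,
                "field_kind": self.field_kind,
                **self.config,
            }
            with open(json_path, "w") as fh:
                json.dump(summary, fh, sort_keys=True, indent=2)


def cell_cosine(v1, v2) -> float:
    """Cosine of the angle between two 2-D vectors; NaN if either is zero."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        return math.nan
    return float(np.dot(v1, v2) / (n1 * n2))


def field_similarity(f1: VectorField, f2: VectorField, policy: str = "valid") -> SimilarityResult:
    """Mean per-cell cosine similarity S between two vector fields.

    The fields must share grid size and substrate.  Identical fields give
    S = 1 and elementwise-negated fields give S = -1 (over valid cells).
    """
    if policy not in ("valid", "literal"):
        raise ValueError("policy must be 'valid' or 'literal'")
    if f1.grid_n != f2.grid_n:
        raise ValueError(f"grid sizes differ: {f1.grid_n} vs {f2.grid_n}")
    if tuple(f1.substrate) != tuple(f2.substrate):
        raise ValueError("substrates differ")
    a = f1.vectors
    b = f2.vectors
    na = np.linalg.norm(a, axis=2)
    nb = np.linalg.norm(b, axis=2)
    valid = (na > 0) & (nb > 0)
    per_cell = np.full(na.shape, np.nan)
    dots = np.sum(a * b, axis=2)
    per_cell[valid] = dots[valid] / (na[valid] * nb[valid])
    # guard round-off outside [-1, 1]
    per_cell = np.clip(per_cell, -1.0, 1.0)
    n_valid = int(np.count_nonzero(valid))
    if policy == "valid":
        S = float(np.mean(per_cell[valid])) if n_valid else math.nan
    else:
        S = float(np.nansum(per_cell) / per_cell.size)
    return SimilarityResult(per_cell=per_cell, S=S, n_valid_cells=n_valid, handling_policy=policy)


def stability_from_networks(
    networks: Sequence,
    times: Sequence[float],
    field_kind: str = "weight",
    grid_n: int = 20,
    policy: str = "valid",
    config: dict | None = None,
) -> StabilityReport:
    """Pairwise field similarity over a list of network states."""
    builder = FIELD_BUILDERS[field_kind]
    fields = [builder(net, grid_n=grid_n, timestamp=t) for net, t in zip(networks, times)]
    k = len(fields)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            S = field_similarity(fields[i], fields[j], policy=policy).S
            mat[i, j] = mat[j, i] = S
    off = mat[np.triu_indices(k, 1)]
    return StabilityReport(
        snapshot_times=np.asarray(times, dtype=float),
        pairwise_S=mat,
        mean_S=float(np.mean(off)) if len(off) else math.nan,
        field_kind=field_kind,
        policy=policy,
        config=dict(config or {}),
    )


def stability_protocol(
    sim_factory: Callable,
    total_time: float,
    snapshot_every: float,
    field_kind: str = "weight",
    grid_n: int = 20,
    policy: str = "valid",
) -> StabilityReport:
    """Run one simulation and measure the reproducibility of its connectome.

    ``sim_factory(duration, snapshot_every)`` must run a simulation and
    return an object with a ``snapshots`` attribute (list of objects with
    ``t_s`` and ``network``), as produced by :func:`plastinet.engine.run`.
    The state snapshot at t = 0 (before any dynamics) is excluded, so a
    15000 s run recorded every 1000 s yields 15 snapshots and 105
    off-diagonal pairs.  The off-diagonal mean of the pairwise similarity
    matrix is the stabilization measure.
    """
    if total_time <= 0 or snapshot_every <= 0:
        raise ValueError("times must be positive")
    ratio = total_time / snapshot_every
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("total_time must be a multiple of snapshot_every")
    run = sim_factory(duration=total_time, snapshot_every=snapshot_every)
    snaps = [s for s in run.snapshots if s.t_s > 0]
    return stability_from_networks(
        [s.network for s in snaps],
        [s.t_s for s in snaps],
        field_kind=field_kind,
        grid_n=grid_n,
        policy=policy,
        config={"total_time_s": total_time, "snapshot_every_s": snapshot_every},
    )


def parameter_sweep(
    run_factory: Callable,
    w_new_values: Sequence[float] = (),
    t_w_values: Sequence[float] = (),
    multiplicities: Sequence[str] = ("single",),
    seeds: Sequence[int] = (0,),
    total_time: float = 15000.0,
    snapshot_every: float = 1000.0,
    field_kind: str = "weight",
    grid_n: int = 20,
):
    """Batch runner for rewiring-parameter sweeps.

    ``run_factory(w_new, t_w, multiplicity, seed, duration, snapshot_every)``
    must return a finished simulation run.  Emits one tidy row per run with
    the mean pairwise similarity, ready for downstream statistics.
    """
    import pandas as pd

    w_new_values = list(w_new_values) or [None]
    t_w_values = list(t_w_values) or [None]
    rows = []
    for mult in multiplicities:
        for w_new in w_new_values:
            for t_w in t_w_values:
                for seed in seeds:
                    run = run_factory(
                        w_new=w_new,
                        t_w=t_w,
                        multiplicity=mult,
                        seed=seed,
                        duration=total_time,
                        snapshot_every=snapshot_every,
                    )
                    snaps = [s for s in run.snapshots if s.t_s > 0]
                    rep = stability_from_networks(
                        [s.network for s in snaps],
                        [s.t_s for s in snaps],
                        field_kind=field_kind,
                        grid_n=grid_n,
                    )
                    rows.append(
                        {
                            "multiplicity": mult,
                            "w_new": w_new,
                            "t_w": t_w,
                            "seed": seed,
                            "mean_S": rep.mean_S,
                            "n_snapshots": len(snaps),
                        }
                    )
    return pd.DataFrame(rows)
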