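"""Angle-Relation Connection (ARC) graphs from amplitude series.

The ARC rule maps a time series onto a directed acyclic graph whose nodes
are the sample indices.  An edge i -> j (j > i) exists iff the chord angle

    theta_ij = arctan((x_j - x_i) / (j - i))

strictly exceeds theta_ik for every intermediate index i < k < j.  The
condition is vacuous for adjacent samples, so consecutive nodes are always
connected and the graph contains the time-ordered chain as a spanning
backbone.  Geometrically the rule is the left-to-right natural-visibility
criterion: i sees j iff every intermediate sample lies strictly below the
straight chord from (i, x_i) to (j, x_j).

Each edge carries a composite weight combining amplitude difference,
temporal proximity and chord angle,

    w_ij = alpha * |x_j - x_i| + beta / (j - i) + gamma * |theta_ij|,

with tunable nonnegative coefficients (defaults alpha=0.5, beta=0.3,
gamma=0.2).  Time enters in sample-index units throughout, so the output
depends on the amplitude scale relative to the unit sample step; topology
and weights are both invariant to adding a constant to all amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

__all__ = [
    "ARCParams",
    "Edge",
    "WeightedNetwork",
    "arc_edges",
    "arc_edges_bruteforce",
    "edge_weight",
    "build_network",
    "write_edgelist_tsv",
    "write_adjacency_mtx",
]

#: exploration grid reported for the weight coefficients; exposed for
#: sensitivity harnesses, not used by default
PARAM_GRID = {
    "alpha": (0.3, 0.4, 0.5, 0.6, 0.7),
    "beta": (0.1, 0.2, 0.3, 0.4),
    "gamma": (0.1, 0.2, 0.3),
}


@dataclass(frozen=True)
class ARCParams:
    """Coefficients of the composite edge-weight function.

    ``signed_weights`` drops the absolute values on the amplitude and
    angular terms (off by default; downstream strength/Gini/efficiency
    semantics assume nonnegative weights).
    """

    alpha: float = 0.5
    beta: float = 0.3
    gamma: float = 0.2
    signed_weights: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("weight coefficients must be nonnegative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one weight coefficient must be positive")


class Edge(NamedTuple):
    i: int
    j: int
    weight: float
    theta: float


def _as_series(segment) -> np.ndarray:
    x = np.asarray(getattr(segment, "x", segment), dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D amplitude series")
    if x.size < 2:
        raise ValueError(f"need at least 2 samples to build a network, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    return x


def arc_edges(segment) -> list[tuple[int, int]]:
    """Edge set of the ARC graph, sorted by ``(i, j)``.

    O(n^2) sweep: for each source i the chord angles theta_ij are an
    increasing function of the slope, so i -> j is an edge iff the slope to
    j strictly exceeds the running maximum of the slopes to all earlier
    targets.  arctan is monotone, hence slopes compare identically to
    angles and need not be transformed.
    """
    x = _as_series(segment)
    n = x.size
    edges: list[tuple[int, int]] = []
    for i in range(n - 1):
        slopes = (x[i + 1:] - x[i]) / np.arange(1, n - i, dtype=float)
        # prior_max[m] = max slope to targets before the (m+1)-th candidate
        prior_max = np.empty_like(slopes)
        prior_max[0] = -np.inf
        if slopes.size > 1:
            np.maximum.accumulate(slopes[:-1], out=prior_max[1:])
        for off in np.nonzero(slopes > prior_max)[0]:
            edges.append((i, i + 1 + int(off)))
    edges.sort()
    return edges


def arc_edges_bruteforce(segment) -> list[tuple[int, int]]:
    """Literal transcription of the ARC condition; the O(n^3) oracle.

    Checks theta_ik < theta_ij for every intermediate k explicitly.
    Intended for n <= 500.
    """
    x = _as_series(segment)
    n = x.size
    edges: list[tuple[int, int]] = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            theta_ij = math.atan2(x[j] - x[i], j - i)
            ok = True
            for k in range(i + 1, j):
                theta_ik = math.atan2(x[k] - x[i], k - i)
                if not theta_ik < theta_ij:
                    ok = False
                    break
            if ok:
                edges.append((i, j))
    return edges


def edge_weight(x_i: float, x_j: float, i: int, j: int,
                params: ARCParams = ARCParams()) -> float:
    """Composite weight of the edge i -> j."""
    if j <= i:
        raise ValueError(f"edges run left to right in time; got i={i}, j={j}")
    dx = x_j - x_i
    dt = j - i
    theta = math.atan2(dx, dt)
    if params.signed_weights:
        return params.alpha * dx + params.beta / dt + params.gamma * theta
    return params.alpha * abs(dx) + params.beta / dt + params.gamma * abs(theta)


@dataclass
class WeightedNetwork:
    """Directed acyclic ARC graph on time indices.

    Edges are stored as parallel arrays (``edge_i``, ``edge_j``,
    ``weight``, ``theta``) sorted by source then target; a dense adjacency
    is never materialized since |E| can approach n^2/2 on convex segments.
    """

    n: int
    node_amplitude: np.ndarray
    edge_i: np.ndarray
    edge_j: np.ndarray
    weight: np.ndarray
    theta: np.ndarray
    params: ARCParams = field(default_factory=ARCParams)

    def __post_init__(self) -> None:
        if not (self.n - 1 <= self.n_edges <= self.n * (self.n - 1) // 2):
            raise ValueError(
                f"edge count {self.n_edges} outside [{self.n - 1}, "
                f"{self.n * (self.n - 1) // 2}] for n={self.n}"
            )
        if np.any(self.edge_j <= self.edge_i):
            raise ValueError("all edges must satisfy j > i")

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    @property
    def edges(self) -> list[Edge]:
        return [Edge(int(i), int(j), float(w), float(t))
                for i, j, w, t in zip(self.edge_i, self.edge_j,
                                      self.weight, self.theta)]

    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.edge_i.tolist(), self.edge_j.tolist()))


def build_network(segment, params: ARCParams = ARCParams()) -> WeightedNetwork:
    """Construct the weighted ARC network of a segment."""
    x = _as_series(segment)
    pairs = arc_edges(x)
    ei = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
    ej = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
    dx = x[ej] - x[ei]
    dt = (ej - ei).astype(float)
    theta = np.arctan2(dx, dt)
    if params.signed_weights:
        w = params.alpha * dx + params.beta / dt + params.gamma * theta
    else:
        w = params.alpha * np.abs(dx) + params.beta / dt + params.gamma * np.abs(theta)
    return WeightedNetwork(n=x.size, node_amplitude=x, edge_i=ei, edge_j=ej,
                           weight=w, theta=theta, params=params)


def write_edgelist_tsv(network: WeightedNetwork, path) -> None:
    """Export edges as TSV with columns ``i  j  weight  theta`` (0-based)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\ttheta\n")
        for i, j, w, t in zip(network.edge_i, network.edge_j,
                              network.weight, network.theta):
            fh.write(f"{i}\t{j}\t{w:.17g}\t{t:.17g}\n")


def write_adjacency_mtx(network: WeightedNetwork, path) -> None:
    """Export the weighted adjacency in MatrixMarket coordinate format."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    adj = coo_matrix(
        (network.weight, (network.edge_i, network.edge_j)),
        shape=(network.n, network.n),
    )
    mmwrite(str(path), adj)
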