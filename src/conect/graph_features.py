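"""The 15-entry feature vector of a weighted ARC network.

Thirteen classical descriptors of the edge-weight distribution and the
graph topology, followed by two geometry-aware indices:

* WAII (Weighted Angular Irregularity Index) — mean over nodes of the
  coefficient of variation (population std / mean) of each node's
  *outgoing* edge weights; nodes with out-degree <= 1 contribute 0.
* CBEFI (Curvature-Based Edge Feature Index) — mean over edges of the
  normalized absolute second difference
  ``|x_j - 2 x_k + x_i| / (j - i)^2`` with k the integer midpoint
  ``(i + j) // 2``, time in sample units.

Path-based quantities (global efficiency, betweenness, average shortest
path) and community detection (modularity) operate on the undirected view
of the graph with edge length equal to the raw weight: the ARC digraph is
a DAG, so directed distances would be infinite for every right-to-left
pair, which is not what the pair sums of the classical definitions intend.
WAII alone keeps direction.  Moments of the weight distribution use
population denominators; skewness and kurtosis of a zero-variance
distribution are defined as 0.

Shortest-path and community computations are delegated to igraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .arc_network import ARCParams, WeightedNetwork, build_network
from .dataset import LabeledDataset, SegmentCohort, feature_column

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "waii",
    "cbefi",
    "classical_features",
    "feature_vector",
    "extract_dataset",
]

#: Feature names in index order (1-based indices 1..15 in reports).
FEATURE_NAMES: tuple[str, ...] = (
    "edge_count",
    "edge_weight_kurtosis",
    "edge_weight_mean",
    "edge_weight_skewness",
    "edge_weight_variance",
    "gini_index",
    "global_efficiency",
    "modularity",
    "weighted_average_degree",
    "average_degree",
    "average_betweenness",
    "average_node_strength",
    "average_path_length",
    "waii",
    "cbefi",
)


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 15 features, keyed by 1-based index."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (15,):
            raise ValueError(f"expected 15 features, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite entries")

    def __getitem__(self, index: int) -> float:
        if not 1 <= index <= 15:
            raise IndexError("feature indices are 1-based, 1..15")
        return float(self.values[index - 1])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


def waii(network: WeightedNetwork) -> float:
    """Mean coefficient of variation of per-node outgoing edge weights."""
    n = network.n
    counts = np.bincount(network.edge_i, minlength=n)
    sums = np.bincount(network.edge_i, weights=network.weight, minlength=n)
    sumsq = np.bincount(network.edge_i, weights=network.weight ** 2, minlength=n)
    multi = counts > 1
    total = 0.0
    if np.any(multi):
        mean = sums[multi] / counts[multi]
        var = np.maximum(sumsq[multi] / counts[multi] - mean ** 2, 0.0)
        nz = mean != 0
        total = float(np.sum(np.sqrt(var[nz]) / mean[nz]))
    return total / n


def cbefi(network: WeightedNetwork) -> float:
    """Mean normalized absolute second difference along the edges."""
    if network.n_edges == 0:
        raise ValueError("CBEFI is undefined for an empty edge set")
    x = network.node_amplitude
    i, j = network.edge_i, network.edge_j
    k = (i + j) // 2
    kappa = np.abs(x[j] - 2.0 * x[k] + x[i]) / (j - i).astype(float) ** 2
    return float(kappa.mean())


def _population_moments(w: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, excess kurtosis), population denominators."""
    mu = float(w.mean())
    d = w - mu
    var = float(np.mean(d ** 2))
    if var == 0.0:
        return mu, 0.0, 0.0, 0.0
    sd = np.sqrt(var)
    skew = float(np.mean(d ** 3) / sd ** 3)
    kurt = float(np.mean(d ** 4) / var ** 2 - 3.0)
    return mu, var, skew, kurt


def _gini(w: np.ndarray) -> float:
    """Mean absolute difference Gini: sum_ij |w_i - w_j| / (2 n^2 mu)."""
    n = w.size
    mu = float(w.mean())
    if mu == 0.0:
        return 0.0
    ws = np.sort(w)
    if ws[0] == ws[-1]:
        return 0.0
    ranks = np.arange(1, n + 1, dtype=float)
    return float(max(np.sum((2.0 * ranks - n - 1.0) * ws) / (n ** 2 * mu), 0.0))


def _undirected_igraph(network: WeightedNetwork) -> ig.Graph:
    g = ig.Graph(
        n=network.n,
        edges=list(zip(network.edge_i.tolist(), network.edge_j.tolist())),
        directed=False,
    )
    g.es["weight"] = network.weight.tolist()
    return g


def community_partition(network: WeightedNetwork) -> list[int]:
    """Greedy modularity-maximization membership on the undirected view."""
    g = _undirected_igraph(network)
    dendro = g.community_fastgreedy(weights="weight")
    return list(dendro.as_clustering().membership)


def classical_features(network: WeightedNetwork) -> np.ndarray:
    """The 13 classical descriptors, in feature-index order 1..13."""
    w = network.weight
    n_nodes = network.n
    n_edges = network.n_edges
    mu, var, skew, kurt = _population_moments(w)
    gini = _gini(w)

    g = _undirected_igraph(network)
    # shortest-path distances with weight-as-cost; ARC graphs are connected
    # through the adjacent-sample chain, but unreachable pairs would
    # contribute 0 to efficiency and be excluded from path length
    dist = np.asarray(g.distances(weights="weight"), dtype=float)
    off = ~np.eye(n_nodes, dtype=bool)
    d = dist[off]
    reachable = np.isfinite(d)
    e_glob = float(np.sum(1.0 / d[reachable]) / (n_nodes * (n_nodes - 1)))
    path_len = float(d[reachable].mean()) if np.any(reachable) else 0.0

    membership = community_partition(network)
    modularity = float(g.modularity(membership, weights="weight"))

    strength_mean = float(2.0 * w.sum() / n_nodes)
    avg_degree = 2.0 * n_edges / n_nodes
    bc = np.asarray(g.betweenness(weights="weight"), dtype=float)
    norm = (n_nodes - 1) * (n_nodes - 2) / 2.0
    avg_betweenness = float(bc.mean() / norm) if norm > 0 else 0.0

    return np.array([
        float(n_edges),   # 1 edge count
        kurt,             # 2 kurtosis
        mu,               # 3 mean
        skew,             # 4 skewness
        var,              # 5 variance
        gini,             # 6 Gini index
        e_glob,           # 7 global efficiency
        modularity,       # 8 modularity
        strength_mean,    # 9 weighted average degree
        avg_degree,       # 10 average degree
        avg_betweenness,  # 11 average betweenness centrality
        strength_mean,    # 12 average node strength (same sum as 9)
        path_len,         # 13 average shortest path length
    ])


def feature_vector(network: WeightedNetwork) -> FeatureVector:
    """All 15 features in index order."""
    classical = classical_features(network)
    return FeatureVector(np.concatenate([classical, [waii(network), cbefi(network)]]))


def extract_dataset(cohort: SegmentCohort,
                    params: ARCParams = ARCParams()) -> LabeledDataset:
    """Build ARC networks for every segment and tabulate their features."""
    rows = np.empty((len(cohort), 15), dtype=float)
    for r, seg in enumerate(cohort.segments):
        rows[r] = feature_vector(build_network(seg, params)).values
    X = pd.DataFrame(rows, columns=[feature_column(i) for i in range(1, 16)])
    return LabeledDataset(X=X, labels=list(cohort.labels),
                          groups=list(cohort.groups),
                          channel=list(cohort.channel))
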