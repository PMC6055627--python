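"""Graph-theoretical network parameters with degree-preserving normalization.

Basic parameters: network size (node count), degree, connectivity density.
Higher-order parameters: clustering coefficient, characteristic path length,
betweenness centrality, plus their normalized forms gamma (clustering / mean
clustering of randomized references), lambda (path length / reference mean),
and the small-world coefficient gamma / lambda.  References are produced by
Maslov-Sneppen double-edge swaps, which randomize topology while preserving
every node's degree exactly; by default 20 references are averaged.

Betweenness is reported as raw (unnormalized) ordered-pair path counts — the
convention matching whole-brain magnitudes in the thousands — with the
normalized proportion (relative to the (n-1)(n-2)/2 pairs not involving the
node) emitted alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .extract import BinaryNetwork

__all__ = [
    "NetworkMetricSet",
    "ReferenceEnsemble",
    "degree",
    "connectivity_density",
    "density_from_counts",
    "clustering_coefficient",
    "characteristic_path_length",
    "path_length_harmonic",
    "betweenness_centrality",
    "rewire_reference",
    "normalized_metrics",
    "compute_metrics",
]


def _as_graph(network: BinaryNetwork | nx.Graph) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.to_networkx()


def _n_nodes(network: BinaryNetwork | nx.Graph) -> int:
    if isinstance(network, nx.Graph):
        return network.number_of_nodes()
    return network.n_nodes


def degree(network: BinaryNetwork | nx.Graph) -> tuple[np.ndarray, float]:
    """Nodal degree (adjacency row sums) and its mean over nodes."""
    if _n_nodes(network) < 1:
        raise ValueError("network must contain at least one node")
    if isinstance(network, nx.Graph):
        nodal = np.array([d for _, d in sorted(network.degree())], dtype=float)
    else:
        nodal = network.degrees().astype(float)
    return nodal, float(nodal.mean())


def density_from_counts(n_edges: int, n_possible_pairs: int) -> float:
    """Connectivity density in percent: 100 * edges / possible pairs."""
    if n_possible_pairs <= 0:
        raise ValueError("need at least one possible pair")
    return 100.0 * n_edges / n_possible_pairs


def connectivity_density(network: BinaryNetwork | nx.Graph) -> float:
    """Percent of all possible node pairs that are connected."""
    n = _n_nodes(network)
    if n < 2:
        raise ValueError("connectivity density is undefined for fewer than 2 nodes")
    g = _as_graph(network)
    return density_from_counts(g.number_of_edges(), n * (n - 1) // 2)


def clustering_coefficient(network: BinaryNetwork | nx.Graph) -> tuple[np.ndarray, float]:
    """Nodal clustering (fraction of neighbor pairs that are connected) and
    its mean.  Nodes with degree < 2 have clustering 0."""
    if _n_nodes(network) < 1:
        raise ValueError("network must contain at least one node")
    g = _as_graph(network)
    cdict = nx.clustering(g)
    nodal = np.array([cdict[v] for v in sorted(g.nodes())], dtype=float)
    return nodal, float(nodal.mean())


def characteristic_path_length(
    network: BinaryNetwork | nx.Graph,
) -> tuple[np.ndarray, float, int]:
    """Shortest-path lengths by breadth-first search.

    Nodal value: mean distance to reachable partners (NaN for isolated
    nodes).  Global value: mean over all reachable pairs.  Unreachable
    pairs are excluded from both averages; their (unordered) count is
    returned and a warning emitted when nonzero.
    """
    n = _n_nodes(network)
    if n < 2:
        raise ValueError("path length is undefined for fewer than 2 nodes")
    g = _as_graph(network)
    order = {v: i for i, v in enumerate(sorted(g.nodes()))}
    nodal = np.full(n, np.nan)
    total, count = 0.0, 0
    n_unreachable = 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        dists = [d for tgt, d in lengths.items() if tgt != src]
        n_unreachable += (n - 1) - len(dists)
        if dists:
            nodal[order[src]] = float(np.mean(dists))
            total += sum(dists)
            count += len(dists)
    if count == 0:
        raise ValueError("network has no connected node pairs; path length undefined")
    n_unreachable //= 2  # ordered -> unordered pairs
    if n_unreachable:
        warnings.warn(f"{n_unreachable} node pair(s) unreachable; excluded from path length")
    return nodal, total / count, n_unreachable


def shortest_path_matrix(network: BinaryNetwork | nx.Graph) -> np.ndarray:
    """All-pairs shortest-path length matrix by BFS (inf where unreachable)."""
    n = _n_nodes(network)
    g = _as_graph(network)
    order = {v: i for i, v in enumerate(sorted(g.nodes()))}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for tgt, d in lengths.items():
            dist[order[src], order[tgt]] = d
    return dist


def path_length_harmonic(network: BinaryNetwork | nx.Graph) -> float:
    """Harmonic-mean path length variant: unreachable pairs contribute 0
    inverse distance instead of being dropped.  Not the default metric."""
    n = _n_nodes(network)
    if n < 2:
        raise ValueError("path length is undefined for fewer than 2 nodes")
    g = _as_graph(network)
    inv_sum = 0.0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        inv_sum += sum(1.0 / d for tgt, d in lengths.items() if tgt != src)
    n_pairs = n * (n - 1)
    if inv_sum == 0:
        return float("inf")
    return n_pairs / inv_sum


def betweenness_centrality(
    network: BinaryNetwork | nx.Graph,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact (Brandes) betweenness: for node v, the sum over ordered pairs
    (s, t), s != t != v, of the fraction of shortest s-t paths through v.

    Returns (raw nodal counts, their mean, normalized nodal proportions).
    """
    n = _n_nodes(network)
    if n < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    g = _as_graph(network)
    verts = sorted(g.nodes())
    raw_dict = nx.betweenness_centrality(g, normalized=False)
    # networkx counts each unordered pair once for undirected graphs;
    # ordered-pair counts are twice that
    raw = 2.0 * np.array([raw_dict[v] for v in verts])
    norm_dict = nx.betweenness_centrality(g, normalized=True)
    normalized = np.array([norm_dict[v] for v in verts])
    return raw, float(raw.mean()), normalized


@dataclass
class ReferenceEnsemble:
    """Degree-preserving randomized reference networks and their metrics."""

    graphs: list
    clustering_global: np.ndarray
    path_length_global: np.ndarray
    seed: int
    swaps_per_edge: int

    @property
    def n_references(self) -> int:
        return len(self.graphs)


def rewire_reference(
    network: BinaryNetwork | nx.Graph,
    n_references: int = 20,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> ReferenceEnsemble:
    """Build randomized references by repeated double-edge swaps.

    Each swap replaces edges (a,b),(c,d) with (a,d),(c,b) when that creates
    no self-loop or duplicate edge, so every reference keeps the exact
    degree sequence of the input.  Graphs admitting no legal swap (e.g. a
    triangle) are returned unchanged with a warning.
    """
    g = _as_graph(network)
    if g.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if n_references < 1:
        raise ValueError("need at least one reference")
    rng = np.random.default_rng(seed)
    graphs, cl, pl = [], [], []
    nswap = swaps_per_edge * g.number_of_edges()
    for _ in range(n_references):
        ref = g.copy()
        try:
            nx.double_edge_swap(
                ref, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31))
            )
        except nx.NetworkXException as exc:
            warnings.warn(f"double-edge swap unavailable or incomplete ({exc}); "
                          "reference kept as-is")
        graphs.append(ref)
        _, c = clustering_coefficient(ref)
        cl.append(c)
        _, l, _ = characteristic_path_length(ref)
        pl.append(l)
    return ReferenceEnsemble(
        graphs=graphs,
        clustering_global=np.array(cl),
        path_length_global=np.array(pl),
        seed=seed,
        swaps_per_edge=swaps_per_edge,
    )


def normalized_metrics(
    network: BinaryNetwork | nx.Graph, ensemble: ReferenceEnsemble
) -> tuple[float, float, float]:
    """gamma = C / C_ref, lambda = L / L_ref, small-world = gamma / lambda."""
    _, c = clustering_coefficient(network)
    _, l, _ = characteristic_path_length(network)
    c_ref = float(ensemble.clustering_global.mean())
    l_ref = float(ensemble.path_length_global.mean())
    if c_ref == 0:
        raise ValueError(
            "reference clustering is 0 (graph too sparse to form triangles); gamma undefined"
        )
    gamma = c / c_ref
    lam = l / l_ref
    return gamma, lam, gamma / lam


@dataclass
class NetworkMetricSet:
    """All global network parameters plus the per-node table."""

    size: int
    degree_global: float
    connectivity_density: float
    clustering_global: float
    path_length_global: float
    betweenness_global: float
    gamma: float
    lambda_: float
    small_world: float
    n_unreachable_pairs: int = 0
    nodal: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "size": self.size,
            "degree": self.degree_global,
            "connectivity_density": self.connectivity_density,
            "clustering": self.clustering_global,
            "path_length": self.path_length_global,
            "betweenness": self.betweenness_global,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "small_world": self.small_world,
        }


def compute_metrics(
    network: BinaryNetwork | nx.Graph,
    n_references: int = 20,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> NetworkMetricSet:
    """Compute every basic and higher-order parameter for one network."""
    deg_nodal, deg_mean = degree(network)
    dens = connectivity_density(network)
    clu_nodal, clu_mean = clustering_coefficient(network)
    pl_nodal, pl_mean, n_unreach = characteristic_path_length(network)
    btw_raw, btw_mean, btw_norm = betweenness_centrality(network)
    ens = rewire_reference(
        network, n_references=n_references, swaps_per_edge=swaps_per_edge, seed=seed
    )
    gamma, lam, sw = normalized_metrics(network, ens)
    nodal = pd.DataFrame(
        {
            "degree": deg_nodal,
            "clustering": clu_nodal,
            "path_length": pl_nodal,
            "betweenness": btw_raw,
            "betweenness_normalized": btw_norm,
        }
    )
    return NetworkMetricSet(
        size=_n_nodes(network),
        degree_global=deg_mean,
        connectivity_density=dens,
        clustering_global=clu_mean,
        path_length_global=pl_mean,
        betweenness_global=btw_mean,
        gamma=gamma,
        lambda_=lam,
        small_world=sw,
        n_unreachable_pairs=n_unreach,
        nodal=nodal,
    )
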