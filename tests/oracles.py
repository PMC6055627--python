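"""Independent brute-force oracles used to verify graph metrics and
statistical procedures.  Everything here recomputes quantities from first
principles (Floyd-Warshall distances, explicit shortest-path counting,
the step-up rule written out) so the tests never depend on the code paths
they check."""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by the O(n^3) recurrence."""
    n = len(adj)
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return dist


def shortest_path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of distinct shortest s-t paths, by dynamic
    programming over the distance matrix (not Brandes accumulation)."""
    n = len(adj)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    order = np.argsort(dist, axis=1)
    for s in range(n):
        for t in order[s]:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = [u for u in range(n) if adj[u, t] and dist[s, u] == dist[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return sigma


def betweenness_ordered(adj: np.ndarray) -> np.ndarray:
    """Raw betweenness: sum over ordered pairs (s, t), s != t != v, of the
    fraction of shortest s-t paths passing through v."""
    n = len(adj)
    dist = floyd_warshall(adj)
    sigma = shortest_path_counts(adj, dist)
    btw = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


def clustering_nodal(adj: np.ndarray) -> np.ndarray:
    """Fraction of neighbor pairs connected; 0 when degree < 2."""
    n = len(adj)
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[a, b] for i, a in enumerate(nbrs) for b in nbrs[i + 1 :])
        out[v] = links / (k * (k - 1) / 2)
    return out


def path_length_stats(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """(nodal mean distance over reachable partners, global mean over all
    reachable pairs); NaN for isolated nodes."""
    dist = floyd_warshall(adj)
    n = len(adj)
    off = ~np.eye(n, dtype=bool)
    reach = np.isfinite(dist) & off
    nodal = np.full(n, np.nan)
    for v in range(n):
        if reach[v].any():
            nodal[v] = dist[v, reach[v]].mean()
    return nodal, float(dist[reach].mean())


def fdr_step_up(p: np.ndarray, correction: float = 1.0) -> np.ndarray:
    """Adjusted p-values of the step-up FDR rule, written out directly:
    q_(i) = min over j >= i of (m * c / j) * p_(j), clipped at 1.
    ``correction`` = 1 gives Benjamini-Hochberg; sum(1/i) gives
    Benjamini-Yekutieli."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        j = order[rank - 1]
        running = min(running, m * correction * p[j] / rank)
        adj[j] = min(running, 1.0)
    return adj
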