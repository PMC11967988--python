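"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths (and algorithms) of the package:
distances come from a numpy Floyd–Warshall sweep, shortest-path counts from
dynamic programming on the distance matrix, and contact graphs from an
explicit double loop over all site pairs with minimum-image displacements.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path hop counts; inf where unreachable."""
    n = len(adj)
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    return dist


def path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of shortest s-t paths (DP over hop shells)."""
    n = len(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        finite = np.isfinite(dist[s])
        for d in range(1, int(dist[s][finite].max()) + 1 if finite.any() else 1):
            for v in np.nonzero(dist[s] == d)[0]:
                preds = np.nonzero((adj[v] > 0) & (dist[s] == d - 1))[0]
                sigma[s, v] = sigma[s, preds].sum()
    return sigma


def brute_degree_centrality(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    return adj.sum(axis=1) / (n - 1)


def brute_closeness_wf(adj: np.ndarray) -> np.ndarray:
    """Wasserman–Faust closeness from the Floyd–Warshall distance matrix."""
    n = len(adj)
    dist = floyd_warshall(adj)
    out = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(dist[v]) & (np.arange(n) != v)
        nv = reach.sum()
        if nv == 0:
            continue
        out[v] = (nv / (n - 1)) * (nv / dist[v][reach].sum())
    return out


def brute_betweenness(adj: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Raw betweenness via sigma[s,v]*sigma[v,t]/sigma[s,t] over unordered pairs."""
    n = len(adj)
    dist = floyd_warshall(adj)
    sigma = path_counts(adj, dist)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    out[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if normalized and n > 2:
        out /= (n - 1) * (n - 2) / 2
    return out


def brute_clustering(adj: np.ndarray, convention: str = "half") -> np.ndarray:
    """Triangle counts by explicit triple loop."""
    n = len(adj)
    out = np.zeros(n)
    for v in range(n):
        k = int(adj[v].sum())
        if k <= 1:
            continue
        tri = 0
        nbrs = np.nonzero(adj[v])[0]
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                if adj[nbrs[a], nbrs[b]]:
                    tri += 1
        out[v] = tri / (k * (k - 1))
        if convention == "standard":
            out[v] *= 2
    return out


def brute_contact_edges(config, tail_roles, cutoff: float) -> set:
    """All-pairs minimum-image contact edges over the 27 periodic images."""
    mask = np.isin(config.site_role, list(tail_roles))
    pos = config.positions[mask]
    mol = config.molecule_id[mask]
    box = config.box
    edges = set()
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            if mol[i] == mol[j]:
                continue
            best = np.inf
            for sx in (-1, 0, 1):
                for sy in (-1, 0, 1):
                    for sz in (-1, 0, 1):
                        shift = np.array([sx, sy, sz]) * box
                        d = np.linalg.norm(pos[i] - pos[j] + shift)
                        best = min(best, d)
            if best < cutoff:
                edges.add((min(mol[i], mol[j]), max(mol[i], mol[j])))
    return edges


def brute_mass_function(adj: np.ndarray, origin: int, r_max: int) -> np.ndarray:
    dist = floyd_warshall(adj)[origin]
    return np.array([(dist <= r).sum() for r in range(1, r_max + 1)])
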