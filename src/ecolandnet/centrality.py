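"""Whole-network density and Freeman node centralities with rankings.

Density of a directed network is m / (n(n-1)). Centralities are computed on
the symmetrized graph by default (a tie in either direction connects the
pair), matching the single-column reporting convention of classical SNA
software; in/out variants of degree are exposed.

- degree: deg_i / (n-1)
- betweenness (Brandes' algorithm): sum over unordered pairs j<k of the
  fraction of shortest j-k paths through i; normalized by (n-1)(n-2)/2
- closeness: (n-1) / farness_i, farness_i = sum_j d_ij, with unreachable
  distances set to n (configurable convention for disconnected graphs)
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gravity import TieNetwork

__all__ = [
    "NetworkSummary",
    "network_density",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "centrality_report",
]


@dataclass(frozen=True)
class NetworkSummary:
    n: int
    m: int
    density: float


def network_density(net: TieNetwork) -> NetworkSummary:
    """Directed density m / (n(n-1))."""
    n = net.n
    if n < 2:
        raise ValueError("density needs at least two nodes")
    m = net.tie_count
    return NetworkSummary(n=n, m=m, density=m / (n * (n - 1)))


def _symmetrized(net: TieNetwork) -> np.ndarray:
    return ((net.A + net.A.T) > 0).astype(int)


def degree_centrality(net: TieNetwork, mode: str = "symmetrized") -> np.ndarray:
    """Normalized degree deg_i/(n-1); mode picks symmetrized/in/out degree."""
    n = net.n
    if mode == "symmetrized":
        deg = _symmetrized(net).sum(axis=1)
    elif mode == "in":
        deg = net.A.sum(axis=0)
    elif mode == "out":
        deg = net.A.sum(axis=1)
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    return deg / (n - 1)


def _bfs_distances(adj: list[np.ndarray], source: int, n: int) -> np.ndarray:
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def betweenness_centrality(net: TieNetwork, normalized: bool = True) -> np.ndarray:
    """Shortest-path betweenness on the symmetrized graph (Brandes).

    Pair contributions are counted over unordered pairs; normalization
    divides by (n-1)(n-2)/2. Unreachable pairs contribute zero.
    """
    A = _symmetrized(net)
    n = net.n
    adj = [np.flatnonzero(A[v]) for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1, dtype=int)
        dist[s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair counted from both endpoints
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def closeness_centrality(net: TieNetwork,
                         unreachable_distance: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(closeness, farness) on the symmetrized graph.

    farness_i = sum of geodesic distances from i; unreachable nodes count as
    ``unreachable_distance`` (default n). closeness_i = (n-1)/farness_i.
    """
    A = _symmetrized(net)
    n = net.n
    if unreachable_distance is None:
        unreachable_distance = float(n)
    adj = [np.flatnonzero(A[v]) for v in range(n)]
    farness = np.zeros(n)
    for v in range(n):
        dist = _bfs_distances(adj, v, n).astype(float)
        dist[dist < 0] = unreachable_distance
        dist[v] = 0.0
        farness[v] = dist.sum()
    closeness = np.where(farness > 0, (n - 1) / farness, 0.0)
    return closeness, farness


def centrality_report(net: TieNetwork) -> pd.DataFrame:
    """Ranked degree/closeness/betweenness table with a mean row.

    Values are reported both as fractions and percentages; ranks break ties
    lexicographically by city_id so the output is deterministic.
    """
    cities = list(net.cities)
    deg = degree_centrality(net)
    clo, _ = closeness_centrality(net)
    btw = betweenness_centrality(net)
    df = pd.DataFrame({
        "city_id": cities,
        "degree": deg, "closeness": clo, "betweenness": btw,
    })
    for col in ("degree", "closeness", "betweenness"):
        df[col + "_pct"] = 100.0 * df[col]
        order = df.sort_values([col, "city_id"],
                               ascending=[False, True]).index
        ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
        df[col + "_rank"] = ranks
    mean_row = {"city_id": "Average"}
    for col in ("degree", "closeness", "betweenness"):
        mean_row[col] = df[col].mean()
        mean_row[col + "_pct"] = df[col + "_pct"].mean()
        mean_row[col + "_rank"] = np.nan
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
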