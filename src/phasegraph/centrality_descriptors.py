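"""Per-node centrality and clustering descriptors and their statistics.

The four node descriptors used to characterise molecular aggregates:

- degree centrality          C_d(v) = deg(v) / (N - 1)
- closeness centrality       C_c(v) = [n_v/(N-1)] * [n_v / sum_u d(v, u)]
  (Wasserman–Faust form: n_v is the number of nodes reachable from v,
  excluding v, and the sum runs over that reachable set — well defined on
  disconnected graphs, reducing to classical closeness when connected;
  isolated nodes score 0)
- betweenness centrality     C_b(v) = sum_{s<t, v not in {s,t}} sigma_st(v)/sigma_st
  (raw by default; the normalized variant divides by (N-1)(N-2)/2)
- clustering coefficient     CC(v) = T(v) / (deg(v)(deg(v)-1))
  with T(v) the number of triangles through v.  This "half" convention
  omits the factor 2 of the standard definition (so it is half the usual
  2T/k(k-1) value); both are available.

Plus pooled histograms, running averages, min-max normalization and
cross-metric Pearson correlation used when comparing descriptor time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .particles import ConfigurationError

__all__ = [
    "NodeMetricTable",
    "MetricDistribution",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "clustering_coefficient",
    "metric_distribution",
    "running_average",
    "minmax_normalize",
    "metric_correlation",
]


@dataclass
class NodeMetricTable:
    """Per-node values of one descriptor for one frame."""

    name: str
    values: pd.Series  # indexed by node id
    time: float | None = None

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float).sort_index()

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"node_id": self.values.index, "metric": self.name,
             "value": self.values.to_numpy()}
        )
        df["time"] = self.time
        return df


@dataclass
class MetricDistribution:
    """Probability histogram of a descriptor pooled over frames."""

    bin_edges: np.ndarray
    probability: np.ndarray  # sums to 1
    mean: float
    std: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode(self) -> float:
        """Centre of the most probable bin."""
        return float(self.bin_centers[int(np.argmax(self.probability))])


def _as_table(name, mapping, graph, time=None) -> NodeMetricTable:
    values = pd.Series(mapping, dtype=float)
    return NodeMetricTable(name=name, values=values,
                           time=time if time is not None else graph.graph.get("time"))


def degree_centrality(graph: nx.Graph) -> NodeMetricTable:
    """Degree normalized by the maximum possible degree N - 1."""
    if graph.number_of_nodes() < 2:
        raise ConfigurationError("degree centrality needs at least 2 nodes")
    return _as_table("degree_centrality", nx.degree_centrality(graph), graph)


def closeness_centrality(graph: nx.Graph) -> NodeMetricTable:
    """Wasserman–Faust closeness, well defined on disconnected graphs."""
    if graph.number_of_nodes() < 2:
        raise ConfigurationError("closeness centrality needs at least 2 nodes")
    vals = nx.closeness_centrality(graph, wf_improved=True)
    return _as_table("closeness_centrality", vals, graph)


def betweenness_centrality(graph: nx.Graph, normalized: bool = False) -> NodeMetricTable:
    """Shortest-path betweenness; endpoints excluded, ties split by path counts.

    Raw values sum sigma_st(v)/sigma_st over unordered pairs {s, t} not
    containing v; ``normalized=True`` divides by (N-1)(N-2)/2.
    """
    vals = nx.betweenness_centrality(graph, normalized=normalized)
    name = "betweenness_centrality" + ("_normalized" if normalized else "")
    return _as_table(name, vals, graph)


def clustering_coefficient(graph: nx.Graph, convention: str = "half") -> NodeMetricTable:
    """Per-node clustering coefficient.

    ``convention="half"`` computes T(v)/(deg(v)(deg(v)-1)) (half the
    usual value — the factor-2-free variant found in parts of the
    literature); ``"standard"`` computes 2T(v)/(deg(v)(deg(v)-1)).
    Nodes of degree <= 1 score 0.
    """
    if convention not in ("half", "standard"):
        raise ConfigurationError(f"unknown clustering convention {convention!r}")
    triangles = nx.triangles(graph)
    vals = {}
    for v, k in graph.degree():
        vals[v] = 0.0 if k <= 1 else triangles[v] / (k * (k - 1))
        if convention == "standard":
            vals[v] *= 2.0
    return _as_table(f"clustering_coefficient_{convention}", vals, graph)


def metric_distribution(tables, bins: int = 50) -> MetricDistribution:
    """Pooled probability histogram (plus mean/std) over one or more frames."""
    if isinstance(tables, NodeMetricTable):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ConfigurationError("metric_distribution needs at least one table")
    pooled = np.concatenate([t.values.to_numpy() for t in tables])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ConfigurationError("no finite metric values to histogram")
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:  # constant metric: one occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(pooled, bins=bins, range=(lo, hi))
    return MetricDistribution(
        bin_edges=edges,
        probability=counts / counts.sum(),
        mean=float(pooled.mean()),
        std=float(pooled.std()),
    )


def running_average(series, window: int = 25) -> np.ndarray:
    """Centered moving average; edges use the truncated window.

    ``window`` must be odd (so the window is symmetric) and no longer than
    the series.
    """
    values = np.asarray(pd.Series(series), dtype=float)
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("window must be a positive odd integer")
    if window > len(values):
        raise ConfigurationError(
            f"window ({window}) exceeds series length ({len(values)})"
        )
    out = pd.Series(values).rolling(window, center=True, min_periods=1).mean()
    return out.to_numpy()


def minmax_normalize(series) -> np.ndarray:
    """Rescale to [0, 1] via (x - min)/(max - min); constant input is an error."""
    values = np.asarray(series, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ConfigurationError("cannot min-max normalize a constant series")
    return (values - lo) / (hi - lo)


def metric_correlation(series_a, series_b) -> float:
    """Pearson correlation between two equal-length metric series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ConfigurationError("series must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ConfigurationError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(a, b).statistic)
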