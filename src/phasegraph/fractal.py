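"""Node-based fractal dimension (NFD) and node-based multifractal analysis.

The box-growing method takes each node i as the origin of a "box" of
shortest-path radius r and records the mass M_i(r): the number of nodes
within distance r (origin included).  For self-similar graphs
M(r) ~ r**d, and the node-based fractal dimension d is the log-log slope of
that power law below saturation.

Multifractality generalises this through the partition function

    U_q(r) = sum_i (M_i(r) / N) ** q

whose scaling exponents tau(q) (slope of ln U_q vs ln r) yield, by Legendre
transform, the Lipschitz-Hoelder exponent alpha(q) = dtau/dq and the
spectrum f(alpha) = q * alpha - tau(q).  The spectrum width
w = alpha_max - alpha_min measures the heterogeneity of the growth rules:
a homogeneous (monofractal) graph collapses toward a single point, while a
mixture of architectures widens the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .centrality_descriptors import NodeMetricTable
from .particles import ConfigurationError

__all__ = [
    "MassFunction",
    "NFDResult",
    "MultifractalSpectrum",
    "mass_function",
    "mass_matrix",
    "node_fractal_dimension",
    "nfd_table",
    "partition_function",
    "mass_exponent",
    "multifractal_spectrum",
    "default_q_grid",
]

#: Smallest component on which a per-node dimension fit is attempted.
MIN_FIT_COMPONENT = 8

#: Fits stop at the largest radius with M(r) below this fraction of the
#: component size: beyond half the component the ball begins to close on
#: itself (periodic/finite saturation) and the log-log curve bends, so the
#: plateau is excluded — the same rule as the multifractal r-range.
SATURATION_FRACTION = 0.5


@dataclass
class MassFunction:
    """Box mass M_i(r) for one origin node, r = 1..r_max (hops)."""

    origin: object
    r: np.ndarray
    m: np.ndarray  # node counts, origin included; non-decreasing

    @property
    def component_size(self) -> int:
        return int(self.m[-1]) if len(self.m) else 1


@dataclass
class NFDResult:
    """Per-node fractal dimension with fit diagnostics."""

    origin: object
    dimension: float  # nan when undefined
    r_fit: int
    r_squared: float

    @property
    def valid(self) -> bool:
        return np.isfinite(self.dimension)


@dataclass
class MultifractalSpectrum:
    """tau(q), alpha(q) and f(alpha) on a q grid, with spectrum width w."""

    q: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    r_range: np.ndarray

    @property
    def width(self) -> float:
        """w = alpha_max - alpha_min (degree of heterogeneity)."""
        return float(self.alpha.max() - self.alpha.min())

    def to_dict(self) -> dict:
        return {
            "q": self.q.tolist(),
            "tau": self.tau.tolist(),
            "alpha": self.alpha.tolist(),
            "f_alpha": self.f_alpha.tolist(),
            "width": self.width,
        }


def default_q_grid(qmin: float = -5.0, qmax: float = 5.0, dq: float = 0.25) -> np.ndarray:
    """Distortion-exponent grid; the default covers q in [-5, 5] by 0.25."""
    n = int(round((qmax - qmin) / dq)) + 1
    return np.linspace(qmin, qmax, n)


def mass_function(graph: nx.Graph, origin, r_max: int | None = None) -> MassFunction:
    """M_i(r) = number of nodes within shortest-path distance r of origin."""
    if origin not in graph:
        raise ConfigurationError(f"origin node {origin!r} not in graph")
    lengths = nx.single_source_shortest_path_length(graph, origin)
    dist = np.fromiter(lengths.values(), dtype=int)
    ecc = int(dist.max()) if len(dist) > 1 else 1
    if r_max is None:
        r_max = max(ecc, 1)
    elif r_max < 1:
        raise ConfigurationError("r_max must be >= 1")
    counts = np.bincount(dist, minlength=r_max + 1)[: r_max + 1]
    m = np.cumsum(counts)[1:]  # M(r) for r = 1..r_max (M includes the origin)
    return MassFunction(origin=origin, r=np.arange(1, r_max + 1), m=m)


def mass_matrix(graph: nx.Graph, r_max: int | None = None):
    """Stack of mass functions for every node: (nodes, masses, r grid).

    ``masses[i, r-1]`` is M_i(r); columns run r = 1..r_max where r_max
    defaults to the graph's largest eccentricity.
    """
    nodes = list(graph.nodes)
    per_node = []
    ecc_max = 1
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(graph, v)
        dist = np.fromiter(lengths.values(), dtype=int)
        per_node.append(dist)
        if len(dist) > 1:
            ecc_max = max(ecc_max, int(dist.max()))
    if r_max is None:
        r_max = ecc_max
    masses = np.empty((len(nodes), r_max), dtype=float)
    for i, dist in enumerate(per_node):
        counts = np.bincount(dist, minlength=r_max + 1)[: r_max + 1]
        masses[i] = np.cumsum(counts)[1:]
    return nodes, masses, np.arange(1, r_max + 1)


def _loglog_slope(r: np.ndarray, y: np.ndarray):
    x = np.log(r.astype(float))
    ly = np.log(y.astype(float))
    slope, intercept = np.polyfit(x, ly, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def node_fractal_dimension(
    graph: nx.Graph,
    origin,
    min_component: int = MIN_FIT_COMPONENT,
    saturation: float = SATURATION_FRACTION,
) -> NFDResult:
    """NFD of one origin: least-squares slope of ln M(r) vs ln r.

    The fit uses the asymptotic scaling window
    ``r = max(2, r_fit // 3) .. r_fit`` with r_fit the largest radius at
    which M(r) < ``saturation`` x component size.  The trivial r = 1 point
    (pure degree), the small-r transient and the saturation plateau all sit
    off the power law, so — as is standard in box-counting — only the upper
    scaling window is fitted.  Origins in components smaller than
    ``min_component``, or with fewer than 3 usable radii, yield an
    undefined (NaN) dimension that is excluded from distributions.
    """
    mf = mass_function(graph, origin)
    comp = mf.component_size
    usable = mf.m < saturation * comp
    r_fit = int(mf.r[usable].max()) if usable.any() else 0
    if comp < min_component or r_fit < 4:
        return NFDResult(origin=origin, dimension=float("nan"),
                         r_fit=r_fit, r_squared=float("nan"))
    sel = (mf.r >= max(2, r_fit // 3)) & (mf.r <= r_fit)
    slope, r2 = _loglog_slope(mf.r[sel], mf.m[sel])
    return NFDResult(origin=origin, dimension=slope, r_fit=r_fit, r_squared=r2)


def nfd_table(graph: nx.Graph, min_component: int = MIN_FIT_COMPONENT) -> NodeMetricTable:
    """Per-node NFD table; undefined origins are NaN (and counted in attrs)."""
    results = {v: node_fractal_dimension(graph, v, min_component=min_component)
               for v in graph.nodes}
    values = {v: res.dimension for v, res in results.items()}
    table = NodeMetricTable(name="nfd", values=values,
                            time=graph.graph.get("time"))
    table.excluded = sum(0 if res.valid else 1 for res in results.values())
    return table


def partition_function(graph: nx.Graph, q: float, r: int, _masses=None) -> float:
    """U_q(r) = sum_i (M_i(r)/N)^q over all N nodes.

    Since every M_i(r) >= 1 the sum is finite for all real q; U_0(r) = N.
    """
    if r < 1:
        raise ConfigurationError("r must be >= 1")
    if _masses is None:
        _, masses, r_grid = mass_matrix(graph, r_max=r)
    else:
        masses, r_grid = _masses
        if r > r_grid[-1]:
            raise ConfigurationError(f"r={r} beyond precomputed mass matrix")
    n = masses.shape[0]
    col = masses[:, r - 1]
    return float(np.sum((col / n) ** q))


def _default_r_range(masses: np.ndarray, r_grid: np.ndarray) -> np.ndarray:
    """r = 2 up to the largest r with median mass below half the graph."""
    n = masses.shape[0]
    median = np.median(masses, axis=0)
    below = r_grid[median < 0.5 * n]
    r_hi = int(below.max()) if below.size else 0
    return r_grid[(r_grid >= 2) & (r_grid <= r_hi)]


def mass_exponent(graph: nx.Graph, q: float, r_range=None, _masses=None) -> float:
    """tau(q): slope of ln U_q(r) vs ln r over the scaling regime.

    A regression estimator is used rather than a single-radius ratio: for a
    perfect power law the two coincide, and the slope is robust for finite
    graphs.  At least 3 radii below saturation are required.
    """
    if _masses is None:
        r_max = None if r_range is None else int(max(r_range))
        _, masses, r_grid = mass_matrix(graph, r_max=r_max)
        _masses = (masses, r_grid)
    masses, r_grid = _masses
    r_range = _default_r_range(masses, r_grid) if r_range is None \
        else np.asarray(list(r_range), dtype=int)
    if len(r_range) < 3:
        raise ConfigurationError(
            "graph too small: need >= 3 radii below saturation for tau(q)"
        )
    n = masses.shape[0]
    u = np.array([np.sum((masses[:, r - 1] / n) ** q) for r in r_range])
    if not np.all(np.isfinite(np.log(u))):
        raise ConfigurationError(f"degenerate partition function at q={q}")
    slope, _ = _loglog_slope(r_range, u)
    return slope


def multifractal_spectrum(
    graph: nx.Graph,
    q_grid=None,
    r_range=None,
) -> MultifractalSpectrum:
    """Full NMFA spectrum: tau(q), alpha(q) = dtau/dq, f(alpha) = q*alpha - tau.

    alpha is obtained by central finite differences on the q grid (one-sided
    at the ends, as computed by ``numpy.gradient``).
    """
    q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    if len(q_grid) < 5 or np.any(np.diff(q_grid) <= 0):
        raise ConfigurationError("q_grid must be sorted with at least 5 points")
    r_max = None if r_range is None else int(max(r_range))
    _, masses, r_grid = mass_matrix(graph, r_max=r_max)
    r_range = _default_r_range(masses, r_grid) if r_range is None \
        else np.asarray(list(r_range), dtype=int)
    if len(r_range) < 3:
        raise ConfigurationError(
            "graph too small: need >= 3 radii below saturation for the spectrum"
        )
    tau = np.empty_like(q_grid)
    for k, q in enumerate(q_grid):
        tau[k] = mass_exponent(graph, q, r_range=r_range, _masses=(masses, r_grid))
        if not np.isfinite(tau[k]):
            raise ConfigurationError(f"non-finite mass exponent at q={q}")
    alpha = np.gradient(tau, q_grid)
    f_alpha = q_grid * alpha - tau
    return MultifractalSpectrum(q=q_grid, tau=tau, alpha=alpha,
                                f_alpha=f_alpha, r_range=r_range)
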