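"""Classical structural order parameters: RDF, P2 orientation order, density.

These are the conventional baselines against which the graph descriptors are
compared: the radial distribution function g(r) (local pair density
normalized by the bulk density), the nematic order parameter
P2 = <(3 cos^2 theta - 1)/2> over neighbouring molecular orientation vectors
(1 parallel, -0.5 perpendicular, 0 isotropic), the mass density, and RDFs
conditioned on descriptor quartiles (used to show that molecules sharing a
phase label are spatially clustered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .centrality_descriptors import NodeMetricTable
from .graph_construction import build_contact_graph
from .particles import (
    DEFAULT_CUTOFF,
    DEFAULT_SELECTION,
    ConfigurationError,
    ParticleConfiguration,
    SelectionSpec,
    minimum_image,
    wrap_positions,
)

__all__ = [
    "RDFResult",
    "OrientationTable",
    "MASS_TABLE",
    "AVOGADRO",
    "radial_distribution",
    "p2_order",
    "mass_density",
    "metric_conditioned_rdf",
]

AVOGADRO = 6.02214076e23

#: Bead masses in g/mol for the coarse-grained surfactant/water model
#: (trimethylammonium head, two C4 tail beads, 4-water bead, argon).
MASS_TABLE = {
    "head": 59.13,
    "tail": 56.12,
    "terminal_tail": 57.13,
    "solvent": 72.0,
    "atom": 39.948,
}


@dataclass
class RDFResult:
    """g(r) on a radial grid with the reference density used to normalize."""

    r: np.ndarray          # bin centers, nm
    g: np.ndarray          # dimensionless
    rho0: float            # reference density, nm^-3
    selection: str

    @property
    def first_peak(self) -> float:
        """Position of the global maximum of g(r)."""
        return float(self.r[int(np.argmax(self.g))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "g_r": self.g})


@dataclass
class OrientationTable:
    """Per-molecule orientation vectors and neighbour-averaged P2 values."""

    molecule_ids: np.ndarray
    vectors: np.ndarray          # (n_mol, 3) unit vectors
    per_molecule: pd.Series      # mean P2 over each molecule's neighbours (NaN: none)
    system_p2: float             # mean over molecules with >= 1 neighbour (NaN: none)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.system_p2)


def _wrapped_tree(points: np.ndarray, box: np.ndarray) -> cKDTree:
    pts = wrap_positions(points, box)
    return cKDTree(np.minimum(pts, np.nextafter(box, 0.0)), boxsize=box)


def _pair_counts(tree_a: cKDTree, tree_b: cKDTree, edges: np.ndarray) -> np.ndarray:
    """Ordered pair counts of (a, b) within each cumulative radius."""
    return tree_a.count_neighbors(tree_b, edges).astype(float)


def radial_distribution(
    config: ParticleConfiguration,
    selection: str = "terminal_tail",
    bin_width: float = 0.01,
    r_max: float | None = None,
) -> RDFResult:
    """Site-site RDF with periodic minimum-image pair counting.

    Pair counts per shell are normalized by the ideal-gas expectation
    ``N * rho0 * V_shell / 2`` at the bulk density ``rho0 = n/V``, so g -> 1
    at large r in a homogeneous system.  ``r_max`` defaults to (and may not
    exceed) half the smallest box edge.
    """
    box = config.box
    limit = float(np.min(box)) / 2.0
    if r_max is None:
        r_max = limit
    if r_max > limit + 1e-12:
        raise ConfigurationError(f"r_max must be <= min(box)/2 = {limit:.3f} nm")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    roles = [selection] if isinstance(selection, str) else list(selection)
    pos = config.positions[config.select(roles)]
    n = len(pos)
    if n < 2:
        raise ConfigurationError(f"selection {roles} matches fewer than 2 sites")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    tree = _wrapped_tree(pos, box)
    cum = _pair_counts(tree, tree, edges)
    cum -= n  # remove self pairs; remaining counts are ordered -> /2
    pair_counts = np.diff(cum) / 2.0
    rho0 = n / config.volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n * rho0 * shell / 2.0
    return RDFResult(
        r=0.5 * (edges[:-1] + edges[1:]),
        g=pair_counts / ideal,
        rho0=rho0,
        selection=",".join(roles),
    )


def molecular_vectors(config: ParticleConfiguration, selection: SelectionSpec):
    """Unit orientation vectors (from_role -> to_role site, minimum image)."""
    from_role, to_role = selection.vector_sites
    mols = config.molecules
    vecs = np.empty((len(mols), 3))
    for k, mol in enumerate(mols):
        mask = config.molecule_id == mol
        roles = config.site_role[mask]
        pos = config.positions[mask]
        a = pos[roles == from_role]
        b = pos[roles == to_role]
        if len(a) == 0 or len(b) == 0:
            raise ConfigurationError(
                f"molecule {mol} lacks a {from_role!r} or {to_role!r} site"
            )
        v = minimum_image(b[0] - a[0], config.box)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ConfigurationError(f"zero-length orientation vector on molecule {mol}")
        vecs[k] = v / norm
    return mols, vecs


def p2_order(
    config: ParticleConfiguration,
    selection: SelectionSpec = DEFAULT_SELECTION,
    neighbor_cutoff: float = DEFAULT_CUTOFF,
) -> OrientationTable:
    """Nematic order parameter over neighbouring molecule pairs.

    Neighbours are defined by the same rule as graph edges (minimum tail-site
    distance below ``neighbor_cutoff``).  For each neighbour pair,
    P2 = (3 cos^2 theta - 1)/2 with theta the angle between orientation
    vectors; each molecule's value is the mean over its neighbours and the
    system value the mean over molecules with at least one neighbour (NaN,
    flagged via ``defined``, when there are no pairs).
    """
    mols, vecs = molecular_vectors(config, selection)
    index = {m: i for i, m in enumerate(mols)}
    graph = build_contact_graph(config, selection, neighbor_cutoff)
    per_mol_sum = np.zeros(len(mols))
    per_mol_n = np.zeros(len(mols), dtype=int)
    for i, j in graph.edges:
        c = float(np.dot(vecs[index[i]], vecs[index[j]]))
        p2 = 0.5 * (3.0 * c * c - 1.0)
        per_mol_sum[index[i]] += p2
        per_mol_n[index[i]] += 1
        per_mol_sum[index[j]] += p2
        per_mol_n[index[j]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        per_mol = np.where(per_mol_n > 0, per_mol_sum / np.maximum(per_mol_n, 1),
                           np.nan)
    has_neighbors = per_mol_n > 0
    system = float(np.mean(per_mol[has_neighbors])) if has_neighbors.any() \
        else float("nan")
    return OrientationTable(
        molecule_ids=mols,
        vectors=vecs,
        per_molecule=pd.Series(per_mol, index=mols),
        system_p2=system,
    )


def mass_density(config: ParticleConfiguration, site_masses=None) -> float:
    """Mass density in g/cm^3 from per-role masses (g/mol) and box volume."""
    masses = MASS_TABLE if site_masses is None else site_masses
    total = 0.0
    for role in config.site_role:
        if role not in masses:
            raise ConfigurationError(f"no mass provided for site role {role!r}")
        total += masses[role]
    volume_cm3 = config.volume * 1e-21
    return total / AVOGADRO / volume_cm3


def metric_conditioned_rdf(
    config: ParticleConfiguration,
    metric_table: NodeMetricTable,
    mode: str = "all",
    selection: str = "terminal_tail",
    bin_width: float = 0.01,
    r_max: float | None = None,
) -> RDFResult:
    """RDF restricted to metric quartiles of the molecules.

    ``low25_low25`` / ``high25_high25`` compute the RDF among terminal-tail
    sites of the bottom / top metric quartile; ``high25_vs_low25`` computes
    the distribution of top-quartile sites around bottom-quartile sites;
    ``all`` is the unconditioned RDF.  Quartile ties are broken by node id.
    """
    if mode not in ("low25_low25", "high25_high25", "high25_vs_low25", "all"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if mode == "all":
        return radial_distribution(config, selection, bin_width, r_max)
    values = metric_table.values.dropna()
    if len(values) < 4:
        raise ConfigurationError("need at least 4 molecules for quartile RDFs")
    # stable sort by (value, node id) for deterministic ties
    df = pd.DataFrame({"node": values.index, "value": values.to_numpy()})
    df = df.sort_values(["value", "node"], kind="mergesort")
    q = len(df) // 4
    low = set(df["node"].iloc[:q])
    high = set(df["node"].iloc[-q:])

    roles = [selection] if isinstance(selection, str) else list(selection)
    role_mask = config.select(roles)
    box = config.box

    def sites_of(nodes):
        mask = role_mask & np.isin(config.molecule_id, list(nodes))
        return config.positions[mask]

    limit = float(np.min(box)) / 2.0
    if r_max is None:
        r_max = limit
    if r_max > limit + 1e-12:
        raise ConfigurationError(f"r_max must be <= min(box)/2 = {limit:.3f} nm")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    if mode in ("low25_low25", "high25_high25"):
        pos = sites_of(low if mode == "low25_low25" else high)
        if len(pos) < 2:
            raise ConfigurationError("quartile contains fewer than 2 sites")
        tree = _wrapped_tree(pos, box)
        cum = _pair_counts(tree, tree, edges) - len(pos)
        counts = np.diff(cum) / 2.0
        rho0 = len(pos) / config.volume
        ideal = len(pos) * rho0 * shell / 2.0
    else:  # high25_vs_low25: top-quartile density around bottom-quartile sites
        pos_low, pos_high = sites_of(low), sites_of(high)
        if len(pos_low) == 0 or len(pos_high) == 0:
            raise ConfigurationError("empty quartile selection")
        tree_low = _wrapped_tree(pos_low, box)
        tree_high = _wrapped_tree(pos_high, box)
        counts = np.diff(_pair_counts(tree_low, tree_high, edges))
        rho0 = len(pos_high) / config.volume
        ideal = len(pos_low) * rho0 * shell
    return RDFResult(
        r=0.5 * (edges[:-1] + edges[1:]),
        g=counts / ideal,
        rho0=rho0,
        selection=f"{','.join(roles)}[{mode}]",
    )
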