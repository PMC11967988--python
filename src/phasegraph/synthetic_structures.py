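"""Synthetic particle configurations and benchmark graphs.

These generators stand in for molecular-dynamics output: they build idealized
but geometrically realistic surfactant mesophases (spherical micelles,
hexagonally packed cylinders, stacked lamellae), baseline systems (FCC
crystal, random "ideal solution"), the five idealized reference aggregates,
and deterministic hierarchical graphs with a known box-growing fractal
dimension for validating the fractal estimators.

Every surfactant molecule is a linear 3-bead chain — polar head, middle tail
bead, terminal tail bead — with 0.47 nm bead spacing, mirroring a
coarse-grained octyltrimethylammonium ion.  All randomness is controlled by
an explicit integer seed.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from .particles import (
    BOND_LENGTH,
    DEFAULT_CUTOFF,
    ConfigurationError,
    ParticleConfiguration,
    minimum_image,
    wrap_positions,
)

__all__ = [
    "generate_fcc",
    "generate_ideal_solution",
    "generate_micellar",
    "generate_hexagonal",
    "generate_lamellar",
    "generate_idealized",
    "generate_fractal_graph",
    "IDEALIZED_KINDS",
]

#: Minimum site-site separation enforced by random placement (nm).
MIN_SEPARATION = 0.3

#: Roles of the 3-bead surfactant template, head first.
SURFACTANT_ROLES = ("head", "tail", "terminal_tail")


# ---------------------------------------------------------------------------
# small geometry helpers

def _surfactant_sites(head: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Sites of one molecule: head at ``head``, tails along ``direction``."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return np.stack([head + k * BOND_LENGTH * direction for k in range(3)])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _place_centers(
    n: int,
    box: np.ndarray,
    min_sep: float,
    rng: np.random.Generator,
    what: str,
    max_tries_per_center: int = 2000,
    max_restarts: int = 50,
) -> np.ndarray:
    """Rejection-sample ``n`` periodic points with pairwise separation > min_sep.

    Sequential placement can jam at moderate packing fractions, so a failed
    pass restarts from an empty box (bounded number of restarts).
    """
    for _restart in range(max_restarts):
        centers: list[np.ndarray] = []
        for _ in range(n):
            for _ in range(max_tries_per_center):
                c = rng.uniform(0.0, 1.0, 3) * box
                if not centers:
                    centers.append(c)
                    break
                d = minimum_image(np.asarray(centers) - c, box)
                if np.min(np.linalg.norm(d, axis=1)) > min_sep:
                    centers.append(c)
                    break
            else:
                break  # jammed: restart the whole placement
        if len(centers) == n:
            return np.asarray(centers)
    raise ConfigurationError(
        f"could not place {n} {what} with separation > {min_sep:.2f} nm "
        f"in box {tuple(box)}; density too high"
    )


def _assemble(
    site_blocks: list[np.ndarray],
    roles_per_molecule: list[tuple],
    box,
    jitter: float,
    rng: np.random.Generator | None,
    time: float | None = None,
) -> ParticleConfiguration:
    positions = np.concatenate(site_blocks, axis=0)
    if jitter > 0 and rng is not None:
        positions = positions + rng.normal(0.0, jitter, positions.shape)
    molecule_id = np.concatenate(
        [np.full(len(r), i) for i, r in enumerate(roles_per_molecule)]
    )
    roles = np.concatenate([np.asarray(r, dtype="U16") for r in roles_per_molecule])
    box = np.asarray(box, dtype=float).reshape(3)
    return ParticleConfiguration(
        positions=wrap_positions(positions, box),
        box=box,
        molecule_id=molecule_id,
        site_role=roles,
        time=time,
    )


# ---------------------------------------------------------------------------
# crystalline / random baselines

def generate_fcc(cells_per_edge: int, lattice_constant: float) -> ParticleConfiguration:
    """FCC crystal of single-site atoms (argon-like).

    Produces ``4 * cells_per_edge**3`` atoms in a cubic box of edge
    ``cells_per_edge * lattice_constant``; the nearest-neighbour distance is
    ``lattice_constant / sqrt(2)``.
    """
    if cells_per_edge < 1:
        raise ConfigurationError("cells_per_edge must be >= 1")
    if lattice_constant <= 0:
        raise ConfigurationError("lattice_constant must be positive")
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
    )
    cells = np.array(
        list(itertools.product(range(cells_per_edge), repeat=3)), dtype=float
    )
    positions = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    positions *= lattice_constant
    n = len(positions)
    box = np.full(3, cells_per_edge * lattice_constant)
    return ParticleConfiguration(
        positions=positions,
        box=box,
        molecule_id=np.arange(n),
        site_role=np.full(n, "atom"),
    )


def generate_ideal_solution(
    n_molecules: int,
    sites_per_molecule: int = 3,
    box=(22.04, 22.04, 22.04),
    seed: int = 0,
) -> ParticleConfiguration:
    """Uniformly random, non-aggregating molecules — the "ideal solution".

    Molecule centres are uniform in the box (rejection-sampled so that no two
    sites of different molecules come closer than 0.3 nm); sites of each
    molecule are collinear at the 0.47 nm bead spacing along a random
    direction.  Deterministic under ``seed``.
    """
    if n_molecules < 1 or sites_per_molecule < 1:
        raise ConfigurationError("n_molecules and sites_per_molecule must be >= 1")
    box = np.asarray(box, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    if sites_per_molecule == 1:
        roles = ("tail",)
    elif sites_per_molecule == 2:
        roles = ("tail", "terminal_tail")
    else:
        roles = ("head",) + ("tail",) * (sites_per_molecule - 2) + ("terminal_tail",)

    placed_sites: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    half_span = 0.5 * BOND_LENGTH * (sites_per_molecule - 1)
    max_tries = 2000
    for _ in range(n_molecules):
        for _ in range(max_tries):
            center = rng.uniform(0.0, 1.0, 3) * box
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            offsets = (np.arange(sites_per_molecule) * BOND_LENGTH - half_span)
            sites = center + offsets[:, None] * u
            if placed_sites:
                existing = np.concatenate(placed_sites)
                d = minimum_image(existing[:, None, :] - sites[None, :, :], box)
                if np.min(np.linalg.norm(d, axis=-1)) < MIN_SEPARATION:
                    continue
            placed_sites.append(sites)
            blocks.append(sites)
            break
        else:
            raise ConfigurationError(
                "could not place molecules without overlap; density too high"
            )
    return _assemble(blocks, [roles] * n_molecules, box, 0.0, None)


# ---------------------------------------------------------------------------
# mesophase generators

def generate_micellar(
    n_micelles: int = 32,
    aggregation_number: int = 25,
    micelle_radius: float = 1.6,
    box=(22.04, 22.04, 22.04),
    seed: int = 0,
    jitter: float = 0.04,
) -> ParticleConfiguration:
    """Disconnected spherical micelles.

    Heads sit on a sphere of radius ``micelle_radius`` around each micelle
    centre, tails point inward along the radius, so the terminal tail beads
    crowd near the centre and every micelle forms a tightly connected graph
    component.  Micelle centres are separated by more than
    ``2 * (radius + tail length) + cutoff`` so distinct micelles stay
    disconnected at the default 0.7 nm contact cutoff.
    """
    if n_micelles < 1 or aggregation_number < 1:
        raise ConfigurationError("counts must be >= 1")
    if micelle_radius <= 0:
        raise ConfigurationError("micelle_radius must be positive")
    box = np.asarray(box, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    tail_length = 2 * BOND_LENGTH
    min_sep = 2 * (micelle_radius + tail_length) + DEFAULT_CUTOFF
    centers = _place_centers(n_micelles, box, min_sep, rng, "micelles")

    blocks = []
    base_dirs = _fibonacci_sphere(aggregation_number)
    for c in centers:
        rot = _random_rotation(rng)
        dirs = base_dirs @ rot.T
        for u in dirs:
            head = c + micelle_radius * u
            blocks.append(_surfactant_sites(head, -u))
    roles = [SURFACTANT_ROLES] * (n_micelles * aggregation_number)
    return _assemble(blocks, roles, box, jitter, rng)


def generate_hexagonal(
    n_cylinders: int = 4,
    molecules_per_ring: int = 10,
    rings_per_cylinder: int = 20,
    ring_spacing: float = 0.5,
    box=None,
    seed: int = 0,
    cylinder_radius: float = 1.4,
    jitter: float = 0.04,
) -> ParticleConfiguration:
    """Hexagonally packed cylinders, periodic ("infinite") along z.

    Each cylinder is a stack of rings of radially oriented molecules (heads
    outward at ``cylinder_radius``, terminal tails near the axis); successive
    rings are staggered by half the angular spacing.  Cylinder axes sit on a
    staggered (triangular-like) lattice in the xy plane.  The box must close
    the stack periodically: ``box_z = rings_per_cylinder * ring_spacing``.
    """
    if min(n_cylinders, molecules_per_ring, rings_per_cylinder) < 1:
        raise ConfigurationError("counts must be >= 1")
    if ring_spacing <= 0 or cylinder_radius <= 0:
        raise ConfigurationError("spacings must be positive")
    ncols = math.ceil(math.sqrt(n_cylinders))
    nrows = math.ceil(n_cylinders / ncols)
    lattice = 2 * cylinder_radius + 2 * DEFAULT_CUTOFF + 1.2
    box_z = rings_per_cylinder * ring_spacing
    if box is None:
        box = np.array([ncols * lattice, nrows * lattice, box_z])
    else:
        box = np.asarray(box, dtype=float).reshape(3)
        if abs(box[2] - box_z) > 1e-9:
            raise ConfigurationError(
                f"box_z must equal rings_per_cylinder * ring_spacing = {box_z}"
            )
        ax, ay = box[0] / ncols, box[1] / nrows
        if min(ax, ay) < 2 * cylinder_radius + DEFAULT_CUTOFF:
            raise ConfigurationError("cylinder lattice does not fit box")

    rng = np.random.default_rng(seed)
    ax, ay = box[0] / ncols, box[1] / nrows
    axes = []
    for k in range(n_cylinders):
        i, j = k % ncols, k // ncols
        axes.append(((i + 0.5 + 0.5 * (j % 2)) % ncols * ax, (j + 0.5) * ay))

    blocks = []
    dtheta = 2 * np.pi / molecules_per_ring
    for x0, y0 in axes:
        for ring in range(rings_per_cylinder):
            z = (ring + 0.5) * ring_spacing
            offset = 0.5 * dtheta * (ring % 2)
            for m in range(molecules_per_ring):
                theta = m * dtheta + offset
                u = np.array([np.cos(theta), np.sin(theta), 0.0])
                head = np.array([x0, y0, z]) + cylinder_radius * u
                blocks.append(_surfactant_sites(head, -u))
    n_mol = n_cylinders * molecules_per_ring * rings_per_cylinder
    return _assemble(blocks, [SURFACTANT_ROLES] * n_mol, box, jitter, rng)


def generate_lamellar(
    n_lamellae: int = 4,
    grid=(10, 10),
    in_plane_spacing: float = 0.6,
    interlamellar_gap: float = 0.7,
    hole_fraction: float = 0.0,
    bridge_count: int = 0,
    box=None,
    seed: int = 0,
    jitter: float = 0.03,
) -> ParticleConfiguration:
    """Stacked bilayers (lamellae), periodic in the xy plane.

    Each lamella is a bilayer of two ``grid`` leaflets with tails pointing
    inward (opposing terminal beads 0.5 nm apart); leaflets are laterally
    staggered by half the grid spacing.  ``hole_fraction`` removes that
    fraction of molecules per lamella at seeded-random positions.  Each
    "bridge" inserts a tail-to-tail pair of molecules spanning the gap
    between adjacent lamellae (including the periodic z wrap), modelling the
    transient inter-lamellar contacts seen in the lamellar phase;
    ``bridge_count`` bridges are inserted per adjacent pair.
    """
    if hole_fraction >= 1.0 or hole_fraction < 0.0:
        raise ConfigurationError("hole_fraction must be in [0, 1)")
    if n_lamellae < 1 or bridge_count < 0:
        raise ConfigurationError("n_lamellae >= 1 and bridge_count >= 0 required")
    nx_, ny_ = grid
    if nx_ < 1 or ny_ < 1 or in_plane_spacing <= 0 or interlamellar_gap <= 0:
        raise ConfigurationError("grid and spacings must be positive")

    leaflet_sep = 0.5  # terminal-to-terminal across the bilayer midplane (nm)
    tail_len = 2 * BOND_LENGTH
    thickness = 2 * tail_len + leaflet_sep  # head plane to head plane
    period = thickness + interlamellar_gap
    if box is None:
        box = np.array([nx_ * in_plane_spacing, ny_ * in_plane_spacing,
                        n_lamellae * period])
    else:
        box = np.asarray(box, dtype=float).reshape(3)
        if abs(box[2] - n_lamellae * period) > 1e-9:
            raise ConfigurationError("box_z inconsistent with lamellar stack period")

    rng = np.random.default_rng(seed)
    sp = in_plane_spacing
    blocks: list[np.ndarray] = []
    roles: list[tuple] = []
    head_planes = []  # (z_bottom_heads, z_top_heads) per lamella
    for lam in range(n_lamellae):
        z_mid = lam * period + 0.5 * thickness
        z_top = z_mid + 0.5 * thickness
        z_bot = z_mid - 0.5 * thickness
        head_planes.append((z_bot, z_top))
        lam_blocks = []
        for i in range(nx_):
            for j in range(ny_):
                # top leaflet: heads up, tails down
                head = np.array([i * sp, j * sp, z_top])
                lam_blocks.append(_surfactant_sites(head, np.array([0, 0, -1.0])))
                # bottom leaflet: staggered half a cell, heads down
                head = np.array([(i + 0.5) * sp, (j + 0.5) * sp, z_bot])
                lam_blocks.append(_surfactant_sites(head, np.array([0, 0, 1.0])))
        if hole_fraction > 0:
            n_keep = len(lam_blocks) - round(hole_fraction * len(lam_blocks))
            keep = rng.choice(len(lam_blocks), size=n_keep, replace=False)
            lam_blocks = [lam_blocks[k] for k in sorted(keep)]
        blocks.extend(lam_blocks)
        roles.extend([SURFACTANT_ROLES] * len(lam_blocks))

    if bridge_count > 0 and n_lamellae > 1:
        penetration = 0.35  # how deep a bridge terminal bead dips below a head plane
        for lam in range(n_lamellae):
            z_top = head_planes[lam][1]
            for _ in range(bridge_count):
                x, y = rng.uniform(0, box[0]), rng.uniform(0, box[1])
                # molecule reaching down into lamella `lam`
                term_down = np.array([x, y, z_top - penetration])
                blocks.append(_surfactant_sites(
                    term_down + 2 * BOND_LENGTH * np.array([0, 0, 1.0]),
                    np.array([0, 0, -1.0])))
                # partner reaching up into lamella `lam+1` (periodic)
                z_bot_next = z_top + interlamellar_gap
                term_up = np.array([x + 0.1, y, z_bot_next + penetration])
                blocks.append(_surfactant_sites(
                    term_up - 2 * BOND_LENGTH * np.array([0, 0, 1.0]),
                    np.array([0, 0, 1.0])))
                roles.extend([SURFACTANT_ROLES] * 2)

    return _assemble(blocks, roles, box, jitter, rng)


# ---------------------------------------------------------------------------
# idealized reference aggregates

IDEALIZED_KINDS = (
    "bidimensional_micelle",
    "infinite_cylinder",
    "monolayer",
    "bilayer1",
    "bilayer2",
)

_RING_SIZE = 8          # molecules in a planar ring
_RING_HEAD_RADIUS = 1.4  # nm
_LAYER_SPACING = 0.6     # hexagonal in-plane spacing of layer structures (nm)


def _planar_ring(center: np.ndarray, z: float) -> list[np.ndarray]:
    sites = []
    for m in range(_RING_SIZE):
        theta = 2 * np.pi * m / _RING_SIZE
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        head = center + _RING_HEAD_RADIUS * u
        head[2] = z
        sites.append(_surfactant_sites(head, -u))
    return sites


def _hex_layer_xy(n_molecules: int, spacing: float):
    """Hexagonal (staggered-row) lattice points, row-major, n_molecules of them."""
    ncols = math.ceil(math.sqrt(n_molecules / (math.sqrt(3) / 2)))
    pts = []
    row = 0
    while len(pts) < n_molecules:
        for col in range(ncols):
            if len(pts) == n_molecules:
                break
            x = (col + 0.5 * (row % 2)) * spacing
            y = row * spacing * math.sqrt(3) / 2
            pts.append((x, y))
        row += 1
    extent_x = ncols * spacing
    extent_y = row * spacing * math.sqrt(3) / 2
    return np.asarray(pts), (extent_x, extent_y)


def generate_idealized(kind: str) -> ParticleConfiguration:
    """One of the five idealized reference aggregates (static geometry).

    - ``bidimensional_micelle``: planar ring of 8 molecules, tails toward the
      centre, every site at one z value.
    - ``infinite_cylinder``: 16 such rings stacked along z in a z-periodic box
      (128 molecules).
    - ``monolayer``: 224 molecules standing along z on a hexagonal lattice,
      heads coplanar.
    - ``bilayer1``: as monolayer but with alternate molecules flipped, giving
      two hydrophilic surfaces (224 molecules, interdigitated).
    - ``bilayer2``: the monolayer plus a second, oppositely oriented layer
      with tails in contact (448 molecules).
    """
    if kind not in IDEALIZED_KINDS:
        raise ConfigurationError(
            f"unknown idealized kind {kind!r}; choose from {IDEALIZED_KINDS}"
        )
    margin = 3.0
    if kind == "bidimensional_micelle":
        edge = 2 * (_RING_HEAD_RADIUS + margin)
        center = np.array([edge / 2, edge / 2, 0.0])
        blocks = _planar_ring(center, edge / 2)
        box = (edge, edge, edge)
    elif kind == "infinite_cylinder":
        n_rings, spacing = 16, 0.5
        edge = 2 * (_RING_HEAD_RADIUS + margin)
        blocks = []
        for ring in range(n_rings):
            z = (ring + 0.5) * spacing
            center = np.array([edge / 2, edge / 2, 0.0])
            offset = np.pi / _RING_SIZE * (ring % 2)
            for m in range(_RING_SIZE):
                theta = 2 * np.pi * m / _RING_SIZE + offset
                u = np.array([np.cos(theta), np.sin(theta), 0.0])
                head = center + _RING_HEAD_RADIUS * u
                head[2] = z
                blocks.append(_surfactant_sites(head, -u))
        box = (edge, edge, n_rings * spacing)  # z-periodic: infinite cylinder
    elif kind in ("monolayer", "bilayer1"):
        pts, (ex, ey) = _hex_layer_xy(224, _LAYER_SPACING)
        z_head = 2 * BOND_LENGTH + margin
        blocks = []
        for k, (x, y) in enumerate(pts):
            flip = kind == "bilayer1" and k % 2 == 1
            direction = np.array([0, 0, 1.0]) if flip else np.array([0, 0, -1.0])
            head_z = z_head - 2 * BOND_LENGTH if flip else z_head
            blocks.append(_surfactant_sites(np.array([x, y, head_z]), direction))
        box = (ex, ey, z_head + margin)
    else:  # bilayer2
        pts, (ex, ey) = _hex_layer_xy(224, _LAYER_SPACING)
        tail_gap = 0.5
        z_mid = 2 * BOND_LENGTH + margin
        blocks = []
        for x, y in pts:
            # upper layer: heads up
            head = np.array([x, y, z_mid + tail_gap / 2 + 2 * BOND_LENGTH])
            blocks.append(_surfactant_sites(head, np.array([0, 0, -1.0])))
            # lower layer: staggered, heads down
            head = np.array([x + _LAYER_SPACING / 2, y + _LAYER_SPACING / 2,
                             z_mid - tail_gap / 2 - 2 * BOND_LENGTH])
            blocks.append(_surfactant_sites(head, np.array([0, 0, 1.0])))
        box = (ex, ey, 2 * z_mid + tail_gap)
    roles = [SURFACTANT_ROLES] * len(blocks)
    return _assemble(blocks, roles, box, 0.0, None)


# ---------------------------------------------------------------------------
# benchmark fractal graphs

def generate_fractal_graph(b: int, f: float, levels: int) -> nx.Graph:
    """Deterministic hierarchical graph with box-growing dimension ln(b)/ln(1/f).

    The level-k unit is built from ``b`` copies of the level-(k-1) unit:
    ``s = 1/f`` copies glued end-to-end into a backbone chain (so the
    terminal-to-terminal distance multiplies by s at every level) and the
    remaining ``b - s`` copies attached as dangling branches, distributed
    round-robin over the s backbone junctions.  The construction is
    metrically self-similar: the BFS ball of radius ``s**j`` around the left
    terminal (node 0, stored as ``graph.graph["origin"]``) contains the
    complete level-j prefix unit of ~``b**j`` nodes, hence
    ``M(r) ~ r**(ln b / ln s)`` with log-periodic oscillation.

    Requires ``1/f`` integer >= 2 and ``b >= 1/f`` (a connected graph cannot
    have dimension below 1).  The analytic dimension is stored in
    ``graph.graph["analytic_dimension"]``.
    """
    if not (0.0 < f < 1.0):
        raise ConfigurationError("f must lie strictly between 0 and 1")
    s_real = 1.0 / f
    s = round(s_real)
    if abs(s_real - s) > 1e-9 or s < 2:
        raise ConfigurationError("1/f must be an integer >= 2")
    if b < s:
        raise ConfigurationError(
            "b must be >= 1/f: a connected graph cannot have dimension below 1"
        )
    if levels < 1:
        raise ConfigurationError("levels must be >= 1")

    # per-junction dangling-copy counts (junctions follow backbone units 1..s)
    extra = b - s
    dangles = [extra // s + (1 if p < extra % s else 0) for p in range(s)]

    def glue(unit_edges, unit_n, left_map, next_free):
        """Place a copy of the unit with its left terminal at ``left_map``."""
        mapping = {0: left_map}
        for node in range(1, unit_n):
            mapping[node] = next_free
            next_free += 1
        edges = [(mapping[u], mapping[v]) for u, v in unit_edges]
        return edges, next_free, mapping

    # current unit: edge list over local labels 0..unit_n-1 with left
    # terminal 0 and right terminal `right`; start from a single edge
    unit_edges, unit_n, right = [(0, 1)], 2, 1
    for _level in range(levels):
        edges_new: list[tuple] = []
        next_free = 1  # 0 is the new unit's left terminal
        attach = 0     # backbone junction being extended
        for p in range(s):
            edges, next_free, mapping = glue(unit_edges, unit_n, attach, next_free)
            edges_new.extend(edges)
            attach = mapping[right]
            for _d in range(dangles[p]):
                edges, next_free, _ = glue(unit_edges, unit_n, attach, next_free)
                edges_new.extend(edges)
        unit_edges, unit_n, right = edges_new, next_free, attach

    g = nx.Graph(unit_edges)
    g.graph["analytic_dimension"] = math.log(b) / math.log(s)
    g.graph["b"], g.graph["f"], g.graph["levels"] = b, f, levels
    g.graph["origin"] = 0
    g.graph["terminal"] = right
    return g
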