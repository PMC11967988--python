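"""Core containers: particle configurations and site selections.

All coordinates are in nanometres and boxes are orthorhombic, following the
GRO convention.  A *site* is one coarse-grained bead; a *molecule* is a group
of sites sharing a ``molecule_id``.  Site roles distinguish the polar head,
the hydrophobic tail beads (the terminal one kept separate because several
analyses select it specifically), solvent beads and plain atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

#: Recognised site roles.
ROLES = ("head", "tail", "terminal_tail", "solvent", "atom")

#: Coarse-grained bond length between consecutive beads of a surfactant (nm).
BOND_LENGTH = 0.47

#: Contact cutoff between tail sites defining graph edges (nm) — the first
#: minimum of the tail-site RDF in the surfactant systems this package models.
DEFAULT_CUTOFF = 0.7


class ConfigurationError(ValueError):
    """Invalid parameters or inconsistent configuration data."""


@dataclass(frozen=True)
class SelectionSpec:
    """Which sites form graph contacts and define molecular orientation.

    Parameters
    ----------
    tail_roles
        Site roles whose pairwise distances define contact-graph edges.
    vector_sites
        Ordered ``(from_role, to_role)`` pair defining each molecule's
        orientation vector (default: head to terminal tail bead).
    node_scope
        What a graph node represents.  ``surfactant_molecule`` (default)
        maps one node per molecule owning at least one tail-role site;
        ``atom`` maps one node per site.
    """

    tail_roles: frozenset = frozenset({"tail", "terminal_tail"})
    vector_sites: tuple = ("head", "terminal_tail")
    node_scope: str = "surfactant_molecule"

    def __post_init__(self):
        object.__setattr__(self, "tail_roles", frozenset(self.tail_roles))
        if not self.tail_roles:
            raise ConfigurationError("tail_roles must be non-empty")
        if len(self.vector_sites) != 2 or self.vector_sites[0] == self.vector_sites[1]:
            raise ConfigurationError("vector_sites must be two distinct roles")
        if self.node_scope not in ("surfactant_molecule", "cation_chain", "atom"):
            raise ConfigurationError(f"unknown node_scope {self.node_scope!r}")


#: Default selection for 3-bead surfactant systems.
DEFAULT_SELECTION = SelectionSpec()

#: Selection for single-site atomic systems (e.g. argon).
ATOM_SELECTION = SelectionSpec(
    tail_roles=frozenset({"atom"}), vector_sites=("head", "terminal_tail"),
    node_scope="atom",
)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into ``[0, box)`` (idempotent)."""
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    return positions - np.floor(positions / box) * box


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


@dataclass
class ParticleConfiguration:
    """Positions, box, molecule ids and site roles of one frame.

    Attributes
    ----------
    positions : (n, 3) float array, nm
    box : (3,) float array, nm (orthorhombic edge lengths, all > 0)
    molecule_id : (n,) int array
    site_role : (n,) str array, entries from :data:`ROLES`
    time : frame time in ns, or None
    """

    positions: np.ndarray
    box: np.ndarray
    molecule_id: np.ndarray
    site_role: np.ndarray
    time: float | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int).reshape(-1)
        self.site_role = np.asarray(self.site_role, dtype="U16").reshape(-1)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ConfigurationError("positions must be an (n, 3) array")
        if not np.all(self.box > 0):
            raise ConfigurationError("box lengths must be positive")
        if len(self.molecule_id) != n or len(self.site_role) != n:
            raise ConfigurationError(
                "molecule_id and site_role must have one entry per site"
            )
        bad = set(np.unique(self.site_role)) - set(ROLES)
        if bad:
            raise ConfigurationError(f"unknown site roles: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def molecules(self) -> np.ndarray:
        """Sorted unique molecule ids."""
        return np.unique(self.molecule_id)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def volume(self) -> float:
        """Box volume in nm^3."""
        return float(np.prod(self.box))

    def wrapped(self) -> "ParticleConfiguration":
        """Return a copy with all positions wrapped into the box."""
        return replace(self, positions=wrap_positions(self.positions, self.box))

    def select(self, roles: Iterable[str]) -> np.ndarray:
        """Boolean mask of sites whose role is in ``roles``."""
        return np.isin(self.site_role, list(roles))

    def site_positions(self, role: str) -> np.ndarray:
        """Positions of all sites with the given role."""
        return self.positions[self.site_role == role]
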