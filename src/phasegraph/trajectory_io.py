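"""Reading and writing configurations, trajectories and selection files.

Supported formats (all plain text, coordinates in nm):

- GRO (GROMACS coordinate file) via MDAnalysis; molecule identity comes from
  residue numbers and site roles from a documented atom-name mapping
  (HEA/TAI/TER/W/AR).  Only orthorhombic box lines are accepted.
- XYZ with the orthorhombic box lengths as the first three floats of the
  comment line ("Lx Ly Lz"); a sidecar selection file carrying per-site
  roles and molecule ids is mandatory.
- CSV with columns mol_id, role, x, y, z and a leading "# box Lx Ly Lz"
  comment line.

A selection file is a simple key=value text file declaring which roles form
graph contacts, which site pair defines the orientation vector, and
(optionally, for XYZ) the per-site roles and molecule ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .particles import ConfigurationError, ParticleConfiguration, SelectionSpec

__all__ = [
    "Trajectory",
    "ParseError",
    "read_configuration",
    "write_configuration",
    "read_trajectory",
    "read_selection",
    "write_selection",
    "ROLE_TO_ATOM_NAME",
]


class ParseError(ValueError):
    """A file did not parse in its declared dialect."""


#: Role <-> GRO/XYZ atom-name mapping.
ROLE_TO_ATOM_NAME = {
    "head": "HEA",
    "tail": "TAI",
    "terminal_tail": "TER",
    "solvent": "W",
    "atom": "AR",
}
ATOM_NAME_TO_ROLE = {v: k for k, v in ROLE_TO_ATOM_NAME.items()}
_RESNAME = {"head": "SUR", "tail": "SUR", "terminal_tail": "SUR",
            "solvent": "SOL", "atom": "ATM"}


@dataclass
class Trajectory:
    """An ordered sequence of frames with consistent molecule topology."""

    frames: list
    timestep: float | None = None

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k):
        return self.frames[k]


# ---------------------------------------------------------------------------
# selection files

def write_selection(selection: SelectionSpec, path, config=None) -> None:
    """Write a key=value selection file; with ``config`` also the per-site
    roles and molecule ids (needed to re-read XYZ)."""
    lines = [
        f"tail_roles = {','.join(sorted(selection.tail_roles))}",
        f"vector_sites = {selection.vector_sites[0]},{selection.vector_sites[1]}",
        f"node_scope = {selection.node_scope}",
    ]
    if config is not None:
        lines.append("site_roles = " + " ".join(config.site_role))
        lines.append("molecule_ids = " + " ".join(map(str, config.molecule_id)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_selection(path):
    """Read a selection file -> (SelectionSpec, site_roles|None, mol_ids|None)."""
    entries = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        entries[key] = value
    try:
        spec = SelectionSpec(
            tail_roles=frozenset(entries["tail_roles"].split(",")),
            vector_sites=tuple(entries["vector_sites"].split(",")),
            node_scope=entries.get("node_scope", "surfactant_molecule"),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing required key {exc}") from exc
    roles = np.array(entries["site_roles"].split()) if "site_roles" in entries else None
    mol_ids = (np.array(entries["molecule_ids"].split(), dtype=int)
               if "molecule_ids" in entries else None)
    return spec, roles, mol_ids


# ---------------------------------------------------------------------------
# GRO via MDAnalysis

def _read_gro(path) -> ParticleConfiguration:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ParseError("MDAnalysis is required for GRO files") from exc
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not a valid GRO file ({exc})") from exc
    dims = universe.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ParseError(f"{path}: missing or invalid box line")
    if not np.allclose(dims[3:], 90.0):
        raise ParseError(f"{path}: triclinic boxes are not supported")
    names = universe.atoms.names
    try:
        roles = np.array([ATOM_NAME_TO_ROLE[n] for n in names])
    except KeyError as exc:
        raise ParseError(
            f"{path}: unknown atom name {exc} (expected one of "
            f"{sorted(ATOM_NAME_TO_ROLE)})"
        ) from exc
    return ParticleConfiguration(
        positions=universe.atoms.positions.astype(float) / 10.0,  # A -> nm
        box=dims[:3].astype(float) / 10.0,
        molecule_id=universe.atoms.resids.astype(int),
        site_role=roles,
    )


def _write_gro(config: ParticleConfiguration, path) -> None:
    import MDAnalysis as mda

    n = config.n_sites
    mols = config.molecules
    resindex = np.searchsorted(mols, config.molecule_id)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(
            n_atoms=n, n_residues=len(mols), atom_resindex=resindex,
            trajectory=True,
        )
        universe.add_TopologyAttr(
            "names", [ROLE_TO_ATOM_NAME[r] for r in config.site_role]
        )
        first_role = [config.site_role[config.molecule_id == m][0] for m in mols]
        universe.add_TopologyAttr("resnames", [_RESNAME[r] for r in first_role])
        universe.add_TopologyAttr("resids", mols)
        universe.atoms.positions = config.positions * 10.0  # nm -> A
        universe.dimensions = [*(config.box * 10.0), 90.0, 90.0, 90.0]
        universe.atoms.write(str(path))


# ---------------------------------------------------------------------------
# XYZ / CSV dialects

def _write_xyz(config: ParticleConfiguration, path) -> None:
    comment = " ".join(f"{b:.6f}" for b in config.box)
    if config.time is not None:
        comment += f" t={config.time:g}"
    lines = [str(config.n_sites), comment]
    for role, p in zip(config.site_role, config.positions):
        name = ROLE_TO_ATOM_NAME[role]
        lines.append(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_xyz(path, selection_path=None) -> ParticleConfiguration:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}:1: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:1: expected an atom count") from exc
    floats = []
    time = None
    for token in lines[1].replace(",", " ").split():
        if token.startswith("t="):
            time = float(token[2:])
            continue
        try:
            floats.append(float(token))
        except ValueError:
            continue
    if len(floats) < 3:
        raise ParseError(
            f"{path}:2: comment line must carry the box as 'Lx Ly Lz'"
        )
    box = np.array(floats[:3])
    records = lines[2:2 + n]
    if len(records) < n:
        raise ParseError(f"{path}: header declares {n} sites, found {len(records)}")
    positions = np.empty((n, 3))
    names = []
    for k, rec in enumerate(records):
        parts = rec.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{k + 3}: expected 'name x y z'")
        try:
            positions[k] = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}:{k + 3}: malformed coordinates") from exc
        names.append(parts[0])
    if selection_path is None:
        raise ParseError(
            f"{path}: XYZ input requires a sidecar selection file with "
            "molecule_ids (and optionally site_roles)"
        )
    _, roles, mol_ids = read_selection(selection_path)
    if mol_ids is None:
        raise ParseError(f"{selection_path}: missing molecule_ids for XYZ input")
    if len(mol_ids) != n or (roles is not None and len(roles) != n):
        raise ParseError(
            f"{selection_path}: sidecar lengths do not match {n} sites"
        )
    if roles is None:
        roles = np.array([ATOM_NAME_TO_ROLE.get(nm, "atom") for nm in names])
    return ParticleConfiguration(positions=positions, box=box,
                                 molecule_id=mol_ids, site_role=roles,
                                 time=time)


def _write_csv(config: ParticleConfiguration, path) -> None:
    with open(path, "w") as fh:
        header = "# box " + " ".join(f"{b:.6f}" for b in config.box)
        if config.time is not None:
            header += f" t={config.time:g}"
        fh.write(header + "\n")
        fh.write("mol_id,role,x,y,z\n")
        for mol, role, p in zip(config.molecule_id, config.site_role,
                                config.positions):
            fh.write(f"{mol},{role},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")


def _read_csv(path) -> ParticleConfiguration:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# box"):
        raise ParseError(f"{path}:1: expected leading '# box Lx Ly Lz' line")
    tokens = first.split()[2:]
    time = None
    if tokens and tokens[-1].startswith("t="):
        time = float(tokens[-1][2:])
        tokens = tokens[:-1]
    try:
        box = np.array([float(t) for t in tokens[:3]])
        assert len(box) == 3
    except (ValueError, AssertionError) as exc:
        raise ParseError(f"{path}:1: malformed box line") from exc
    try:
        df = pd.read_csv(path, skiprows=1)
    except Exception as exc:
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    required = {"mol_id", "role", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}:2: missing columns {sorted(required - set(df.columns))}"
        )
    return ParticleConfiguration(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        box=box,
        molecule_id=df["mol_id"].to_numpy(dtype=int),
        site_role=df["role"].to_numpy(dtype="U16"),
        time=time,
    )


# ---------------------------------------------------------------------------
# public API

def _infer_format(path, format):
    if format is not None:
        return format
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("gro", "xyz", "csv"):
        return suffix
    raise ConfigurationError(f"cannot infer format from {path}; pass format=")


def read_configuration(path, format: str | None = None,
                       selection_path=None) -> ParticleConfiguration:
    """Read one configuration from a GRO, XYZ or CSV file."""
    fmt = _infer_format(path, format)
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "xyz":
        return _read_xyz(path, selection_path)
    if fmt == "csv":
        return _read_csv(path)
    raise ConfigurationError(f"unknown format {fmt!r}")


def write_configuration(config: ParticleConfiguration, path,
                        format: str | None = None) -> None:
    """Write a configuration as GRO, XYZ or CSV (format from the extension)."""
    fmt = _infer_format(path, format)
    if fmt == "gro":
        _write_gro(config, path)
    elif fmt == "xyz":
        _write_xyz(config, path)
    elif fmt == "csv":
        _write_csv(config, path)
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")


def read_trajectory(paths, format: str | None = None, selection_path=None,
                    timestep: float | None = None) -> Trajectory:
    """Read an ordered trajectory from per-frame coordinate files.

    Frames are ordered by their time attribute when available (out-of-order
    input is re-sorted with a warning); all frames must share molecule count
    and site roles.
    """
    frames = []
    for k, path in enumerate(paths):
        config = read_configuration(path, format, selection_path)
        if config.time is None:
            config.time = float(k) if timestep is None else k * timestep
        frames.append((config, path))
    if not frames:
        raise ConfigurationError("no frames given")
    ref, ref_path = frames[0]
    for config, path in frames[1:]:
        if (config.n_sites != ref.n_sites
                or not np.array_equal(config.site_role, ref.site_role)
                or not np.array_equal(config.molecule_id, ref.molecule_id)):
            raise ConfigurationError(
                f"frame {path} does not share the topology of {ref_path}"
            )
    times = [c.time for c, _ in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        warnings.warn("frames out of time order; reordering by time")
        frames.sort(key=lambda item: item[0].time)
    return Trajectory(frames=[c for c, _ in frames], timestep=timestep)
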