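"""Trajectory and topology readers/writers.

Two trajectory branches are supported:

* LAMMPS text dumps (``ITEM:`` sections), parsed natively. Dump coordinates
  are assumed to be in Angstroms unless ``length_unit='nm'``; the TIMESTEP
  counter is converted to ns via ``timestep_fs``.
* GRO coordinate (+ optional XTC-class trajectory) files through MDAnalysis;
  MDAnalysis reports Angstroms and ps, converted on ingest.

Molecular bookkeeping comes from a *topology sidecar*: whitespace-delimited
text with one row per bead, columns ``bead molecule species role``.
``#category SPECIES CATEGORY`` comment lines extend the species vocabulary
(e.g. a custom neutral lipid mapped to category ``tg``).

Internal units on return are always nm / ns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BeadFrame, Trajectory
from .errors import ContractError, ParseError, StructuralError

__all__ = [
    "Topology",
    "read_topology",
    "write_topology",
    "read_lammps_dump",
    "write_lammps_dump",
    "read_gro_xtc",
    "read_trajectory",
]

ANGSTROM_TO_NM = 0.1


@dataclass
class Topology:
    """Per-bead molecular assignments plus vocabulary extensions."""

    bead_to_molecule: np.ndarray
    molecule_to_species: dict[int, str]
    bead_role: np.ndarray
    species_categories: dict[str, str]

    @property
    def n_beads(self) -> int:
        return len(self.bead_to_molecule)


def read_topology(path: str | os.PathLike) -> Topology:
    """Parse a topology sidecar (columns: bead molecule species role)."""
    beads: dict[int, tuple[int, str, str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0].lower() == "category":
                    if len(parts) != 3:
                        raise ParseError("expected '#category SPECIES CATEGORY'", lineno)
                    categories[parts[1]] = parts[2].lower()
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"expected 'bead molecule species [role]', got {line!r}", lineno
                )
            try:
                bead = int(parts[0])
                mol = int(parts[1])
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            role = parts[3] if len(parts) > 3 else "other"
            if bead in beads:
                raise ParseError(f"duplicate bead index {bead}", lineno)
            beads[bead] = (mol, parts[2], role)
    if not beads:
        raise ParseError("topology file declares no beads")
    n = max(beads) + 1
    if sorted(beads) != list(range(n)):
        raise StructuralError("bead indices must be contiguous from 0")
    b2m = np.empty(n, dtype=np.int64)
    roles = np.empty(n, dtype="U8")
    m2s: dict[int, str] = {}
    for bead, (mol, species, role) in beads.items():
        b2m[bead] = mol
        roles[bead] = role
        prev = m2s.setdefault(mol, species)
        if prev != species:
            raise StructuralError(
                f"molecule {mol} assigned two species ({prev}, {species})"
            )
    return Topology(b2m, m2s, roles, categories)


def write_topology(path: str | os.PathLike, frame: BeadFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# bead molecule species role\n")
        extra = getattr(frame, "species_categories", None) or {}
        for sp, cat in sorted(extra.items()):
            fh.write(f"#category {sp} {cat}\n")
        for i in range(frame.n_beads):
            mol = int(frame.bead_to_molecule[i])
            fh.write(
                f"{i} {mol} {frame.molecule_to_species[mol]} {frame.bead_role[i]}\n"
            )


# ---------------------------------------------------------------------------
# LAMMPS dump


def write_lammps_dump(
    path: str | os.PathLike,
    frames: Sequence[BeadFrame],
    timestep_fs: float = 20.0,
    length_unit: str = "angstrom",
) -> None:
    """Write frames as a text LAMMPS dump (``id mol x y z`` columns)."""
    scale = 1.0 / ANGSTROM_TO_NM if length_unit == "angstrom" else 1.0
    with open(path, "w") as fh:
        for frame in frames:
            step = int(round(frame.time * 1e6 / timestep_fs))  # ns -> fs -> steps
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % frame.n_beads)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for ax in range(3):
                fh.write("0.0 %.10g\n" % (frame.box[ax] * scale))
            fh.write("ITEM: ATOMS id mol x y z\n")
            for i in range(frame.n_beads):
                x, y, z = frame.coords[i] * scale
                fh.write(
                    "%d %d %.8f %.8f %.8f\n"
                    % (i + 1, int(frame.bead_to_molecule[i]), x, y, z)
                )


def read_lammps_dump(
    path: str | os.PathLike,
    topology: Topology,
    timestep_fs: float = 20.0,
    length_unit: str = "angstrom",
) -> Trajectory:
    """Parse a text LAMMPS dump into a Trajectory (nm / ns on return)."""
    scale = ANGSTROM_TO_NM if length_unit == "angstrom" else 1.0
    frames: list[BeadFrame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    frame_index = 0
    expected_n = topology.n_beads
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("ITEM: TIMESTEP"):
            raise ParseError(f"expected 'ITEM: TIMESTEP', got {line!r}", i + 1)
        try:
            step = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ParseError("bad TIMESTEP value", i + 2) from exc
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError("expected 'ITEM: NUMBER OF ATOMS'", i + 3)
        try:
            n_atoms = int(lines[i + 3].strip())
        except ValueError as exc:
            raise ParseError("bad atom count", i + 4) from exc
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise ParseError("expected 'ITEM: BOX BOUNDS'", i + 5)
        box = np.empty(3)
        for ax in range(3):
            parts = lines[i + 5 + ax].split()
            try:
                lo, hi = float(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise ParseError("bad box bounds", i + 6 + ax) from exc
            box[ax] = (hi - lo) * scale
        header = lines[i + 8].strip()
        if not header.startswith("ITEM: ATOMS"):
            raise ParseError("expected 'ITEM: ATOMS'", i + 9)
        cols = header.split()[2:]
        try:
            c_id = cols.index("id")
            c_x, c_y, c_z = cols.index("x"), cols.index("y"), cols.index("z")
        except ValueError as exc:
            raise ParseError(f"ATOMS header must name id/x/y/z, got {cols}", i + 9) from exc
        if n_atoms != expected_n:
            raise StructuralError(
                f"frame {frame_index}: {n_atoms} beads but topology declares {expected_n}"
            )
        coords = np.empty((n_atoms, 3))
        seen = np.zeros(n_atoms, dtype=bool)
        for k in range(n_atoms):
            lineno = i + 9 + k
            if lineno >= n_lines:
                raise StructuralError(
                    f"frame {frame_index}: truncated after {k} of {n_atoms} beads"
                )
            parts = lines[lineno].split()
            try:
                bead = int(parts[c_id]) - 1
                coords[bead] = (
                    float(parts[c_x]),
                    float(parts[c_y]),
                    float(parts[c_z]),
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"bad atom record {lines[lineno]!r}", lineno + 1) from exc
            if bead < 0 or bead >= n_atoms or seen[bead]:
                raise ParseError(f"bad or duplicate bead id {bead + 1}", lineno + 1)
            seen[bead] = True
        frames.append(
            BeadFrame(
                time=step * timestep_fs * 1e-6,  # fs -> ns
                box=box,
                coords=coords * scale,
                bead_to_molecule=topology.bead_to_molecule,
                molecule_to_species=topology.molecule_to_species,
                bead_role=topology.bead_role,
                species_categories=topology.species_categories or None,
            )
        )
        i += 9 + n_atoms
        frame_index += 1
    if not frames:
        raise ParseError("dump file contains no frames")
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# GRO / XTC via MDAnalysis


def read_gro_xtc(
    gro_path: str | os.PathLike,
    xtc_path: str | os.PathLike | None = None,
    topology: Topology | None = None,
) -> Trajectory:
    """Read GRO coordinates (plus optional XTC-class trajectory) via
    MDAnalysis. If no sidecar topology is given, molecules are taken from
    residue ids and species from residue names; roles default to 'other'."""
    import MDAnalysis as mda

    args = (str(gro_path),) if xtc_path is None else (str(gro_path), str(xtc_path))
    u = mda.Universe(*args)
    n = len(u.atoms)
    if topology is not None:
        if topology.n_beads != n:
            raise StructuralError(
                f"topology declares {topology.n_beads} beads, file has {n}"
            )
        b2m = topology.bead_to_molecule
        m2s = topology.molecule_to_species
        roles = topology.bead_role
        cats = topology.species_categories or None
    else:
        b2m = u.atoms.resindices.astype(np.int64)
        m2s = {int(r.resindex): str(r.resname) for r in u.residues}
        roles = None
        cats = None
    frames = []
    for ts in u.trajectory:
        if len(u.atoms) != n:
            raise StructuralError(f"frame {ts.frame}: bead count changed")
        frames.append(
            BeadFrame(
                time=float(ts.time) / 1000.0,  # ps -> ns
                box=np.asarray(ts.dimensions[:3], dtype=float) * ANGSTROM_TO_NM,
                coords=np.asarray(ts.positions, dtype=float) * ANGSTROM_TO_NM,
                bead_to_molecule=b2m,
                molecule_to_species=m2s,
                bead_role=roles,
                species_categories=cats,
            )
        )
    # MDAnalysis may report identical times (e.g. 0.0) for single-frame files
    if len(frames) > 1 and frames[1].time <= frames[0].time:
        for k, f in enumerate(frames):
            f.time = float(k)
    return Trajectory(frames=frames)


def read_trajectory(
    path: str | os.PathLike,
    format: str = "lammps-dump",
    topology: str | os.PathLike | Topology | None = None,
    **kwargs,
) -> Trajectory:
    """Dispatch to the LAMMPS-dump or GRO/XTC reader.

    For ``format='gro-xtc'``, ``path`` is the GRO file and ``kwargs`` may
    carry ``xtc_path``.
    """
    if topology is not None and not isinstance(topology, Topology):
        if not os.path.exists(topology):
            raise ContractError(f"topology file not found: {topology}")
        topology = read_topology(topology)
    if not os.path.exists(path):
        raise ContractError(f"trajectory file not found: {path}")
    if format == "lammps-dump":
        if topology is None:
            raise ContractError("lammps-dump requires a topology sidecar")
        return read_lammps_dump(path, topology, **kwargs)
    if format == "gro-xtc":
        return read_gro_xtc(path, topology=topology, **kwargs)
    raise ContractError(f"unknown trajectory format {format!r}")
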