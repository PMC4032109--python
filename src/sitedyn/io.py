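"""Structures, trajectories and grid/table I/O.

Coordinates are in Å throughout; trajectory frame spacing is in ps and
trajectory length is reported in ns. The trajectory dialect of record is
multi-model PDB (``MODEL``/``ENDMDL``); DCD is supported behind the same
interface when MDAnalysis is installed.

The PDB reader is deliberately strict about the fixed-column coordinate
records it consumes (ATOM/HETATM): a malformed record raises
:class:`~sitedyn.exceptions.PDBParseError` carrying the 1-based line number.
Only the first model of a structure file is read, and only altloc ``''``/``'A'``
atoms are kept, so a topology read from disk is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    CongruenceError,
    EmptyInputError,
    ParameterError,
    PDBParseError,
    SelectionError,
)

# Two-letter elements whose PDB atom names start in column 13 (0-based 12)
_TWO_LETTER_ELEMENTS = {
    "MG", "MN", "ZN", "FE", "NA", "CL", "BR", "CA", "CU", "NI", "CO", "CD", "SE",
}

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def residue_label(residue_name: str, residue_number: int) -> str:
    """One-letter label like ``R138``; falls back to the full residue name."""
    code = _ONE_LETTER.get(residue_name.upper(), residue_name)
    return f"{code}{residue_number}"


@dataclass
class Structure:
    """A set of atoms with identity and one coordinate set.

    Parallel arrays/lists, one entry per atom, in record order. The triple
    ``(chain_id, residue_number, atom_name)`` is unique and serials are
    strictly increasing (both enforced by :meth:`validate`).
    """

    serials: np.ndarray
    atom_names: list[str]
    residue_names: list[str]
    chain_ids: list[str]
    residue_numbers: np.ndarray
    coords: np.ndarray
    b_factors: np.ndarray
    elements: list[str]
    het_flags: np.ndarray | None = None

    def __post_init__(self):
        self.serials = np.asarray(self.serials, dtype=int)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        if self.het_flags is None:
            self.het_flags = np.zeros(self.n_atoms, dtype=bool)
        else:
            self.het_flags = np.asarray(self.het_flags, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def validate(self) -> "Structure":
        if self.n_atoms == 0:
            raise EmptyInputError("structure contains no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError("structure coordinates must be finite")
        if np.any(np.diff(self.serials) <= 0):
            raise ParameterError("atom serials must be strictly increasing")
        keys = self.identity_keys()
        if len(set(keys)) != len(keys):
            raise ParameterError(
                "(chain_id, residue_number, atom_name) must be unique per atom"
            )
        return self

    def identity_keys(self) -> list[tuple[str, int, str]]:
        return list(
            zip(self.chain_ids, map(int, self.residue_numbers), self.atom_names)
        )

    def select(self, selection: str) -> np.ndarray:
        """Indices of atoms matched by a ``chain:resnum:atomname`` selection.

        Each field is ``*`` (any) or a comma-separated list of alternatives;
        a bare token without ``:`` matches on atom name alone
        (``"MG"`` == ``"*:*:MG"``).
        """
        if ":" not in selection:
            selection = f"*:*:{selection}"
        parts = selection.split(":")
        if len(parts) != 3:
            raise SelectionError(
                f"selection {selection!r} must have 3 ':'-separated fields"
            )
        chain_f, resnum_f, name_f = (p.strip() for p in parts)

        def _match_str(values, pattern, upper=False):
            if pattern == "*":
                return np.ones(self.n_atoms, dtype=bool)
            alts = {a.strip() for a in pattern.split(",")}
            if upper:
                alts = {a.upper() for a in alts}
                values = [v.upper() for v in values]
            return np.array([v in alts for v in values])

        mask = _match_str(self.chain_ids, chain_f)
        if resnum_f != "*":
            try:
                nums = {int(a) for a in resnum_f.split(",")}
            except ValueError as exc:
                raise SelectionError(f"bad residue number field {resnum_f!r}") from exc
            mask &= np.isin(self.residue_numbers, list(nums))
        mask &= _match_str(self.atom_names, name_f, upper=True)
        return np.flatnonzero(mask)

    def select_one(self, selection: str) -> int:
        idx = self.select(selection)
        if len(idx) != 1:
            raise SelectionError(
                f"selection {selection!r} resolved to {len(idx)} atoms, expected 1"
            )
        return int(idx[0])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if coords.shape[0] != self.n_atoms:
            raise CongruenceError(
                f"coordinate set has {coords.shape[0]} atoms, topology has {self.n_atoms}"
            )
        return replace(self, coords=coords)

    def residues(self):
        """Iterate residues as ``((chain, resnum, resname), atom indices)`` in order."""
        seen: dict[tuple, list[int]] = {}
        for i in range(self.n_atoms):
            key = (self.chain_ids[i], int(self.residue_numbers[i]), self.residue_names[i])
            seen.setdefault(key, []).append(i)
        for key, idx in seen.items():
            yield key, np.asarray(idx, dtype=int)


@dataclass
class Trajectory:
    """Ordered frames of coordinates sharing one topology.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Å; ``frame_spacing``
    is in ps. ``length_ns`` is ``n_frames * frame_spacing / 1000``.
    """

    topology: Structure
    coords: np.ndarray
    frame_spacing: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise CongruenceError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise CongruenceError(
                f"frames have {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if not self.frame_spacing > 0:
            raise ParameterError("frame_spacing must be > 0 ps")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def length_ns(self) -> float:
        return self.n_frames * self.frame_spacing / 1000.0

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


@dataclass
class ResultTable:
    """Labelled rows of named reals plus free-form provenance metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}={self.metadata[key]}\n")
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ResultTable":
        path = Path(path)
        metadata = {}
        skip = 0
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
        data = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(data=data, metadata=metadata)


# ---------------------------------------------------------------------------
# PDB fixed-column records
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError("coordinate record shorter than 54 columns", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"malformed fixed-column record ({exc})", lineno) from exc
    if not element:
        element = _guess_element(name)
    return serial, name, altloc, resname, chain, resnum, (x, y, z), bfac, element.upper()


def _guess_element(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if stripped in _TWO_LETTER_ELEMENTS:
        return stripped
    return stripped[:1]


def read_pdb_structure(path) -> Structure:
    """Read all ATOM/HETATM atoms of the first model of a PDB file.

    Alternate locations other than ``''``/``'A'`` are dropped. The B-factor
    column is preserved.
    """
    path = Path(path)
    rows = []
    in_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model:
                    break  # first model only
                in_model = True
            elif rec == "ENDMDL":
                if in_model:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                if parsed[2] in ("", "A"):
                    rows.append((parsed, rec == "HETATM"))
    if not rows:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    parsed_rows = [r for r, _ in rows]
    return Structure(
        serials=np.array([r[0] for r in parsed_rows]),
        atom_names=[r[1] for r in parsed_rows],
        residue_names=[r[3] for r in parsed_rows],
        chain_ids=[r[4] for r in parsed_rows],
        residue_numbers=np.array([r[5] for r in parsed_rows]),
        coords=np.array([r[6] for r in parsed_rows], dtype=float),
        b_factors=np.array([r[7] for r in parsed_rows]),
        elements=[r[8] for r in parsed_rows],
        het_flags=np.array([h for _, h in rows], dtype=bool),
    )


def _format_atom_name(name: str, element: str) -> str:
    # names start in column 14 unless the element symbol is two letters
    # (or the name already fills four columns)
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def _atom_line(rec, serial, name, resname, chain, resnum, xyz, occ, bfac, element):
    return (
        f"{rec:<6}{serial:>5} {_format_atom_name(name, element)} "
        f"{resname:<3} {chain:1}{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{bfac:6.2f}"
        f"          {element:>2}\n"
    )


def _write_atoms(fh, structure: Structure, coords: np.ndarray) -> None:
    for i in range(structure.n_atoms):
        rec = "HETATM" if structure.het_flags[i] else "ATOM  "
        fh.write(
            _atom_line(
                rec,
                int(structure.serials[i]) % 100000,
                structure.atom_names[i],
                structure.residue_names[i],
                structure.chain_ids[i],
                int(structure.residue_numbers[i]),
                coords[i],
                1.00,
                float(structure.b_factors[i]),
                structure.elements[i],
            )
        )


def write_pdb_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file (ATOM/HETATM records, 0.001 Å precision)."""
    with Path(path).open("w") as fh:
        _write_atoms(fh, structure, structure.coords)
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (or DCD for a ``.dcd`` path)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        _write_dcd(traj, path)
        return
    with path.open("w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:>4}\n")
            _write_atoms(fh, traj.topology, traj.coords[i])
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(path, topology: Structure, frame_spacing: float) -> Trajectory:
    """Read a multi-model PDB (or DCD) trajectory congruent with ``topology``.

    Atom correspondence is by position in record order; a frame whose atom
    count differs from the topology raises
    :class:`~sitedyn.exceptions.CongruenceError` naming the frame index.
    """
    path = Path(path)
    if not frame_spacing > 0:
        raise ParameterError("frame_spacing must be > 0 ps")
    if path.suffix.lower() == ".dcd":
        return _read_dcd(path, topology, frame_spacing)

    frames: list[np.ndarray] = []
    current: list[tuple] | None = None
    saw_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    _append_frame(frames, current, topology)
                    current = None
            elif rec in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                if parsed[2] not in ("", "A"):
                    continue
                if current is None:
                    if saw_model:
                        continue  # stray atoms outside MODEL blocks
                    current = []
                    saw_model = False
                current.append(parsed[6])
    if current:  # single-model file without MODEL/ENDMDL, or missing ENDMDL
        _append_frame(frames, current, topology)
    if not frames:
        raise EmptyInputError(f"{path}: no coordinate frames found")
    return Trajectory(topology=topology, coords=np.array(frames), frame_spacing=frame_spacing)


def _append_frame(frames, current, topology):
    if len(current) != topology.n_atoms:
        raise CongruenceError(
            f"frame {len(frames)} has {len(current)} atoms, topology has "
            f"{topology.n_atoms}"
        )
    frames.append(np.array(current, dtype=float))


def _read_dcd(path, topology, frame_spacing):
    from MDAnalysis.coordinates.DCD import DCDReader

    frames = []
    with DCDReader(str(path)) as reader:
        for i, ts in enumerate(reader):
            if ts.positions.shape[0] != topology.n_atoms:
                raise CongruenceError(
                    f"frame {i} has {ts.positions.shape[0]} atoms, topology has "
                    f"{topology.n_atoms}"
                )
            frames.append(np.array(ts.positions, dtype=float))
    if not frames:
        raise EmptyInputError(f"{path}: no coordinate frames found")
    return Trajectory(topology=topology, coords=np.array(frames), frame_spacing=frame_spacing)


def _write_dcd(traj, path):
    from MDAnalysis.coordinates.DCD import DCDWriter

    with DCDWriter(str(path), n_atoms=traj.topology.n_atoms) as writer:
        for i in range(traj.n_frames):
            writer.write(_FramePositions(traj.coords[i]))


class _FramePositions:
    """Minimal adapter so MDAnalysis' DCDWriter accepts a bare coordinate array."""

    def __init__(self, coords):
        import MDAnalysis

        self.ts = MDAnalysis.coordinates.timestep.Timestep(coords.shape[0])
        self.ts.positions = coords.astype(np.float32)

    @property
    def universe(self):  # pragma: no cover - attribute probe only
        raise AttributeError


# ---------------------------------------------------------------------------
# OpenDX scalar fields
# ---------------------------------------------------------------------------

def write_density_dx(grid, path) -> None:
    """Write a density grid as an OpenDX scalar field.

    Voxel values are written in the grid's C order (z fastest), three per
    line, with fixed ``%.10g`` formatting so identical grids produce
    byte-identical files.
    """
    nx, ny, nz = (int(c) for c in grid.counts)
    values = np.asarray(grid.values, dtype=float).reshape(nx, ny, nz)
    s = float(grid.spacing)
    ox, oy, oz = (float(v) for v in grid.origin)
    with Path(path).open("w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.10g} {oy:.10g} {oz:.10g}\n")
        fh.write(f"delta {s:.10g} 0 0\n")
        fh.write(f"delta 0 {s:.10g} 0\n")
        fh.write(f"delta 0 0 {s:.10g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} "
            "data follows\n"
        )
        flat = values.ravel(order="C")
        for start in range(0, flat.size, 3):
            chunk = flat[start:start + 3]
            fh.write(" ".join(f"{v:.10g}" for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_density_dx(path):
    """Read an OpenDX scalar field written by :func:`write_density_dx`."""
    from .density import DensityGrid  # local import to avoid a cycle

    counts = origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with Path(path).open() as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "object" and "gridpositions" in tok:
                counts = [int(v) for v in tok[-3:]]
            elif tok[0] == "origin":
                origin = [float(v) for v in tok[1:4]]
            elif tok[0] == "delta":
                deltas.append([float(v) for v in tok[1:4]])
            elif tok[0] == "object" and "array" in tok:
                n_items = int(tok[tok.index("items") + 1])
            elif n_items is not None and len(values) < n_items:
                try:
                    values.extend(float(v) for v in tok)
                except ValueError:
                    continue
    if counts is None or origin is None or len(deltas) != 3 or n_items is None:
        raise PDBParseError(f"{path}: not a recognisable OpenDX scalar field")
    deltas = np.asarray(deltas)
    diag = np.diag(deltas)
    if not np.allclose(deltas, np.diag(diag)) or not np.allclose(diag, diag[0]):
        raise ParameterError("only isotropic axis-aligned DX grids are supported")
    arr = np.asarray(values[:n_items], dtype=float).reshape(counts)
    return DensityGrid(
        origin=np.asarray(origin, dtype=float),
        spacing=float(diag[0]),
        counts=np.asarray(counts, dtype=int),
        values=arr,
        n_frames=0,
    )
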