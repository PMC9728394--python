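"""Readers and writers for the molecular file formats the pipeline touches.

Three dialects are supported:

* **PDB** (v3.3 fixed columns) for receptor structures,
* **PDBQT** (the AutoDock dialect: PDB columns plus a trailing partial
  charge and AutoDock atom type, with multi-``MODEL`` docking output and
  ``REMARK VINA RESULT`` score lines),
* multi-frame **XYZ** for trajectory coordinates.

All coordinates are in Angstrom throughout the package; no unit conversion
happens anywhere downstream.  Parsers never silently drop ``ATOM``/``HETATM``
records: every skipped record (e.g. a discarded alternate location) is
counted and logged as a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Pose",
    "Trajectory",
    "ParseError",
    "FormatError",
    "read_pdb",
    "write_pdb",
    "read_pdbqt_poses",
    "write_pdbqt_poses",
    "read_trajectory",
    "write_xyz_trajectory",
    "STANDARD_AMINO_ACIDS",
]


class ParseError(ValueError):
    """A structure file violates its fixed-column format."""


class FormatError(ValueError):
    """A trajectory file is internally inconsistent (e.g. atom-count drift)."""


#: Three-letter codes treated as protein residues.  Used to separate ligand
#: atoms from (flexible) receptor side-chain atoms inside a docking MODEL.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split()
)

# AutoDock atom type -> element
_ADTYPE_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "O": "O", "OA": "O",
    "OS": "O", "S": "S", "SA": "S", "H": "H", "HD": "H", "HS": "H", "P": "P",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "MG": "Mg", "ZN": "Zn",
    "MN": "Mn", "CA": "Ca", "FE": "Fe",
}


@dataclass
class AtomRecord:
    """One ATOM/HETATM record.

    ``residue_number`` together with ``icode`` (PDB insertion code)
    disambiguates residues; ``charge`` and ``pdbqt_type`` carry the two
    trailing PDBQT columns and are retained but unused by any geometry.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str = "A"
    xyz: np.ndarray = field(default_factory=lambda: np.zeros(3))
    icode: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    charge: float | None = None
    pdbqt_type: str | None = None
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"xyz must be a 3-vector, got shape {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("xyz must be finite")
        if not self.element:
            raise ValueError("element must be non-empty")

    @property
    def residue_key(self) -> tuple[int, str]:
        return (self.residue_number, self.icode)


@dataclass
class Pose:
    """One docked ligand conformation (one MODEL of a docking output)."""

    model_index: int
    atoms: list[AtomRecord]
    score: float | None = None

    def __post_init__(self) -> None:
        if self.model_index < 1:
            raise ValueError(f"model_index must be >= 1, got {self.model_index}")
        if not self.atoms:
            raise ValueError("a pose needs at least one atom")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])


@dataclass
class Trajectory:
    """Ordered frames of labelled coordinates for one simulation replica.

    The atom roster (names / residue numbers / residue names) is fixed across
    frames; ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom and
    ``frame_times`` is in picoseconds, strictly increasing.
    """

    replica_id: str
    atom_names: list[str]
    residue_numbers: np.ndarray
    residue_names: list[str]
    frame_times: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_frames, n_atoms, _ = self.coords.shape
        if len(self.atom_names) != n_atoms or len(self.residue_names) != n_atoms:
            raise ValueError("atom roster length does not match coords")
        if self.residue_numbers.shape != (n_atoms,):
            raise ValueError("residue_numbers length does not match coords")
        if self.frame_times.shape != (n_frames,):
            raise ValueError("frame_times length does not match number of frames")
        if n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB / PDBQT parsing
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    letters = [c for c in name if c.isalpha()]
    if not letters:
        return "X"
    # two-letter metals etc. are rare in this pipeline; atom names like CA/CB
    # are carbons, so the first letter wins.
    return letters[0].upper()


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise ParseError(f"line {lineno}: ATOM/HETATM record too short")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno  # some tools write '*****' for >99999; fall back
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or " "
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad residue number field: {line[22:26]!r}") from exc
    icode = line[26].strip()
    try:
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed coordinate field") from exc
    occupancy, bfactor = 1.0, 0.0
    try:
        if line[54:60].strip():
            occupancy = float(line[54:60])
        if line[60:66].strip():
            bfactor = float(line[60:66])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad occupancy/B-factor field") from exc

    charge: float | None = None
    pdbqt_type: str | None = None
    element = ""
    tail = line[66:].split()
    # PDBQT: "... occ bfac  charge  adtype"; PDB: element in cols 77-78.
    if len(tail) >= 2 and "." in tail[-2]:
        try:
            charge = float(tail[-2])
            pdbqt_type = tail[-1]
            element = _ADTYPE_ELEMENT.get(pdbqt_type.upper(), "")
        except ValueError:
            charge, pdbqt_type = None, None
    if not element:
        element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    if not element or any(c.isdigit() for c in element):
        element = _element_from_name(name)

    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=resnum, chain=chain, xyz=xyz, icode=icode,
        altloc=altloc, occupancy=occupancy, bfactor=bfactor,
        charge=charge, pdbqt_type=pdbqt_type,
        is_hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> tuple[list[AtomRecord], int]:
    """Keep one alternate location per atom: highest occupancy, tie -> first."""
    kept: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    n_skipped = 0
    for atom in atoms:
        key = (atom.chain, atom.residue_number, atom.icode, atom.residue_name, atom.name)
        if not atom.altloc:
            if key in kept:
                # duplicate atom without altloc: keep both under distinct keys
                key = key + (atom.serial,)
            kept[key] = atom
            order.append(key)
            continue
        if key not in kept:
            kept[key] = atom
            order.append(key)
        elif atom.occupancy > kept[key].occupancy:
            kept[key] = atom
            n_skipped += 1
        else:
            n_skipped += 1
    return [kept[k] for k in order], n_skipped


def read_pdb(path: str | Path) -> list[AtomRecord]:
    """Parse ATOM/HETATM records from a PDB (or PDBQT) file.

    Alternate locations are reduced to the highest-occupancy conformer
    (ties keep the first encountered); the number of records discarded this
    way is logged as a warning so that records in == records out + skips.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    n_in = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_in += 1
                atoms.append(_parse_atom_line(line, lineno))
    atoms, n_skipped = _resolve_altlocs(atoms)
    if n_skipped:
        logger.warning("%s: discarded %d alternate-location records", path.name, n_skipped)
    if n_in == 0:
        logger.warning("%s: no ATOM/HETATM records found", path.name)
    assert n_in == len(atoms) + n_skipped
    return atoms


def _format_atom_line(atom: AtomRecord, pdbqt: bool = False) -> str:
    record = "HETATM" if atom.is_hetatm else "ATOM  "
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    line = (
        f"{record}{atom.serial:>5d} {name:<4.4s}{atom.altloc or ' ':1.1s}"
        f"{atom.residue_name:>3.3s} {atom.chain:1.1s}{atom.residue_number:>4d}"
        f"{atom.icode or ' ':1.1s}   "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
    )
    if pdbqt:
        charge = atom.charge if atom.charge is not None else 0.0
        adtype = atom.pdbqt_type or atom.element
        line += f"    {charge:6.3f} {adtype:<2s}"
    else:
        line += f"          {atom.element:>2.2s}"
    return line


def write_pdb(atoms: Iterable[AtomRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for atom in atoms:
            fh.write(_format_atom_line(atom) + "\n")
        fh.write("END\n")


def read_pdbqt_poses(path: str | Path) -> list[Pose]:
    """Parse a multi-MODEL PDBQT docking output into poses.

    The docking score is taken from a ``REMARK VINA RESULT`` line when
    present.  A file without MODEL records but with atoms yields a single
    pose; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    poses: list[Pose] = []
    atoms: list[AtomRecord] = []
    score: float | None = None
    in_model = False
    model_index = 0
    seen_indices: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                if in_model:
                    raise ParseError(f"line {lineno}: nested MODEL record")
                in_model = True
                atoms, score = [], None
                try:
                    model_index = int(line.split()[1])
                except (IndexError, ValueError):
                    model_index = len(poses) + 1
                continue
            if line.startswith("ENDMDL"):
                if not in_model:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                if model_index in seen_indices:
                    raise ParseError(f"line {lineno}: duplicate MODEL index {model_index}")
                seen_indices.add(model_index)
                poses.append(Pose(model_index=model_index, atoms=atoms, score=score))
                in_model = False
                continue
            if line.startswith("REMARK VINA RESULT"):
                parts = line.split(":", 1)[-1].split()
                if parts:
                    score = float(parts[0])
                continue
            if line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_atom_line(line, lineno))
    if in_model:
        raise ParseError(f"{path.name}: unterminated MODEL block (model {model_index})")
    if not poses:
        if atoms:  # model-less single-pose file
            poses.append(Pose(model_index=1, atoms=atoms, score=score))
        else:
            logger.warning("%s: no poses found", path.name)
    return poses


def write_pdbqt_poses(poses: Sequence[Pose], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pose in poses:
            fh.write(f"MODEL {pose.model_index}\n")
            if pose.score is not None:
                fh.write(f"REMARK VINA RESULT:{pose.score:9.3f}      0.000      0.000\n")
            for atom in pose.atoms:
                fh.write(_format_atom_line(atom, pdbqt=True) + "\n")
            fh.write("ENDMDL\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame XYZ file; frame times go in the comment line."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"replica={traj.replica_id} time_ps={traj.frame_times[f]:.6g}\n")
            for name, xyz in zip(traj.atom_names, traj.coords[f]):
                fh.write(f"{name:<6s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")


def _read_xyz_frames(path: Path) -> tuple[list[str], list[np.ndarray], list[float | None]]:
    names: list[str] = []
    frames: list[np.ndarray] = []
    times: list[float | None] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"frame {frame_index}: bad atom-count line {lines[i]!r}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t: float | None = None
        for token in comment.split():
            if token.startswith("time_ps="):
                t = float(token.split("=", 1)[1])
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise FormatError(f"frame {frame_index}: truncated (expected {n_atoms} atoms)")
        coords = np.empty((n_atoms, 3))
        frame_names = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"frame {frame_index}: bad atom line {row!r}")
            frame_names.append(parts[0])
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if not names:
            names = frame_names
        elif frame_names != names or n_atoms != len(names):
            raise FormatError(f"frame {frame_index}: atom roster mismatch")
        frames.append(coords)
        times.append(t)
        i += 2 + n_atoms
        frame_index += 1
    return names, frames, times


def read_trajectory(
    path: str | Path,
    fmt: str = "xyz",
    stride_ps: float = 1.0,
    replica_id: str | None = None,
) -> Trajectory:
    """Read a multi-frame XYZ or multi-MODEL PDB file as a Trajectory.

    Frame times come from ``time_ps=`` metadata when every frame carries it,
    otherwise from ``stride_ps``.  For XYZ input (which has no residue
    information) the roster assigns one residue per atom, matching the
    one-designated-atom-per-residue convention used for RMSF.
    """
    path = Path(path)
    rid = replica_id or path.stem
    if fmt == "xyz":
        names, frames, times = _read_xyz_frames(path)
        if not frames:
            raise FormatError(f"{path.name}: no frames found")
        coords = np.stack(frames)
        if all(t is not None for t in times):
            frame_times = np.array(times, dtype=float)
        else:
            frame_times = np.arange(len(frames)) * stride_ps
        n_atoms = len(names)
        return Trajectory(
            replica_id=rid,
            atom_names=names,
            residue_numbers=np.arange(1, n_atoms + 1),
            residue_names=["UNK"] * n_atoms,
            frame_times=frame_times,
            coords=coords,
        )
    if fmt == "pdb":
        models: list[list[AtomRecord]] = []
        current: list[AtomRecord] | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("MODEL"):
                    current = []
                elif line.startswith("ENDMDL"):
                    if current is None:
                        raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                    models.append(current)
                    current = None
                elif line.startswith(("ATOM", "HETATM")):
                    if current is None:
                        current = []
                    atom = _parse_atom_line(line, lineno)
                    current.append(atom)
        if current:
            models.append(current)
        if not models:
            raise FormatError(f"{path.name}: no frames found")
        roster = models[0]
        coords = np.empty((len(models), len(roster), 3))
        for f, model in enumerate(models):
            if len(model) != len(roster):
                raise FormatError(f"frame {f}: atom count {len(model)} != {len(roster)}")
            coords[f] = [a.xyz for a in model]
        return Trajectory(
            replica_id=rid,
            atom_names=[a.name for a in roster],
            residue_numbers=np.array([a.residue_number for a in roster]),
            residue_names=[a.residue_name for a in roster],
            frame_times=np.arange(len(models)) * stride_ps,
            coords=coords,
        )
    raise ValueError(f"unknown trajectory format: {fmt!r}")
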