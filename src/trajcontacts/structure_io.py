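"""Multi-model PDB trajectory I/O, timestamping and atom role assignment.

The native trajectory format is the multi-model PDB dialect: successive
MODEL/ENDMDL blocks hold successive frames.  Atom identity is the 1-based PDB
serial as read from the file; serials are never renumbered, because every
interaction key downstream is a tuple of atom serials and must be stable
across frames.  Binary formats (XTC, DCD) are out of scope here; convert them
to multi-model PDB upstream (e.g. with ``gmx trjconv`` or MDAnalysis) before
running the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Role", "Atom", "Frame", "LigandSelection",
    "PDBParseError", "TopologyMismatchError",
    "EmptyLigandError", "AmbiguousSelectionError",
    "read_multimodel_pdb", "assign_roles",
    "write_frame_pdb", "write_multimodel_pdb",
    "PdbTrajectory",
    "WATER_RESNAMES", "AMINO_ACIDS", "NUCLEOTIDES", "ION_RESNAMES",
]


class PDBParseError(ValueError):
    """Malformed PDB record; message names the offending line number."""


class TopologyMismatchError(ValueError):
    """Atom serial sets differ between models of one trajectory."""


class EmptyLigandError(ValueError):
    """Ligand selection matched no atoms."""


class AmbiguousSelectionError(ValueError):
    """Ligand selection with residue_number resolved to >1 distinct residue."""


class Role(str, Enum):
    LIGAND = "ligand"
    RECEPTOR_PROTEIN = "receptor_protein"
    RECEPTOR_NUCLEIC = "receptor_nucleic"
    WATER = "water"
    ION = "ion"
    OTHER = "other"


WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3"})

AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
})

_NUC_BASES = ("DA", "DT", "DG", "DC", "DU", "A", "U", "G", "C", "T")
NUCLEOTIDES = frozenset(
    {b for b in _NUC_BASES}
    | {b + "5" for b in _NUC_BASES}
    | {b + "3" for b in _NUC_BASES}
)

ION_RESNAMES = frozenset({"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "BR", "IOD"})


@dataclass(frozen=True)
class Atom:
    """One atom of one frame.

    ``serial`` is the PDB atom serial and serves as the atom ID in every
    interaction key.  ``coords`` are Cartesian, in Angstrom.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    insertion_code: str = ""
    role: Role = Role.OTHER
    is_hetatm: bool = False

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.residue_name, self.residue_number, self.chain_id)


@dataclass
class Frame:
    """A time-stamped snapshot: all atoms of the system at one timestamp."""

    index: int
    time_ps: float
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)  # from CONECT

    def __post_init__(self) -> None:
        self._by_serial: dict[int, Atom] | None = None

    @property
    def by_serial(self) -> dict[int, Atom]:
        if self._by_serial is None or len(self._by_serial) != len(self.atoms):
            self._by_serial = {a.serial: a for a in self.atoms}
        return self._by_serial

    @property
    def serials(self) -> frozenset[int]:
        return frozenset(a.serial for a in self.atoms)

    @property
    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)

    def coords_of(self, serial: int) -> np.ndarray:
        return self.by_serial[serial].coords

    def atoms_with_role(self, *roles: Role) -> list[Atom]:
        want = set(roles)
        return [a for a in self.atoms if a.role in want]


@dataclass(frozen=True)
class LigandSelection:
    """Which residues constitute the ligand.

    All selected atoms are treated as one group; a ``residue_number`` (with
    optional ``chain_id``) pins the selection to a single residue.
    """

    residue_names: frozenset[str]
    chain_id: str | None = None
    residue_number: int | None = None

    def __post_init__(self) -> None:
        if not self.residue_names:
            raise ValueError("ligand selection needs at least one residue name")

    @classmethod
    def parse(cls, text: str) -> "LigandSelection":
        """Parse ``resname[:chain[:resnum]]``, e.g. ``CPT`` or ``LIG:L:1``."""
        parts = text.split(":")
        names = frozenset(p.strip().upper() for p in parts[0].split(",") if p.strip())
        chain = parts[1] if len(parts) > 1 and parts[1] else None
        resnum = int(parts[2]) if len(parts) > 2 and parts[2] else None
        return cls(residue_names=names, chain_id=chain, residue_number=resnum)

    def matches(self, atom: Atom) -> bool:
        if atom.residue_name not in self.residue_names:
            return False
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_number is not None and atom.residue_number != self.residue_number:
            return False
        return True


_ELEMENT_RE = re.compile(r"[A-Za-z]")


def _infer_element(name: str) -> str:
    """Element from an atom name when columns 77-78 are blank.

    Handles leading digits ('1HB2' -> H) and two-letter elements embedded in
    common MD names (CL, NA as full names).
    """
    stripped = name.strip()
    if stripped.upper() in {"CL", "NA", "MG", "ZN", "BR", "FE", "MN", "K"} and len(stripped) <= 2:
        return stripped.capitalize() if len(stripped) == 2 else stripped.upper()
    m = _ELEMENT_RE.search(stripped)
    return m.group(0).upper() if m else "X"


def _parse_atom_line(line: str, lineno: int) -> Atom:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: truncated coordinate record: {line!r}")
    try:
        serial = int(line[6:11])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad atom serial {line[6:11]!r}") from exc
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:21].strip().upper()
    chain = line[21].strip()
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from exc
    icode = line[26].strip()
    try:
        coords = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])],
            dtype=float,
        )
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinates") from exc
    if not np.all(np.isfinite(coords)):
        raise PDBParseError(f"line {lineno}: non-finite coordinates")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name)
    element = element.capitalize() if len(element) == 2 else element.upper()
    if altloc not in ("", "A"):
        raise _AltLocSkip()
    return Atom(
        serial=serial, name=name, element=element,
        residue_name=resname, residue_number=resnum,
        chain_id=chain, insertion_code=icode,
        coords=coords, is_hetatm=line.startswith("HETATM"),
    )


class _AltLocSkip(Exception):
    """Internal: alternate location other than blank/'A' -> drop the record."""


_TITLE_T_RE = re.compile(r"\bt=\s*([-+0-9.eE]+)")


def _scan_models(lines: Iterable[str]) -> Iterator[tuple[float | None, list[tuple[int, str]], list[str]]]:
    """Yield (title_time, [(lineno, atom_line)], conect_lines) per model.

    A file with no MODEL records yields a single pseudo-model.  A ``TITLE``
    line carrying ``t=`` (as written by trjconv) is associated with the model
    that follows it.
    """
    pending_time: float | None = None
    in_model = False
    saw_model = False
    current: list[tuple[int, str]] = []
    conect: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        rec = raw[:6]
        if rec.startswith("TITLE") or rec.startswith("REMARK"):
            m = _TITLE_T_RE.search(raw)
            if m:
                pending_time = float(m.group(1))
        elif rec.startswith("MODEL"):
            saw_model = True
            in_model = True
            current = []
        elif rec.startswith("ENDMDL"):
            in_model = False
            yield pending_time, current, conect
            pending_time = None
            current = []
        elif rec.startswith(("ATOM  ", "HETATM")):
            if saw_model and not in_model:
                continue  # stray record between models
            current.append((lineno, raw.rstrip("\n")))
        elif rec.startswith("CONECT"):
            conect.append(raw.rstrip("\n"))
    if not saw_model and current:
        yield pending_time, current, conect


def _parse_conect(lines: Sequence[str]) -> list[tuple[int, int]]:
    bonds: set[tuple[int, int]] = set()
    for line in lines:
        fields = [line[i:i + 5] for i in range(6, min(len(line), 31), 5)]
        serials = [int(f) for f in fields if f.strip()]
        if not serials:
            continue
        a = serials[0]
        for b in serials[1:]:
            bonds.add((min(a, b), max(a, b)))
    return sorted(bonds)


def read_multimodel_pdb(
    path: str | Path, t_start: float = 0.0, dt: float = 10.0
) -> list[Frame]:
    """Read a multi-model PDB file into a list of time-stamped frames.

    ATOM and HETATM records are both ingested; alternate-location indicators
    other than blank/'A' are dropped.  A frame's time is taken from a
    ``TITLE ... t=<ps>`` record when present, else ``t_start + index*dt``.

    Raises :class:`PDBParseError` on malformed records (naming the line) and
    :class:`TopologyMismatchError` when models disagree on the atom serial set.
    """
    path = Path(path)
    frames: list[Frame] = []
    conect_lines: list[str] = []
    with path.open() as fh:
        for model_idx, (title_time, atom_lines, conect) in enumerate(_scan_models(fh)):
            conect_lines = conect
            atoms: list[Atom] = []
            for lineno, line in atom_lines:
                try:
                    atoms.append(_parse_atom_line(line, lineno))
                except _AltLocSkip:
                    continue
            time_ps = title_time if title_time is not None else t_start + model_idx * dt
            frames.append(Frame(index=model_idx, time_ps=time_ps, atoms=atoms))
    if not frames:
        raise PDBParseError(f"{path}: no coordinate records found")
    ref = frames[0].serials
    if len(ref) != len(frames[0].atoms):
        dupes = len(frames[0].atoms) - len(ref)
        raise PDBParseError(f"{path}: {dupes} duplicate atom serial(s) in model 1")
    for fr in frames[1:]:
        if fr.serials != ref:
            missing = sorted(ref - fr.serials)[:5]
            extra = sorted(fr.serials - ref)[:5]
            raise TopologyMismatchError(
                f"model {fr.index + 1} atom serials differ from model 1 "
                f"(missing {missing}, unexpected {extra})"
            )
    bonds = _parse_conect(conect_lines)
    for fr in frames:
        fr.bonds = bonds
    return frames


def assign_roles(frame: Frame, selection: LigandSelection) -> Frame:
    """Partition the frame's atoms into ligand / receptor / water / ion / other.

    The partition is exhaustive and exclusive; exactly the atoms matching
    ``selection`` get the ligand role.  Returns a new Frame (atoms are
    immutable records).
    """
    matched = [a for a in frame.atoms if selection.matches(a)]
    if not matched:
        raise EmptyLigandError(
            f"ligand selection {sorted(selection.residue_names)} matched no atoms"
        )
    if selection.residue_number is not None:
        residues = {a.residue_id for a in matched}
        if len(residues) > 1:
            raise AmbiguousSelectionError(
                f"selection resolves to {len(residues)} residues: {sorted(residues)}"
            )
    residue_sizes: dict[tuple[str, int, str], int] = {}
    for a in frame.atoms:
        residue_sizes[a.residue_id] = residue_sizes.get(a.residue_id, 0) + 1

    new_atoms: list[Atom] = []
    for a in frame.atoms:
        if selection.matches(a):
            role = Role.LIGAND
        elif a.residue_name in WATER_RESNAMES:
            role = Role.WATER
        elif a.residue_name in AMINO_ACIDS:
            role = Role.RECEPTOR_PROTEIN
        elif a.residue_name in NUCLEOTIDES:
            role = Role.RECEPTOR_NUCLEIC
        elif a.residue_name in ION_RESNAMES and residue_sizes[a.residue_id] == 1:
            role = Role.ION
        else:
            role = Role.OTHER
        new_atoms.append(replace(a, role=role))
    out = Frame(index=frame.index, time_ps=frame.time_ps, atoms=new_atoms,
                bonds=frame.bonds)
    return out


def _format_atom_line(atom: Atom) -> str:
    record = "HETATM" if atom.is_hetatm else "ATOM  "
    name = atom.name
    # PDB alignment: 1-char elements start in column 14 unless the name is 4 chars
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    name = name.ljust(4)
    elem = atom.element.rjust(2)
    return (
        f"{record}{atom.serial:>5d} {name}{'':1}{atom.residue_name:<4.4s}"
        f"{atom.chain_id or ' ':1}{atom.residue_number:>4d}{atom.insertion_code or ' ':1}"
        f"   {atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {elem}"
    )


def _conect_lines(bonds: Sequence[tuple[int, int]]) -> list[str]:
    neighbors: dict[int, list[int]] = {}
    for a, b in bonds:
        neighbors.setdefault(a, []).append(b)
        neighbors.setdefault(b, []).append(a)
    lines = []
    for serial in sorted(neighbors):
        ns = sorted(neighbors[serial])
        for i in range(0, len(ns), 4):
            chunk = ns[i:i + 4]
            lines.append("CONECT" + f"{serial:>5d}" + "".join(f"{n:>5d}" for n in chunk))
    return lines


def write_frame_pdb(frame: Frame, path: str | Path) -> None:
    """Write one frame as a single-model PDB (3-decimal coordinate precision)."""
    if not frame.atoms:
        raise ValueError("cannot write a frame with no atoms")
    write_multimodel_pdb([frame], path)


def write_multimodel_pdb(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL blocks with ``TITLE t=`` timestamps."""
    if not frames:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    lines: list[str] = []
    for i, fr in enumerate(frames, start=1):
        lines.append(f"TITLE     frame t= {fr.time_ps:.3f}")
        lines.append(f"MODEL     {i:>4d}")
        for atom in fr.atoms:
            lines.append(_format_atom_line(atom))
        lines.append("ENDMDL")
    lines.extend(_conect_lines(frames[0].bonds))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class PdbTrajectory:
    """Random access to the frames of a multi-model PDB without loading it all.

    Scans the file once for model byte offsets so that workers can materialize
    only their own bounded chunk of frames at a time.
    """

    def __init__(self, path: str | Path, t_start: float = 0.0, dt: float = 10.0):
        self.path = Path(path)
        self.t_start = float(t_start)
        self.dt = float(dt)
        self._offsets: list[tuple[int, int]] = []  # (byte_start, byte_end) per model
        self._conect_raw: list[str] = []
        self._scan()
        self._bonds: list[tuple[int, int]] | None = None
        self._ref_serials: frozenset[int] | None = None

    def _scan(self) -> None:
        saw_model = False
        start = None
        with self.path.open("rb") as fh:
            pos = 0
            for raw in fh:
                rec = raw[:6]
                if rec.startswith(b"MODEL"):
                    saw_model = True
                    start = pos
                elif rec.startswith(b"ENDMDL") and start is not None:
                    self._offsets.append((start, pos + len(raw)))
                    start = None
                elif rec.startswith(b"CONECT"):
                    self._conect_raw.append(raw.decode())
                pos += len(raw)
        if not saw_model:
            self._offsets = [(0, self.path.stat().st_size)]

    def __len__(self) -> int:
        return len(self._offsets)

    @property
    def bonds(self) -> list[tuple[int, int]]:
        if self._bonds is None:
            self._bonds = _parse_conect(self._conect_raw)
        return self._bonds

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(len(self))

    def read_frames(self, start: int, stop: int) -> list[Frame]:
        """Materialize frames [start, stop) only."""
        frames: list[Frame] = []
        with self.path.open() as fh:
            for idx in range(start, min(stop, len(self))):
                byte_start, byte_end = self._offsets[idx]
                fh.seek(byte_start)
                block = fh.read(byte_end - byte_start)
                title_time: float | None = None
                atoms: list[Atom] = []
                for lineno, line in enumerate(block.splitlines(), start=1):
                    if line.startswith(("TITLE", "REMARK")):
                        m = _TITLE_T_RE.search(line)
                        if m:
                            title_time = float(m.group(1))
                    elif line.startswith(("ATOM  ", "HETATM")):
                        try:
                            atoms.append(_parse_atom_line(line, lineno))
                        except _AltLocSkip:
                            continue
                time_ps = title_time if title_time is not None else self.t_start + idx * self.dt
                fr = Frame(index=idx, time_ps=time_ps, atoms=atoms, bonds=self.bonds)
                if self._ref_serials is None:
                    self._ref_serials = fr.serials
                elif fr.serials != self._ref_serials:
                    raise TopologyMismatchError(
                        f"model {idx + 1} atom serials differ from the first model read"
                    )
                frames.append(fr)
        return frames
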