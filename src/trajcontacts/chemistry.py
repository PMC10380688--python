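"""Chemical perception: donors, acceptors, hydrophobic atoms, rings, charges.

Standard amino acids and nucleotides are perceived from residue templates
(atom-name lists reflecting their known covalent topology).  The ligand —
whose topology is not known a priori — is perceived from its CONECT bond
graph when present, else from a covalent-radius distance heuristic; aromatic
rings are found by cycle detection plus a planarity test, charged groups by
functional-group patterns (carboxylate, amidinium/guanidinium, quaternary N).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from trajcontacts.structure_io import Atom, Frame, Role, WATER_RESNAMES

logger = logging.getLogger(__name__)

__all__ = ["Ring", "ChargedGroup", "Perception", "perceive_chemistry",
           "RING_PLANARITY_TOL"]

RING_PLANARITY_TOL = 0.3  # Angstrom, max out-of-plane deviation

# covalent-radius sums (Angstrom) + 0.45 slack for distance-based bond inference
_COV_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
              "P": 1.07, "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39}
_BOND_SLACK = 0.45
_H_BOND_MAX = 1.25  # Angstrom, H considered bonded to a heavy atom within this


@dataclass(frozen=True)
class Ring:
    """A 5- or 6-membered planar ring with centroid and unit normal."""

    member_serials: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray
    role: Role


@dataclass(frozen=True)
class ChargedGroup:
    """A formally charged group; center is the mean of member coordinates."""

    charge_sign: int  # +1 or -1
    member_serials: tuple[int, ...]
    center: np.ndarray
    role: Role


@dataclass
class Perception:
    """Per-frame perception tables consumed by the interaction detectors.

    ``donors`` maps a donor heavy-atom serial to the serials of its bonded
    hydrogens (empty list when the frame has no explicit hydrogens).
    """

    donors: dict[int, list[int]] = field(default_factory=dict)
    acceptors: set[int] = field(default_factory=set)
    hydrophobic: set[int] = field(default_factory=set)
    rings: list[Ring] = field(default_factory=list)
    charged_groups: list[ChargedGroup] = field(default_factory=list)
    water_oxygens: list[int] = field(default_factory=list)
    has_hydrogens: bool = False

    def polar(self, frame: Frame, *roles: Role) -> list[int]:
        """Donor-or-acceptor heavy atoms with one of the given roles."""
        want = set(roles)
        out = []
        for s in sorted(set(self.donors) | self.acceptors):
            if frame.by_serial[s].role in want:
                out.append(s)
        return out


# ---------------------------------------------------------------------------
# Residue templates: donor / acceptor / hydrophobic-carbon / ring / charge
# atom-name lists for the standard residues.  Backbone N (donor, except PRO)
# and O/OXT (acceptors) are added to every amino acid automatically.
# ---------------------------------------------------------------------------

_AA_SIDE: dict[str, dict] = {
    "ALA": {"hphob": ["CB"]},
    "GLY": {},
    "VAL": {"hphob": ["CB", "CG1", "CG2"]},
    "LEU": {"hphob": ["CB", "CG", "CD1", "CD2"]},
    "ILE": {"hphob": ["CB", "CG1", "CG2", "CD1"]},
    "PRO": {"hphob": ["CB", "CG"]},
    "MET": {"hphob": ["CB", "CG", "CE"]},
    "CYS": {"hphob": ["CB"]},
    "SER": {"don": ["OG"], "acc": ["OG"]},
    "THR": {"don": ["OG1"], "acc": ["OG1"], "hphob": ["CG2"]},
    "ASN": {"don": ["ND2"], "acc": ["OD1"], "hphob": ["CB"]},
    "GLN": {"don": ["NE2"], "acc": ["OE1"], "hphob": ["CB", "CG"]},
    "ASP": {"acc": ["OD1", "OD2"], "hphob": ["CB"],
            "charged": [(-1, ["CG", "OD1", "OD2"])]},
    "GLU": {"acc": ["OE1", "OE2"], "hphob": ["CB", "CG"],
            "charged": [(-1, ["CD", "OE1", "OE2"])]},
    "LYS": {"don": ["NZ"], "hphob": ["CB", "CG", "CD"],
            "charged": [(+1, ["NZ"])]},
    "ARG": {"don": ["NE", "NH1", "NH2"], "hphob": ["CB", "CG"],
            "charged": [(+1, ["NE", "CZ", "NH1", "NH2"])]},
    "HIS": {"don": ["ND1", "NE2"], "acc": ["ND1", "NE2"],
            "rings": [["CG", "ND1", "CE1", "NE2", "CD2"]], "hphob": ["CB"]},
    "PHE": {"hphob": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
            "rings": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]]},
    "TYR": {"don": ["OH"], "acc": ["OH"],
            "hphob": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
            "rings": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]]},
    "TRP": {"don": ["NE1"],
            "hphob": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
            "rings": [["CG", "CD1", "NE1", "CE2", "CD2"],
                      ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]]},
}
# protonation variants share the parent template
for _src, _dst in (("HIS", "HID"), ("HIS", "HIE"), ("HIS", "HIP"),
                   ("CYS", "CYX"), ("ASP", "ASH"), ("GLU", "GLH"),
                   ("LYS", "LYN")):
    _AA_SIDE[_dst] = _AA_SIDE[_src]

_PURINE_RINGS = [["N1", "C2", "N3", "C4", "C5", "C6"],
                 ["C4", "C5", "N7", "C8", "N9"]]
_PYRIMIDINE_RING = [["N1", "C2", "N3", "C4", "C5", "C6"]]

_NUC_BASE: dict[str, dict] = {
    "DA": {"don": ["N6"], "acc": ["N1", "N3", "N7"], "rings": _PURINE_RINGS},
    "DG": {"don": ["N1", "N2"], "acc": ["O6", "N3", "N7"], "rings": _PURINE_RINGS},
    "DC": {"don": ["N4"], "acc": ["O2", "N3"], "rings": _PYRIMIDINE_RING},
    "DT": {"don": ["N3"], "acc": ["O2", "O4"], "rings": _PYRIMIDINE_RING,
           "hphob": ["C7"]},
    "DU": {"don": ["N3"], "acc": ["O2", "O4"], "rings": _PYRIMIDINE_RING},
}
_NUC_BASE["A"] = _NUC_BASE["DA"]
_NUC_BASE["G"] = _NUC_BASE["DG"]
_NUC_BASE["C"] = _NUC_BASE["DC"]
_NUC_BASE["T"] = _NUC_BASE["DT"]
_NUC_BASE["U"] = _NUC_BASE["DU"]

_SUGAR_ACCEPTORS = ["O4'", "O3'", "O5'", "O2'"]
_PHOSPHATE_NAMES = (["P", "OP1", "OP2"], ["P", "O1P", "O2P"])


def _nuc_template(resname: str) -> dict | None:
    base = resname
    if base.endswith(("5", "3")) and len(base) > 1:
        base = base[:-1]
    return _NUC_BASE.get(base)


def _fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane by SVD: (centroid, unit normal, max |deviation|)."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    dev = float(np.abs(centered @ normal).max())
    return centroid, normal, dev


def _make_ring(serials: list[int], frame: Frame, role: Role) -> Ring | None:
    coords = np.array([frame.coords_of(s) for s in serials])
    centroid, normal, dev = _fit_plane(coords)
    if dev > RING_PLANARITY_TOL:
        return None
    return Ring(member_serials=tuple(serials), centroid=centroid,
                normal=normal, role=role)


def _infer_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    """Distance-based bond inference from covalent radii (fallback for no CONECT)."""
    bonds = []
    n = len(atoms)
    for i in range(n):
        ri = _COV_RADII.get(atoms[i].element, 0.77)
        for j in range(i + 1, n):
            rj = _COV_RADII.get(atoms[j].element, 0.77)
            cut = ri + rj + _BOND_SLACK
            if np.linalg.norm(atoms[i].coords - atoms[j].coords) <= cut:
                bonds.append((atoms[i].serial, atoms[j].serial))
    return bonds


def _perceive_ligand(frame: Frame, ligand: list[Atom],
                     bonds: list[tuple[int, int]], p: Perception) -> None:
    lig_serials = {a.serial for a in ligand}
    graph = nx.Graph()
    graph.add_nodes_from(lig_serials)
    lig_bonds = [(a, b) for a, b in bonds if a in lig_serials and b in lig_serials]
    if not lig_bonds:
        inferred = _infer_bonds(ligand)
        lig_bonds = [(a, b) for a, b in inferred]
    graph.add_edges_from(lig_bonds)

    by_serial = frame.by_serial
    bonds_ok = graph.number_of_edges() > 0 or len(ligand) == 1
    if not bonds_ok:
        warnings.warn(
            "ligand has no CONECT records and no bonds detectable at covalent "
            "radii; ring and charged-group perception skipped for the ligand",
            stacklevel=3,
        )
        logger.warning("ligand bond perception failed; rings/charges skipped")

    def neighbors(s: int) -> list[Atom]:
        return [by_serial[n] for n in graph.neighbors(s)]

    for a in ligand:
        if a.element == "H":
            continue
        nbrs = neighbors(a.serial)
        h_nbrs = [n.serial for n in nbrs if n.element == "H"]
        heavy = [n for n in nbrs if n.element != "H"]
        if a.element in ("N", "O"):
            if h_nbrs:
                p.donors[a.serial] = sorted(h_nbrs)
            elif not p.has_hydrogens:
                # no explicit hydrogens anywhere: any polar atom may donate
                p.donors[a.serial] = []
            if a.element == "O" or len(heavy) < 3:
                p.acceptors.add(a.serial)
        elif a.element == "C":
            if all(n.element in ("C", "H", "S") for n in nbrs) and (nbrs or len(ligand) == 1):
                p.hydrophobic.add(a.serial)

    if not bonds_ok:
        return

    # rings: 5/6-cycles passing the planarity test
    heavy_graph = graph.subgraph(
        [s for s in lig_serials if by_serial[s].element != "H"])
    for cycle in nx.cycle_basis(nx.Graph(heavy_graph)):
        if len(cycle) in (5, 6):
            ring = _make_ring(sorted(cycle), frame, Role.LIGAND)
            if ring is not None:
                p.rings.append(ring)

    # charged-group patterns on the bond graph
    for a in ligand:
        nbrs = [n for n in neighbors(a.serial) if n.element != "H"]
        if a.element == "C":
            term_o = [n for n in nbrs if n.element == "O"
                      and sum(1 for m in graph.neighbors(n.serial)
                              if by_serial[m].element != "H") == 1]
            if len(term_o) == 2:  # carboxylate
                members = sorted([a.serial] + [o.serial for o in term_o])
                p.charged_groups.append(_group(-1, members, frame, Role.LIGAND))
                continue
            term_n = [n for n in nbrs if n.element == "N"
                      and sum(1 for m in graph.neighbors(n.serial)
                              if by_serial[m].element != "H") == 1]
            if len(term_n) >= 2:  # amidinium / guanidinium
                members = sorted([a.serial] + [x.serial for x in term_n])
                p.charged_groups.append(_group(+1, members, frame, Role.LIGAND))
        elif a.element == "N" and len(nbrs) == 4:  # quaternary N
            p.charged_groups.append(_group(+1, [a.serial], frame, Role.LIGAND))


def _group(sign: int, members: list[int], frame: Frame, role: Role) -> ChargedGroup:
    center = np.mean([frame.coords_of(s) for s in members], axis=0)
    return ChargedGroup(charge_sign=sign, member_serials=tuple(members),
                        center=center, role=role)


def _residue_atoms(frame: Frame) -> dict[tuple[str, int, str], list[Atom]]:
    residues: dict[tuple[str, int, str], list[Atom]] = {}
    for a in frame.atoms:
        residues.setdefault(a.residue_id, []).append(a)
    return residues


def _h_attached(atom: Atom, res_atoms: list[Atom]) -> list[int]:
    return [h.serial for h in res_atoms
            if h.element == "H"
            and np.linalg.norm(h.coords - atom.coords) <= _H_BOND_MAX]


def _perceive_receptor_residue(resname: str, atoms: list[Atom], frame: Frame,
                               role: Role, p: Perception) -> None:
    tmpl = _AA_SIDE.get(resname) if role == Role.RECEPTOR_PROTEIN else _nuc_template(resname)
    by_name = {a.name: a for a in atoms}

    don_names: list[str] = []
    acc_names: list[str] = []
    if role == Role.RECEPTOR_PROTEIN:
        if resname != "PRO":
            don_names.append("N")
        acc_names += ["O", "OXT"]
    else:
        acc_names += _SUGAR_ACCEPTORS
        if "O2'" in by_name:
            don_names.append("O2'")
    if tmpl:
        don_names += tmpl.get("don", [])
        acc_names += tmpl.get("acc", [])
        for name in tmpl.get("hphob", []):
            if name in by_name:
                p.hydrophobic.add(by_name[name].serial)
        for ring_names in tmpl.get("rings", []):
            if all(n in by_name for n in ring_names):
                ring = _make_ring([by_name[n].serial for n in ring_names],
                                  frame, role)
                if ring is not None:
                    p.rings.append(ring)
        for sign, member_names in tmpl.get("charged", []):
            if all(n in by_name for n in member_names):
                p.charged_groups.append(
                    _group(sign, sorted(by_name[n].serial for n in member_names),
                           frame, role))

    # HIS is neutral donor/acceptor unless both ring nitrogens carry explicit H
    if resname in ("HIS", "HIP") and p.has_hydrogens:
        ring_n = [by_name[n] for n in ("ND1", "NE2") if n in by_name]
        if len(ring_n) == 2 and all(_h_attached(a, atoms) for a in ring_n):
            members = [by_name[n].serial for n in
                       ("CG", "ND1", "CE1", "NE2", "CD2") if n in by_name]
            p.charged_groups.append(_group(+1, sorted(members), frame, role))

    if role == Role.RECEPTOR_NUCLEIC:
        for names in _PHOSPHATE_NAMES:
            if all(n in by_name for n in names):
                p.charged_groups.append(
                    _group(-1, sorted(by_name[n].serial for n in names),
                           frame, role))
                acc_names += names[1:]
                break

    for name in don_names:
        a = by_name.get(name)
        if a is None:
            continue
        if p.has_hydrogens:
            hs = _h_attached(a, atoms)
            if hs:
                p.donors[a.serial] = sorted(hs)
        else:
            p.donors[a.serial] = []
    for name in acc_names:
        a = by_name.get(name)
        if a is not None:
            p.acceptors.add(a.serial)


def perceive_chemistry(frame: Frame,
                       conect: list[tuple[int, int]] | None = None) -> Perception:
    """Build the perception tables for one frame with roles assigned.

    Receptor residues are perceived from templates; the ligand from its bond
    graph (``conect`` overrides ``frame.bonds``).  Water contributes its
    oxygen atoms to the water-bridge search.
    """
    p = Perception(has_hydrogens=frame.has_hydrogens)
    bonds = conect if conect is not None else frame.bonds
    ligand = frame.atoms_with_role(Role.LIGAND)
    if ligand:
        _perceive_ligand(frame, ligand, bonds, p)
    for (resname, _resnum, _chain), atoms in _residue_atoms(frame).items():
        role = atoms[0].role
        if role in (Role.RECEPTOR_PROTEIN, Role.RECEPTOR_NUCLEIC):
            _perceive_receptor_residue(resname, atoms, frame, role, p)
        elif role == Role.WATER or resname in WATER_RESNAMES:
            for a in atoms:
                if a.element == "O":
                    p.water_oxygens.append(a.serial)
    p.water_oxygens.sort()
    return p
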