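"""Synthetic multi-model PDB trajectories with a known interaction schedule.

Each schedule entry plants one ligand fragment / receptor fragment pair
(hydroxyl donor vs SER acceptor, methyl vs LEU, benzene vs PHE ring,
carboxylate vs ARG guanidinium, water-bridged hydroxyl vs SER) at its own
widely separated station.  In the entry's scheduled frames the fragments sit
strictly inside the detection thresholds; in all other frames the receptor
fragment is displaced strictly outside them.  The generator emits the
trajectory and a manifest stating, for every frame, exactly which
interaction keys must hold — the ground truth the rest of the test suite is
checked against.

Geometry here is scripted, not simulated: fixtures exercise detection and
bookkeeping, not physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from trajcontacts.chemistry import Perception, Ring, ChargedGroup
from trajcontacts.detect import GeometricCriteria
from trajcontacts.structure_io import (
    Atom, Frame, Role, write_multimodel_pdb,
)

__all__ = ["ScheduleEntry", "build_trajectory", "build_frames",
           "build_oracle_frame", "standard_schedule", "one_of_each_schedule",
           "FixtureError"]

_STATION_SPACING = 25.0  # Angstrom between schedule entries
_MARGIN_DIST = 0.2       # required slack inside/outside every distance cutoff
_MARGIN_ANGLE = 10.0     # degrees
_MAX_JITTER_SIGMA = 0.04


class FixtureError(ValueError):
    """The requested schedule would produce an ambiguous fixture."""


@dataclass(frozen=True)
class ScheduleEntry:
    """One planted interaction: bond type, target frames, displacement.

    ``frames`` lists the frame indices in which the interaction must hold;
    in every other frame the receptor fragment is pushed ``off_shift``
    Angstrom further away along the approach axis.
    """

    bond_type: str
    frames: frozenset[int]
    off_shift: float = 6.0

    def __post_init__(self) -> None:
        if self.bond_type not in ("hbond", "hydrophobic", "pi_stack",
                                  "salt_bridge", "water_bridge"):
            raise ValueError(f"unknown bond type {self.bond_type!r}")


@dataclass
class _FragmentAtom:
    name: str
    element: str
    resname: str
    resnum: int
    chain: str
    offset: np.ndarray        # relative to the entry's station origin
    group: str                # "ligand" | "receptor" | "water"
    hetatm: bool = False


def _hexagon(radius: float = 1.39) -> list[np.ndarray]:
    return [np.array([radius * math.cos(a), radius * math.sin(a), 0.0])
            for a in (math.radians(60 * i) for i in range(6))]


def _entry_atoms(entry: ScheduleEntry, idx: int) -> tuple[list[_FragmentAtom], dict]:
    """Fragment geometry for one entry; returns atoms + expected-key metadata.

    All coordinates are offsets from the entry's station; the approach axis
    is +x except for the pi stack, which approaches along +z.
    """
    resnum = 10 * (idx + 1)
    atoms: list[_FragmentAtom] = []
    info: dict = {"axis": np.array([1.0, 0.0, 0.0])}
    bt = entry.bond_type
    if bt == "hbond":
        # ligand hydroxyl donor 2.9 A from a SER OG acceptor, D-H-A 180 deg
        atoms += [
            _FragmentAtom("O1", "O", "LIG", 1, "L", np.array([0.0, 0, 0]), "ligand", True),
            _FragmentAtom("H1", "H", "LIG", 1, "L", np.array([0.96, 0, 0]), "ligand", True),
        ]
        atoms += [
            _FragmentAtom("OG", "O", "SER", resnum, "A", np.array([2.9, 0, 0]), "receptor"),
            _FragmentAtom("CB", "C", "SER", resnum, "A", np.array([4.33, 0, 0]), "receptor"),
            _FragmentAtom("CA", "C", "SER", resnum, "A", np.array([5.2, 1.2, 0]), "receptor"),
        ]
        info["lig_names"] = ["O1"]
        info["rcpt_names"] = ["OG"]
        info["bonds"] = [("O1", "H1")]
        info["geometry"] = {"da_dist": 2.9, "dha_angle": 180.0}
    elif bt == "hydrophobic":
        # ligand ethyl carbon 3.6 A from LEU CD1; partner carbon points away
        atoms += [
            _FragmentAtom("C1", "C", "LIG", 1, "L", np.array([0.0, 0, 0]), "ligand", True),
            _FragmentAtom("C2", "C", "LIG", 1, "L", np.array([-1.5, 0, 0]), "ligand", True),
        ]
        atoms += [
            _FragmentAtom("CD1", "C", "LEU", resnum, "A", np.array([3.6, 0, 0]), "receptor"),
            _FragmentAtom("CG", "C", "LEU", resnum, "A", np.array([5.0, 0.9, 0]), "receptor"),
            _FragmentAtom("CD2", "C", "LEU", resnum, "A", np.array([5.6, 2.2, 0]), "receptor"),
            _FragmentAtom("CB", "C", "LEU", resnum, "A", np.array([6.3, 0.0, 0]), "receptor"),
        ]
        info["lig_names"] = ["C1"]
        info["rcpt_names"] = ["CD1"]
        info["bonds"] = [("C1", "C2")]
        info["geometry"] = {"dist": 3.6}
    elif bt == "pi_stack":
        # coaxial parallel benzene / PHE rings, centroids 4.3 A apart
        ring = _hexagon()
        for i, off in enumerate(ring, start=1):
            atoms.append(_FragmentAtom(f"C1{i}", "C", "LIG", 1, "L", off,
                                       "ligand", True))
        phe_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        for name, off in zip(phe_names, ring):
            atoms.append(_FragmentAtom(name, "C", "PHE", resnum, "A",
                                       off + np.array([0, 0, 4.3]), "receptor"))
        info["axis"] = np.array([0.0, 0.0, 1.0])
        info["lig_names"] = [f"C1{i}" for i in range(1, 7)]
        info["rcpt_names"] = phe_names
        info["bonds"] = [(f"C1{i}", f"C1{i % 6 + 1}") for i in range(1, 7)]
        info["geometry"] = {"centroid_dist": 4.3, "offset": 0.0, "angle": 0.0}
    elif bt == "salt_bridge":
        # ligand carboxylate center 4.0 A from an ARG guanidinium center
        atoms += [
            _FragmentAtom("C20", "C", "LIG", 1, "L", np.array([0.0, 0, 0]), "ligand", True),
            _FragmentAtom("O21", "O", "LIG", 1, "L", np.array([-0.63, 1.08, 0]), "ligand", True),
            _FragmentAtom("O22", "O", "LIG", 1, "L", np.array([-0.63, -1.08, 0]), "ligand", True),
        ]
        carbox_center = np.array([-0.42, 0.0, 0.0])
        guan_center = carbox_center + np.array([4.0, 0, 0])
        for name, off in (("CZ", [0, 0, 0]), ("NE", [-1.33, 0, 0]),
                          ("NH1", [0.67, 1.15, 0]), ("NH2", [0.67, -1.15, 0])):
            atoms.append(_FragmentAtom(name, "N" if name != "CZ" else "C",
                                       "ARG", resnum, "A",
                                       guan_center + np.array(off, dtype=float),
                                       "receptor"))
        info["lig_names"] = ["C20", "O21", "O22"]
        info["rcpt_names"] = ["NE", "CZ", "NH1", "NH2"]
        info["bonds"] = [("C20", "O21"), ("C20", "O22")]
        info["geometry"] = {"center_dist": 4.0}
    elif bt == "water_bridge":
        # ligand hydroxyl -- water oxygen -- SER OG, collinear, 2.8 + 3.0 A
        atoms += [
            _FragmentAtom("O40", "O", "LIG", 1, "L", np.array([0.0, 0, 0]), "ligand", True),
            _FragmentAtom("H40", "H", "LIG", 1, "L", np.array([0.96, 0, 0]), "ligand", True),
        ]
        atoms.append(_FragmentAtom("O", "O", "HOH", 500 + resnum, "W",
                                   np.array([2.8, 0, 0]), "water", True))
        atoms += [
            _FragmentAtom("OG", "O", "SER", resnum, "A", np.array([5.8, 0, 0]), "receptor"),
            _FragmentAtom("CB", "C", "SER", resnum, "A", np.array([7.23, 0, 0]), "receptor"),
        ]
        info["lig_names"] = ["O40"]
        info["rcpt_names"] = ["OG"]
        info["bonds"] = [("O40", "H40")]
        info["water_name"] = "O"
        info["geometry"] = {"dist_lw": 2.8, "dist_rw": 3.0}
    return atoms, info


def _check_margins(entry: ScheduleEntry, info: dict,
                   criteria: GeometricCriteria) -> None:
    g = info["geometry"]
    bt = entry.bond_type
    ok = True
    if bt == "hbond":
        ok = (g["da_dist"] <= criteria.hbond_max_da_dist - _MARGIN_DIST
              and g["dha_angle"] >= criteria.hbond_min_dha_angle + _MARGIN_ANGLE
              and g["da_dist"] + entry.off_shift
              >= criteria.hbond_max_da_dist + _MARGIN_DIST)
    elif bt == "hydrophobic":
        ok = (g["dist"] <= criteria.hydrophobic_max_dist - _MARGIN_DIST
              and g["dist"] + entry.off_shift
              >= criteria.hydrophobic_max_dist + _MARGIN_DIST)
    elif bt == "pi_stack":
        ok = (g["centroid_dist"] <= criteria.pistack_max_centroid_dist - _MARGIN_DIST
              and g["offset"] <= criteria.pistack_max_offset - _MARGIN_DIST
              and g["angle"] <= criteria.pistack_parallel_max_angle - _MARGIN_ANGLE
              and g["centroid_dist"] + entry.off_shift
              >= criteria.pistack_max_centroid_dist + _MARGIN_DIST)
    elif bt == "salt_bridge":
        ok = (g["center_dist"] <= criteria.saltbridge_max_dist - _MARGIN_DIST
              and g["center_dist"] + entry.off_shift
              >= criteria.saltbridge_max_dist + _MARGIN_DIST)
    elif bt == "water_bridge":
        ok = (criteria.waterbridge_min_dist + _MARGIN_DIST
              <= g["dist_lw"] <= criteria.waterbridge_max_dist - _MARGIN_DIST
              and criteria.waterbridge_min_dist + _MARGIN_DIST
              <= g["dist_rw"] <= criteria.waterbridge_max_dist - _MARGIN_DIST
              and g["dist_lw"] + entry.off_shift
              >= criteria.waterbridge_max_dist + _MARGIN_DIST)
    if not ok:
        raise FixtureError(
            f"{bt} schedule geometry violates the +/-{_MARGIN_DIST} A / "
            f"{_MARGIN_ANGLE} deg safety margin against the criteria")


def build_frames(
    schedule: list[ScheduleEntry],
    n_frames: int,
    dt: float = 10.0,
    t_start: float = 0.0,
    seed: int = 0,
    jitter_sigma: float = 0.0,
    criteria: GeometricCriteria | None = None,
) -> tuple[list[Frame], dict]:
    """Build the scheduled frames in memory; returns (frames, manifest).

    The manifest maps every frame index to the exact list of interaction keys
    that must hold there, plus per-entry key and frame lists.  Deterministic
    for a fixed seed.
    """
    criteria = criteria or GeometricCriteria()
    if jitter_sigma > _MAX_JITTER_SIGMA:
        raise FixtureError(
            f"jitter sigma {jitter_sigma} would endanger the detection margin "
            f"(max {_MAX_JITTER_SIGMA})")
    if any(f >= n_frames or f < 0 for e in schedule for f in e.frames):
        raise FixtureError("schedule references frames outside the trajectory")

    rng = np.random.default_rng(seed)
    per_entry = []
    serial = 0
    template: list[tuple[Atom, int, np.ndarray, str]] = []  # atom, entry idx, base xyz, group
    bonds: list[tuple[int, int]] = []
    for idx, entry in enumerate(schedule):
        frag_atoms, info = _entry_atoms(entry, idx)
        _check_margins(entry, info, criteria)
        station = np.array([_STATION_SPACING * idx, 0.0, 0.0])
        name_to_serial: dict[str, int] = {}
        for fa in frag_atoms:
            serial += 1
            name_to_serial[fa.name] = serial
            atom = Atom(
                serial=serial, name=fa.name, element=fa.element,
                residue_name=fa.resname, residue_number=fa.resnum,
                chain_id=fa.chain, coords=np.zeros(3), is_hetatm=fa.hetatm,
            )
            template.append((atom, idx, station + fa.offset, fa.group))
        for a, b in info.get("bonds", []):
            bonds.append((name_to_serial[a], name_to_serial[b]))
        lig_serials = tuple(sorted(name_to_serial[n] for n in info["lig_names"]))
        rcpt_serials = tuple(sorted(name_to_serial[n] for n in info["rcpt_names"]))
        water = name_to_serial.get(info.get("water_name", ""), None)
        key = (entry.bond_type, lig_serials, rcpt_serials, water)
        per_entry.append({"entry": entry, "info": info, "key": key})

    frames: list[Frame] = []
    frame_truth: dict[int, list] = {}
    for i in range(n_frames):
        atoms = []
        for atom, idx, base, group in template:
            entry = schedule[idx]
            info = per_entry[idx]["info"]
            xyz = base.copy()
            if i not in entry.frames and group in ("receptor", "water"):
                xyz = xyz + info["axis"] * entry.off_shift
            if jitter_sigma > 0:
                xyz = xyz + rng.normal(0.0, jitter_sigma, size=3)
            atoms.append(
                Atom(serial=atom.serial, name=atom.name, element=atom.element,
                     residue_name=atom.residue_name,
                     residue_number=atom.residue_number,
                     chain_id=atom.chain_id, coords=xyz,
                     is_hetatm=atom.is_hetatm))
        frames.append(Frame(index=i, time_ps=t_start + i * dt, atoms=atoms,
                            bonds=sorted(bonds)))
        frame_truth[i] = sorted(
            (pe["key"] for pe in per_entry if i in pe["entry"].frames),
            key=repr)

    manifest = {
        "n_frames": n_frames, "dt": dt, "t_start": t_start,
        "ligand": "LIG", "seed": seed, "jitter_sigma": jitter_sigma,
        "entries": [
            {"bond_type": pe["entry"].bond_type,
             "key": pe["key"],
             "frames": sorted(pe["entry"].frames)}
            for pe in per_entry
        ],
        "frames": frame_truth,
    }
    return frames, manifest


def build_trajectory(
    schedule: list[ScheduleEntry],
    n_frames: int,
    path: str | Path,
    dt: float = 10.0,
    t_start: float = 0.0,
    seed: int = 0,
    jitter_sigma: float = 0.0,
    criteria: GeometricCriteria | None = None,
) -> tuple[Path, dict]:
    """Write the scheduled trajectory as a multi-model PDB; returns (path, manifest)."""
    frames, manifest = build_frames(
        schedule, n_frames, dt=dt, t_start=t_start, seed=seed,
        jitter_sigma=jitter_sigma, criteria=criteria)
    path = Path(path)
    write_multimodel_pdb(frames, path)
    return path, manifest


def one_of_each_schedule(n_frames: int = 10,
                         frames: frozenset[int] | None = None) -> list[ScheduleEntry]:
    """One entry per bond type, all active in the same frames (default: all)."""
    active = frames if frames is not None else frozenset(range(n_frames))
    return [ScheduleEntry(bt, active)
            for bt in ("hbond", "hydrophobic", "pi_stack",
                       "salt_bridge", "water_bridge")]


def standard_schedule(n_frames: int = 200) -> list[ScheduleEntry]:
    """Four entries with staggered, partially overlapping residence windows."""
    q = n_frames // 4
    return [
        ScheduleEntry("hbond", frozenset(range(0, 2 * q))),
        ScheduleEntry("hydrophobic", frozenset(range(q, n_frames))),
        ScheduleEntry("pi_stack",
                      frozenset(range(0, n_frames, 2))),  # intermittent
        ScheduleEntry("salt_bridge", frozenset(range(3 * q, n_frames))),
    ]


# ---------------------------------------------------------------------------
# Randomized micro-systems for the brute-force oracle equivalence suite.
# Perception labels are constructed alongside the coordinates, so these test
# the detectors in isolation from template/bond-graph perception.
# ---------------------------------------------------------------------------

def build_oracle_frame(n_atoms: int = 60, box_size: float = 20.0,
                       seed: int = 0) -> tuple[Frame, Perception]:
    """Random frame + matching perception tables for detector oracles.

    Roughly: polar atoms (donors with an explicit H, acceptors, some both) on
    ligand and receptor sides, hydrophobic carbons, water oxygens, a few
    planar six-rings and single-atom charged groups.  Receptor atoms share
    residue numbers from a small pool so the hydrophobic closest-per-residue
    rule is exercised.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    p = Perception(has_hydrogens=True)
    serial = 0

    def place() -> np.ndarray:
        return rng.uniform(0, box_size, size=3)

    def add(name, element, resname, resnum, chain, xyz, role, het=False) -> int:
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial=serial, name=name, element=element,
                          residue_name=resname, residue_number=resnum,
                          chain_id=chain, coords=np.asarray(xyz, dtype=float),
                          role=role, is_hetatm=het))
        return serial

    if n_atoms == 0:
        return Frame(index=0, time_ps=0.0, atoms=[]), p

    n_polar = max(2, n_atoms // 5)
    n_hphob = max(2, n_atoms // 6)
    n_water = max(1, n_atoms // 10)
    n_rings = 2 if n_atoms >= 40 else 1
    n_charged = 2 if n_atoms >= 30 else 1

    for side, role, resname, chain in (("l", Role.LIGAND, "LIG", "L"),
                                       ("r", Role.RECEPTOR_PROTEIN, "ALA", "A")):
        for i in range(n_polar):
            resnum = 1 if side == "l" else 100 + i % 5
            xyz = place()
            kind = rng.integers(0, 3)  # 0 donor, 1 acceptor, 2 both
            s = add(f"O{side}{i}", "O", resname, resnum, chain, xyz, role,
                    side == "l")
            if kind in (0, 2):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                h = add(f"H{side}{i}", "H", resname, resnum, chain,
                        xyz + 0.96 * direction, role, side == "l")
                p.donors[s] = [h]
            if kind in (1, 2):
                p.acceptors.add(s)
            if kind == 0 and rng.random() < 0.3:
                p.acceptors.add(s)  # donor that can also accept
        for i in range(n_hphob):
            resnum = 1 if side == "l" else 200 + i % 4
            s = add(f"C{side}{i}", "C", resname, resnum, chain, place(), role,
                    side == "l")
            p.hydrophobic.add(s)
        for i in range(n_rings):
            resnum = 1 if side == "l" else 300 + i
            center = place()
            # random ring orientation via two orthonormal in-plane axes
            a = rng.normal(size=3); a /= np.linalg.norm(a)
            b = rng.normal(size=3); b -= a * (a @ b); b /= np.linalg.norm(b)
            members = []
            for k in range(6):
                ang = math.radians(60 * k)
                xyz = center + 1.39 * (math.cos(ang) * a + math.sin(ang) * b)
                members.append(add(f"R{side}{i}{k}", "C", resname, resnum,
                                   chain, xyz, role, side == "l"))
            normal = np.cross(a, b)
            normal /= np.linalg.norm(normal)
            p.rings.append(Ring(member_serials=tuple(members),
                                centroid=center, normal=normal, role=role))
        for i in range(n_charged):
            resnum = 1 if side == "l" else 400 + i
            sign = +1 if (i + (0 if side == "l" else 1)) % 2 == 0 else -1
            elem = "N" if sign > 0 else "O"
            xyz = place()
            s = add(f"Q{side}{i}", elem, resname, resnum, chain, xyz, role,
                    side == "l")
            p.charged_groups.append(ChargedGroup(
                charge_sign=sign, member_serials=(s,), center=xyz, role=role))

    for i in range(n_water):
        s = add("O", "O", "HOH", 900 + i, "W", place(), Role.WATER, True)
        p.water_oxygens.append(s)

    frame = Frame(index=0, time_ps=0.0, atoms=atoms)
    return frame, p
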