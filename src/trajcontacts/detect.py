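"""Geometric detection of the five ligand-receptor interaction classes.

Each detector is a pure function of (coordinates, roles, perception tables,
criteria): hydrogen bonds, hydrophobic contacts, pi stacks (parallel and
T-shaped), salt bridges and water bridges.  All threshold comparisons are
closed (<= / >=): a pair exactly at a cutoff is reported.  Only pairs with
exactly one ligand side and one receptor side are ever considered, so
intra-ligand and intra-receptor contacts cannot appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from trajcontacts.chemistry import Perception, perceive_chemistry
from trajcontacts.structure_io import Frame, Role

__all__ = [
    "BOND_TYPES", "GeometricCriteria", "Interaction",
    "detect_hbonds", "detect_hydrophobic", "detect_pi_stacks",
    "detect_salt_bridges", "detect_water_bridges", "profile_frame",
]

BOND_TYPES = ("hbond", "hydrophobic", "pi_stack", "salt_bridge", "water_bridge")

_RECEPTOR_ROLES = (Role.RECEPTOR_PROTEIN, Role.RECEPTOR_NUCLEIC)


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle cutoffs for interaction detection (Angstrom, degrees).

    Defaults follow the published criteria of the standard protein-ligand
    interaction profiler; every value can be overridden per run and the
    values used are echoed into the output metadata.
    """

    hbond_max_da_dist: float = 4.1
    hbond_min_dha_angle: float = 100.0
    hbond_heavy_only_max_dist: float = 3.5  # used when no explicit hydrogens
    hydrophobic_max_dist: float = 4.0
    pistack_max_centroid_dist: float = 5.5
    pistack_max_offset: float = 2.0
    pistack_parallel_max_angle: float = 30.0
    pistack_tshaped_min_angle: float = 60.0
    saltbridge_max_dist: float = 5.5
    waterbridge_min_dist: float = 2.5
    waterbridge_max_dist: float = 4.1
    min_pair_dist: float = 0.5  # rejects clashes / self-pairs

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if "angle" in name:
                if not 0.0 <= value <= 180.0:
                    raise ValueError(f"{name} must be in [0, 180], got {value}")
            elif value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.waterbridge_min_dist >= self.waterbridge_max_dist:
            raise ValueError("waterbridge_min_dist must be < waterbridge_max_dist")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "GeometricCriteria":
        return cls(**d)


@dataclass(frozen=True)
class Interaction:
    """One detected contact of one bond type at one timestamp."""

    bond_type: str
    ligand_serials: tuple[int, ...]
    receptor_serials: tuple[int, ...]
    receptor_residue: tuple[str, int, str]
    time_ps: float
    metrics: dict[str, float] = field(default_factory=dict)
    water_serial: int | None = None

    @property
    def key(self) -> tuple:
        return (self.bond_type, self.ligand_serials, self.receptor_serials,
                self.water_serial)


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _is_receptor(frame: Frame, serial: int) -> bool:
    return frame.by_serial[serial].role in _RECEPTOR_ROLES


def _is_ligand(frame: Frame, serial: int) -> bool:
    return frame.by_serial[serial].role == Role.LIGAND


def detect_hbonds(frame: Frame, perception: Perception,
                  criteria: GeometricCriteria) -> list[Interaction]:
    """Hydrogen bonds between ligand and receptor heavy atoms.

    With explicit hydrogens: D-A distance and D-H-A angle criteria.  Without:
    a tighter heavy-atom-only distance cutoff.  When a pair qualifies in both
    donor directions it is reported once (ligand-as-donor preferred); the
    ``protisdon`` metric records whether the receptor donates.
    """
    hits: dict[tuple[int, int], Interaction] = {}
    by_serial = frame.by_serial
    for d_serial, h_serials in perception.donors.items():
        d_atom = by_serial[d_serial]
        d_is_lig = d_atom.role == Role.LIGAND
        if not (d_is_lig or d_atom.role in _RECEPTOR_ROLES):
            continue
        for a_serial in perception.acceptors:
            if a_serial == d_serial:
                continue
            a_atom = by_serial[a_serial]
            a_is_lig = a_atom.role == Role.LIGAND
            if d_is_lig == a_is_lig:
                continue
            if not (a_is_lig or a_atom.role in _RECEPTOR_ROLES):
                continue
            da = float(np.linalg.norm(d_atom.coords - a_atom.coords))
            if da < criteria.min_pair_dist:
                continue
            metrics: dict[str, float] = {"da_dist": round(da, 4)}
            if h_serials:
                if da > criteria.hbond_max_da_dist:
                    continue
                best = max(
                    _angle_deg(d_atom.coords, by_serial[h].coords, a_atom.coords)
                    for h in h_serials
                )
                if best < criteria.hbond_min_dha_angle:
                    continue
                metrics["dha_angle"] = round(best, 4)
            else:
                if da > criteria.hbond_heavy_only_max_dist:
                    continue
            lig_serial = d_serial if d_is_lig else a_serial
            rcpt_serial = a_serial if d_is_lig else d_serial
            metrics["protisdon"] = 0.0 if d_is_lig else 1.0
            pair = (lig_serial, rcpt_serial)
            if pair in hits and hits[pair].metrics["protisdon"] == 0.0:
                continue  # ligand-as-donor already recorded
            rcpt = by_serial[rcpt_serial]
            hits[pair] = Interaction(
                bond_type="hbond",
                ligand_serials=(lig_serial,),
                receptor_serials=(rcpt_serial,),
                receptor_residue=rcpt.residue_id,
                time_ps=frame.time_ps,
                metrics=metrics,
            )
    return list(hits.values())


def detect_hydrophobic(frame: Frame, perception: Perception,
                       criteria: GeometricCriteria) -> list[Interaction]:
    """Hydrophobic carbon-carbon contacts.

    Per (ligand atom, receptor residue) pair only the closest receptor carbon
    is kept, so clusters of equivalent carbons yield one contact per frame.
    """
    by_serial = frame.by_serial
    lig = sorted(s for s in perception.hydrophobic if _is_ligand(frame, s))
    rcpt = sorted(s for s in perception.hydrophobic if _is_receptor(frame, s))
    if not lig or not rcpt:
        return []
    lig_xyz = np.array([by_serial[s].coords for s in lig])
    rcpt_xyz = np.array([by_serial[s].coords for s in rcpt])
    dmat = np.linalg.norm(lig_xyz[:, None, :] - rcpt_xyz[None, :, :], axis=2)
    best: dict[tuple[int, tuple], tuple[float, int]] = {}
    for i, ls in enumerate(lig):
        for j, rs in enumerate(rcpt):
            d = float(dmat[i, j])
            if not (criteria.min_pair_dist <= d <= criteria.hydrophobic_max_dist):
                continue
            res = by_serial[rs].residue_id
            cur = best.get((ls, res))
            if cur is None or (d, rs) < cur:
                best[(ls, res)] = (d, rs)
    out = []
    for (ls, res), (d, rs) in best.items():
        out.append(Interaction(
            bond_type="hydrophobic",
            ligand_serials=(ls,), receptor_serials=(rs,),
            receptor_residue=res, time_ps=frame.time_ps,
            metrics={"dist": round(d, 4)},
        ))
    return out


def detect_pi_stacks(frame: Frame, perception: Perception,
                     criteria: GeometricCriteria) -> list[Interaction]:
    """Parallel (P) and T-shaped (T) aromatic ring stacking.

    The interplanar angle is folded to [0, 90] degrees; angles between the
    parallel and T-shaped bands give no interaction.  The offset is the
    smaller of the centroid-centroid vector projections onto the two ring
    planes (the larger projection equals the full centroid distance for
    edge-to-face geometries, so it cannot discriminate).
    """
    lig_rings = [r for r in perception.rings if r.role == Role.LIGAND]
    rcpt_rings = [r for r in perception.rings if r.role in _RECEPTOR_ROLES]
    out = []
    by_serial = frame.by_serial
    for lr in lig_rings:
        for rr in rcpt_rings:
            delta = rr.centroid - lr.centroid
            d = float(np.linalg.norm(delta))
            if d > criteria.pistack_max_centroid_dist or d < criteria.min_pair_dist:
                continue
            cosang = abs(float(np.dot(lr.normal, rr.normal)))
            theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            # in-plane projection of the centroid separation, on each plane
            off1 = float(np.linalg.norm(delta - np.dot(delta, lr.normal) * lr.normal))
            off2 = float(np.linalg.norm(delta - np.dot(delta, rr.normal) * rr.normal))
            offset = min(off1, off2)
            if offset > criteria.pistack_max_offset:
                continue
            if theta <= criteria.pistack_parallel_max_angle:
                stype = "P"
            elif theta >= criteria.pistack_tshaped_min_angle:
                stype = "T"
            else:
                continue
            rcpt_res = by_serial[rr.member_serials[0]].residue_id
            out.append(Interaction(
                bond_type="pi_stack",
                ligand_serials=tuple(sorted(lr.member_serials)),
                receptor_serials=tuple(sorted(rr.member_serials)),
                receptor_residue=rcpt_res, time_ps=frame.time_ps,
                metrics={"centroid_dist": round(d, 4), "angle": round(theta, 4),
                         "offset": round(offset, 4),
                         "stack_type": 0.0 if stype == "P" else 1.0},
            ))
    return out


def detect_salt_bridges(frame: Frame, perception: Perception,
                        criteria: GeometricCriteria) -> list[Interaction]:
    """Opposite-sign charged-group centers within the salt-bridge cutoff."""
    lig_groups = [g for g in perception.charged_groups if g.role == Role.LIGAND]
    rcpt_groups = [g for g in perception.charged_groups if g.role in _RECEPTOR_ROLES]
    by_serial = frame.by_serial
    out = []
    for lg in lig_groups:
        for rg in rcpt_groups:
            if lg.charge_sign == rg.charge_sign:
                continue
            d = float(np.linalg.norm(lg.center - rg.center))
            if not (criteria.min_pair_dist <= d <= criteria.saltbridge_max_dist):
                continue
            rcpt_res = by_serial[rg.member_serials[0]].residue_id
            out.append(Interaction(
                bond_type="salt_bridge",
                ligand_serials=tuple(sorted(lg.member_serials)),
                receptor_serials=tuple(sorted(rg.member_serials)),
                receptor_residue=rcpt_res, time_ps=frame.time_ps,
                metrics={"center_dist": round(d, 4),
                         "ligand_sign": float(lg.charge_sign)},
            ))
    return out


def detect_water_bridges(frame: Frame, perception: Perception,
                         criteria: GeometricCriteria) -> list[Interaction]:
    """Water-mediated contacts: ligand and receptor polar atoms sharing a water.

    A water oxygen W bridges ligand atom L and receptor atom R when both
    L-W and R-W distances lie in the water-bridge band and the (L, R) pair
    provides at least one donor and one acceptor.  Each (L, R, W) triple is
    reported once; one water may bridge several pairs.
    """
    lig_polar = perception.polar(frame, Role.LIGAND)
    rcpt_polar = perception.polar(frame, *_RECEPTOR_ROLES)
    if not lig_polar or not rcpt_polar or not perception.water_oxygens:
        return []
    by_serial = frame.by_serial
    donors = set(perception.donors)
    acceptors = perception.acceptors
    lo, hi = criteria.waterbridge_min_dist, criteria.waterbridge_max_dist
    out = []
    for w in perception.water_oxygens:
        w_xyz = by_serial[w].coords
        near_lig = [s for s in lig_polar
                    if lo <= np.linalg.norm(by_serial[s].coords - w_xyz) <= hi]
        if not near_lig:
            continue
        near_rcpt = [s for s in rcpt_polar
                     if lo <= np.linalg.norm(by_serial[s].coords - w_xyz) <= hi]
        for ls in near_lig:
            for rs in near_rcpt:
                donor_ok = (ls in donors and rs in acceptors) or \
                           (rs in donors and ls in acceptors)
                if not donor_ok:
                    continue
                out.append(Interaction(
                    bond_type="water_bridge",
                    ligand_serials=(ls,), receptor_serials=(rs,),
                    receptor_residue=by_serial[rs].residue_id,
                    time_ps=frame.time_ps,
                    water_serial=w,
                    metrics={
                        "dist_lw": round(float(np.linalg.norm(
                            by_serial[ls].coords - w_xyz)), 4),
                        "dist_rw": round(float(np.linalg.norm(
                            by_serial[rs].coords - w_xyz)), 4),
                    },
                ))
    return out


_DETECTORS = (detect_hbonds, detect_hydrophobic, detect_pi_stacks,
              detect_salt_bridges, detect_water_bridges)


def profile_frame(frame: Frame, criteria: GeometricCriteria | None = None,
                  perception: Perception | None = None) -> list[Interaction]:
    """Run all five detectors on one frame; deterministic output order.

    Interactions are sorted by (bond type, ligand serials, receptor serials,
    water serial), so the result is invariant under atom record reordering.
    """
    criteria = criteria or GeometricCriteria()
    if perception is None:
        perception = perceive_chemistry(frame)
    hits: list[Interaction] = []
    for det in _DETECTORS:
        hits.extend(det(frame, perception, criteria))
    hits.sort(key=lambda i: (i.bond_type, i.ligand_serials, i.receptor_serials,
                             -1 if i.water_serial is None else i.water_serial))
    return hits
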