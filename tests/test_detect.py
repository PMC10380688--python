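"""Detector geometry rules and brute-force oracle equivalence."""

import math

import numpy as np
import pytest

from trajcontacts.chemistry import ChargedGroup, Perception, Ring
from trajcontacts.detect import (
    GeometricCriteria, detect_hbonds, detect_hydrophobic, detect_pi_stacks,
    detect_salt_bridges, detect_water_bridges, profile_frame,
)
from trajcontacts.fixtures import build_frames, build_oracle_frame, \
    one_of_each_schedule
from trajcontacts.structure_io import Atom, Frame, Role

from oracles import (
    oracle_all, oracle_hbonds, oracle_hydrophobic, oracle_pi_stacks,
    oracle_salt_bridges, oracle_water_bridges,
)

CRIT = GeometricCriteria()


def atom(serial, name, element, res, num, chain, xyz, role):
    return Atom(serial=serial, name=name, element=element, residue_name=res,
                residue_number=num, chain_id=chain,
                coords=np.asarray(xyz, dtype=float), role=role)


def polar_pair_frame(da_dist, with_h=True, h_angle_collinear=True):
    """Ligand hydroxyl donor vs receptor O acceptor at a given D-A distance."""
    atoms = [atom(1, "O1", "O", "LIG", 1, "L", [0, 0, 0], Role.LIGAND)]
    p = Perception(has_hydrogens=with_h)
    if with_h:
        hx = 0.96 if h_angle_collinear else -0.96
        atoms.append(atom(2, "H1", "H", "LIG", 1, "L", [hx, 0, 0], Role.LIGAND))
        p.donors[1] = [2]
    else:
        p.donors[1] = []
    atoms.append(atom(3, "OG", "O", "SER", 5, "A", [da_dist, 0, 0],
                      Role.RECEPTOR_PROTEIN))
    p.acceptors.add(3)
    return Frame(index=0, time_ps=0.0, atoms=atoms), p


class TestHbondRules:
    def test_good_geometry_is_reported(self):
        frame, p = polar_pair_frame(2.9)
        hits = detect_hbonds(frame, p, CRIT)
        assert [h.key for h in hits] == [("hbond", (1,), (3,), None)]
        assert hits[0].metrics["dha_angle"] == pytest.approx(180.0)

    def test_beyond_distance_cutoff_is_silent(self):
        frame, p = polar_pair_frame(4.2)
        assert detect_hbonds(frame, p, CRIT) == []

    def test_bad_angle_is_silent(self):
        # H points away from the acceptor: D-H-A angle 0 deg
        frame, p = polar_pair_frame(2.9, h_angle_collinear=False)
        assert detect_hbonds(frame, p, CRIT) == []

    def test_heavy_only_fallback_without_hydrogens(self):
        ok, p1 = polar_pair_frame(3.4, with_h=False)
        far, p2 = polar_pair_frame(3.6, with_h=False)
        assert len(detect_hbonds(ok, p1, CRIT)) == 1
        assert detect_hbonds(far, p2, CRIT) == []

    def test_clash_distance_rejected(self):
        frame, p = polar_pair_frame(0.3)
        assert detect_hbonds(frame, p, CRIT) == []


class TestHydrophobicRules:
    def test_closest_contact_per_residue_kept(self):
        atoms = [atom(1, "C1", "C", "LIG", 1, "L", [0, 0, 0], Role.LIGAND),
                 atom(2, "CD1", "C", "LEU", 9, "A", [3.8, 0, 0],
                      Role.RECEPTOR_PROTEIN),
                 atom(3, "CD2", "C", "LEU", 9, "A", [0, 3.9, 0],
                      Role.RECEPTOR_PROTEIN)]
        p = Perception(hydrophobic={1, 2, 3})
        hits = detect_hydrophobic(Frame(index=0, time_ps=0.0, atoms=atoms),
                                  p, CRIT)
        assert [h.key for h in hits] == [("hydrophobic", (1,), (2,), None)]
        assert hits[0].metrics["dist"] == pytest.approx(3.8)

    def test_distinct_residues_each_keep_their_contact(self):
        atoms = [atom(1, "C1", "C", "LIG", 1, "L", [0, 0, 0], Role.LIGAND),
                 atom(2, "CD1", "C", "LEU", 9, "A", [3.8, 0, 0],
                      Role.RECEPTOR_PROTEIN),
                 atom(3, "CD1", "C", "LEU", 10, "A", [0, 3.9, 0],
                      Role.RECEPTOR_PROTEIN)]
        p = Perception(hydrophobic={1, 2, 3})
        hits = detect_hydrophobic(Frame(index=0, time_ps=0.0, atoms=atoms),
                                  p, CRIT)
        assert len(hits) == 2


def ring_pair(d, tilt_deg, offset=0.0):
    """Ligand ring at origin; receptor ring at distance d, tilted, offset in-plane."""
    def hexa(center, rot):
        pts = []
        for i in range(6):
            v = np.array([1.39 * math.cos(math.radians(60 * i)),
                          1.39 * math.sin(math.radians(60 * i)), 0.0])
            pts.append(center + rot @ v)
        return pts

    t = math.radians(tilt_deg)
    rot = np.array([[1, 0, 0],
                    [0, math.cos(t), -math.sin(t)],
                    [0, math.sin(t), math.cos(t)]])
    center2 = np.array([offset, 0.0, math.sqrt(max(d * d - offset * offset, 0))])
    atoms, rings = [], []
    serial = 0
    for center, rmat, role, res in (
            (np.zeros(3), np.eye(3), Role.LIGAND, ("LIG", 1, "L")),
            (center2, rot, Role.RECEPTOR_PROTEIN, ("PHE", 9, "A"))):
        members = []
        for xyz in hexa(center, rmat):
            serial += 1
            atoms.append(atom(serial, f"C{serial}", "C", res[0], res[1], res[2],
                              xyz, role))
            members.append(serial)
        normal = rmat @ np.array([0.0, 0.0, 1.0])
        rings.append(Ring(member_serials=tuple(members), centroid=center,
                          normal=normal, role=role))
    frame = Frame(index=0, time_ps=0.0, atoms=atoms)
    return frame, Perception(rings=rings)


class TestPiStackRules:
    @pytest.mark.parametrize("tilt,expected", [
        (0.0, "P"), (90.0, "T"), (45.0, None), (29.0, "P"), (61.0, "T"),
    ])
    def test_angle_classification_with_dead_zone(self, tilt, expected):
        frame, p = ring_pair(4.0, tilt)
        hits = detect_pi_stacks(frame, p, CRIT)
        if expected is None:
            assert hits == []
        else:
            assert len(hits) == 1
            got = "P" if hits[0].metrics["stack_type"] == 0.0 else "T"
            assert got == expected

    def test_offset_beyond_limit_is_silent(self):
        near, p1 = ring_pair(5.0, 0.0, offset=1.9)
        far, p2 = ring_pair(5.0, 0.0, offset=2.3)
        assert len(detect_pi_stacks(near, p1, CRIT)) == 1
        assert detect_pi_stacks(far, p2, CRIT) == []


class TestSaltBridgeRules:
    def _frame(self, d, lig_sign=-1, rcpt_sign=+1):
        a1 = atom(1, "O21", "O", "LIG", 1, "L", [0, 0, 0], Role.LIGAND)
        a2 = atom(2, "NH1", "N", "ARG", 9, "A", [d, 0, 0], Role.RECEPTOR_PROTEIN)
        p = Perception(charged_groups=[
            ChargedGroup(lig_sign, (1,), a1.coords, Role.LIGAND),
            ChargedGroup(rcpt_sign, (2,), a2.coords, Role.RECEPTOR_PROTEIN)])
        return Frame(index=0, time_ps=0.0, atoms=[a1, a2]), p

    def test_opposite_signs_within_cutoff(self):
        frame, p = self._frame(4.0)
        hits = detect_salt_bridges(frame, p, CRIT)
        assert len(hits) == 1
        assert hits[0].metrics["ligand_sign"] == -1.0

    def test_same_sign_never_bridges(self):
        frame, p = self._frame(4.0, lig_sign=+1)
        assert detect_salt_bridges(frame, p, CRIT) == []


class TestWaterBridgeRules:
    def _frame(self, dlw, drw, lig_donor=True):
        atoms = [atom(1, "O40", "O", "LIG", 1, "L", [0, 0, 0], Role.LIGAND),
                 atom(2, "O", "O", "HOH", 50, "W", [dlw, 0, 0], Role.WATER),
                 atom(3, "OG", "O", "SER", 9, "A", [dlw + drw, 0, 0],
                      Role.RECEPTOR_PROTEIN)]
        p = Perception(water_oxygens=[2], has_hydrogens=False)
        if lig_donor:
            p.donors[1] = []
            p.acceptors.add(3)
        else:
            p.acceptors.update({1, 3})  # two acceptors, no donor anywhere
        return Frame(index=0, time_ps=0.0, atoms=atoms), p

    def test_bridge_inside_band(self):
        frame, p = self._frame(2.8, 3.0)
        hits = detect_water_bridges(frame, p, CRIT)
        assert [h.key for h in hits] == [("water_bridge", (1,), (3,), 2)]

    def test_far_water_leg_is_silent(self):
        frame, p = self._frame(2.8, 4.5)
        assert detect_water_bridges(frame, p, CRIT) == []

    def test_requires_donor_acceptor_complementarity(self):
        frame, p = self._frame(2.8, 3.0, lig_donor=False)
        assert detect_water_bridges(frame, p, CRIT) == []


class TestOracleEquivalence:
    """Detectors must equal independent brute-force enumeration exactly."""

    DETECTORS = [
        (detect_hbonds, oracle_hbonds),
        (detect_hydrophobic, oracle_hydrophobic),
        (detect_pi_stacks, oracle_pi_stacks),
        (detect_salt_bridges, oracle_salt_bridges),
        (detect_water_bridges, oracle_water_bridges),
    ]

    @pytest.mark.parametrize("seed", range(30))
    def test_random_micro_systems(self, seed):
        frame, perception = build_oracle_frame(n_atoms=60, box_size=18.0,
                                               seed=seed)
        for detector, oracle in self.DETECTORS:
            got = {h.key for h in detector(frame, perception, CRIT)}
            want = oracle(frame, perception, CRIT)
            assert got == want, detector.__name__

    @pytest.mark.parametrize("seed", [100, 101])
    def test_dense_boxes_and_whole_frame_profile(self, seed):
        frame, perception = build_oracle_frame(n_atoms=150, box_size=14.0,
                                               seed=seed)
        got = {h.key for h in profile_frame(frame, CRIT, perception)}
        assert got == oracle_all(frame, perception, CRIT)


class TestDeterminism:
    def test_atom_record_order_is_irrelevant(self):
        frames, _ = build_frames(one_of_each_schedule(1), 1)
        frame = frames[0]
        from trajcontacts.structure_io import LigandSelection, assign_roles
        sel = LigandSelection.parse("LIG")
        base = [h.key for h in profile_frame(assign_roles(frame, sel))]
        shuffled = Frame(index=0, time_ps=0.0, atoms=list(reversed(frame.atoms)),
                         bonds=frame.bonds)
        assert [h.key for h in profile_frame(assign_roles(shuffled, sel))] == base

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rigid_motion_invariance(self, seed):
        """A global rotation+translation preserves every detection."""
        frame, perception = build_oracle_frame(n_atoms=60, seed=seed)
        base = {h.key for h in profile_frame(frame, CRIT, perception)}

        rng = np.random.default_rng(seed + 7)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-20, 20, size=3)
        moved_atoms = [
            Atom(serial=a.serial, name=a.name, element=a.element,
                 residue_name=a.residue_name, residue_number=a.residue_number,
                 chain_id=a.chain_id, coords=q @ a.coords + shift,
                 role=a.role, is_hetatm=a.is_hetatm)
            for a in frame.atoms
        ]
        moved = Frame(index=0, time_ps=0.0, atoms=moved_atoms)
        moved_p = Perception(
            donors=perception.donors, acceptors=perception.acceptors,
            hydrophobic=perception.hydrophobic,
            rings=[Ring(r.member_serials, q @ r.centroid + shift,
                        q @ r.normal, r.role) for r in perception.rings],
            charged_groups=[ChargedGroup(g.charge_sign, g.member_serials,
                                         q @ g.center + shift, g.role)
                            for g in perception.charged_groups],
            water_oxygens=perception.water_oxygens,
            has_hydrogens=perception.has_hydrogens,
        )
        assert {h.key for h in profile_frame(moved, CRIT, moved_p)} == base

    def test_no_receptor_means_no_interactions(self):
        atoms = [atom(1, "O1", "O", "LIG", 1, "L", [0, 0, 0], Role.LIGAND)]
        p = Perception(donors={1: []}, acceptors={1})
        assert profile_frame(Frame(index=0, time_ps=0.0, atoms=atoms),
                             CRIT, p) == []
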