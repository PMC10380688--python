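"""Multi-model PDB parsing, timestamping, role partition and round-trips."""

import numpy as np
import pytest

from trajcontacts.structure_io import (
    Atom, Frame, LigandSelection, PdbTrajectory, Role,
    AmbiguousSelectionError, EmptyLigandError, PDBParseError,
    TopologyMismatchError, assign_roles, read_multimodel_pdb,
    write_frame_pdb, write_multimodel_pdb,
)

HB = "HETATM"


def _pdb_line(serial, name, resname, chain, resnum, x, y, z, element,
              record="ATOM  ", altloc=" "):
    nm = (" " + name).ljust(4) if len(name) < 4 and len(element) == 1 else name.ljust(4)
    return (f"{record}{serial:>5d} {nm}{altloc}{resname:<4.4s}{chain}{resnum:>4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")


def _model(n, lines):
    return [f"MODEL     {n:>4d}"] + lines + ["ENDMDL"]


def write_text(tmp_path, lines, name="t.pdb"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReading:
    def test_single_model_gets_time_zero(self, tmp_path):
        p = write_text(tmp_path, [_pdb_line(1, "CA", "ALA", "A", 1, 1, 2, 3, "C")])
        frames = read_multimodel_pdb(p, t_start=0, dt=10)
        assert len(frames) == 1
        assert frames[0].time_ps == 0
        a = frames[0].atoms[0]
        assert (a.serial, a.name, a.residue_name) == (1, "CA", "ALA")
        assert np.allclose(a.coords, [1, 2, 3])

    def test_three_models_timestamped_from_t_start(self, tmp_path):
        lines = []
        for m in range(3):
            lines += _model(m + 1, [_pdb_line(1, "CA", "ALA", "A", 1, m, 0, 0, "C")])
        frames = read_multimodel_pdb(write_text(tmp_path, lines),
                                     t_start=100, dt=10)
        assert [f.time_ps for f in frames] == [100, 110, 120]
        assert [f.index for f in frames] == [0, 1, 2]

    def test_title_t_record_overrides_arithmetic_time(self, tmp_path):
        lines = ["TITLE     frame t= 3500.000"]
        lines += _model(1, [_pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C")])
        lines += ["TITLE     frame t= 3510.000"]
        lines += _model(2, [_pdb_line(1, "CA", "ALA", "A", 1, 1, 0, 0, "C")])
        frames = read_multimodel_pdb(write_text(tmp_path, lines))
        assert [f.time_ps for f in frames] == [3500.0, 3510.0]

    def test_missing_atom_in_model_is_topology_mismatch(self, tmp_path):
        full = [_pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
                _pdb_line(2, "CB", "ALA", "A", 1, 1, 0, 0, "C")]
        lines = _model(1, full) + _model(2, full[:1])
        with pytest.raises(TopologyMismatchError, match="model 2"):
            read_multimodel_pdb(write_text(tmp_path, lines))

    def test_malformed_coordinates_name_the_line(self, tmp_path):
        bad = _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C")
        bad = bad[:32] + "xxxxxx" + bad[38:]
        p = write_text(tmp_path, [_pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C")])
        p2 = write_text(tmp_path, [bad], name="bad.pdb")
        read_multimodel_pdb(p)  # sane control
        with pytest.raises(PDBParseError, match="line 1"):
            read_multimodel_pdb(p2)

    def test_altloc_b_records_are_dropped(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C", altloc="A"),
            _pdb_line(2, "CA", "ALA", "A", 1, 9, 9, 9, "C", altloc="B"),
        ]
        frames = read_multimodel_pdb(write_text(tmp_path, lines))
        assert [a.serial for a in frames[0].atoms] == [1]

    def test_hetatm_ingested_and_flagged(self, tmp_path):
        p = write_text(tmp_path,
                       [_pdb_line(1, "C1", "LIG", "L", 1, 0, 0, 0, "C",
                                  record=HB)])
        assert read_multimodel_pdb(p)[0].atoms[0].is_hetatm


class TestRoles:
    def _frame(self):
        def at(serial, name, elem, res, chain, num):
            return Atom(serial=serial, name=name, element=elem,
                        residue_name=res, residue_number=num, chain_id=chain,
                        coords=np.zeros(3))
        atoms = [at(1, "C1", "C", "CPT", "L", 1)]
        atoms += [at(10 + i, n, n[0], "ALA", "A", 5) for i, n in
                  enumerate(["N", "CA", "C", "O", "CB"])]
        atoms += [at(20 + i, "O", "O", "HOH", "W", 100 + i) for i in range(3)]
        atoms += [at(30, "NA", "Na", "NA", " ", 200)]
        atoms += [at(31, "N1", "N", "DA", "B", 7)]
        return Frame(index=0, time_ps=0.0, atoms=atoms)

    def test_partition_is_exhaustive_and_exclusive(self):
        fr = assign_roles(self._frame(), LigandSelection.parse("CPT"))
        roles = [a.role for a in fr.atoms]
        assert roles.count(Role.LIGAND) == 1
        assert roles.count(Role.RECEPTOR_PROTEIN) == 5
        assert roles.count(Role.WATER) == 3
        assert roles.count(Role.ION) == 1
        assert roles.count(Role.RECEPTOR_NUCLEIC) == 1
        assert all(isinstance(r, Role) for r in roles)

    def test_absent_selection_is_empty_ligand_error(self):
        with pytest.raises(EmptyLigandError):
            assign_roles(self._frame(), LigandSelection.parse("XYZ"))

    def test_resnum_selection_spanning_two_residues_is_ambiguous(self):
        fr = self._frame()
        # two HOH residues share resnum nowhere; force ambiguity via resname
        sel = LigandSelection(frozenset({"HOH"}), residue_number=None)
        assign_roles(fr, sel)  # fine without resnum
        fr2 = Frame(index=0, time_ps=0.0, atoms=[
            Atom(serial=1, name="C1", element="C", residue_name="LIG",
                 residue_number=1, chain_id="L", coords=np.zeros(3)),
            Atom(serial=2, name="C1", element="C", residue_name="LIG",
                 residue_number=1, chain_id="M", coords=np.zeros(3)),
        ])
        with pytest.raises(AmbiguousSelectionError):
            assign_roles(fr2, LigandSelection(frozenset({"LIG"}),
                                              residue_number=1))

    def test_selection_parse_roundtrip(self):
        sel = LigandSelection.parse("LIG:L:1")
        assert sel.residue_names == frozenset({"LIG"})
        assert sel.chain_id == "L" and sel.residue_number == 1


class TestRoundTrip:
    def test_write_read_identity_at_pdb_precision(self, tmp_path, tiny_traj):
        path, _ = tiny_traj
        frames = read_multimodel_pdb(path)
        out = tmp_path / "one.pdb"
        write_frame_pdb(frames[0], out)
        back = read_multimodel_pdb(out)[0]
        assert back.serials == frames[0].serials
        for a, b in zip(frames[0].atoms, back.atoms):
            assert (a.serial, a.name, a.element, a.residue_id) == \
                   (b.serial, b.name, b.element, b.residue_id)
            assert np.allclose(a.coords, b.coords, atol=5e-4)

    def test_coordinates_written_to_three_decimals(self, tmp_path):
        a = Atom(serial=1, name="C1", element="C", residue_name="LIG",
                 residue_number=1, chain_id="L",
                 coords=np.array([1.23456, 0.0, 0.0]))
        fr = Frame(index=0, time_ps=0.0, atoms=[a])
        out = tmp_path / "p.pdb"
        write_frame_pdb(fr, out)
        back = read_multimodel_pdb(out)[0].atoms[0]
        assert back.coords[0] == pytest.approx(1.235, abs=1e-9)

    def test_empty_frame_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_frame_pdb(Frame(index=0, time_ps=0.0, atoms=[]),
                            tmp_path / "x.pdb")

    def test_conect_round_trip(self, tmp_path, tiny_traj):
        path, _ = tiny_traj
        frames = read_multimodel_pdb(path)
        assert frames[0].bonds  # fixture has ligand bonds
        out = tmp_path / "rt.pdb"
        write_multimodel_pdb(frames, out)
        assert read_multimodel_pdb(out)[0].bonds == frames[0].bonds

    def test_timestamp_span_matches_frame_count(self, tiny_traj):
        path, manifest = tiny_traj
        frames = read_multimodel_pdb(path)
        dt = manifest["dt"]
        assert frames[-1].time_ps - frames[0].time_ps == \
            pytest.approx((len(frames) - 1) * dt)


class TestLazyTrajectory:
    def test_chunked_reads_match_full_read(self, tiny_traj):
        path, _ = tiny_traj
        full = read_multimodel_pdb(path)
        lazy = PdbTrajectory(path)
        assert len(lazy) == len(full)
        chunk = lazy.read_frames(2, 4)
        assert [f.index for f in chunk] == [2, 3]
        for a, b in zip(chunk[0].atoms, full[2].atoms):
            assert a.serial == b.serial
            assert np.allclose(a.coords, b.coords)
        assert lazy.bonds == full[0].bonds
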