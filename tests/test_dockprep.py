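import math

import numpy as np
import pytest

from oryzapep.dockprep import (
    ANTIADIPOGENIC_HOTSPOTS,
    DEFAULT_GRIDBOX,
    AtomRecord,
    GridBox,
    HotspotSet,
    contact_residues,
    detect_hbonds,
    make_gridbox_config,
    parse_docking_log,
    parse_gridbox_config,
    parse_pdb,
    write_pdb,
)
from oryzapep.synthdata import make_planted_geometry

VINA_LOG = """\
Detected 4 CPUs
Refining results ... done.

mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1         -7.98      0.000      0.000
   2         -7.10      1.922      3.001
   3         -6.55      2.508      4.612
"""


def atom(serial, name, resname, resnum, x, y, z, element, **kw):
    return AtomRecord(
        serial=serial, atom_name=name, residue_name=resname, chain="A",
        residue_number=resnum, x=x, y=y, z=z, element=element, **kw
    )


class TestPdbIO:
    def test_three_atom_parse(self, tmp_path):
        atoms = [
            atom(1, "N", "CYS", 285, 1.234, -2.5, 0.001, "N"),
            atom(2, "CA", "CYS", 285, 2.0, -1.4, 0.5, "C"),
            atom(3, "O", "CYS", 285, 3.125, 0.0, -0.75, "O"),
        ]
        p = tmp_path / "mini.pdb"
        write_pdb(atoms, p)
        back = parse_pdb(p)
        assert [(a.serial, a.atom_name, a.x) for a in back] == [
            (1, "N", 1.234), (2, "CA", 2.0), (3, "O", 3.125)
        ]

    def test_second_model_ignored_with_warning(self, tmp_path, caplog):
        p = tmp_path / "two_models.pdb"
        p.write_text(
            "MODEL        1\n"
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      2  N   GLY A   1       9.000   9.000   9.000  1.00  0.00           N\n"
            "ENDMDL\n"
        )
        with caplog.at_level("WARNING"):
            atoms = parse_pdb(p)
        assert len(atoms) == 1 and atoms[0].x == 0.0
        assert any("MODEL" in r.message for r in caplog.records)

    def test_round_trip_preserves_coordinates_to_pdb_precision(self, tmp_path, rng):
        atoms = [
            atom(i + 1, "O", "SER", 289, rng.uniform(-99, 99), rng.uniform(-99, 99),
                 rng.uniform(-99, 99), "O")
            for i in range(10)
        ]
        p = tmp_path / "rt.pdb"
        write_pdb(atoms, p)
        back = parse_pdb(p)
        for a, b in zip(atoms, back):
            assert (b.x, b.y, b.z) == pytest.approx((a.x, a.y, a.z), abs=5e-4)

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   1      bogus:   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(ValueError, match=":2:"):
            parse_pdb(p)

    def test_agrees_with_biopython_parser(self, tmp_path):
        """Independent cross-check: Biopython reads our emitted fixed
        columns to the same coordinates and residue numbering."""
        Bio = pytest.importorskip("Bio.PDB")
        geom = make_planted_geometry(2, seed=11)
        p = tmp_path / "rec.pdb"
        write_pdb(geom.receptor, p)
        structure = Bio.PDBParser(QUIET=True).get_structure("x", str(p))
        ours = {(a.residue_number, a.atom_name): (a.x, a.y, a.z) for a in geom.receptor}
        theirs = {
            (res.id[1], at.get_name()): tuple(at.coord)
            for res in structure.get_residues() for at in res
        }
        assert set(ours) == set(theirs)
        for key in ours:
            assert ours[key] == pytest.approx(theirs[key], abs=5e-4)


class TestGridBox:
    def test_default_box_extents(self):
        assert DEFAULT_GRIDBOX.extent_angstrom == pytest.approx((26.25, 15.0, 15.0))
        text = make_gridbox_config()
        assert "size_x = 26.25" in text and "size_y = 15" in text

    def test_unit_spacing(self):
        box = GridBox(0, 0, 0, 10, 10, 10, 1.0)
        assert box.extent_angstrom == (10.0, 10.0, 10.0)

    def test_config_round_trip(self):
        assert parse_gridbox_config(make_gridbox_config(DEFAULT_GRIDBOX)) == DEFAULT_GRIDBOX

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            GridBox(0, 0, 0, 0, 10, 10, 0.375)


class TestDockingLog:
    def test_best_mode_first(self):
        pairs = parse_docking_log(VINA_LOG)
        assert pairs[0] == (1, -7.98) and len(pairs) == 3

    def test_empty_text_is_an_error(self):
        with pytest.raises(ValueError):
            parse_docking_log("")

    def test_nine_mode_block(self):
        body = "mode |   affinity | dist\n-----+------------+-----\n"
        body += "".join(f"{i:>4d}      {-8 + i * 0.5:7.2f}    0.0    0.0\n" for i in range(1, 10))
        pairs = parse_docking_log(body)
        assert [r for r, _ in pairs] == list(range(1, 10))


class TestHbondDetection:
    def test_planted_bond_recovered(self):
        geom = make_planted_geometry(1, seed=3)
        bonds = detect_hbonds(list(geom.ligand), list(geom.receptor))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-6)
        assert bonds[0].angle == pytest.approx(160.0, abs=1e-5)

    def test_beyond_cutoff_is_empty(self):
        donor = [atom(1, "N1", "LIG", 1, 5.0, 0, 0, "N", hetatm=True),
                 atom(2, "H1", "LIG", 1, 4.0, 0, 0, "H", hetatm=True)]
        acceptor = [atom(3, "O", "CYS", 285, 0, 0, 0, "O")]
        assert detect_hbonds(donor, acceptor) == []

    def test_rigid_motion_invariance(self):
        geom0 = make_planted_geometry(3, seed=5)
        bonds0 = detect_hbonds(list(geom0.ligand), list(geom0.receptor))
        rng = np.random.default_rng(99)
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q *= np.sign(np.diag(r))
        shift = rng.uniform(-30, 30, 3)

        def move(a):
            p = q @ a.coords + shift
            return AtomRecord(
                serial=a.serial, atom_name=a.atom_name, residue_name=a.residue_name,
                chain=a.chain, residue_number=a.residue_number,
                x=p[0], y=p[1], z=p[2], element=a.element, hetatm=a.hetatm,
            )

        bonds1 = detect_hbonds([move(a) for a in geom0.ligand],
                               [move(a) for a in geom0.receptor])
        assert len(bonds0) == len(bonds1)
        for b0, b1 in zip(bonds0, bonds1):
            assert b1.distance == pytest.approx(b0.distance, abs=1e-6)
            assert (b1.donor.serial, b1.acceptor.serial) == (b0.donor.serial, b0.acceptor.serial)

    def test_role_swap_symmetry(self):
        geom = make_planted_geometry(2, seed=13)
        fwd = detect_hbonds(list(geom.ligand), list(geom.receptor))
        rev = detect_hbonds(list(geom.receptor), list(geom.ligand))
        pairs = lambda bonds: {
            frozenset([(b.donor.serial, b.donor.residue_name),
                       (b.acceptor.serial, b.acceptor.residue_name)])
            for b in bonds
        }
        assert pairs(fwd) == pairs(rev)

    def test_empty_atom_list_rejected(self):
        with pytest.raises(ValueError):
            detect_hbonds([], [atom(1, "O", "CYS", 285, 0, 0, 0, "O")])


class TestContactReport:
    def _bond_to(self, resname, resnum):
        acc = atom(1, "O", resname, resnum, 0, 0, 0, "O")
        don = atom(2, "N1", "LIG", 1, 2.9, 0, 0, "N", hetatm=True)
        return detect_hbonds([don], [acc])

    def test_hotspot_intersection(self):
        bonds = self._bond_to("CYS", 285) + self._bond_to("SER", 289)
        report = contact_residues(bonds)
        assert set(report.hotspot_contacts) == {("CYS", 285), ("SER", 289)}
        assert report.non_hotspot_contacts == ()

    def test_non_hotspot_contact_flagged_not_dropped(self):
        # the activation-helix tyrosine lies outside the antiadipogenic set
        report = contact_residues(self._bond_to("TYR", 473))
        assert report.hotspot_contacts == ()
        assert report.non_hotspot_contacts == (("TYR", 473),)
        assert ("TYR", 473) in report.contacted

    def test_no_bonds(self):
        report = contact_residues([])
        assert report.contacted == () and report.hbonds == ()

    def test_intersection_is_subset_of_contacts(self):
        geom = make_planted_geometry(4, seed=21)
        bonds = detect_hbonds(list(geom.ligand), list(geom.receptor))
        report = contact_residues(bonds)
        assert set(report.hotspot_contacts) <= set(report.contacted)

    def test_hotspot_set_invariants(self):
        assert ("CYS", 285) in ANTIADIPOGENIC_HOTSPOTS
        assert len(ANTIADIPOGENIC_HOTSPOTS.residues) == 8
        with pytest.raises(ValueError):
            HotspotSet(residues=())
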