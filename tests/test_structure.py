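"""Structure parsing, donor/acceptor enumeration and H-bond detection."""

import math

import numpy as np
import pytest

from rbind.structure import (Atom, HBondCriteria, PDBParseError, Residue,
                             Structure, detect_hbonds, donor_acceptor_sites,
                             label_binding, parse_pdb, place_hydrogen)
from rbind.synth import ComplexSpec, PlantedBond, synth_complex

from conftest import brute_force_hbond_keys, random_complex_spec


def _pdb_line(serial, name, resname, chain, resseq, x, y, z,
              altloc=" ", occ=1.0, element=None):
    element = element or name[0]
    return (f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


TWO_RESIDUE_PDB = "\n".join([
    _pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
    _pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, element="C"),
    _pdb_line(3, "P", "A", "B", 1, 10.0, 0.0, 0.0),
    _pdb_line(4, "OP1", "A", "B", 1, 11.5, 0.0, 0.0, element="O"),
]) + "\n"


class TestParsePdb:
    def test_minimal_two_chain_complex(self):
        s = parse_pdb(TWO_RESIDUE_PDB)
        assert s.chain_ids == ["A", "B"]
        assert s.chain("A")[0].polymer == "protein"
        assert s.chain("B")[0].polymer == "rna"
        assert s.chain("A")[0].code == "A" and s.chain("B")[0].code == "A"

    def test_altloc_keeps_highest_occupancy(self):
        text = "\n".join([
            _pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.6),
            _pdb_line(2, "N", "ALA", "A", 1, 5.0, 0.0, 0.0, altloc="B", occ=0.4),
        ])
        res = parse_pdb(text).chain("A")[0]
        assert len(res.atoms) == 1
        assert res.atoms[0].altloc == "A"
        assert res.atoms[0].coords[0] == 0.0

    def test_altloc_occupancy_tie_prefers_a(self):
        text = "\n".join([
            _pdb_line(1, "N", "ALA", "A", 1, 5.0, 0.0, 0.0, altloc="B", occ=0.5),
            _pdb_line(2, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.5),
        ])
        assert parse_pdb(text).chain("A")[0].atoms[0].altloc == "A"

    def test_modified_residue_typed_other_and_excluded(self):
        text = TWO_RESIDUE_PDB + _pdb_line(5, "N1", "5MU", "B", 2, 50.0, 0.0, 0.0,
                                           element="N")
        s = parse_pdb(text)
        assert s.chain("B")[1].polymer == "other"
        pair = label_binding(s, "A", "B")
        assert pair.rna_seq == "A"  # the modified nucleotide is not in the sequence

    def test_legacy_atom_names_canonicalised(self):
        text = _pdb_line(1, "O1P", "A", "B", 1, 0.0, 0.0, 0.0, element="O")
        text = text.replace("O1P", "O1P")  # explicit legacy spelling
        res = parse_pdb(text).chain("B")[0]
        assert res.atoms[0].name == "OP1"

    def test_malformed_record_names_line(self):
        bad = TWO_RESIDUE_PDB + "ATOM      9  N   ALA A   2    badcoordinates\n"
        with pytest.raises(PDBParseError, match="line 5"):
            parse_pdb(bad)

    def test_empty_input_rejected(self):
        with pytest.raises(PDBParseError):
            parse_pdb("")
        with pytest.raises(PDBParseError):
            parse_pdb("HEADER    NOTHING\nEND\n")

    def test_only_first_model_parsed(self):
        text = ("MODEL        1\n" + TWO_RESIDUE_PDB + "ENDMDL\n"
                + "MODEL        2\n"
                + _pdb_line(9, "N", "GLY", "C", 1, 0.0, 0.0, 0.0) + "\nENDMDL\n")
        assert parse_pdb(text).chain_ids == ["A", "B"]

    def test_biopython_agrees_on_atom_inventory(self, tmp_path):
        """Independent cross-check of the fixed-column reader against Bio.PDB."""
        Bio = pytest.importorskip("Bio.PDB")
        pdb_text, _ = synth_complex(ComplexSpec(
            seed=3, n_protein_residues=8, n_rna_nucleotides=6,
            planted_bonds=(PlantedBond(2, 1, 3.0), PlantedBond(5, 4, 2.9))))
        path = tmp_path / "toy.pdb"
        path.write_text(pdb_text)
        ours = parse_pdb(pdb_text)
        theirs = Bio.PDBParser(QUIET=True).get_structure("toy", str(path))
        ref = sorted((a.get_parent().get_parent().id, a.get_parent().id[1],
                      a.get_name(), *(round(float(x), 3) for x in a.get_coord()))
                     for a in theirs.get_atoms())
        got = sorted((cid, r.number, a.name, *(round(float(x), 3) for x in a.coords))
                     for cid, residues in ours.chains
                     for r in residues for a in r.atoms)
        assert got == ref


class TestDonorAcceptorSites:
    def _residue(self, name, polymer, atom_names):
        atoms = [Atom(name=n, element=n[0], coords=(float(i), 0.0, 0.0))
                 for i, n in enumerate(atom_names)]
        return Residue(chain_id="A", number=1, icode="", name=name,
                       polymer=polymer, atoms=atoms)

    def test_adenosine_acceptors_include_all_backbone_oxygens(self):
        res = self._residue("A", "rna",
                            ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                             "C3'", "O3'", "C2'", "O2'", "C1'", "N9", "C8",
                             "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"])
        donors, acceptors = donor_acceptor_sites(res)
        acc_names = {a.name for a, _ in acceptors}
        assert {"OP1", "OP2", "O2'", "O3'", "O4'", "O5'"} <= acc_names
        assert {"N1", "N3", "N7"} <= acc_names
        assert {d.name for d, _ in donors} == {"N6", "O2'", "O3'"}

    def test_glycine_backbone_only(self):
        res = self._residue("GLY", "protein", ["N", "CA", "C", "O"])
        donors, acceptors = donor_acceptor_sites(res)
        assert [d.name for d, _ in donors] == ["N"]
        assert [a.name for a, _ in acceptors] == ["O"]

    def test_arginine_guanidinium_donors(self):
        res = self._residue("ARG", "protein",
                            ["N", "CA", "C", "O", "CB", "CG", "CD",
                             "NE", "CZ", "NH1", "NH2"])
        donors, _ = donor_acceptor_sites(res)
        assert {"NE", "NH1", "NH2"} <= {d.name for d, _ in donors}

    def test_proline_backbone_nitrogen_not_a_donor(self):
        res = self._residue("PRO", "protein", ["N", "CA", "C", "O"])
        donors, _ = donor_acceptor_sites(res)
        assert donors == []

    def test_unknown_residue_warns_and_returns_empty(self):
        res = self._residue("XYZ", "protein", ["N", "O"])
        with pytest.warns(UserWarning):
            donors, acceptors = donor_acceptor_sites(res)
        assert donors == [] and acceptors == []


class TestPlaceHydrogen:
    def test_toward_acceptor_unit_vector(self):
        d = Atom("N", "N", (0, 0, 0))
        a = Atom("O", "O", (3, 0, 0))
        assert np.allclose(place_hydrogen(d, None, a, "toward_acceptor"), (1, 0, 0))

    def test_explicit_returns_deposited_hydrogen(self):
        d = Atom("N", "N", (0, 0, 0))
        h = Atom("H", "H", (0.95, 0.1, 0.0))
        a = Atom("O", "O", (3, 0, 0))
        res = Residue("A", 1, "", "ALA", "protein", atoms=[d, h])
        assert np.allclose(place_hydrogen(d, None, a, "explicit", residue=res),
                           (0.95, 0.1, 0.0))

    def test_explicit_without_hydrogen_instructs_fallback(self):
        d = Atom("N", "N", (0, 0, 0))
        a = Atom("O", "O", (3, 0, 0))
        res = Residue("A", 1, "", "ALA", "protein", atoms=[d])
        with pytest.raises(ValueError, match="toward_acceptor"):
            place_hydrogen(d, None, a, "explicit", residue=res)

    def test_coincident_donor_acceptor_rejected(self):
        d = Atom("N", "N", (1, 1, 1))
        a = Atom("O", "O", (1, 1, 1))
        with pytest.raises(ValueError):
            place_hydrogen(d, None, a, "toward_acceptor")


def _hand_structure(acceptor_xyz, aa_xyz, h_xyz=(1.0, 0.0, 0.0)):
    """One protein N-H donor vs one RNA OP1 acceptor at given coordinates."""
    prot = Residue("A", 1, "", "GLY", "protein", atoms=[
        Atom("N", "N", (0, 0, 0)), Atom("H", "H", h_xyz),
        Atom("CA", "C", (-1.5, 0, 0))])
    rna = Residue("B", 1, "", "U", "rna", atoms=[
        Atom("OP1", "O", acceptor_xyz), Atom("P", "P", aa_xyz)])
    return Structure("hand", [("A", [prot]), ("B", [rna])])


class TestDetectHbonds:
    def test_hand_geometry_accepted_with_measurements(self):
        s = _hand_structure((2.8, 0, 0), (3.5, 1.0, 0))
        bonds = detect_hbonds(s, "A", "B", mode="explicit")
        assert len(bonds) == 1
        b = bonds[0]
        assert b.d_da == pytest.approx(2.8)
        assert b.d_ha == pytest.approx(1.8)
        assert b.ang_dha == pytest.approx(180.0)
        assert b.ang_haaa == pytest.approx(125.0, abs=0.05)
        assert b.d_proj == pytest.approx(1.8)

    def test_distance_at_threshold_rejected(self):
        s = _hand_structure((4.0, 0, 0), (4.7, 1.0, 0))
        assert detect_hbonds(s, "A", "B", mode="explicit") == []

    def test_dha_angle_below_threshold_rejected(self):
        # planted geometry with D-H-A = 85 deg; both distances satisfy their
        # thresholds (d_DA = 2.5, d_HA ~ 2.38) so only the angle can reject
        bond = PlantedBond(1, 1, d_da=2.5, ang_dha=85.0, ang_haaa=130.0)
        d_da, d_ha, _ = bond.geometry()
        assert d_da < 3.9 and d_ha < 2.5
        pdb_text, labels = synth_complex(ComplexSpec(
            seed=9, n_protein_residues=2, n_rna_nucleotides=2,
            planted_bonds=(bond,)))
        s = parse_pdb(pdb_text)
        assert detect_hbonds(s, "A", "B", mode="explicit") == []
        assert labels == [-1, -1]

    def test_missing_chain_raises(self):
        s = _hand_structure((2.8, 0, 0), (3.5, 1.0, 0))
        with pytest.raises(KeyError):
            detect_hbonds(s, "A", "Z")

    def test_all_emitted_bonds_satisfy_strict_criteria(self):
        crit = HBondCriteria()
        for seed in range(5):
            pdb_text, _ = synth_complex(random_complex_spec(seed))
            s = parse_pdb(pdb_text)
            for b in detect_hbonds(s, "A", "B", crit, mode="explicit"):
                assert b.d_da < crit.d_da_max
                assert b.d_ha < crit.d_ha_max
                assert b.ang_dha > crit.ang_dha_min
                assert b.ang_haaa > crit.ang_haaa_min
                assert b.d_proj > 0
                assert b.d_da >= b.d_ha - 1.2

    def test_rigid_motion_invariance(self):
        pdb_text, _ = synth_complex(random_complex_spec(17))
        s = parse_pdb(pdb_text)
        ref = {(b.donor_residue.number, b.donor.name,
                b.acceptor_residue.number, b.acceptor.name)
               for b in detect_hbonds(s, "A", "B", mode="explicit")}
        # rotate 60 deg about z and translate
        th = math.radians(60)
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        shift = np.array([7.0, -3.0, 11.0])
        for _, residues in s.chains:
            for r in residues:
                for a in r.atoms:
                    a.coords = rot @ a.coords + shift
        moved = {(b.donor_residue.number, b.donor.name,
                  b.acceptor_residue.number, b.acceptor.name)
                 for b in detect_hbonds(s, "A", "B", mode="explicit")}
        assert moved == ref

    def test_tighter_distance_threshold_yields_subset(self):
        pdb_text, _ = synth_complex(random_complex_spec(23))
        s = parse_pdb(pdb_text)
        loose = {(b.donor_residue.number, b.acceptor_residue.number)
                 for b in detect_hbonds(s, "A", "B", HBondCriteria(), "explicit")}
        tight = {(b.donor_residue.number, b.acceptor_residue.number)
                 for b in detect_hbonds(s, "A", "B",
                                        HBondCriteria(d_da_max=3.0), "explicit")}
        assert tight <= loose

    def test_matches_brute_force_scan(self):
        crit = HBondCriteria()
        for seed in range(40, 50):
            pdb_text, _ = synth_complex(random_complex_spec(seed))
            s = parse_pdb(pdb_text)
            got = {(b.donor_residue.number, b.donor.name,
                    b.acceptor_residue.number, b.acceptor.name)
                   for b in detect_hbonds(s, "A", "B", crit, "explicit")}
            assert got == brute_force_hbond_keys(s, "A", "B", crit)


class TestLabelBinding:
    def test_planted_residues_recovered(self):
        spec = ComplexSpec(seed=5, n_protein_residues=12, n_rna_nucleotides=10,
                           planted_bonds=(PlantedBond(2, 1, 3.0),
                                          PlantedBond(5, 3, 2.9),
                                          PlantedBond(9, 7, 3.2)))
        pdb_text, labels = synth_complex(spec)
        pair = label_binding(parse_pdb(pdb_text), "A", "B", mode="explicit")
        assert pair.labels == labels
        assert [i for i, l in enumerate(pair.labels, 1) if l == 1] == [2, 5, 9]

    def test_no_contacts_all_negative(self):
        pdb_text, _ = synth_complex(ComplexSpec(seed=6, n_protein_residues=5,
                                                n_rna_nucleotides=4))
        pair = label_binding(parse_pdb(pdb_text), "A", "B", mode="explicit")
        assert all(l == -1 for l in pair.labels)
        assert pair.contacts == []

    def test_two_bonds_one_label_two_contacts(self):
        spec = ComplexSpec(seed=7, n_protein_residues=6, n_rna_nucleotides=5,
                           planted_bonds=(PlantedBond(3, 1, 3.0),
                                          PlantedBond(3, 2, 2.9)))
        pdb_text, _ = synth_complex(spec)
        pair = label_binding(parse_pdb(pdb_text), "A", "B", mode="explicit")
        assert pair.labels[2] == 1 and sum(1 for l in pair.labels if l == 1) == 1
        assert len([c for c in pair.contacts if c[0] == 3]) == 2

    def test_label_iff_contact_and_length_matches(self):
        for seed in range(60, 66):
            pdb_text, _ = synth_complex(random_complex_spec(seed))
            pair = label_binding(parse_pdb(pdb_text), "A", "B", mode="explicit")
            assert len(pair.labels) == len(pair.protein_seq)
            bound = {i for i, _, _ in pair.contacts}
            for i, lab in enumerate(pair.labels, 1):
                assert (lab == 1) == (i in bound)
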