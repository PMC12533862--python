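"""Structure/series IO: parsing, round trips, bond perception, unit handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ALANINE_PDB, ETHANOL_MOL2, ETHANOL_SDF
from docktriage.errors import FormatError, UnknownElementError
from docktriage.struct_io import (
    AtomRecord,
    ResidueKey,
    RmsdSeries,
    perceive_bonds,
    read_ligand,
    read_receptor,
    read_rmsd_series,
    write_mol2,
    write_receptor,
)
from docktriage.synthetic import make_pocket_fixture


class TestReadReceptor:
    def test_single_residue_pdb(self):
        rec = read_receptor(ALANINE_PDB)
        assert len(rec.residues) == 1
        assert len(rec.atoms) == 5
        key = rec.residues[0]
        assert (key.chain, key.number, key.name) == ("A", 1, "ALA")

    def test_hetatm_records_kept_separate(self):
        text = ALANINE_PDB.replace("END\n", "") + (
            "HETATM    6  C1  LIG A 999       1.000   2.000   3.000  1.00  0.00           C\n"
            "END\n"
        )
        rec = read_receptor(text)
        assert len(rec.atoms) == 5
        assert list(rec.het_groups) == [ResidueKey("A", 999, "", "LIG")]

    def test_no_atom_records_is_format_error(self):
        with pytest.raises(FormatError):
            read_receptor("HEADER    NOTHING HERE\nEND\n")

    def test_bad_coordinate_names_line_number(self):
        bad = ALANINE_PDB.replace("11.639", "xx.639")
        with pytest.raises(FormatError, match="line 2"):
            read_receptor(bad)

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60  0.00           C\n"
            "END\n"
        )
        rec = read_receptor(text)
        assert len(rec.atoms) == 1
        assert rec.atoms[0].coords[0] == pytest.approx(9.0)

    def test_altloc_tie_prefers_a(self):
        text = (
            "ATOM      1  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C\n"
            "ATOM      2  CA AALA A   1       0.000   1.000   2.000  0.50  0.00           C\n"
            "END\n"
        )
        rec = read_receptor(text)
        assert rec.atoms[0].coords[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_write_read_round_trip(self, seed):
        rec_text, _ = make_pocket_fixture(5, 2, 3, seed=seed).artifact
        rec = read_receptor(rec_text)
        again = read_receptor(write_receptor(rec))
        assert [a.residue_key for a in again.atoms] == [a.residue_key for a in rec.atoms]
        for a, b in zip(rec.atoms, again.atoms):
            assert np.allclose(a.coords, b.coords, atol=5e-4)


class TestReadLigand:
    def test_sdf_ethanol(self):
        g = read_ligand(ETHANOL_SDF)
        assert g.n_atoms == 3
        assert g.bonds == {(0, 1), (1, 2)}

    def test_mol2_and_sdf_give_identical_graphs(self):
        a = read_ligand(ETHANOL_MOL2)
        b = read_ligand(ETHANOL_SDF)
        assert [x.element for x in a.atoms] == [x.element for x in b.atoms]
        assert a.bonds == b.bonds
        assert np.allclose(a.coords, b.coords)

    def test_mol2_round_trip(self):
        g = read_ligand(ETHANOL_SDF)
        again = read_ligand(write_mol2(g))
        assert again.bonds == g.bonds
        assert np.allclose(again.coords, g.coords, atol=1e-4)

    def test_zero_atom_record_is_error(self):
        with pytest.raises(FormatError):
            read_ligand("")

    def test_garbage_is_error(self):
        with pytest.raises(FormatError):
            read_ligand("not a molecule at all")

    def test_multi_record_sdf_takes_first_with_warning(self):
        with pytest.warns(UserWarning, match="taking the first"):
            g = read_ligand(ETHANOL_SDF + "$$$$\n" + ETHANOL_SDF + "$$$$\n")
        assert g.n_atoms == 3

    def test_missing_bond_block_falls_back_to_perception(self):
        no_bonds = (
            "two carbons\n  synthetic\n\n"
            "  2  0  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "    1.5400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "M  END\n"
        )
        with pytest.warns(UserWarning, match="perceiving bonds"):
            g = read_ligand(no_bonds)
        assert g.bonds == {(0, 1)}


def _carbon(name, xyz):
    return AtomRecord("C", name, np.array(xyz, dtype=float), False)


class TestPerceiveBonds:
    def test_typical_cc_distance_bonds(self):
        assert perceive_bonds([_carbon("C1", [0, 0, 0]), _carbon("C2", [1.54, 0, 0])]) == {(0, 1)}

    def test_distant_atoms_do_not_bond(self):
        assert perceive_bonds([_carbon("C1", [0, 0, 0]), _carbon("C2", [4.0, 0, 0])]) == set()

    def test_overlapping_atoms_do_not_bond(self):
        assert perceive_bonds([_carbon("C1", [0, 0, 0]), _carbon("C2", [0.1, 0, 0])]) == set()

    def test_ideal_benzene_has_12_bonds(self):
        # 6 ring C–C bonds plus 6 C–H bonds at standard geometry
        atoms = []
        for i in range(6):
            ang = np.radians(60 * i)
            atoms.append(_carbon(f"C{i+1}", [1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0]))
        for i in range(6):
            ang = np.radians(60 * i)
            atoms.append(AtomRecord("H", f"H{i+1}",
                                    np.array([2.48 * np.cos(ang), 2.48 * np.sin(ang), 0.0]), True))
        bonds = perceive_bonds(atoms)
        assert len(bonds) == 12
        ring = {b for b in bonds if max(b) < 6}
        assert len(ring) == 6

    def test_unknown_element_named_in_error(self):
        weird = AtomRecord("Xx", "X1", np.zeros(3), False)
        with pytest.raises(UnknownElementError, match="Xx"):
            perceive_bonds([weird])

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_atom_reordering(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 4, size=(6, 3))
        atoms = [_carbon(f"C{i}", coords[i]) for i in range(6)]
        perm = rng.permutation(6)
        shuffled = [atoms[i] for i in perm]
        direct = perceive_bonds(atoms)
        via_perm = {
            (min(perm[i], perm[j]), max(perm[i], perm[j]))
            for i, j in perceive_bonds(shuffled)
        }
        # map shuffled indices back: shuffled[k] is atoms[perm[k]]
        assert direct == via_perm


class TestReadRmsdSeries:
    XVG = "# comment\n@ title\n0.0 0.05\n1.0 0.12\n2.0 0.30\n"

    def test_nm_values_scaled_to_angstrom(self):
        s = read_rmsd_series(self.XVG, unit="nm")
        assert np.allclose(s.values, [0.5, 1.2, 3.0])

    def test_angstrom_identity(self):
        s = read_rmsd_series("t,r\n0.0,0.5\n1.0,1.2\n", unit="A")
        assert np.allclose(s.values, [0.5, 1.2])

    def test_nm_is_ten_times_angstrom(self):
        nm = read_rmsd_series(self.XVG, unit="nm")
        ang = read_rmsd_series(self.XVG, unit="A")
        assert np.allclose(nm.values, 10 * ang.values)

    def test_non_monotone_time_is_error(self):
        with pytest.raises(FormatError, match="strictly increasing"):
            read_rmsd_series("1.0 0.1\n0.5 0.2\n", unit="nm")

    def test_single_point_is_error(self):
        with pytest.raises(FormatError, match="at least 2"):
            read_rmsd_series("0.0 0.1\n", unit="nm")


class TestRmsdSeries:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            RmsdSeries("r", np.array([0.0, 1.0]), np.array([-0.1, 0.2]))

    def test_censored_from_must_index_series(self):
        with pytest.raises(ValueError):
            RmsdSeries("r", np.array([0.0, 1.0]), np.array([0.1, 0.2]), censored_from=5)
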