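"""Contact/H-bond detection and the key-residue score against planted pockets."""

import numpy as np
import pandas as pd
import pytest

from docktriage.interactions import (
    HBondCriteria,
    KeyResidueSpec,
    default_key_residues,
    detect_hbonds,
    find_close_contacts,
    key_residue_score,
    score_pose,
)
from docktriage.struct_io import AtomRecord, MolecularGraph, ReceptorStructure, ResidueKey, read_ligand, read_receptor
from docktriage.synthetic import make_pocket_fixture


def one_atom_ligand(xyz=(0.0, 0.0, 0.0)):
    return MolecularGraph(atoms=[AtomRecord("C", "C1", np.array(xyz), False)], bonds=set())


def one_atom_receptor(distance, resname="GLY", resnum=10):
    key = ResidueKey("A", resnum, "", resname)
    return ReceptorStructure(
        atoms=[AtomRecord("C", "CB", np.array([distance, 0.0, 0.0]), False, residue_key=key)]
    )


class TestFindCloseContacts:
    def test_atom_just_inside_cutoff_is_contact(self):
        df = find_close_contacts(one_atom_ligand(), one_atom_receptor(4.9), cutoff=5.0)
        assert len(df) == 1 and bool(df.iloc[0]["contact"])

    def test_atom_just_outside_cutoff_is_not_contact(self):
        df = find_close_contacts(one_atom_ligand(), one_atom_receptor(5.1), cutoff=5.0)
        assert len(df) == 1 and not bool(df.iloc[0]["contact"])
        assert df.iloc[0]["min_dist"] == pytest.approx(5.1)

    def test_residues_beyond_context_window_not_reported(self):
        df = find_close_contacts(one_atom_ligand(), one_atom_receptor(7.5), cutoff=5.0)
        assert len(df) == 0

    def test_empty_pose_is_error(self):
        empty = MolecularGraph(
            atoms=[AtomRecord("H", "H1", np.zeros(3), True)], bonds=set()
        )
        with pytest.raises(ValueError, match="no heavy atoms"):
            find_close_contacts(empty, one_atom_receptor(4.0))

    def test_contact_set_monotone_in_cutoff(self):
        bundle = make_pocket_fixture(6, 2, 4, seed=3)
        receptor = read_receptor(bundle.artifact[0])
        pose = read_ligand(bundle.artifact[1])
        small = find_close_contacts(pose, receptor, cutoff=4.0)
        large = find_close_contacts(pose, receptor, cutoff=6.0)
        inside_small = {r.residue for r in small.itertuples() if r.contact}
        inside_large = {r.residue for r in large.itertuples() if r.contact}
        assert inside_small <= inside_large


def donor_acceptor_system(angle_deg=170.0, ha_dist=1.9):
    """Ligand N–H donor aimed at a receptor carbonyl oxygen."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    theta = np.radians(180.0 - angle_deg)
    acceptor = h + ha_dist * np.array([np.cos(theta), np.sin(theta), 0.0])
    pose = MolecularGraph(
        atoms=[AtomRecord("N", "N1", n, False), AtomRecord("H", "H1", h, True)],
        bonds={(0, 1)},
    )
    key = ResidueKey("A", 75, "", "ASN")
    receptor = ReceptorStructure(
        atoms=[AtomRecord("O", "OD1", acceptor, False, residue_key=key)]
    )
    return pose, receptor


class TestDetectHbonds:
    def test_ideal_geometry_detected(self):
        pose, receptor = donor_acceptor_system(angle_deg=170.0)
        bonds = detect_hbonds(pose, receptor)
        assert len(bonds) == 1
        hb = bonds[0]
        assert hb.donor_side == "ligand"
        assert hb.ha_distance == pytest.approx(1.9, abs=1e-9)
        assert hb.dha_angle == pytest.approx(170.0, abs=1e-6)

    def test_bent_geometry_rejected(self):
        pose, receptor = donor_acceptor_system(angle_deg=90.0)
        assert detect_hbonds(pose, receptor) == []

    def test_long_ha_distance_rejected(self):
        pose, receptor = donor_acceptor_system(ha_dist=2.8)
        assert detect_hbonds(pose, receptor) == []

    def test_heavy_atom_fallback_without_hydrogens(self):
        key = ResidueKey("A", 80, "", "HIS")
        receptor = ReceptorStructure(
            atoms=[AtomRecord("N", "ND1", np.array([3.0, 0.0, 0.0]), False, residue_key=key)]
        )
        pose = MolecularGraph(atoms=[AtomRecord("O", "O1", np.zeros(3), False)], bonds=set())
        bonds = detect_hbonds(pose, receptor)
        assert len(bonds) == 1 and bonds[0].hydrogen_name is None
        strict = HBondCriteria(heavy_atom_fallback=False)
        assert detect_hbonds(pose, receptor, criteria=strict) == []

    def test_carbon_atoms_never_hbond(self):
        pose = one_atom_ligand()
        receptor = one_atom_receptor(2.8)
        assert detect_hbonds(pose, receptor) == []

    @pytest.mark.parametrize("n_hbonds", [0, 2, 4])
    def test_planted_hbond_residues_recovered(self, n_hbonds):
        bundle = make_pocket_fixture(6, n_hbonds, 3, seed=11)
        receptor = read_receptor(bundle.artifact[0])
        pose = read_ligand(bundle.artifact[1])
        found = {hb.residue for hb in detect_hbonds(pose, receptor)}
        assert found == set(bundle.ground_truth["hbond_residues"])


class TestKeyResidueScore:
    def test_no_contacts_scores_zero(self):
        spec = default_key_residues()
        empty = pd.DataFrame(columns=["residue", "min_dist", "contact"])
        report = key_residue_score(empty, [], spec)
        assert report.score == 0 and report.overlap == 0

    def test_all_nine_hbonded_under_default_weights(self):
        bundle = make_pocket_fixture(9, 9, 0, seed=5)
        receptor = read_receptor(bundle.artifact[0])
        pose = read_ligand(bundle.artifact[1])
        report = score_pose(pose, receptor)
        assert report.overlap == pytest.approx(1.0)
        assert report.score == pytest.approx(18.0)

    def test_mixed_engagement_weighting(self):
        # 3 H-bonded (weight 2) + 2 contact-only (weight 1) of 9 → score 8, overlap 5/9
        bundle = make_pocket_fixture(5, 3, 4, seed=9)
        receptor = read_receptor(bundle.artifact[0])
        pose = read_ligand(bundle.artifact[1])
        report = score_pose(pose, receptor)
        assert report.score == pytest.approx(8.0)
        assert report.overlap == pytest.approx(5 / 9)

    def test_invariant_to_key_list_order(self):
        bundle = make_pocket_fixture(7, 3, 2, seed=13)
        receptor = read_receptor(bundle.artifact[0])
        pose = read_ligand(bundle.artifact[1])
        spec = default_key_residues()
        reversed_spec = KeyResidueSpec(residues=spec.residues[::-1], contact_cutoff=5.0)
        a = score_pose(pose, receptor, spec)
        b = score_pose(pose, receptor, reversed_spec)
        assert a.score == b.score and a.overlap == b.overlap

    def test_missing_key_residue_warns_and_counts_absent(self):
        receptor = one_atom_receptor(4.0, resname="GLY", resnum=10)
        pose = one_atom_ligand()
        spec = KeyResidueSpec(residues=(("A", 10, "GLY"), ("A", 999, "TRP")))
        with pytest.warns(UserWarning, match="TRP"):
            report = score_pose(pose, receptor, spec)
        assert report.overlap == pytest.approx(0.5)
        assert report.score == pytest.approx(1.0)

    def test_score_bounded_by_hbond_weight_times_list(self):
        for seed in range(5):
            bundle = make_pocket_fixture(9, 4, 2, seed=seed)
            receptor = read_receptor(bundle.artifact[0])
            pose = read_ligand(bundle.artifact[1])
            report = score_pose(pose, receptor)
            assert 0 <= report.overlap <= 1
            assert report.score <= 2.0 * 9
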