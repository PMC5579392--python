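"""H-bond detection, Leontis-Westhof classification, methyl placement, Kabsch."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kturn_m6a import synthetic_data as syn
from kturn_m6a.structure_geometry import (
    NucleotideResidue,
    add_n6_methyl,
    base_plane_normal,
    clash_check,
    classify_pair,
    classify_structure,
    detect_sheared_GA,
    find_hbonds,
    forced_methyl_rotamer,
    read_structure,
    rmsd_between,
    superpose,
)


def _pairs_by_truth(residues_by_key, truth):
    for _, row in truth.iterrows():
        yield row, residues_by_key[("A", row.chain1_resnum)], residues_by_key[("B", row.chain2_resnum)]


def _rigid(residues, rot, trans):
    return [
        NucleotideResidue(r.chain, r.number, r.base_type,
                          {k: rot @ v + trans for k, v in r.atoms.items()})
        for r in residues
    ]


class TestReadStructure:
    def test_synthetic_duplex_round_trip(self, tmp_path, wc_duplex):
        by, _ = wc_duplex
        path = tmp_path / "duplex.pdb"
        syn.write_pdb(list(by.values()), path)
        parsed = read_structure(path)
        assert len(parsed) == 16
        assert not any(r.incomplete for r in parsed)
        # coordinates survive to PDB precision (1e-3 A)
        ref = by[("A", 1)]
        got = next(r for r in parsed if (r.chain, r.number) == ("A", 1))
        for name, xyz in ref.atoms.items():
            assert np.allclose(got.atoms[name], xyz, atol=2e-3)

    def test_star_dialect_normalized(self, tmp_path):
        pdb = (
            "ATOM      1  C1*   A A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  O2*   A A   1       1.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        path = tmp_path / "star.pdb"
        path.write_text(pdb)
        (res,) = read_structure(path)
        assert "C1'" in res.atoms and "O2'" in res.atoms
        assert res.incomplete  # base ring atoms absent

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        pdb = (
            "ATOM      1  C1'A  A A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  C1'B  A A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        (res,) = read_structure(path)
        assert res.atoms["C1'"][0] == pytest.approx(9.0)


class TestFindHbonds:
    def test_wc_pair_bonds_detected_with_distances(self, wc_duplex):
        by, _ = wc_duplex
        # step 5 is the U.A pair: N3-N1 and N6-O4
        bonds = find_hbonds([by[("A", 6)], by[("B", 3)]])
        pairs = {(b.donor_atom, b.acceptor_atom) for b in bonds if b.base_base}
        assert ("N3", "N1") in pairs and ("N6", "O4") in pairs

    def test_sorted_by_distance(self, sheared_duplex):
        by, _ = sheared_duplex
        bonds = find_hbonds(list(by.values()))
        dists = [b.distance for b in bonds]
        assert dists == sorted(dists)

    def test_cutoff_boundary_excludes(self):
        # two residues with a single N6...O4 contact placed just past the cutoff
        a = syn.nucleotide_template("A")
        u = {k: v * np.array([1.0, -1.0, -1.0]) for k, v in syn.nucleotide_template("U").items()}
        donor_acceptor = np.linalg.norm(a["N6"] - u["O4"])
        for stretch, expected in ((0.0, True), (3.51 / donor_acceptor, False)):
            shifted = {k: v + stretch * (u["O4"] - a["N6"]) for k, v in u.items()} if stretch else u
            r1 = NucleotideResidue("A", 1, "A", a)
            r2 = NucleotideResidue("B", 1, "U", shifted)
            got = {(b.donor_atom, b.acceptor_atom) for b in find_hbonds([r1, r2], d_max=3.5)}
            assert (("N6", "O4") in got) == expected

    def test_planted_sheared_contacts(self, sheared_duplex):
        by, truth = sheared_duplex
        row = truth[truth.true_class != "cis WC/WC"].iloc[0]
        a, g = by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)]
        bonds = {(b.donor_atom, b.acceptor_atom): b.distance for b in find_hbonds([a, g])}
        assert bonds[("N2", "N7")] == pytest.approx(2.8, abs=0.05)
        assert bonds[("N6", "N3")] == pytest.approx(3.4, abs=0.05)


class TestClassifyPair:
    def test_truth_recovered_on_clean_fixtures(self, wc_duplex, sheared_duplex):
        for fixture in (wc_duplex, sheared_duplex):
            by, truth = fixture
            for row, r1, r2 in _pairs_by_truth(by, truth):
                bp = classify_pair(r1, r2)
                if row.true_class == "cis WC/WC":
                    assert bp.class_label.startswith("cis WC/WC")
                    assert len([b for b in bp.hbonds if b.base_base]) >= 2
                else:
                    assert bp.orientation == "trans"
                    edges = {(bp.res1.parent_base, bp.edge1), (bp.res2.parent_base, bp.edge2)}
                    assert edges == {("G", "Sugar"), ("A", "Hoogsteen")}

    def test_displaced_g6ma_not_paired(self, displaced_duplex):
        by, truth = displaced_duplex
        row = truth[truth.true_class == "unpaired"].iloc[0]
        bp = classify_pair(by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)])
        assert not bp.paired and bp.class_label == "unpaired"
        # the adenine has translated away: former H-bond distances beyond 6 A
        a, g = by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)]
        assert np.linalg.norm(g.atoms["N2"] - a.atoms["N7"]) > 6.0
        assert np.linalg.norm(a.atoms["N6"] - g.atoms["N3"]) > 6.0
        # while N6 donates to the guanosine O2'
        assert np.linalg.norm(a.atoms["N6"] - g.atoms["O2'"]) == pytest.approx(2.8, abs=0.05)

    def test_rigid_invariance_of_labels_and_distances(self, sheared_duplex):
        by, truth = sheared_duplex
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 123.0], degrees=True).as_matrix()
        trans = np.array([13.0, -4.0, 77.0])
        moved = {(r.chain, r.number): m
                 for r, m in zip(by.values(), _rigid(list(by.values()), rot, trans))}
        for row, r1, r2 in _pairs_by_truth(by, truth):
            bp0 = classify_pair(r1, r2)
            bp1 = classify_pair(moved[("A", row.chain1_resnum)], moved[("B", row.chain2_resnum)])
            assert bp0.class_label == bp1.class_label
            d0 = sorted(b.distance for b in bp0.hbonds)
            d1 = sorted(b.distance for b in bp1.hbonds)
            assert np.allclose(d0, d1, atol=1e-9)

    def test_robust_to_noise_and_orientation(self):
        for seed in range(5):
            for cls in ("wc", "sheared_GA"):
                res, truth = syn.gen_duplex_coords(
                    syn.DuplexConfig(planted_class=cls, noise_sigma=0.2,
                                     random_orientation=True), seed=seed)
                by = {(r.chain, r.number): r for r in res}
                for row, r1, r2 in _pairs_by_truth(by, truth):
                    bp = classify_pair(r1, r2)
                    if row.true_class == "cis WC/WC":
                        assert bp.class_label.startswith("cis WC/WC")
                    else:
                        assert bp.orientation == "trans"
                        assert {(bp.res1.parent_base, bp.edge1),
                                (bp.res2.parent_base, bp.edge2)} == \
                            {("G", "Sugar"), ("A", "Hoogsteen")}

    def test_incomplete_residue_rejected(self):
        r = NucleotideResidue("A", 1, "A", {"C1'": np.zeros(3)}, incomplete=True)
        with pytest.raises(ValueError):
            classify_pair(r, r)


class TestDetectSheared:
    def test_kturn_core_fixture_two_tandem_pairs(self, tandem_duplex):
        residues, truth = tandem_duplex
        by = {(r.chain, r.number): r for r in residues}
        pairs = [classify_pair(by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)])
                 for _, row in truth.iterrows()]
        sheared, tandem = detect_sheared_GA(pairs)
        assert len(sheared) == 2 and tandem == 1

    def test_all_wc_duplex_empty(self, wc_duplex):
        by, truth = wc_duplex
        pairs = [classify_pair(by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)])
                 for _, row in truth.iterrows()]
        sheared, tandem = detect_sheared_GA(pairs)
        assert sheared == [] and tandem == 0

    def test_single_sheared_not_tandem(self, sheared_duplex):
        by, truth = sheared_duplex
        pairs = [classify_pair(by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)])
                 for _, row in truth.iterrows()]
        sheared, tandem = detect_sheared_GA(pairs)
        assert len(sheared) == 1 and tandem == 0


class TestMethylPlacement:
    def test_geometry_of_placed_carbon(self):
        res = NucleotideResidue("A", 1, "A", syn.nucleotide_template("A"))
        for rot in ("anti", "syn"):
            aug = add_n6_methyl(res, rot)
            cm = aug.atoms["CN6"]
            assert np.linalg.norm(cm - res.atoms["N6"]) == pytest.approx(1.45, abs=0.01)
            normal = base_plane_normal(res)
            ring_pt = res.atoms["N1"]
            assert abs(np.dot(cm - ring_pt, normal)) < 0.1

    def test_anti_and_syn_related_by_rotation(self):
        res = NucleotideResidue("A", 1, "A", syn.nucleotide_template("A"))
        n6 = res.atoms["N6"]
        v1 = add_n6_methyl(res, "anti").atoms["CN6"] - n6
        v2 = add_n6_methyl(res, "syn").atoms["CN6"] - n6
        ang = np.degrees(np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert ang == pytest.approx(120.0, abs=5.0)  # both slots at 120 deg from C6

    def test_non_adenine_rejected(self):
        res = NucleotideResidue("A", 1, "G", syn.nucleotide_template("G"))
        with pytest.raises(ValueError):
            add_n6_methyl(res, "anti")


class TestClashCheck:
    def test_sheared_fixture_clashes(self, sheared_duplex):
        by, truth = sheared_duplex
        row = truth[truth.true_class != "cis WC/WC"].iloc[0]
        a, g = by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)]
        # the N6-H slot pointing at G N3 carries the H-bond; the methyl is
        # forced into the other slot, against the guanosine ribose
        rot = forced_methyl_rotamer(a, g.atoms["N3"])
        dist, clashing, _ = clash_check(add_n6_methyl(a, rot), g)
        assert clashing and dist < 3.0

    def test_syn_slot_closer_than_anti_in_sheared_pair(self, sheared_duplex):
        by, truth = sheared_duplex
        row = truth[truth.true_class != "cis WC/WC"].iloc[0]
        a, g = by[("A", row.chain1_resnum)], by[("B", row.chain2_resnum)]
        d_syn, _, _ = clash_check(add_n6_methyl(a, "syn"), g)
        d_anti, _, _ = clash_check(add_n6_methyl(a, "anti"), g)
        assert d_syn < d_anti

    def test_wc_au_anti_methyl_clears(self, wc_duplex):
        by, truth = wc_duplex
        row = truth[(truth.base1 == "A") | (truth.base2 == "A")].iloc[0]
        a_key = ("A", row.chain1_resnum) if row.base1 == "A" else ("B", row.chain2_resnum)
        u_key = ("B", row.chain2_resnum) if row.base1 == "A" else ("A", row.chain1_resnum)
        dist, clashing, _ = clash_check(add_n6_methyl(by[a_key], "anti"), by[u_key])
        assert not clashing

    def test_distant_partner(self):
        a = NucleotideResidue("A", 1, "A", syn.nucleotide_template("A"))
        far = NucleotideResidue("B", 1, "G",
                                {k: v + np.array([100.0, 0, 0])
                                 for k, v in syn.nucleotide_template("G").items()})
        dist, clashing, _ = clash_check(add_n6_methyl(a, "syn"), far)
        assert dist > 90 and not clashing


class TestSuperpose:
    def test_self_superposition_identity(self):
        coords = np.array([v for v in syn.nucleotide_template("G").values()])
        sup = superpose(coords, coords)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_known_transform_recovered(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(12, 3)) * 5
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        trans = np.array([4.0, -2.0, 9.0])
        moved = coords @ rot.T + trans
        sup = superpose(coords, moved)
        assert np.allclose(sup.rotation, rot, atol=1e-8)
        assert np.allclose(sup.translation, trans, atol=1e-8)
        assert sup.rmsd < 1e-10
        assert np.allclose(np.linalg.det(sup.rotation), 1.0, atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        sup = superpose(a, b)
        rot_sp, _ = Rotation.align_vectors(b - b.mean(axis=0), a - a.mean(axis=0))
        assert np.allclose(sup.rotation, rot_sp.as_matrix(), atol=1e-8)

    def test_kabsch_beats_random_rotations(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        best = superpose(a, b).rmsd
        ca, cb = a - a.mean(axis=0), b - b.mean(axis=0)
        for _ in range(200):
            r = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31))))
            rmsd = np.sqrt(np.mean(np.sum((ca @ r.as_matrix().T - cb) ** 2, axis=1)))
            assert rmsd >= best - 1e-12

    def test_separate_rmsd_selection(self):
        rng = np.random.default_rng(1)
        fit_a = rng.normal(size=(10, 3))
        sel_a = rng.normal(size=(6, 3))
        rot = Rotation.from_rotvec([0.2, 0.4, -0.3]).as_matrix()
        trans = np.array([1.0, 2.0, 3.0])
        sup = superpose(fit_a, fit_a @ rot.T + trans)
        assert rmsd_between(sup, sel_a, sel_a @ rot.T + trans) < 1e-10

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
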