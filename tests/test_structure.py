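"""Ensemble parsing, distances, Shrake-Rupley SASA and crosslink checks."""

import math

import numpy as np
import pytest

from redoxswitch import structure as st
from conftest import make_pdb

ISO_C = 4 * math.pi * (st.VDW_RADII["C"] + 1.4) ** 2


class TestLoadEnsemble:
    def test_minimal_two_atom_file(self, two_atom_pdb):
        ens = st.load_ensemble(two_atom_pdb)
        assert len(ens) == 1
        assert len(ens.models[0]) == 2

    def test_multi_model_count_preserved(self, multimodel_pdb):
        ens = st.load_ensemble(multimodel_pdb)
        assert len(ens) == 3
        assert ens.lowest_energy is ens.models[0]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            st.load_ensemble(tmp_path / "nope.pdb")

    def test_heteroatoms_flagged_not_dropped(self, tmp_path):
        text = ("ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
                "  1.00  0.00           C\n"
                "HETATM    2 ZN    ZN A  90       5.000   0.000   0.000"
                "  1.00  0.00          ZN\nEND\n")
        p = tmp_path / "het.pdb"
        p.write_text(text)
        ens = st.load_ensemble(p)
        flags = {a.name: a.het for a in ens.models[0].atoms}
        assert flags["ZN"] and not flags["CA"]


class TestDistances:
    def test_identical_atom_is_zero(self, two_atom_pdb):
        m = st.load_ensemble(two_atom_pdb).models[0]
        assert st.atom_distance(m, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0

    def test_three_four_five(self, two_atom_pdb):
        m = st.load_ensemble(two_atom_pdb).models[0]
        assert st.atom_distance(m, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(5.0)

    def test_unresolved_selector(self, two_atom_pdb):
        m = st.load_ensemble(two_atom_pdb).models[0]
        with pytest.raises(KeyError):
            st.atom_distance(m, ("A", 1, "CA"), ("B", 9, "SG"))

    def test_rigid_transform_invariance(self, tmp_path):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 5, size=(4, 3))
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=7).as_matrix()
        shift = np.array([10.0, -3.0, 2.5])
        moved = pts @ rot.T + shift

        def write(points, name):
            model = {("A", i + 1, "GLY"): [("CA", "C", tuple(p))]
                     for i, p in enumerate(points)}
            p = tmp_path / name
            p.write_text(make_pdb([model]))
            return st.load_ensemble(p).models[0]

        m1, m2 = write(pts, "orig.pdb"), write(moved, "moved.pdb")
        for i in range(1, 4):
            d1 = st.atom_distance(m1, ("A", i, "CA"), ("A", i + 1, "CA"))
            d2 = st.atom_distance(m2, ("A", i, "CA"), ("A", i + 1, "CA"))
            # PDB coordinates quantize at 1e-3 A
            assert d1 == pytest.approx(d2, abs=5e-3)


class TestSasa:
    def test_isolated_atom_matches_closed_form(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(make_pdb([{("A", 1, "GLY"): [("CA", "C", (0, 0, 0))]}]))
        _, total = st.compute_sasa(st.load_ensemble(p).models[0], n_points=960)
        assert total == pytest.approx(ISO_C, rel=0.01)

    def test_far_separated_atoms_are_additive(self, tmp_path):
        p = tmp_path / "far.pdb"
        p.write_text(make_pdb([{("A", 1, "GLY"): [("CA", "C", (0, 0, 0))],
                                ("A", 2, "GLY"): [("CA", "C", (50, 0, 0))]}]))
        _, total = st.compute_sasa(st.load_ensemble(p).models[0], n_points=960)
        assert total == pytest.approx(2 * ISO_C, rel=0.01)

    def test_buried_atom_has_no_area(self, tmp_path):
        # central atom fully enclosed by an octahedral cage of sulfurs
        cage = [("S%d" % i, "S", pos) for i, pos in enumerate(
            [(2.2, 0, 0), (-2.2, 0, 0), (0, 2.2, 0), (0, -2.2, 0),
             (0, 0, 2.2), (0, 0, -2.2)])]
        p = tmp_path / "cage.pdb"
        p.write_text(make_pdb([{("A", 1, "CYS"): [("C", "C", (0, 0, 0))] + cage}]))
        per, _ = st.compute_sasa(st.load_ensemble(p).models[0], n_points=960)
        # per-residue value includes the cage; check the centre atom alone
        from redoxswitch.structure import _shrake_rupley
        coords = np.array([(0, 0, 0)] + [c[2] for c in cage], dtype=float)
        radii = np.array([st.VDW_RADII["C"]] + [st.VDW_RADII["S"]] * 6)
        areas = _shrake_rupley(coords, radii, 1.4, 960)
        assert areas[0] < 0.02 * ISO_C

    def test_sphere_point_convergence(self, tmp_path):
        rng = np.random.default_rng(11)
        coords = rng.normal(0, 3, size=(12, 3))
        from redoxswitch.structure import _shrake_rupley
        radii = np.full(12, st.VDW_RADII["C"])
        a1 = _shrake_rupley(coords, radii, 1.4, 960).sum()
        a4 = _shrake_rupley(coords, radii, 1.4, 3840).sum()
        assert abs(a4 / a1 - 1.0) < 0.005

    def test_agrees_with_independent_implementation(self):
        # cross-check against biotite's Shrake-Rupley on the same radii
        import biotite.structure as bst
        rng = np.random.default_rng(21)
        coords = rng.normal(0, 2.5, size=(10, 3))
        elements = np.array(["C", "N", "O", "S", "C", "N", "O", "C", "C", "N"])
        arr = bst.AtomArray(10)
        arr.coord = coords.astype(np.float32)
        arr.element = elements
        arr.res_id = np.arange(1, 11)
        arr.chain_id = np.full(10, "A")
        arr.atom_name = np.full(10, "X")
        arr.res_name = np.full(10, "GLY")
        ref = bst.sasa(arr, probe_radius=1.4, point_number=1000,
                       vdw_radii="Single").sum()
        from redoxswitch.structure import _shrake_rupley
        radii = np.array([st.VDW_RADII[e] for e in elements])
        mine = _shrake_rupley(coords, radii, 1.4, 1000).sum()
        assert mine == pytest.approx(ref, rel=0.03)

    def test_unknown_element_rejected(self, tmp_path):
        p = tmp_path / "weird.pdb"
        p.write_text(make_pdb([{("A", 1, "UNK"): [("XX", "XX", (0, 0, 0))]}]))
        with pytest.raises(KeyError):
            st.compute_sasa(st.load_ensemble(p).models[0])

    def test_ensemble_mean_and_sd(self, multimodel_pdb):
        ens = st.load_ensemble(multimodel_pdb)
        mean, sd = st.ensemble_sasa(ens, n_points=240)
        assert mean > 0 and sd >= 0


class TestCrosslinks:
    def test_close_link_satisfied(self, two_atom_pdb):
        m = st.load_ensemble(two_atom_pdb).models[0]
        rep = st.check_crosslinks(m, [st.Crosslink(("A", 1), ("A", 2), "BS2G")])
        assert rep.satisfied == [True]
        assert rep.fraction_satisfied == 1.0

    def test_absent_residue_unevaluable(self, two_atom_pdb):
        m = st.load_ensemble(two_atom_pdb).models[0]
        rep = st.check_crosslinks(m, [st.Crosslink(("A", 1), ("A", 99), "BS3")])
        assert rep.satisfied == [None]
        assert rep.n_unevaluable == 1

    def test_unknown_linker_rejected(self):
        with pytest.raises(ValueError):
            st.Crosslink(("A", 1), ("A", 2), "EDC").cutoff()

    def test_native_scores_above_decoy(self, tmp_path):
        # native-like fold keeps crosslinked residues compact; a stretched
        # decoy violates the same restraints
        n_res = 10
        native = {("A", i + 1, "GLY"): [("CA", "C", (3.0 * math.cos(i), 3.0 * math.sin(i), 0.5 * i))]
                  for i in range(n_res)}
        decoy = {("A", i + 1, "GLY"): [("CA", "C", (12.0 * i, 0.0, 0.0))]
                 for i in range(n_res)}
        links = [st.Crosslink(("A", 1), ("A", 6), "BS2G"),
                 st.Crosslink(("A", 2), ("A", 9), "BS3"),
                 st.Crosslink(("A", 3), ("A", 10), "BS3")]
        for name, model in (("native.pdb", native), ("decoy.pdb", decoy)):
            (tmp_path / name).write_text(make_pdb([model]))
        rep_n = st.check_crosslinks(
            st.load_ensemble(tmp_path / "native.pdb").models[0], links)
        rep_d = st.check_crosslinks(
            st.load_ensemble(tmp_path / "decoy.pdb").models[0], links)
        assert rep_n.fraction_satisfied == 1.0
        assert rep_n.fraction_satisfied > rep_d.fraction_satisfied
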